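"""Benchmark evaluation: affinity conversion, per-target R², reports.

Experimental affinities (Kd, Ki or IC50 in mol/L) are converted to binding
free energies via ΔG = R·T·ln(Ki_eff / 1 M) with R = 1.98720e-3
kcal/mol/K and T defaulting to 298.15 K. Kd and Ki are treated as
equivalent (competitive inhibition); IC50 approximates Ki as IC50/2
(substrate concentration near the Michaelis constant) — a linear map, so
correlations are unaffected.

Ranking quality is the squared Pearson correlation between score totals
and experimental ΔG within each target series; a method is summarized by
the unweighted mean (± population SD) and the minimum of the per-target
R² values. Series enter the benchmark only if their pKi range exceeds 1.5
and they contain at least 10 ligands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._data import GAS_CONSTANT_KCAL

DEFAULT_TEMPERATURE = 298.15  # K


@dataclass
class AffinityRecord:
    kind: str  # "Kd" | "Ki" | "IC50"
    value: float  # mol/L
    assay_pH: float | None = None
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        if self.kind not in ("Kd", "Ki", "IC50"):
            raise ValueError(f"unknown affinity kind {self.kind!r}")
        if not (self.value > 0):
            raise ValueError("affinity value must be positive")

    @property
    def ki_effective(self) -> float:
        return self.value / 2.0 if self.kind == "IC50" else self.value

    @property
    def pKi(self) -> float:
        return -math.log10(self.ki_effective)


def affinity_to_dG(record: AffinityRecord, T: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy in kcal/mol from a measured affinity."""
    return GAS_CONSTANT_KCAL * T * math.log(record.ki_effective)


def dG_to_Ki(dG: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of affinity_to_dG (used by the synthetic generator)."""
    return math.exp(dG / (GAS_CONSTANT_KCAL * T))


@dataclass
class TargetSeries:
    target_id: str
    ligand_ids: list[str]
    affinities: dict[str, AffinityRecord]
    crystal_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [lid for lid in self.ligand_ids if lid not in self.affinities]
        if missing:
            raise ValueError(f"{self.target_id}: ligands without affinity: {missing}")

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_crystals(self) -> int:
        return sum(bool(self.crystal_flags.get(lid, True)) for lid in self.ligand_ids)

    @property
    def pKi_range(self) -> float:
        p = [self.affinities[lid].pKi for lid in self.ligand_ids]
        return max(p) - min(p)


def pearson_r2(x, y) -> float:
    """Squared sample Pearson correlation; requires n ≥ 3 and variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("pearson_r2 needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def apply_inclusion_filters(series: list[TargetSeries], min_range: float = 1.5,
                            min_ligands: int = 10):
    """Keep series with pKi range > min_range and ≥ min_ligands ligands.

    Returns (included series, exclusion rows) where each exclusion row
    names the series and the reason.
    """
    included, excluded = [], []
    for s in series:
        if s.n_ligands < min_ligands:
            excluded.append({"target": s.target_id, "reason": "ligand count",
                             "value": s.n_ligands})
        elif not (s.pKi_range > min_range):
            excluded.append({"target": s.target_id, "reason": "pKi range",
                             "value": s.pKi_range})
        else:
            included.append(s)
    return included, excluded


def manifest_stats(series: list[TargetSeries]) -> dict[str, int]:
    """Dataset composition totals (complexes, crystals, modeled, targets)."""
    total = sum(s.n_ligands for s in series)
    crystals = sum(s.n_crystals for s in series)
    return {"total_complexes": total, "crystals": crystals,
            "modeled": total - crystals, "targets": len(series)}


@dataclass
class BenchmarkReport:
    per_target: pd.DataFrame  # columns: target, n, r2
    mean_r2: float
    sd_r2: float
    min_r2: float
    worst_target: str
    stats: dict[str, int]

    def to_markdown(self) -> str:
        lines = ["| target | n | R² |", "|---|---|---|"]
        for _, row in self.per_target.iterrows():
            lines.append(f"| {row['target']} | {row['n']} | {row['r2']:.2f} |")
        lines.append("")
        lines.append(f"Average R² = {self.mean_r2:.2f} ± {self.sd_r2:.2f}; "
                     f"minimum {self.min_r2:.2f} ({self.worst_target}). "
                     f"{self.stats['total_complexes']} complexes over "
                     f"{self.stats['targets']} targets "
                     f"({self.stats['crystals']} crystal, "
                     f"{self.stats['modeled']} modeled).")
        return "\n".join(lines)


def evaluate(score_table: pd.DataFrame, series: list[TargetSeries],
             T: float = DEFAULT_TEMPERATURE, min_points: int = 3,
             score_column: str = "total") -> BenchmarkReport:
    """Per-target R² of score vs experimental ΔG, plus aggregate statistics.

    The mean and population SD are unweighted over targets; undersized
    targets (fewer than ``min_points`` scored ligands) are dropped with a
    warning row rather than an error. A scored ligand with no affinity is
    an error.
    """
    scores = score_table.set_index("id")[score_column]
    rows = []
    for s in series:
        lids = [lid for lid in s.ligand_ids if lid in scores.index
                and pd.notna(scores.loc[lid])]
        for lid in scores.index:
            if lid in s.ligand_ids and lid not in s.affinities:
                raise KeyError(f"ligand {lid} has a score but no affinity")
        if len(lids) < min_points:
            rows.append({"target": s.target_id, "n": len(lids), "r2": np.nan,
                         "note": "excluded: too few scored ligands"})
            continue
        dg = [affinity_to_dG(s.affinities[lid], T) for lid in lids]
        sc = [float(scores.loc[lid]) for lid in lids]
        rows.append({"target": s.target_id, "n": len(lids),
                     "r2": pearson_r2(sc, dg), "note": ""})
    table = pd.DataFrame(rows, columns=["target", "n", "r2", "note"])
    valid = table.dropna(subset=["r2"])
    if valid.empty:
        raise ValueError("no target had enough scored ligands to evaluate")
    r2 = valid["r2"].to_numpy()
    worst = valid.loc[valid["r2"].idxmin(), "target"]
    return BenchmarkReport(
        per_target=table,
        mean_r2=float(r2.mean()),
        sd_r2=float(r2.std(ddof=0)),
        min_r2=float(r2.min()),
        worst_target=str(worst),
        stats=manifest_stats(series),
    )


# --------------------------------------------------------------------------
# dataset composition table (PL-REX)
# --------------------------------------------------------------------------

def load_plrex_composition() -> pd.DataFrame:
    """Published composition of the PL-REX benchmark (per-target counts).

    Columns: target, ligands, crystals, pki_range. Used for manifest
    arithmetic without downloading the structures themselves.
    """
    with resources.files("plscore.data").joinpath("plrex_composition.csv").open() as fh:
        return pd.read_csv(fh)


def composition_to_series(table: pd.DataFrame) -> list[TargetSeries]:
    """Expand a composition table into placeholder series.

    Each target gets synthetic ligand ids and affinities whose pKi values
    exactly span the tabulated range, with the tabulated crystal count;
    suitable for composition arithmetic and inclusion filtering only.
    """
    series = []
    for _, row in table.iterrows():
        n = int(row["ligands"])
        ncry = int(row["crystals"])
        lids = [f"{row['target']}_L{i:02d}" for i in range(n)]
        # pKi values spanning exactly the printed range (pKi = -log10 Ki)
        pki = np.linspace(5.0, 5.0 + float(row["pki_range"]), n)
        aff = {lid: AffinityRecord(kind="Ki", value=10.0 ** (-p))
               for lid, p in zip(lids, pki)}
        flags = {lid: (i < ncry) for i, lid in enumerate(lids)}
        series.append(TargetSeries(target_id=str(row["target"]), ligand_ids=lids,
                                   affinities=aff, crystal_flags=flags))
    return series
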