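"""Proton-transfer free-energy correction and ligand-entropy penalty.

When a ligand's protonation state changes upon binding, the score must pay
the free-energy cost of converting the solution-dominant species into the
bound form. Two acid-base reactions with water are considered:

    uptake:   L  + H2O -> LH+ + OH-     (ligand is protonated on binding)
    release:  LH + H2O -> L-  + H3O+    (ligand is deprotonated on binding)

The reaction free energy is weighted by the solution fraction of the
species that must change protonation, from the rearranged
Henderson-Hasselbalch equation

    f(pH, pKa) = 10^(pH-pKa) / (1 + 10^(pH-pKa))   (deprotonated fraction)

so the uptake term is f·ΔG_rxn and the release term is (1−f)·ΔG_rxn.
Ligand-species free energies come from the energy backend (gas + solvation
at the relaxed free-ligand geometry); the water-species free energies
combine a computed gas-phase enthalpy with an experimental solvation free
energy and must be supplied in configuration — no defaults are invented.

The conformational-entropy penalty defaults to 1 kcal/mol per rotatable
bond (reported as the positive −TΔS contribution to the score); a plugin
hook accepts descriptor-based estimators instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .structio import Molecule, count_rotatable_bonds

UPTAKE = "uptake"
RELEASE = "release"
NONE = "none"


@dataclass
class SpeciesFreeEnergies:
    """Free energies (kcal/mol) of the species entering the reactions.

    Only the fields needed for the active direction must be present:
    uptake needs G_L, G_LHplus, G_H2O, G_OHminus; release needs G_LH,
    G_Lminus, G_H2O, G_H3Oplus.
    """

    G_L: float | None = None
    G_LH: float | None = None
    G_LHplus: float | None = None
    G_Lminus: float | None = None
    G_H2O: float | None = None
    G_OHminus: float | None = None
    G_H3Oplus: float | None = None


@dataclass
class ProtonationCase:
    direction: str = NONE  # "uptake" | "release" | "none"
    pKa: float | None = None
    pH: float | None = None
    species_G: SpeciesFreeEnergies = field(default_factory=SpeciesFreeEnergies)

    def __post_init__(self) -> None:
        if self.direction not in (UPTAKE, RELEASE, NONE):
            raise ValueError(f"unknown protonation direction {self.direction!r}")


def deprotonated_fraction(pH: float, pKa: float) -> float:
    """Solution fraction of the deprotonated species; in [0, 1].

    Strictly increasing in pH; 0.5 at pH = pKa.
    """
    import math
    if not (math.isfinite(pH) and math.isfinite(pKa)):
        raise ValueError("pH and pKa must be finite")
    x = 10.0 ** (pH - pKa)
    return x / (1.0 + x)


def proton_transfer_term(case: ProtonationCase) -> float:
    """Protonation-change free energy dG_H+ in kcal/mol (0 when unchanged)."""
    if case.direction == NONE:
        return 0.0
    if case.pH is None or case.pKa is None:
        raise ValueError("pH and pKa are required when the protonation changes")
    f = deprotonated_fraction(case.pH, case.pKa)
    g = case.species_G

    def need(value: float | None, name: str) -> float:
        if value is None:
            raise ValueError(f"missing species free energy {name} for "
                             f"direction {case.direction}")
        return value

    if case.direction == UPTAKE:
        rxn = (need(g.G_LHplus, "G_LHplus") - need(g.G_L, "G_L")
               + need(g.G_OHminus, "G_OHminus") - need(g.G_H2O, "G_H2O"))
        return f * rxn
    rxn = (need(g.G_Lminus, "G_Lminus") - need(g.G_LH, "G_LH")
           + need(g.G_H3Oplus, "G_H3Oplus") - need(g.G_H2O, "G_H2O"))
    return (1.0 - f) * rxn


@dataclass
class EntropyModel:
    """Ligand conformational-entropy penalty model.

    ``per_rotatable_bond`` charges ``penalty_per_bond`` (default
    1.0 kcal/mol) per rotatable bond. ``plugin`` delegates to a callable
    ``molecule -> kcal/mol`` (descriptor-based estimators plug in here).
    """

    kind: str = "per_rotatable_bond"
    penalty_per_bond: float = 1.0
    plugin: Callable[[Molecule], float] | None = None

    def __post_init__(self) -> None:
        if self.penalty_per_bond < 0:
            raise ValueError("penalty_per_bond must be non-negative")
        if self.kind not in ("per_rotatable_bond", "plugin"):
            raise ValueError(f"unknown entropy model kind {self.kind!r}")
        if self.kind == "plugin" and self.plugin is None:
            raise ValueError("plugin entropy model needs a callable")


def entropy_penalty(ligand: Molecule, model: EntropyModel | None = None) -> float:
    """-TΔS contribution in kcal/mol, reported positive for binding."""
    model = model or EntropyModel()
    if model.kind == "plugin":
        try:
            value = float(model.plugin(ligand))
        except Exception as exc:
            raise RuntimeError(f"entropy plugin failed: {exc}") from exc
        import math
        if not math.isfinite(value):
            raise RuntimeError("entropy plugin returned a non-finite value")
        return value
    if model.penalty_per_bond == 0.0:
        return 0.0
    return model.penalty_per_bond * count_rotatable_bonds(ligand)
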