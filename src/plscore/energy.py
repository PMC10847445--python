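"""Energy backends and the per-complex energy terms.

A scoring backend is any object mapping (atoms, coordinates, net charge,
solvated flag) to a gas-phase energy and a solvation free energy, both in
kcal/mol. The production target of that contract is an external
semiempirical engine (rendered to / parsed from MOPAC-style text files);
a self-contained classical backend (Lennard-Jones + Coulomb + Born-like
solvation with analytic gradients) ships for testing the full pipeline.
The classical backend is a deliberately simple surrogate and is not a
physical substitute for a quantum-chemical treatment.

The three structure-derived score terms are computed here:

    interaction energy   dE_int   = E_gas(PL) - E_gas(P) - E_gas(L)
    desolvation penalty  ddG_solv = G_solv(PL) - G_solv(P) - G_solv(L)
    ligand strain        dG_conf  = G(bound geometry) - G(relaxed geometry)

all evaluated at the fixed complex geometry (the relaxed geometry of the
free ligand comes from a local gradient optimization in solvent).

A pairwise dispersion correction with Becke-Johnson damping is provided,
with default damping parameters s8 = 0.9220, a1 = 0.3419, a2 = 5.2955
(s6 fixed at 1.0). Dispersion works in atomic units internally
(Ha, bohr) and converts to kcal/mol at the surface.
"""

from __future__ import annotations

import hashlib
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform

from ._data import (
    ANGSTROM_TO_BOHR,
    BORN_RADII,
    COULOMB_KCAL,
    DISPERSION_ELEMENTS,
    HARTREE_TO_KCAL,
    LJ_PARAMS,
    builtin_c6c8,
)
from .pocket import PocketModel
from .structio import Molecule


class BackendError(RuntimeError):
    """Backend evaluation failure."""


class RelaxationError(RuntimeError):
    """Geometry optimization failed to converge."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


# --------------------------------------------------------------------------
# system container
# --------------------------------------------------------------------------

@dataclass
class System:
    """Flat atomistic system handed to energy backends."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3) Å
    charges: np.ndarray  # (N,) e — point charges used by classical backends
    net_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if len(self.elements) != len(self.coords) or len(self.charges) != len(self.coords):
            raise ValueError("elements/coords/charges length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "System":
        return System(self.elements, np.asarray(coords, dtype=float),
                      self.charges.copy(), self.net_charge)

    @classmethod
    def from_molecule(cls, mol: Molecule) -> "System":
        charges = [a.partial_charge if a.partial_charge is not None
                   else float(a.formal_charge) for a in mol.atoms]
        return cls(tuple(mol.elements), mol.coords, np.array(charges), mol.net_charge)

    @classmethod
    def from_pocket(cls, model: PocketModel) -> "System":
        atoms = model.all_atoms()
        charges = [a.partial_charge if a.partial_charge is not None
                   else float(a.formal_charge) for a in atoms]
        coords = np.array([a.coords for a in atoms])
        return cls(tuple(a.element for a in atoms), coords, np.array(charges),
                   model.net_charge)


def combine(a: System, b: System) -> System:
    return System(a.elements + b.elements,
                  np.vstack([a.coords, b.coords]),
                  np.concatenate([a.charges, b.charges]),
                  a.net_charge + b.net_charge)


@dataclass
class EnergyResult:
    e_gas: float
    g_solv: float | None = None
    converged: bool = True
    meta: str = ""

    @property
    def total(self) -> float:
        return self.e_gas + (self.g_solv or 0.0)


class EnergyBackend:
    """Contract: deterministic energies (and optionally gradients)."""

    has_gradient = False
    has_solvation = False

    def evaluate(self, system: System, solvated: bool = False) -> EnergyResult:
        raise NotImplementedError

    def gradient(self, system: System, solvated: bool = False) -> np.ndarray:
        raise NotImplementedError("backend does not provide gradients")


# --------------------------------------------------------------------------
# dispersion (pairwise, BJ damping)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionParams:
    s6: float = 1.0
    s8: float = 0.9220
    a1: float = 0.3419
    a2: float = 5.2955  # bohr

    def __post_init__(self) -> None:
        if self.a2 <= 0 or self.s8 < 0:
            raise ValueError("require a2 > 0 and s8 >= 0")


class CoefficientTable:
    """Per-pair C6 (Ha·bohr^6) and C8 (Ha·bohr^8) dispersion coefficients."""

    def __init__(self, pairs: dict[tuple[str, str], tuple[float, float]]):
        self._pairs: dict[tuple[str, str], tuple[float, float]] = {}
        for (a, b), (c6, c8) in pairs.items():
            if c6 <= 0 or c8 <= 0:
                raise ValueError(f"non-positive coefficient for pair {(a, b)}")
            self._pairs[(a, b)] = (c6, c8)
            self._pairs[(b, a)] = (c6, c8)

    def get(self, elem_a: str, elem_b: str) -> tuple[float, float]:
        try:
            return self._pairs[(elem_a, elem_b)]
        except KeyError:
            raise KeyError(
                f"no dispersion coefficients for pair {elem_a}-{elem_b}") from None

    @classmethod
    def builtin(cls) -> "CoefficientTable":
        elems = sorted(DISPERSION_ELEMENTS)
        pairs = {}
        for i, a in enumerate(elems):
            for b in elems[i:]:
                pairs[(a, b)] = builtin_c6c8(a, b)
        return cls(pairs)

    @classmethod
    def from_tsv(cls, text: str) -> "CoefficientTable":
        pairs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, c6, c8 = line.split("\t")[:4]
            pairs[(a, b)] = (float(c6), float(c8))
        return cls(pairs)

    def to_tsv(self) -> str:
        seen = set()
        lines = ["#elemA\telemB\tC6_Ha_bohr6\tC8_Ha_bohr8"]
        for (a, b), (c6, c8) in sorted(self._pairs.items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            lines.append(f"{a}\t{b}\t{c6:.6f}\t{c8:.6f}")
        return "\n".join(lines) + "\n"


def d3bj_pair_energy(elem_a: str, elem_b: str, r: float,
                     params: DispersionParams | None = None,
                     table: CoefficientTable | None = None) -> float:
    """BJ-damped pair dispersion energy in Ha at separation r (bohr).

    E = -s6·C6/(r^6 + f0^6) - s8·C8/(r^8 + f0^8),  f0 = a1·sqrt(C8/C6) + a2.
    Finite at r = 0 by construction of the damping radius f0.
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    params = params or DispersionParams()
    table = table or CoefficientTable.builtin()
    c6, c8 = table.get(elem_a, elem_b)
    f0 = params.a1 * np.sqrt(c8 / c6) + params.a2
    return float(-params.s6 * c6 / (r ** 6 + f0 ** 6)
                 - params.s8 * c8 / (r ** 8 + f0 ** 8))


def dispersion_energy(system: System,
                      params: DispersionParams | None = None,
                      table: CoefficientTable | None = None,
                      groups: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Sum of BJ-damped pair energies, in kcal/mol.

    ``groups=None`` sums all pairs; ``groups=(idx_a, idx_b)`` restricts to
    cross-group (intermolecular) pairs and rejects overlapping groups.
    """
    params = params or DispersionParams()
    table = table or CoefficientTable.builtin()
    n = len(system)
    if n < 2:
        return 0.0
    coords_bohr = system.coords * ANGSTROM_TO_BOHR
    if groups is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        idx_a = np.asarray(groups[0], dtype=int)
        idx_b = np.asarray(groups[1], dtype=int)
        if np.intersect1d(idx_a, idx_b).size:
            raise ValueError("intermolecular groups overlap")
        pairs = [(int(i), int(j)) for i in idx_a for j in idx_b]
    total_ha = 0.0
    for i, j in pairs:
        r = float(np.linalg.norm(coords_bohr[i] - coords_bohr[j]))
        total_ha += d3bj_pair_energy(system.elements[i], system.elements[j],
                                     r, params, table)
    return total_ha * HARTREE_TO_KCAL


# --------------------------------------------------------------------------
# classical test backend
# --------------------------------------------------------------------------

@dataclass
class TestBackendConfig:
    """Parameters of the classical surrogate backend.

    Gas phase: 12-6 Lennard-Jones (Lorentz-Berthelot combination) plus
    Coulomb point charges (332.0636 kcal·Å/mol/e²), optionally plus the
    BJ-damped dispersion term. Solvation: a Born-like polar term whose
    effective radius grows with local atom density (burial raises the
    solvation energy → positive desolvation penalty for charges) and a
    surface term favorable in proportion to solvent exposure.
    """

    lj_params: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(LJ_PARAMS))
    born_radii: dict[str, float] = field(default_factory=lambda: dict(BORN_RADII))
    dielectric: float = 78.4
    use_lj: bool = True
    include_dispersion: bool = False
    dispersion_params: DispersionParams = field(default_factory=DispersionParams)
    burial_width: float = 3.5       # Å, Gaussian width of the density counter
    burial_scale: float = 0.2       # Born-radius growth per density unit
    surface_tension: float = 0.010  # kcal/mol/Å², exposure term
    surface_density: float = 6.0    # density scale of the exposure decay


class ClassicalTestBackend(EnergyBackend):
    """Self-contained classical backend with analytic gradients.

    Deterministic, size-consistent (all terms are pairwise or local-density
    functions that vanish between distant fragments) and fast enough for
    property tests. Not a physical substitute for a quantum-chemical
    backend — its role is to exercise the scoring pipeline end to end.
    """

    has_gradient = True
    has_solvation = True

    def __init__(self, config: TestBackendConfig | None = None):
        self.config = config or TestBackendConfig()
        self._table = CoefficientTable.builtin()

    # -- parameter lookup ---------------------------------------------------

    def _lj(self, elements: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        sig, eps = [], []
        for e in elements:
            if e not in cfg.lj_params:
                raise BackendError(f"no Lennard-Jones parameters for element {e}")
            s, p = cfg.lj_params[e]
            sig.append(s)
            eps.append(p)
        return np.array(sig), np.array(eps)

    def _born(self, elements: tuple[str, ...]) -> np.ndarray:
        cfg = self.config
        out = []
        for e in elements:
            if e not in cfg.born_radii:
                raise BackendError(f"no Born radius for element {e}")
            out.append(cfg.born_radii[e])
        return np.array(out)

    # -- energies ------------------------------------------------------------

    def _pair_matrices(self, system: System):
        n = len(system)
        d = squareform(pdist(system.coords)) if n > 1 else np.zeros((1, 1))
        np.fill_diagonal(d, np.inf)
        return d

    def _gas_energy(self, system: System, d: np.ndarray) -> float:
        cfg = self.config
        n = len(system)
        if n < 2:
            return 0.0
        e = 0.0
        q = system.charges
        e += 0.5 * COULOMB_KCAL * float(np.sum(np.outer(q, q) / d))
        if cfg.use_lj:
            sig, eps = self._lj(system.elements)
            sij = 0.5 * (sig[:, None] + sig[None, :])
            eij = np.sqrt(np.outer(eps, eps))
            x6 = (sij / d) ** 6
            e += 0.5 * float(np.sum(4.0 * eij * (x6 ** 2 - x6)))
        if cfg.include_dispersion:
            e += dispersion_energy(system, cfg.dispersion_params, self._table)
        return e

    def _solvation_energy(self, system: System, d: np.ndarray) -> float:
        cfg = self.config
        tau = 1.0 - 1.0 / cfg.dielectric
        a = self._born(system.elements)
        g = np.exp(-(d / cfg.burial_width) ** 2)
        np.fill_diagonal(g, 0.0)
        dens = g.sum(axis=1)
        b_eff = a * (1.0 + cfg.burial_scale * dens)
        polar = -0.5 * COULOMB_KCAL * tau * float(np.sum(system.charges ** 2 / b_eff))
        area = 4.0 * np.pi * (a + 1.4) ** 2
        surface = -cfg.surface_tension * float(
            np.sum(area * np.exp(-dens / cfg.surface_density)))
        return polar + surface

    def evaluate(self, system: System, solvated: bool = False) -> EnergyResult:
        d = self._pair_matrices(system)
        e_gas = self._gas_energy(system, d)
        g_solv = self._solvation_energy(system, d) if solvated else None
        return EnergyResult(e_gas=e_gas, g_solv=g_solv,
                            meta="classical test backend (LJ+Coulomb+Born-like)")

    # -- analytic gradient ----------------------------------------------------

    def gradient(self, system: System, solvated: bool = False) -> np.ndarray:
        cfg = self.config
        n = len(system)
        grad = np.zeros((n, 3))
        if n < 2:
            return grad
        coords = system.coords
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.sum(diff ** 2, axis=-1))
        np.fill_diagonal(d, np.inf)
        q = system.charges

        # dE/dr for each pair, then chain rule through r
        dEdr = -COULOMB_KCAL * np.outer(q, q) / d ** 2
        if cfg.use_lj:
            sig, eps = self._lj(system.elements)
            sij = 0.5 * (sig[:, None] + sig[None, :])
            eij = np.sqrt(np.outer(eps, eps))
            dEdr += 4.0 * eij * (-12.0 * sij ** 12 / d ** 13 + 6.0 * sij ** 6 / d ** 7)
        if cfg.include_dispersion:
            p = cfg.dispersion_params
            for i in range(n):
                for j in range(i + 1, n):
                    c6, c8 = self._table.get(system.elements[i], system.elements[j])
                    f0 = p.a1 * np.sqrt(c8 / c6) + p.a2
                    rb = d[i, j] * ANGSTROM_TO_BOHR
                    dd = (p.s6 * c6 * 6 * rb ** 5 / (rb ** 6 + f0 ** 6) ** 2
                          + p.s8 * c8 * 8 * rb ** 7 / (rb ** 8 + f0 ** 8) ** 2)
                    # Ha/bohr → kcal/mol/Å
                    val = dd * HARTREE_TO_KCAL * ANGSTROM_TO_BOHR
                    dEdr[i, j] += val
                    dEdr[j, i] += val

        if solvated:
            tau = 1.0 - 1.0 / cfg.dielectric
            a = self._born(system.elements)
            g = np.exp(-(d / cfg.burial_width) ** 2)
            np.fill_diagonal(g, 0.0)
            dens = g.sum(axis=1)
            b_eff = a * (1.0 + cfg.burial_scale * dens)
            # dG/d(dens_i)
            dG_ddens = (0.5 * COULOMB_KCAL * tau * q ** 2 * a * cfg.burial_scale
                        / b_eff ** 2)
            area = 4.0 * np.pi * (a + 1.4) ** 2
            dG_ddens += (cfg.surface_tension * area
                         * np.exp(-dens / cfg.surface_density) / cfg.surface_density)
            # d(g_ij)/dr = -2 r / w^2 · g_ij ; contributes to dens_i and dens_j
            d_fin = np.where(np.isfinite(d), d, 0.0)
            coef = (dG_ddens[:, None] + dG_ddens[None, :]) * (
                -2.0 * d_fin / cfg.burial_width ** 2) * g
            dEdr += coef

        with np.errstate(invalid="ignore"):
            unit = diff / d[..., None]
        unit = np.nan_to_num(unit)
        grad = np.sum(dEdr[..., None] * unit, axis=1)
        return grad


def make_test_backend(config: TestBackendConfig | dict | None = None) -> ClassicalTestBackend:
    """Construct the classical test backend from a config (or defaults)."""
    if isinstance(config, dict):
        config = TestBackendConfig(**config)
    return ClassicalTestBackend(config)


# --------------------------------------------------------------------------
# caching wrapper
# --------------------------------------------------------------------------

class CachingBackend(EnergyBackend):
    """Memoizes evaluate/gradient on (elements, coords, charge, flag).

    Makes batch scoring resumable and lets tests count true backend calls.
    """

    def __init__(self, backend: EnergyBackend):
        self.backend = backend
        self.has_gradient = backend.has_gradient
        self.has_solvation = backend.has_solvation
        self._energy_cache: dict[str, EnergyResult] = {}
        self._grad_cache: dict[str, np.ndarray] = {}
        self.n_evaluate_calls = 0
        self.n_gradient_calls = 0

    @staticmethod
    def _key(system: System, solvated: bool, kind: str) -> str:
        h = hashlib.sha256()
        h.update(kind.encode())
        h.update(",".join(system.elements).encode())
        h.update(np.round(system.coords, 10).tobytes())
        h.update(np.round(system.charges, 10).tobytes())
        h.update(str((system.net_charge, solvated)).encode())
        return h.hexdigest()

    def evaluate(self, system: System, solvated: bool = False) -> EnergyResult:
        key = self._key(system, solvated, "e")
        if key not in self._energy_cache:
            self.n_evaluate_calls += 1
            self._energy_cache[key] = self.backend.evaluate(system, solvated)
        return self._energy_cache[key]

    def gradient(self, system: System, solvated: bool = False) -> np.ndarray:
        key = self._key(system, solvated, "g")
        if key not in self._grad_cache:
            self.n_gradient_calls += 1
            self._grad_cache[key] = self.backend.gradient(system, solvated)
        return self._grad_cache[key].copy()


# --------------------------------------------------------------------------
# score energy terms
# --------------------------------------------------------------------------

def _check_union(complex_system: System, receptor: System, ligand: System) -> None:
    if complex_system.elements != receptor.elements + ligand.elements:
        raise ValueError("complex is not the receptor+ligand atom union (elements)")
    stacked = np.vstack([receptor.coords, ligand.coords])
    if not np.allclose(complex_system.coords, stacked, atol=1e-8):
        raise ValueError("complex coordinates differ from receptor+ligand union")


def interaction_energy(backend: EnergyBackend, complex_system: System,
                       receptor: System, ligand: System) -> float:
    """Gas-phase interaction energy at the fixed complex geometry."""
    _check_union(complex_system, receptor, ligand)
    e_pl = backend.evaluate(complex_system, solvated=False).e_gas
    e_p = backend.evaluate(receptor, solvated=False).e_gas
    e_l = backend.evaluate(ligand, solvated=False).e_gas
    return e_pl - e_p - e_l


def desolvation_penalty(backend: EnergyBackend, complex_system: System,
                        receptor: System, ligand: System) -> float:
    """Change of solvation free energy upon complex formation."""
    if not backend.has_solvation:
        raise BackendError("backend does not provide solvation energies")
    _check_union(complex_system, receptor, ligand)
    parts = []
    for sys_ in (complex_system, receptor, ligand):
        res = backend.evaluate(sys_, solvated=True)
        if res.g_solv is None:
            raise BackendError("backend returned no solvation energy")
        parts.append(res.g_solv)
    return parts[0] - parts[1] - parts[2]


def relax(backend: EnergyBackend, system: System,
          frozen_mask: np.ndarray | None = None,
          tol: float = 0.1, max_steps: int = 2000,
          solvated: bool = True) -> System:
    """Local geometry optimization (quasi-Newton, line-searched).

    Minimizes E_gas (+ G_solv when ``solvated``) over the unfrozen atoms
    until the largest per-atom gradient norm drops to ``tol`` kcal/mol/Å.
    Frozen atoms are returned bit-identical; energy never increases across
    accepted steps (enforced by the line search).
    """
    if not backend.has_gradient:
        raise BackendError("backend does not provide gradients (required by relax)")
    n = len(system)
    frozen = (np.zeros(n, dtype=bool) if frozen_mask is None
              else np.asarray(frozen_mask, dtype=bool))
    if frozen.shape != (n,):
        raise ValueError("frozen_mask length mismatch")
    free = ~frozen
    if not free.any():
        return system.with_coords(system.coords)

    def grad_ok(g: np.ndarray) -> bool:
        return float(np.linalg.norm(g[free], axis=1).max()) <= tol

    g0 = backend.gradient(system, solvated=solvated)
    if grad_ok(g0):
        return system.with_coords(system.coords)

    base = system.coords.copy()
    trace: list[float] = []

    def unpack(x: np.ndarray) -> np.ndarray:
        coords = base.copy()
        coords[free] = x.reshape(-1, 3)
        return coords

    def fun(x: np.ndarray):
        sys_x = system.with_coords(unpack(x))
        res = backend.evaluate(sys_x, solvated=solvated)
        e = res.total if solvated else res.e_gas
        g = backend.gradient(sys_x, solvated=solvated)
        trace.append(e)
        return e, g[free].ravel()

    out = minimize(fun, base[free].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_steps, "gtol": tol * 1e-3,
                            "ftol": 1e-14, "maxls": 60})
    relaxed = system.with_coords(unpack(out.x))
    g_final = backend.gradient(relaxed, solvated=solvated)
    if not grad_ok(g_final):
        raise RelaxationError(
            f"relaxation not converged after {out.nit} steps "
            f"(max |g| = {np.linalg.norm(g_final[free], axis=1).max():.4g} "
            f"> tol {tol} kcal/mol/Å)", trace)
    relaxed.coords[frozen] = system.coords[frozen]
    return relaxed


def ligand_strain(backend: EnergyBackend, ligand_bound: System,
                  tol: float = 0.1, max_steps: int = 2000) -> float:
    """Ligand conformational strain: G(bound pose) - G(relaxed pose).

    Both evaluations are gas + solvation; the relaxed pose is obtained by
    local optimization in solvent starting from the bound geometry.
    """
    if not backend.has_solvation:
        raise BackendError("ligand strain needs a solvation-capable backend")
    relaxed = relax(backend, ligand_bound, tol=tol, max_steps=max_steps,
                    solvated=True)
    g_bound = backend.evaluate(ligand_bound, solvated=True).total
    g_relaxed = backend.evaluate(relaxed, solvated=True).total
    return g_bound - g_relaxed


# --------------------------------------------------------------------------
# external-engine text interface (MOPAC-style dialect)
# --------------------------------------------------------------------------

@dataclass
class EngineSettings:
    method: str = "PM6"
    single_point: bool = True
    solvated: bool = False
    dielectric: float = 78.4
    mozyme_threshold: int = 300
    title: str = ""


def render_engine_input(system: System, settings: EngineSettings | None = None,
                        frozen_mask: np.ndarray | None = None) -> str:
    """Render an engine input deck (keyword line + Cartesian block).

    Bit-stable: identical system and settings produce identical text.
    Large systems (atom count above the MOZYME threshold) request the
    linear-scaling localized-orbital SCF.
    """
    settings = settings or EngineSettings()
    n = len(system)
    frozen = (np.zeros(n, dtype=bool) if frozen_mask is None
              else np.asarray(frozen_mask, dtype=bool))
    for e in system.elements:
        if not e or not e[0].isalpha():
            raise ValueError(f"unknown element {e!r}")
    tokens = [settings.method]
    if settings.single_point:
        tokens.append("1SCF")
    tokens.append(f"CHARGE={system.net_charge}")
    if n > settings.mozyme_threshold:
        tokens.append("MOZYME")
    if settings.solvated:
        tokens.append(f"EPS={settings.dielectric:g}")
    lines = [" ".join(tokens), settings.title, ""]
    for elem, xyz, fz in zip(system.elements, system.coords, frozen):
        flag = 0 if fz else 1
        lines.append(f"{elem:<2s} {xyz[0]:>15.8f} {flag} {xyz[1]:>15.8f} {flag} "
                     f"{xyz[2]:>15.8f} {flag}")
    return "\n".join(lines) + "\n"


_HEAT_RE = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL")
_SOLV_RE = re.compile(r"SOLVATION (?:FREE )?ENERGY\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL")
_DONE_MARKERS = ("== MOPAC DONE ==", "JOB ENDED NORMALLY")
_ERROR_MARKERS = ("EXCESS NUMBER OF OPTIMIZATION CYCLES", "CALCULATION ABANDONED",
                  "UNABLE TO ACHIEVE SELF-CONSISTENCE", "ERROR")


def parse_engine_output(text: str) -> EnergyResult:
    """Extract the final heat of formation (and solvation energy if printed).

    A log carrying an error marker yields a non-converged result with the
    marker recorded in ``meta``; a log with no energy line is a hard error.
    """
    error = next((m for m in _ERROR_MARKERS if m in text), None)
    heats = _HEAT_RE.findall(text)
    if not heats:
        if error:
            return EnergyResult(e_gas=float("nan"), converged=False,
                                meta=f"engine error: {error}")
        raise ValueError("engine log contains no final heat of formation")
    e_gas = float(heats[-1])
    solv = _SOLV_RE.findall(text)
    g_solv = float(solv[-1]) if solv else None
    done = any(m in text for m in _DONE_MARKERS)
    return EnergyResult(e_gas=e_gas, g_solv=g_solv,
                        converged=done and error is None,
                        meta=f"engine error: {error}" if error else "engine log")


def solvation_free_energy(gas: EnergyResult, solvated: EnergyResult) -> float:
    """g_solv from a (gas, solvated) single-point pair: solvated − gas."""
    return solvated.e_gas - gas.e_gas


class ExternalEngineBackend(EnergyBackend):
    """Runs an external engine executable through the text interface.

    The executable is invoked as ``exe input_file`` and must write
    ``input_file`` with extension replaced by ``.out``. Solvated
    evaluations run a second single point with the solvent keyword and
    report g_solv as the energy difference.
    """

    has_gradient = False
    has_solvation = True

    def __init__(self, executable: str, settings: EngineSettings | None = None,
                 workdir: str | None = None):
        self.executable = executable
        self.settings = settings or EngineSettings()
        self.workdir = workdir

    def _run(self, system: System, solvated: bool) -> EnergyResult:
        settings = EngineSettings(**{**self.settings.__dict__, "solvated": solvated})
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            infile = Path(tmp) / "job.mop"
            infile.write_text(render_engine_input(system, settings))
            proc = subprocess.run([self.executable, str(infile)],
                                  capture_output=True, text=True)
            outfile = infile.with_suffix(".out")
            if proc.returncode != 0 or not outfile.exists():
                raise BackendError(
                    f"engine failed (rc={proc.returncode}): {proc.stderr[:500]}")
            return parse_engine_output(outfile.read_text())

    def evaluate(self, system: System, solvated: bool = False) -> EnergyResult:
        gas = self._run(system, solvated=False)
        if not solvated:
            return gas
        solv = self._run(system, solvated=True)
        return EnergyResult(e_gas=gas.e_gas,
                            g_solv=solvation_free_energy(gas, solv),
                            converged=gas.converged and solv.converged,
                            meta=solv.meta)
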