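"""Speciation solver: oracles, conservation laws, and scheme builders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anisofit import (
    Component,
    ComplexSpecies,
    Scheme,
    SpeciationError,
    build_two_tetramer_scheme,
    closed_form_single_site,
    solve_speciation,
)
from anisofit.speciation import EPS


def one_to_one_scheme(k, p_tot, d_tot):
    return Scheme(
        (Component("P", p_tot), Component("D", d_tot)),
        (ComplexSpecies("PD", {"P": 1, "D": 1}, k),),
    )


def two_site_fixed_point(k, t_tot, d_tot, tol=1e-12):
    """Independent oracle: damped fixed-point iteration on the two-site
    mass balances T+D<=>TD, T+TD<=>T2D with equal stepwise K."""
    t, d = t_tot, d_tot
    for _ in range(100000):
        d_new = d_tot / (1.0 + t / k + (t / k) ** 2)
        t_new = t_tot / (1.0 + d_new / k + 2.0 * t * d_new / k**2)
        t_new = np.sqrt(t * t_new)  # geometric damping
        if abs(t_new - t) <= tol * t_new and abs(d_new - d) <= tol * max(d_new, EPS):
            t, d = t_new, d_new
            break
        t, d = t_new, d_new
    return {"T": t, "D": d, "TD": d * t / k, "T2D": d * (t / k) ** 2}


class TestClosedFormSingleSite:
    def test_zero_protein_gives_zero_complex(self):
        assert closed_form_single_site(1e-7, 0.0, 1e-8) == 0.0

    def test_half_saturation_at_k_with_trace_ligand(self):
        # P_tot = K and D_tot -> 0: half the ligand is bound.
        bound = closed_form_single_site(1e-7, 1e-7, 1e-15)
        assert bound / 1e-15 == pytest.approx(0.5, rel=1e-6)

    def test_quadratic_value(self):
        assert closed_form_single_site(1e-7, 1e-7, 1e-8) == pytest.approx(4.875e-9, rel=1e-3)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            closed_form_single_site(0.0, 1e-7, 1e-8)


class TestSolveSpeciation:
    def test_all_zero_totals(self):
        s = one_to_one_scheme(1e-7, 0.0, 0.0)
        r = solve_speciation(s)
        assert r.free == {"P": 0.0, "D": 0.0}
        assert r.complexed == {"PD": 0.0}
        assert r.residual == 0.0

    def test_matches_quadratic_example(self):
        r = solve_speciation(one_to_one_scheme(1e-7, 1e-7, 1e-8))
        assert r.complexed["PD"] == pytest.approx(4.875e-9, rel=1e-3)

    def test_two_site_example_matches_fixed_point_oracle(self):
        k, t_tot, d_tot = 1e-7, 1e-7, 1e-8
        s = Scheme(
            (Component("T", t_tot), Component("D", d_tot)),
            (
                ComplexSpecies("TD", {"T": 1, "D": 1}, k),
                ComplexSpecies("T2D", {"T": 2, "D": 1}, k**2),
            ),
        )
        r = solve_speciation(s)
        oracle = two_site_fixed_point(k, t_tot, d_tot)
        assert r.free["T"] == pytest.approx(oracle["T"], rel=1e-6)
        assert r.complexed["TD"] == pytest.approx(oracle["TD"], rel=1e-6)
        assert r.complexed["T2D"] == pytest.approx(oracle["T2D"], rel=1e-6)
        # frozen expected values from the oracle
        assert r.free["T"] == pytest.approx(9.07e-8, rel=1e-2)
        assert r.complexed["TD"] == pytest.approx(3.32e-9, rel=1e-2)
        assert r.complexed["T2D"] == pytest.approx(3.01e-9, rel=1e-2)

    def test_rejects_bad_rel_tol(self):
        s = one_to_one_scheme(1e-7, 1e-7, 1e-8)
        for bad in (0.0, -1e-9, 1e-2):
            with pytest.raises(ValueError):
                solve_speciation(s, rel_tol=bad)

    @given(
        k=st.floats(1e-10, 1e-4),
        p=st.floats(1e-12, 1e-4),
        d=st.floats(1e-12, 1e-4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_solver_equals_closed_form_on_one_to_one(self, k, p, d):
        r = solve_speciation(one_to_one_scheme(k, p, d))
        expected = closed_form_single_site(k, p, d)
        assert r.complexed["PD"] == pytest.approx(expected, rel=1e-9, abs=1e-25)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mass_conservation_on_random_schemes(self, data):
        n_comp = data.draw(st.integers(1, 3))
        names = [f"C{i}" for i in range(n_comp)]
        totals = [data.draw(st.floats(0.0, 1e-4)) for _ in names]
        comps = tuple(Component(n, t) for n, t in zip(names, totals))
        n_cplx = data.draw(st.integers(1, 3))
        cplxs = []
        for j in range(n_cplx):
            members = data.draw(
                st.lists(st.sampled_from(names), min_size=1, max_size=n_comp, unique=True)
            )
            comp = {m: data.draw(st.integers(1, 2)) for m in members}
            if sum(comp.values()) < 2:
                comp[members[0]] += 1
            k = data.draw(st.floats(1e-9, 1e-3))
            cplxs.append(ComplexSpecies(f"X{j}", comp, k))
        scheme = Scheme(comps, tuple(cplxs))

        r = solve_speciation(scheme, rel_tol=1e-9)
        assert r.residual <= 1e-9
        assert all(v >= 0 for v in r.free.values())
        assert all(v >= 0 for v in r.complexed.values())
        for c in scheme.components:
            balance = r.free[c.name] + r.bound_total(c.name, scheme)
            assert balance == pytest.approx(c.total, rel=2e-9, abs=1e-20)

    def test_monotone_bound_probe_in_titrant(self):
        bound = []
        for monomer in np.linspace(0.0, 2e-6, 15):
            s = build_two_tetramer_scheme(9.9e-8, 1e-8, monomer)
            r = solve_speciation(s)
            bound.append(r.complexed["TD"] + r.complexed["T2D"])
        assert np.all(np.diff(bound) >= -1e-15)

    def test_dilution_limit_matches_free_equals_total(self):
        # probe -> 0: bound fraction approaches the closed form computed
        # with the free titrant pinned at its total.
        k, t_tot = 1e-7, 3e-7
        s = build_two_tetramer_scheme(k, 1e-13, 4.0 * t_tot)
        r = solve_speciation(s)
        frac = (r.complexed["TD"] + r.complexed["T2D"]) / 1e-13
        x = t_tot / k
        expected = (x + x * x) / (1.0 + x + x * x)
        assert frac == pytest.approx(expected, rel=1e-5)


class TestSchemeValidation:
    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            Component("P", -1e-9)

    def test_nan_total_rejected(self):
        with pytest.raises(ValueError):
            Component("P", float("nan"))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            Scheme((Component("P", 1e-9), Component("P", 1e-9)))

    def test_unknown_component_in_complex_rejected(self):
        with pytest.raises(ValueError):
            Scheme(
                (Component("P", 1e-9),),
                (ComplexSpecies("PQ", {"P": 1, "Q": 1}, 1e-7),),
            )

    def test_monomeric_complex_rejected(self):
        with pytest.raises(ValueError):
            ComplexSpecies("P1", {"P": 1}, 1e-7)

    def test_roundtrip_dict(self):
        s = build_two_tetramer_scheme(9.9e-8, 1e-8, 4e-7)
        s2 = Scheme.from_dict(s.to_dict())
        assert s2 == s


class TestBuildTwoTetramerScheme:
    def test_zero_titrant_is_valid(self):
        s = build_two_tetramer_scheme(9.9e-8, 1e-8, 0.0)
        assert dict((c.name, c.total) for c in s.components)["tetramer"] == 0.0
        r = solve_speciation(s)
        assert r.complexed["TD"] == 0.0 and r.complexed["T2D"] == 0.0

    def test_monomer_division_and_squared_overall_constant(self):
        s = build_two_tetramer_scheme(9.9e-8, 1e-8, 4e-7)
        totals = {c.name: c.total for c in s.components}
        assert totals["tetramer"] == pytest.approx(1e-7)
        ks = {c.name: c.k_overall for c in s.complexes}
        assert ks["TD"] == pytest.approx(9.9e-8)
        assert ks["T2D"] == pytest.approx(9.801e-15)

    def test_stoichiometric_regime_scheme_is_solvable(self):
        s = build_two_tetramer_scheme(1.5e-7, 2.5e-6, 2e-5)
        r = solve_speciation(s)
        assert r.residual <= 1e-9

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_two_tetramer_scheme(-1e-7, 1e-8, 1e-7)
        with pytest.raises(ValueError):
            build_two_tetramer_scheme(1e-7, -1e-8, 1e-7)

    def test_explicit_assembly_mode_matches_reduced_scheme(self):
        k, probe, monomer = 1e-7, 1e-8, 4e-7
        reduced = solve_speciation(build_two_tetramer_scheme(k, probe, monomer))
        explicit = solve_speciation(
            build_two_tetramer_scheme(k, probe, monomer, explicit_assembly=True)
        )
        for name in ("TD", "T2D"):
            assert explicit.complexed[name] == pytest.approx(reduced.complexed[name], rel=1e-6)
        # assembly is quantitative: free monomer is negligible
        assert explicit.free["monomer"] < 1e-9 * monomer
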