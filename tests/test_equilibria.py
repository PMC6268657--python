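"""Equilibrium solver: closed-form checks, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equispec import (
    Component,
    ConvergenceError,
    Species,
    build_model,
    conditional_constant,
    distribution_vs_metal,
    distribution_vs_ph,
    gibbs_from_logk,
    models,
    side_reaction_coefficient,
    solve_speciation,
)


class TestBuildModel:
    def test_hydroxo_species_model_is_valid(self):
        m = build_model(
            [("Al", 3, "metal"), ("H", 1, "proton")],
            [{"label": "Al(OH)", "stoichiometry": {"Al": 1, "H": -1}, "log_beta": -5.5}],
        )
        assert m.species_labels == ["Al(OH)"]
        assert m.proton == "H"

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown component"):
            build_model(
                ["Al", ("H", 1, "proton")],
                [{"label": "CuL", "stoichiometry": {"Cu": 1}, "log_beta": 1.0}],
            )

    def test_duplicate_species_label_rejected(self):
        spec = {"label": "X", "stoichiometry": {"Al": 1}, "log_beta": 1.0}
        with pytest.raises(ValueError, match="duplicate"):
            build_model(["Al"], [spec, spec])

    def test_non_finite_log_beta_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Species("X", {"Al": 1}, np.inf)

    def test_empty_species_list_is_a_valid_model(self):
        m = build_model(["Al", "CIP"], [])
        sol = solve_speciation(m, {"Al": 1e-3, "CIP": 2e-3})
        assert sol.free["Al"] == pytest.approx(1e-3)
        assert sol.free["CIP"] == pytest.approx(2e-3)


class TestSolveSpeciation:
    def test_pure_water_ph(self):
        # [H] = sqrt(Kw) with pKw 13.78  =>  pH = 6.89
        sol = solve_speciation(models.water_model(), {"H": 0.0})
        assert -np.log10(sol.free["H"]) == pytest.approx(6.89, abs=1e-9)

    def test_first_hydrolysis_ratio_at_fixed_ph(self):
        # [Al(OH)]/[Al] = 10**(pH + log beta1) = 10**(5.5 - 5.5) = 1
        sol = solve_speciation(models.al_hydrolysis_model(), {"Al": 1e-3}, fixed_ph=5.5)
        assert sol.species_conc["Al(OH)"] / sol.free["Al"] == pytest.approx(1.0, rel=1e-10)

    def test_hydrolysis_negligible_in_strong_acid(self):
        sol = solve_speciation(models.al_hydrolysis_model(), {"Al": 1e-3}, fixed_ph=2.0)
        assert sol.free["Al"] == pytest.approx(1e-3, rel=1e-3)

    def test_mass_balance_at_convergence(self):
        model = models.ternary_model()
        totals = {"Al": 1e-3, "CIP": 1e-3, "NADP": 1e-3, "H": 0.012}
        sol = solve_speciation(model, totals)
        for comp, t in totals.items():
            assert sol.total(comp, model) == pytest.approx(t, rel=1e-9, abs=1e-16)
        assert max(abs(r) for r in sol.residuals.values()) < 1e-10

    def test_negative_nonproton_total_rejected(self):
        with pytest.raises(ValueError, match="negative total"):
            solve_speciation(models.al_hydrolysis_model(), {"Al": -1e-3, "H": 0.0})

    def test_nonconvergence_reports_residuals(self):
        model = models.ternary_model()
        with pytest.raises(ConvergenceError) as err:
            solve_speciation(
                model,
                {"Al": 1e-3, "CIP": 1e-3, "NADP": 1e-3, "H": 0.015},
                max_iter=2,
            )
        assert err.value.residuals  # carries the last residuals

    def test_bisection_oracle_two_component(self):
        """Newton solution matches a brute-force bisection on a 1:1 + 1:2
        two-component model to 6 significant figures."""
        model = build_model(
            [("M", 2, "metal"), ("L", -1, "ligand")],
            [
                {"label": "ML", "stoichiometry": {"M": 1, "L": 1}, "log_beta": 5.0},
                {"label": "ML2", "stoichiometry": {"M": 1, "L": 2}, "log_beta": 8.5},
            ],
        )
        t_m, t_l = 1e-3, 1.5e-3
        b1, b2 = 10.0**5.0, 10.0**8.5

        def free_m(fl):
            return t_m / (1.0 + b1 * fl + b2 * fl * fl)

        # bisection on the ligand mass balance in free L
        lo, hi = 1e-15, t_l
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = free_m(mid)
            g = mid + b1 * fm * mid + 2 * b2 * fm * mid * mid - t_l
            if g > 0:
                hi = mid
            else:
                lo = mid
        fl_oracle = 0.5 * (lo + hi)
        fm_oracle = free_m(fl_oracle)

        sol = solve_speciation(model, {"M": t_m, "L": t_l})
        assert sol.free["L"] == pytest.approx(fl_oracle, rel=1e-6)
        assert sol.free["M"] == pytest.approx(fm_oracle, rel=1e-6)

    def test_scale_invariance_against_quadratic_oracle(self):
        """For a single 1:1 species without protons, concentrations at
        10x totals match the closed-form binding quadratic."""
        model = build_model(
            [("M", 2, "metal"), ("L", -1, "ligand")],
            [{"label": "ML", "stoichiometry": {"M": 1, "L": 1}, "log_beta": 6.0}],
        )
        k = 10.0**6.0
        for scale in (1.0, 10.0):
            t_m, t_l = 2e-4 * scale, 3e-4 * scale
            b = k * (t_m + t_l) + 1.0
            ml = 2 * k * t_m * t_l / (b + np.sqrt(b * b - 4 * k * k * t_m * t_l))
            sol = solve_speciation(model, {"M": t_m, "L": t_l})
            assert sol.species_conc["ML"] == pytest.approx(ml, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        t_al=st.floats(1e-6, 5e-3),
        t_cip=st.floats(1e-6, 5e-3),
        ph=st.floats(2.5, 10.5),
    )
    def test_mass_balance_property(self, t_al, t_cip, ph):
        """Mass balances close to 1e-10 relative over random compositions."""
        model = models.binary_model("CIP")
        sol = solve_speciation(model, {"Al": t_al, "CIP": t_cip}, fixed_ph=ph)
        assert sol.total("Al", model) == pytest.approx(t_al, rel=1e-9)
        assert sol.total("CIP", model) == pytest.approx(t_cip, rel=1e-9)
        assert all(v >= 0 for v in sol.species_conc.values())


class TestDistributions:
    def test_fractions_sum_to_one_vs_ph(self):
        model = models.ternary_model()
        table = distribution_vs_ph(
            model,
            {"Al": 1e-3, "CIP": 1e-3, "NADP": 1e-3},
            np.linspace(3.0, 8.0, 11),
            reference="Al",
        )
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-8)

    def test_ternary_species_dominate_at_neutral_ph(self):
        """At pH 7 and mM levels the mixed 1:1:1 complexes carry more Al
        than any binary complex."""
        model = models.ternary_model()
        table = distribution_vs_ph(
            model,
            {"Al": 1e-3, "CIP": 1e-3, "NADP": 1e-3},
            np.array([3.0, 5.0, 7.0]),
            reference="Al",
        )
        at7 = table.loc[7.0]
        ternary = at7["Al(CIP)(HNADP)"] + at7["Al(HCIP)(HNADP)"]
        binaries = [
            c
            for c in table.columns
            if c.startswith("Al(")
            and c not in ("Al(CIP)(HNADP)", "Al(HCIP)(HNADP)")
        ]
        assert ternary > max(at7[c] for c in binaries)

    def test_single_species_fraction_is_unity(self):
        model = build_model(
            [("Al", 3, "metal"), ("H", 1, "proton")],
            [],
        )
        table = distribution_vs_ph(model, {"Al": 1e-3}, np.array([3.0, 5.0]), "Al")
        np.testing.assert_allclose(table["Al(free)"], 1.0, atol=1e-10)

    def test_invalid_ph_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            distribution_vs_ph(
                models.al_hydrolysis_model(), {"Al": 1e-3}, np.array([5.0, 4.0]), "Al"
            )

    def test_zero_metal_leaves_ligands_free(self):
        model = models.conditional_binding_model()
        table = distribution_vs_metal(
            model, {"CIP": 20e-6, "NADP": 20e-6}, np.array([0.0, 1e-5]), fixed_ph=7.0
        )
        row0 = table.iloc[0]
        assert row0["CIP(free)"] == pytest.approx(1.0, abs=1e-10)
        assert row0["CIP:Al(CIP)"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_constants_give_equal_complexes(self):
        model = models.conditional_binding_model(10.5, 10.5)
        table = distribution_vs_metal(
            model, {"CIP": 20e-6, "NADP": 20e-6}, np.linspace(0, 25e-6, 6), fixed_ph=7.0
        )
        np.testing.assert_allclose(
            table["CIP:Al(CIP)"], table["NADP:Al(NADP)"], rtol=1e-8
        )

    def test_complex_fractions_increase_with_metal(self):
        table = distribution_vs_metal(
            models.conditional_binding_model(),
            {"CIP": 20e-6, "NADP": 20e-6},
            np.linspace(0, 25e-6, 11),
            fixed_ph=7.0,
        )
        assert np.all(np.diff(table["CIP:Al(CIP)"]) > -1e-12)
        assert np.all(np.diff(table["NADP:Al(NADP)"]) > -1e-12)
        ligand_sums = table["CIP(free)"] + table["CIP:Al(CIP)"]
        np.testing.assert_allclose(ligand_sums, 1.0, atol=1e-8)


class TestConditionalConstants:
    def test_side_reaction_coefficient_at_ph7(self):
        # 1 + 10**1.5 + 10**2.9 + 10**4.4 + 10**4.8  =>  log alpha = 4.95
        assert side_reaction_coefficient(
            models.AL_HYDROLYSIS_LOG_BETAS, 7.0
        ) == pytest.approx(4.9496, abs=1e-3)

    def test_conditional_equals_absolute_in_acid(self):
        assert conditional_constant(
            10.0, models.AL_HYDROLYSIS_LOG_BETAS, 2.0
        ) == pytest.approx(10.0, abs=1e-3)

    def test_alpha_monotone_in_ph(self):
        vals = [
            side_reaction_coefficient(models.AL_HYDROLYSIS_LOG_BETAS, ph)
            for ph in np.linspace(2, 11, 19)
        ]
        assert np.all(np.diff(vals) >= 0)

    def test_model_form_matches_dict_form(self):
        assert side_reaction_coefficient(
            models.al_hydrolysis_model(), 7.0
        ) == pytest.approx(
            side_reaction_coefficient(models.AL_HYDROLYSIS_LOG_BETAS, 7.0), abs=1e-12
        )


class TestGibbs:
    @pytest.mark.parametrize(
        "logk,expected",
        [(10.2, 13.9), (10.7, 14.6), (0.0, 0.0)],
    )
    def test_dissociation_free_energy(self, logk, expected):
        assert gibbs_from_logk(logk, 298.15) == pytest.approx(expected, abs=0.05)

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            gibbs_from_logk(10.0, -1.0)
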