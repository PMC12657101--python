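"""Reference-body Monte Carlo: compartment algebra, summaries, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidstore import densitometry as d, reference_body as rb
from lipidstore.densitometry import Constants


def uniform_composition_table(water, lipid, protein, ash, mass_sd=0.0, comp_sd=0.0):
    """All eight compartments share one composition (zero or fixed SDs).

    Printed composition percentages carry rounding, so the inputs are
    renormalised to sum to one.
    """
    total = water + lipid + protein + ash
    water, lipid, protein, ash = (x / total for x in (water, lipid, protein, ash))
    rows = []
    for name in rb.COMPARTMENT_NAMES:
        rows.append(
            {
                "compartment": name,
                "mass_frac_mean": 1.0 / 8.0,
                "mass_frac_sd": mass_sd,
                "p_water_mean": water,
                "p_water_sd": comp_sd,
                "p_lipid_mean": lipid,
                "p_lipid_sd": comp_sd,
                "p_protein_mean": protein,
                "p_protein_sd": comp_sd,
                "p_ash_mean": ash,
                "p_ash_sd": comp_sd,
            }
        )
    return rb.CompartmentParameterTable(pd.DataFrame(rows))


class TestDrawReferenceBodies:
    def test_zero_variance_lean_composition_fixes_lean_density(self, constants):
        """Lean means 69.1/27.4/3.4 give the canonical lean density each draw."""
        table = uniform_composition_table(0.691, 0.0, 0.274, 0.034)
        draws = rb.draw_reference_bodies(table, constants, n=100, seed=0)
        fracs = np.array([0.691, 0.274, 0.034])
        expected = d.mixture_density(
            d.CompartmentMix([994.0, 1340.0, 2300.0], fracs / fracs.sum(), by="mass")
        )
        np.testing.assert_allclose(draws.rho_lean, expected, rtol=1e-12)
        assert abs(draws.rho_lean[0] - 1093.0) < 7.1

    def test_zero_variance_whole_body_density(self, constants):
        """Whole-body means 52.8/20.9/23.5/2.6 give ~1029 kg/m3, within 1 SD of 1026."""
        table = uniform_composition_table(0.528, 0.235, 0.209, 0.026)
        draws = rb.draw_reference_bodies(table, constants, n=50, seed=1)
        fracs = np.array([0.528, 0.235, 0.209, 0.026])
        expected = d.mixture_density(
            d.CompartmentMix(
                [994.0, 860.0, 1340.0, 2300.0], fracs / fracs.sum(), by="mass"
            )
        )
        np.testing.assert_allclose(draws.rho_total, expected, rtol=1e-12)
        assert abs(expected - 1026.0) < 11.0

    def test_packaged_defaults_reproduce_aggregate_lipid(self, ref_draws):
        assert abs(ref_draws.constituent_fractions[:, 1].mean() - 0.235) < 0.037

    def test_mass_conservation(self, ref_draws):
        np.testing.assert_allclose(
            ref_draws.compartment_masses.sum(axis=1), ref_draws.m_total, rtol=1e-12
        )
        lipid_mass = ref_draws.constituent_fractions[:, 1] * ref_draws.m_total
        np.testing.assert_allclose(
            ref_draws.m_lean + lipid_mass, ref_draws.m_total, rtol=1e-9
        )

    def test_lean_density_exceeds_whole_body_density_drawwise(self, ref_draws):
        assert np.all(ref_draws.rho_lean > ref_draws.rho_total)

    def test_constituent_fractions_sum_to_one(self, ref_draws):
        np.testing.assert_allclose(
            ref_draws.constituent_fractions.sum(axis=1), 1.0, rtol=1e-9
        )

    def test_no_systematic_length_density_trend(self, ref_draws):
        """Compositions are length-free, so density~length rank correlation ~ 0."""
        sub = slice(0, 20000)
        rho, _ = stats.spearmanr(ref_draws.length_m[sub], ref_draws.rho_total[sub])
        assert abs(rho) < 0.02

    def test_seeded_reproducibility(self, constants):
        table = rb.default_compartment_table()
        a = rb.draw_reference_bodies(table, constants, n=500, seed=11)
        b = rb.draw_reference_bodies(table, constants, n=500, seed=11)
        np.testing.assert_array_equal(a.rho_lean, b.rho_lean)
        np.testing.assert_array_equal(a.m_total, b.m_total)

    def test_invalid_inputs(self, constants):
        table = rb.default_compartment_table()
        with pytest.raises(ValueError):
            rb.draw_reference_bodies(table, constants, n=0)
        with pytest.raises(ValueError):
            rb.draw_reference_bodies(table, constants, n=10, length_range=(-1, 5))


class TestSummaries:
    def test_single_draw_mean_is_draw(self, constants):
        draws = rb.draw_reference_bodies(
            rb.default_compartment_table(), constants, n=1, seed=2
        )
        summary = rb.summarize_reference(draws)
        assert summary.stats.loc["rho_lean", "mean"] == pytest.approx(draws.rho_lean[0])
        assert summary.stats.loc["rho_lean", "sd"] == 0.0

    def test_permutation_invariance(self, constants):
        draws = rb.draw_reference_bodies(
            rb.default_compartment_table(), constants, n=2000, seed=3
        )
        perm = np.random.default_rng(0).permutation(2000)
        shuffled = rb.ReferenceBodyDraws(
            length_m=draws.length_m[perm],
            m_total=draws.m_total[perm],
            compartment_masses=draws.compartment_masses[perm],
            m_lean=draws.m_lean[perm],
            v_total=draws.v_total[perm],
            v_lean=draws.v_lean[perm],
            rho_total=draws.rho_total[perm],
            rho_lean=draws.rho_lean[perm],
            constituent_fractions=draws.constituent_fractions[perm],
            v_lipid=draws.v_lipid[perm],
            spa_lipid_mass=draws.spa_lipid_mass[perm],
        )
        a = rb.summarize_reference(draws).stats
        b = rb.summarize_reference(shuffled).stats
        pd.testing.assert_frame_equal(a, b)

    def test_lean_density_spread_same_order_as_reported(self, ref_draws):
        sd = ref_draws.rho_lean.std(ddof=1)
        assert 1.0 < sd < 20.0  # same order as the reported ~7 kg/m3


class TestExternalValidation:
    def test_simulation_mean_inside_envelope(self, ref_draws):
        out = rb.external_validation(ref_draws, [ref_draws.rho_total.mean()])
        assert out.loc[0, "fraction_inside_95"] == 1.0

    def test_far_outlier_outside_envelope(self, ref_draws):
        far = ref_draws.rho_total.mean() + 10 * ref_draws.rho_total.std()
        out = rb.external_validation(ref_draws, [far])
        assert out.loc[0, "fraction_inside_95"] == 0.0

    def test_self_coverage_near_95_percent(self, ref_draws, constants):
        """Observations drawn from the simulator itself land inside ~95%."""
        obs = rb.draw_reference_bodies(
            rb.default_compartment_table(), constants, n=400, seed=21
        )
        dens = rb.external_validation(ref_draws, obs.rho_total)
        assert abs(dens.loc[0, "fraction_inside_95"] - 0.95) < 0.04
        yields = list(
            zip(obs.length_m, obs.constituent_fractions[:, 1] * obs.m_total / 1000.0)
        )
        yd = rb.external_validation(ref_draws, observed_yields=yields)
        assert abs(yd.loc[0, "fraction_inside_95"] - 0.95) < 0.05

    def test_empty_observations_warn(self, ref_draws):
        with pytest.warns(UserWarning, match="no observations"):
            out = rb.external_validation(ref_draws)
        assert out.empty


class TestSpermacetiShare:
    def test_zero_spa_lipid_gives_zero_share(self, constants):
        table = rb.default_compartment_table()
        t = table.table.copy()
        spa = t["compartment"] == rb.SPA
        t.loc[spa, "p_lipid_mean"] = 0.0
        t.loc[spa, "p_lipid_sd"] = 0.0
        t.loc[spa, "p_water_mean"] = 0.88
        table2 = rb.CompartmentParameterTable(t)
        draws = rb.draw_reference_bodies(table2, Constants(), n=200, seed=4)
        assert rb.spermaceti_share(draws).max() == pytest.approx(0.0, abs=1e-12)

    def test_all_lipid_in_spa_gives_unit_share(self, constants):
        rows = []
        for name in rb.COMPARTMENT_NAMES:
            lipid = 0.5 if name == rb.SPA else 0.0
            rows.append(
                {
                    "compartment": name,
                    "mass_frac_mean": 1.0 / 8.0,
                    "mass_frac_sd": 0.0,
                    "p_water_mean": 0.7 - lipid,
                    "p_water_sd": 0.0,
                    "p_lipid_mean": lipid,
                    "p_lipid_sd": 0.0,
                    "p_protein_mean": 0.27,
                    "p_protein_sd": 0.0,
                    "p_ash_mean": 0.03,
                    "p_ash_sd": 0.0,
                }
            )
        table = rb.CompartmentParameterTable(pd.DataFrame(rows))
        draws = rb.draw_reference_bodies(table, constants, n=50, seed=5)
        np.testing.assert_allclose(rb.spermaceti_share(draws), 1.0, rtol=1e-12)

    def test_packaged_share_matches_reported_ratios(self, ref_draws):
        """Spermaceti holds roughly a fifth of total body lipid."""
        share = rb.spermaceti_share(ref_draws)
        assert 0.17 < share.mean() < 0.23


class TestParameterTable:
    def test_wrong_compartment_set_rejected(self):
        t = rb.default_compartment_table().table.iloc[:-1]
        with pytest.raises(ValueError, match="8 compartments"):
            rb.CompartmentParameterTable(t)

    def test_mass_fractions_must_sum_to_one(self):
        t = rb.default_compartment_table().table.copy()
        t.loc[0, "mass_frac_mean"] += 0.5
        with pytest.raises(ValueError, match="sum to"):
            rb.CompartmentParameterTable(t)
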