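import numpy as np
import pytest
from scipy import stats as sps

from groovekit import (
    AssayTable,
    dunnett_critical_value,
    dunnett_sf,
    dunnett_sf_mc,
    dunnett_test,
    percent_of_control,
    simulate_assay,
)

# The DRB1*01:01 competitive-assay column: % binding of HA peptide vs DMSO
# control at four nevirapine doses, quadruplicate mean ± SD.
DRB1_0101_TABLE2 = {
    "1000": (263.9, 15.5, 4),
    "200": (99.7, 11.3, 4),
    "40": (106.2, 6.5, 4),
    "8": (101.9, 8.1, 4),
}


class TestPercentOfControl:
    def test_control_mean_becomes_exactly_100(self, rng):
        raw = {"DMSO": rng.normal(5000, 300, 4), "drug": rng.normal(6000, 300, 4)}
        table = percent_of_control(raw, "DMSO")
        assert table.summaries["DMSO"][0] == pytest.approx(100.0)

    def test_doubled_group_mean_maps_to_200(self):
        raw = {"DMSO": np.array([900.0, 1100.0]), "x": np.array([1900.0, 2100.0])}
        table = percent_of_control(raw, "DMSO")
        assert table.summaries["x"][0] == pytest.approx(200.0)

    def test_matches_hand_scaled_values(self):
        raw = {"DMSO": np.array([800.0, 1200.0]), "x": np.array([500.0, 1500.0])}
        table = percent_of_control(raw, "DMSO")
        np.testing.assert_allclose(table.replicates["x"], [50.0, 150.0])

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control({"DMSO": np.array([0.0, 0.0]), "x": np.array([1.0])}, "DMSO")


class TestDunnettTest:
    def test_null_groups_give_p_near_one(self, rng):
        base = rng.normal(100, 5, 4)
        table = AssayTable.from_replicates(
            {"ctrl": base, "a": base + 1e-9, "b": base - 1e-9}, control="ctrl"
        )
        res = dunnett_test(table)
        assert np.all(res.p_adjusted > 0.999)

    def test_k1_reduces_to_two_sample_t_test(self, rng):
        a = rng.normal(10, 2, 6)
        b = rng.normal(12, 2, 6)
        table = AssayTable.from_replicates({"c": a, "t": b}, control="c")
        res = dunnett_test(table)
        tt = sps.ttest_ind(b, a)
        assert res.t[0] == pytest.approx(tt.statistic, abs=1e-10)
        assert res.p_adjusted[0] == pytest.approx(tt.pvalue, abs=1e-6)

    def test_table2_top_dose_significant_below_1e4(self):
        # fixed-reference mode: control = the constant 100 it was normalised
        # to, variance pooled over the four dose groups (df = 12)
        table = AssayTable.from_summaries(DRB1_0101_TABLE2)
        res = dunnett_test(table, fixed_reference=100.0)
        by = res.as_dict()
        assert by["1000"]["p_adjusted"] < 1e-4
        for dose in ("200", "40", "8"):
            assert by[dose]["p_adjusted"] > 0.05
        assert res.df == 12

    def test_top_dose_robust_to_n8_reading(self):
        # the replicate count is ambiguous in such tables; n = 8 only
        # strengthens the comparison
        table = AssayTable.from_summaries(
            {k: (m, s, 8) for k, (m, s, _) in DRB1_0101_TABLE2.items()}
        )
        res = dunnett_test(table, fixed_reference=100.0)
        assert res.as_dict()["1000"]["p_adjusted"] < 1e-4

    def test_matches_scipy_dunnett_on_replicates(self, rng):
        groups = [rng.normal(11, 2, 5) for _ in range(3)]
        ctrl = rng.normal(10, 2, 5)
        table = AssayTable.from_replicates(
            {"c": ctrl, "g0": groups[0], "g1": groups[1], "g2": groups[2]},
            control="c",
        )
        res = dunnett_test(table)
        ref = sps.dunnett(*groups, control=ctrl)
        np.testing.assert_allclose(res.t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res.p_adjusted, ref.pvalue, atol=2e-3)

    def test_adjusted_never_below_unadjusted(self, rng):
        for _ in range(5):
            groups = {f"g{i}": rng.normal(10, 2, 4) for i in range(4)}
            groups["c"] = rng.normal(10, 2, 4)
            res = dunnett_test(AssayTable.from_replicates(groups, control="c"))
            assert np.all(res.p_adjusted >= res.p_unadjusted - 1e-12)

    def test_single_replicate_without_summary_rejected(self):
        table = AssayTable.from_replicates(
            {"c": np.array([1.0, 2.0]), "t": np.array([3.0])}, control="c"
        )
        with pytest.raises(ValueError):
            dunnett_test(table)

    def test_no_treatment_groups_rejected(self):
        table = AssayTable.from_replicates({"c": np.array([1.0, 2.0])}, control="c")
        with pytest.raises(ValueError):
            dunnett_test(table)


class TestTailMachinery:
    def test_quadrature_matches_exact_t_tail_at_k1(self):
        for q in (1.0, 2.5, 4.0, 7.0):
            exact = 2 * sps.t.sf(q, 12)
            assert dunnett_sf(q, 12, np.zeros(1)) == pytest.approx(exact, rel=1e-5)

    def test_monte_carlo_agrees_with_quadrature(self):
        lam = np.sqrt(np.full(4, 4.0 / 8.0))
        q, df = 2.7, 15
        mc = dunnett_sf_mc(q, df, lam, n_draws=1_000_000, rng=1)
        assert dunnett_sf(q, df, lam) == pytest.approx(mc, abs=0.002)

    def test_p_monotone_in_q(self):
        lam = np.sqrt(np.full(3, 0.5))
        qs = np.linspace(0.5, 6.0, 12)
        ps = [dunnett_sf(q, 10, lam) for q in qs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_critical_value_inverts_sf(self):
        lam = np.zeros(4)
        q = dunnett_critical_value(0.05, 12, lam)
        assert dunnett_sf(q, 12, lam) == pytest.approx(0.05, abs=1e-8)

    def test_family_wise_type_I_error_calibrated(self):
        # 10^4 simulated null assays (k = 4 treatments + control, n = 4):
        # rejection of any comparison at the alpha = 0.05 critical value
        # must occur in 5% +/- 1% of families
        rng = np.random.default_rng(2024)
        k, n, n_sim = 4, 4, 10_000
        x = rng.normal(100.0, 8.0, size=(n_sim, k + 1, n))
        means = x.mean(axis=2)
        variances = x.var(axis=2, ddof=1)
        s2 = variances.mean(axis=1)  # pooled across k+1 equal-size groups
        df = (k + 1) * (n - 1)
        se = np.sqrt(s2 * (2.0 / n))
        t = (means[:, 1:] - means[:, [0]]) / se[:, None]
        lam = np.sqrt(np.full(k, n / (2.0 * n)))
        crit = dunnett_critical_value(0.05, df, lam)
        fwer = (np.abs(t).max(axis=1) >= crit).mean()
        assert fwer == pytest.approx(0.05, abs=0.01)


class TestSimulateAssay:
    def test_null_effects_stay_near_control(self):
        table = simulate_assay(
            {"a": 1.0, "b": 1.0}, noise_sd=5.0, replicates=50, seed=3
        )
        for g in ("a", "b"):
            assert table.summaries[g][0] == pytest.approx(100.0, abs=3.0)

    def test_seeded_tables_are_identical(self):
        t1 = simulate_assay({"a": 1.5}, noise_sd=10.0, seed=11)
        t2 = simulate_assay({"a": 1.5}, noise_sd=10.0, seed=11)
        for g in t1.groups:
            np.testing.assert_array_equal(t1.replicates[g], t2.replicates[g])

    def test_power_to_flag_only_the_real_effect(self):
        # doses mimicking a strong top-dose effect (2.639 x control, 15.5%
        # noise): the affected dose must be flagged at alpha = 0.001 and the
        # null doses must not, in >= 95% of seeded runs
        effects = {"8": 1.0, "40": 1.0, "200": 1.0, "1000": 2.639}
        hits = misses = 0
        for seed in range(20):
            table = simulate_assay(effects, noise_sd=15.5, replicates=4, seed=seed)
            res = dunnett_test(table)
            by = res.as_dict()
            if by["1000"]["p_adjusted"] < 0.001:
                hits += 1
            if all(by[d]["p_adjusted"] >= 0.001 for d in ("8", "40", "200")):
                misses += 1
        assert hits >= 19
        assert misses >= 19

    def test_replicate_validation(self):
        with pytest.raises(ValueError):
            simulate_assay({"a": 1.0}, noise_sd=1.0, replicates=1)
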