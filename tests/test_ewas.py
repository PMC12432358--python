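import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methrisk import (CovariateModelSpec, EwasSiteResult, MethylationMatrix,
                      bh_fdr, delta_beta_filter, ewas_scan, paired_ttest_fdr,
                      robustness_screen, spearman_assoc)
from conftest import make_phenotypes


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        # q_(i) = min_{j>=i} p_(j)*m/j: all become 0.04 here
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_never_decreases_and_order_invariant(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestEwasScan:
    def test_single_site_q_equals_p(self, rng):
        n = 60
        events = (rng.random(n) < 0.3).astype(int)
        events[0] = 1
        ph = make_phenotypes(n, events, rng.exponential(3, n) + 0.1, rng)
        mat = MethylationMatrix(["cg1"], ph.sample_ids,
                                rng.uniform(0.3, 0.7, (1, n)), "beta")
        res = ewas_scan(mat, ph, CovariateModelSpec.model_1())
        assert len(res) == 1 and res[0].q == res[0].p

    def test_sample_mismatch_raises(self, rng, null_cohort):
        ph, mat, _ = null_cohort
        bad = mat.subset_samples(mat.sample_ids[:-1])
        with pytest.raises(ValueError, match="align"):
            ewas_scan(bad, ph, CovariateModelSpec.model_1())

    def test_site_order_invariance(self, null_cohort, rng):
        ph, mat, _ = null_cohort
        small = mat.subset_sites(mat.site_ids[:20])
        perm = list(rng.permutation(20))
        shuffled = small.subset_sites([small.site_ids[i] for i in perm])
        a = {r.site_id: r.p for r in ewas_scan(small, ph, CovariateModelSpec.model_1())}
        b = {r.site_id: r.p for r in ewas_scan(shuffled, ph, CovariateModelSpec.model_1())}
        assert a == b

    def test_null_type_one_error_controlled(self, null_cohort):
        """No planted signal: per-site p < alpha at about the nominal rate."""
        ph, mat, _ = null_cohort
        res = ewas_scan(mat, ph, CovariateModelSpec.model_1())
        frac = np.mean([r.p < 0.05 for r in res])
        bound = 3 * np.sqrt(0.05 * 0.95 / mat.n_sites)
        assert abs(frac - 0.05) < bound

    def test_delta_beta_reported_on_beta_scale(self, null_cohort):
        ph, mat, _ = null_cohort
        res = ewas_scan(mat.subset_sites(mat.site_ids[:5]), ph,
                        CovariateModelSpec.model_1())
        ev = ph.event == 1
        for r in res:
            site = mat.site(r.site_id)
            assert r.delta_beta == pytest.approx(site[ev].mean() - site[~ev].mean())
            assert r.q >= r.p


def make_result(site_id, q, p_by_model):
    return EwasSiteResult(site_id=site_id, log_hr_per_sd=0.1, se=0.05,
                          p=q, q=q, delta_beta=0.03, p_by_model=dict(p_by_model))


class TestRobustnessScreen:
    def secondary(self, p_map):
        """Build per-model scans with given p for our site, 0.01 elsewhere."""
        return {mid: [make_result("cgA", 0.5, {}), make_result("cgB", 0.5, {})]
                for mid in p_map}

    def test_site_kept_when_rule_satisfied(self):
        primary = [make_result("cgA", 0.01, {1: 0.001})]
        secondary = {m: [make_result("cgA", 0.5, {})] for m in range(2, 11)}
        for scans in secondary.values():
            scans[0].p = 0.04
        kept = robustness_screen(primary, secondary)
        assert [r.site_id for r in kept] == ["cgA"]
        assert set(kept[0].p_by_model) >= set(range(2, 11))

    def test_site_dropped_on_one_failure(self):
        primary = [make_result("cgA", 0.01, {1: 0.001})]
        secondary = {m: [make_result("cgA", 0.5, {})] for m in range(2, 11)}
        for m, scans in secondary.items():
            scans[0].p = 0.06 if m == 7 else 0.04
        assert robustness_screen(primary, secondary) == []

    def test_partial_failures_counted(self):
        """10 primary sites, 3 fail one secondary model: 7 survive."""
        primary = [make_result(f"cg{i}", 0.01, {}) for i in range(10)]
        secondary = {2: [make_result(f"cg{i}", 0.5, {}) for i in range(10)]}
        for i, r in enumerate(secondary[2]):
            r.p = 0.2 if i < 3 else 0.01
        assert len(robustness_screen(primary, secondary)) == 7

    def test_missing_site_raises(self):
        primary = [make_result("cgA", 0.01, {})]
        with pytest.raises(ValueError, match="cgA"):
            robustness_screen(primary, {2: [make_result("cgB", 0.5, {})]})

    def test_non_significant_primary_ignored(self):
        primary = [make_result("cgA", 0.2, {})]
        assert robustness_screen(primary, {}) == []


class TestDeltaBetaFilter:
    @pytest.mark.parametrize("delta,kept", [(0.020, True), (0.019, False),
                                            (-0.020, True), (-0.019, False)])
    def test_inclusive_boundary(self, delta, kept):
        r = make_result("cg", 0.01, {})
        r.delta_beta = delta
        assert (len(delta_beta_filter([r])) == 1) is kept

    def test_hand_counted_fixture(self):
        deltas = [0.01, -0.01, 0.02, -0.02, 0.03, -0.03, 0.04, -0.04, 0.05, -0.05]
        results = []
        for i, d in enumerate(deltas):
            r = make_result(f"cg{i}", 0.01, {})
            r.delta_beta = d
            results.append(r)
        assert len(delta_beta_filter(results)) == 8  # |d| >= 0.02: all but +-0.01


class TestPairedTtest:
    def matrices(self, a, b):
        sites = [f"cg{i}" for i in range(a.shape[0])]
        samples = [f"s{j}" for j in range(a.shape[1])]
        return (MethylationMatrix(sites, samples, a, "beta"),
                MethylationMatrix(sites, samples, b, "beta"))

    def test_identical_matrices_null(self, rng):
        a = rng.uniform(0.3, 0.7, (5, 6))
        ma, mb = self.matrices(a, a.copy())
        out = paired_ttest_fdr(ma, mb)
        assert np.all(out["t"] == 0) and np.all(out["p"] == 1)

    def test_matches_scipy_oracle(self, rng):
        a = rng.uniform(0.3, 0.7, (20, 15))
        b = np.clip(a + rng.normal(0, 0.02, a.shape), 0, 1)
        ma, mb = self.matrices(a, b)
        out = paired_ttest_fdr(ma, mb)
        t_ref, p_ref = stats.ttest_rel(a, b, axis=1)
        assert np.allclose(out["t"], t_ref, atol=1e-10)
        assert np.allclose(out["p"], p_ref, atol=1e-10)

    def test_constant_shift_closed_form(self):
        """Differences all 0.02 with tiny jitter: p from the exact t CDF."""
        base = np.tile(np.linspace(0.3, 0.7, 5), (5, 1))
        jitter = np.array([0.0, 1e-3, -1e-3, 2e-3, -2e-3])
        b = base + 0.02 + jitter
        ma, mb = self.matrices(base, np.clip(b, 0, 1))
        out = paired_ttest_fdr(mb, ma)
        d = (np.clip(b, 0, 1) - base)[0]
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_exp = 2 * stats.t.sf(abs(t_exp), df=4)
        assert out["t"][0] == pytest.approx(t_exp, abs=1e-10)
        assert out["p"][0] == pytest.approx(p_exp, abs=1e-10)

    def test_unpaired_samples_raise(self, rng):
        a = rng.uniform(0.3, 0.7, (3, 4))
        ma, _ = self.matrices(a, a)
        mb = MethylationMatrix(ma.site_ids, ["x1", "x2", "x3", "x4"], a, "beta")
        with pytest.raises(ValueError, match="pairing"):
            paired_ttest_fdr(ma, mb)

    def test_null_type_one_error(self, rng):
        a = rng.uniform(0.3, 0.7, (400, 15))
        b = np.clip(a + rng.normal(0, 0.02, a.shape), 0, 1)
        # independent noise in both: differences have mean 0
        a2 = np.clip(a + rng.normal(0, 0.02, a.shape), 0, 1)
        ma, mb = self.matrices(a2, b)
        out = paired_ttest_fdr(ma, mb)
        frac = (out["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_assoc(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_assoc(x, -x**3)[0] == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        rho, p = spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_use_average_ranks(self):
        x = np.array([1, 1, 2, 3, 4, 4, 5, 6.0])
        y = np.array([2, 1, 2, 3, 5, 4, 5, 6.0])
        ref = stats.spearmanr(x, y)
        rho, _ = spearman_assoc(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_assoc(np.ones(6), np.arange(6.0))


def test_results_table_written_as_tsv(tmp_path, null_cohort):
    import pandas as pd
    from methrisk import write_results, CovariateModelSpec
    ph, mat, _ = null_cohort
    res = ewas_scan(mat.subset_sites(mat.site_ids[:5]), ph,
                    CovariateModelSpec.model_1())
    for r in res:
        r.p_by_model[2] = r.p
    path = tmp_path / "ewas.tsv"
    write_results(res, path)
    df = pd.read_csv(path, sep="\t")
    assert {"site_id", "log_hr_per_sd", "hr", "se", "p", "q", "delta_beta",
            "p_model2"} <= set(df.columns)
    assert len(df) == 5
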