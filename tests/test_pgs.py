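"""Clumping against a brute-force oracle, score construction and allele
alignment, association models, and the closed-form polygenic power model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcovpipe.datatypes import SummaryStatsTable
from gcovpipe.pgs import (
    DiscoveryDesign,
    PolygenicModelSpec,
    PolygenicScoreSet,
    assoc_cross_sectional,
    assoc_longitudinal_gaussian,
    assoc_longitudinal_poisson,
    build_scores,
    clump,
    expected_r2,
    polygenic_covariance_from_r2,
    polygenic_power,
)
from gcovpipe.synthetic_data import default_spec, simulate_longitudinal_traits
from gcovpipe.transform import TransformedMeasure

from conftest import make_panel


def sumstats_for(panel, p_values, effects=None, flip=None):
    m = panel.n_snps
    effects = effects if effects is not None else np.full(m, 0.1)
    eff_allele = panel.snps["allele_alt"].to_numpy(object).copy()
    other = panel.snps["allele_ref"].to_numpy(object).copy()
    if flip is not None:
        eff_allele[flip], other[flip] = other[flip], eff_allele[flip]
    return SummaryStatsTable(pd.DataFrame({
        "snp_id": panel.snps["snp_id"],
        "allele_effect": eff_allele,
        "allele_other": other,
        "effect": np.where(flip if flip is not None else np.zeros(m, bool),
                           -np.asarray(effects), np.asarray(effects)),
        "se": 0.05,
        "p_value": p_values,
        "allele_freq": panel.snps["allele_freq"],
    }))


def clump_oracle(sumstats, panel, r2_threshold, window):
    """Exhaustive reference: re-scans every remaining pair each round."""
    tab = sumstats.table.sort_values("p_value").drop_duplicates("snp_id", keep="first")
    tab = tab[tab["snp_id"].isin(set(panel.snps["snp_id"]))]
    idx = list(panel.snp_indices(tab["snp_id"]))
    meta = panel.snps
    x = panel.dosages_float(np.arange(panel.n_snps))
    x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    pvals = dict(zip(idx, tab["p_value"]))
    remaining = sorted(idx, key=lambda i: (pvals[i], meta["chrom"][i], meta["pos"][i]))
    kept = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        survivors = []
        for j in remaining:
            same = meta["chrom"][j] == meta["chrom"][lead]
            near = abs(meta["pos"][j] - meta["pos"][lead]) <= window
            r = np.corrcoef(x[:, lead], x[:, j])[0, 1] if same and near else 0.0
            if not (same and near and r**2 > r2_threshold):
                survivors.append(j)
        remaining = survivors
    return [meta["snp_id"][k] for k in kept]


class TestClump:
    def test_perfect_ld_keeps_most_significant(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=50)
        panel = make_panel(np.column_stack([col, col]), positions=[1000, 2000])
        ss = sumstats_for(panel, [1e-4, 1e-8])
        assert clump(ss, panel, 0.25, 500_000) == ["s1"]

    def test_uncorrelated_snps_all_retained(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.integers(0, 3, size=(400, 10)))
        ss = sumstats_for(panel, rng.uniform(0.01, 1, 10))
        kept = clump(ss, panel, 0.9, 500_000)
        assert sorted(kept) == sorted(panel.snps["snp_id"])

    def test_block_ld_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(200, 6))
        cols = []
        for b in range(6):  # blocks of 5 correlated SNPs
            for _ in range(5):
                noisy = base[:, b].copy()
                swap = rng.random(200) < 0.15
                noisy[swap] = rng.integers(0, 3, swap.sum())
                cols.append(noisy)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 30, replace=False))
        panel = make_panel(np.column_stack(cols)[:, np.argsort(rng.random(30))],
                           positions=pos)
        ss = sumstats_for(panel, rng.uniform(1e-8, 1, 30))
        assert clump(ss, panel, 0.25, 500_000) == clump_oracle(ss, panel, 0.25, 500_000)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.integers(0, 3, size=(150, 20)))
        ss = sumstats_for(panel, rng.uniform(1e-6, 1, 20))
        shuffled = SummaryStatsTable(ss.table.sample(frac=1, random_state=7))
        assert clump(ss, panel, 0.25, 500_000) == clump(shuffled, panel, 0.25, 500_000)

    def test_duplicates_keep_smaller_p(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.integers(0, 3, size=(50, 2)))
        tab = sumstats_for(panel, [0.5, 0.9]).table
        dup = tab.iloc[[0]].assign(p_value=1e-6)
        ss = SummaryStatsTable(pd.concat([tab, dup], ignore_index=True))
        kept = clump(ss, panel, 0.9, 500_000)
        assert set(kept) == {"s0", "s1"}


class TestBuildScores:
    def test_single_snp_linearity(self):
        panel = make_panel([[0], [1], [2]])
        ss = sumstats_for(panel, [0.01], effects=[0.5])
        scores = build_scores(panel, ss, ["s0"], [0.5])
        expect = np.array([0.0, 0.5, 1.0])
        zexp = (expect - expect.mean()) / expect.std(ddof=1)
        assert np.allclose(scores.scores[:, 0], zexp)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(6)
        panel = make_panel(rng.integers(0, 3, size=(100, 8)))
        p = rng.uniform(0.001, 1, 8)
        eff = rng.normal(0, 0.2, 8)
        plain = build_scores(panel, sumstats_for(panel, p, eff), list(panel.snps["snp_id"]))
        flip = np.zeros(8, bool)
        flip[[1, 4, 6]] = True
        flipped = build_scores(panel, sumstats_for(panel, p, eff, flip=flip),
                               list(panel.snps["snp_id"]))
        assert np.allclose(plain.scores, flipped.scores)

    def test_threshold_semantics(self):
        rng = np.random.default_rng(7)
        panel = make_panel(rng.integers(0, 3, size=(60, 5)))
        ss = sumstats_for(panel, [0.3, 0.4, 0.6, 0.8, 0.9])
        scores = build_scores(panel, ss, list(panel.snps["snp_id"]), [0.01, 0.5, 1.0])
        assert scores.n_snps_per_threshold == [0, 2, 5]
        assert scores.usable == [False, True, True]
        with pytest.raises(ValueError):
            scores.column(0.01)

    def test_missing_dosage_imputed_by_frequency(self):
        dos = np.array([[0], [1], [2], [-9]], dtype=np.int8)
        panel = make_panel(dos, freqs=[0.25])
        ss = sumstats_for(panel, [0.01], effects=[1.0])
        scores = build_scores(panel, ss, ["s0"], [0.5])
        raw = np.array([0.0, 1.0, 2.0, 0.5])  # 2 * freq for the missing call
        zexp = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(scores.scores[:, 0], zexp)

    def test_score_mean_zero_unit_variance(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.integers(0, 3, size=(200, 10)))
        ss = sumstats_for(panel, rng.uniform(0.001, 1, 10), rng.normal(0, 0.1, 10))
        scores = build_scores(panel, ss, list(panel.snps["snp_id"]))
        for j, ok in enumerate(scores.usable):
            if ok:
                assert abs(scores.scores[:, j].mean()) < 1e-8
                assert scores.scores[:, j].var(ddof=1) == pytest.approx(1.0, abs=1e-2)


class TestAssociation:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(100)
        s = (s - s.mean()) / s.std(ddof=1)
        scores = PolygenicScoreSet([f"i{j}" for j in range(100)], [0.5], s[:, None], [10], [True])
        y = TransformedMeasure([f"i{j}" for j in range(100)], s.copy())
        res = assoc_cross_sectional(scores, y)[0]
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_permuted_score_null_p_distribution(self):
        rng = np.random.default_rng(10)
        ids = [f"i{j}" for j in range(300)]
        y = TransformedMeasure(ids, rng.standard_normal(300))
        ps = []
        for _ in range(40):
            s = rng.standard_normal(300)
            scores = PolygenicScoreSet(ids, [0.5], s[:, None], [10], [True])
            ps.append(assoc_cross_sectional(scores, y)[0].p)
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) > 1e-4  # no spurious strong association


@pytest.fixture(scope="module")
def longi_setup():
    from gcovpipe.synthetic_data import simulate_genotypes

    panel = simulate_genotypes(250, 400, 0.05, 0.5, seed=81)
    spec = default_spec(seed=82, n_causal=100)
    table, truth = simulate_longitudinal_traits(panel, spec, None, return_truth=True)
    rng = np.random.default_rng(83)
    s = rng.standard_normal(250)  # a null score, independent of the traits
    s = (s - s.mean()) / s.std(ddof=1)
    scores = PolygenicScoreSet(panel.sample_ids, [0.5], s[:, None], [50], [True])
    return table, scores


class TestLongitudinal:
    def test_null_pgs_ci_covers_zero(self, longi_setup):
        table, scores = longi_setup
        res = assoc_longitudinal_gaussian(scores, table, "SDQ-ADHD", 0.5, n_boot=15, seed=1)
        assert res.ci_pgs[0] <= 0.0 <= res.ci_pgs[1]
        assert res.lrt_p > 0.001
        assert 0.0 <= res.marginal_r2 <= 1.0

    def test_degenerate_bootstrap_flagged(self, longi_setup):
        table, scores = longi_setup
        res = assoc_longitudinal_gaussian(scores, table, "SDQ-ADHD", 0.5, n_boot=1, seed=2)
        assert "degenerate" in res.note
        assert res.ci_pgs[0] == res.ci_pgs[1] == res.beta_pgs

    def test_poisson_constant_counts_no_signal(self, longi_setup):
        table, scores = longi_setup
        flat = table.rows.copy()
        flat["score"] = 3
        from gcovpipe.datatypes import PhenotypeTable

        res = assoc_longitudinal_poisson(scores, PhenotypeTable(flat), "SCDC", 0.5,
                                         n_boot=0, seed=3)
        assert abs(res.beta_pgs) < 1e-3

    def test_poisson_recovers_log_scale_effect(self):
        rng = np.random.default_rng(84)
        n, occasions = 400, 4
        s = rng.standard_normal(n)
        u = rng.normal(0, 0.4, n)
        rows = []
        for j in range(n):
            for t in range(occasions):
                age = 8 + 3 * t
                eta = 0.6 + 0.15 * s[j] + u[j]
                rows.append((f"i{j}", "C", age, age, 0, rng.poisson(np.exp(eta)), 0.0, 0.0))
        from gcovpipe.datatypes import PhenotypeTable

        table = PhenotypeTable(pd.DataFrame(
            rows, columns=["iid", "trait", "age_band", "age", "sex", "score", "pc1", "pc2"]))
        scores = PolygenicScoreSet([f"i{j}" for j in range(n)], [0.5],
                                   ((s - s.mean()) / s.std(ddof=1))[:, None], [50], [True])
        res = assoc_longitudinal_poisson(scores, table, "C", 0.5, n_boot=10, seed=4)
        sd_boot = (res.ci_pgs[1] - res.ci_pgs[0]) / (2 * 1.96)
        assert abs(res.beta_pgs - 0.15) <= max(2 * sd_boot, 0.05)


class TestPolygenicModel:
    def _spec(self, **kw):
        base = dict(discovery=DiscoveryDesign(4163, 12040, 0.05, 0.28),
                    target_n=5000, genetic_covariance=0.1)
        base.update(kw)
        return PolygenicModelSpec(**base)

    def test_zero_covariance_power_equals_alpha(self):
        assert polygenic_power(self._spec(genetic_covariance=0.0)) == pytest.approx(0.05)

    def test_power_monotone_in_n_and_covariance(self):
        grid_n = [1000, 3000, 5000, 10000]
        powers_n = [polygenic_power(self._spec(target_n=n)) for n in grid_n]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
        grid_c = [0.02, 0.05, 0.08, 0.12]
        powers_c = [polygenic_power(self._spec(genetic_covariance=c)) for c in grid_c]
        assert all(a < b for a, b in zip(powers_c, powers_c[1:]))

    def test_forward_inverse_round_trip(self):
        for c in [0.01, 0.05, 0.1, 0.2]:
            r2 = expected_r2(self._spec(genetic_covariance=c))
            est, _, _ = polygenic_covariance_from_r2(self._spec(), r2)
            assert est == pytest.approx(c, abs=1e-6)

    def test_zero_r2_gives_zero_with_one_sided_ci(self):
        est, lo, hi = polygenic_covariance_from_r2(self._spec(), 0.0)
        assert est == 0.0 and lo == 0.0 and hi > 0.0

    def test_inconsistent_covariance_rejected(self):
        with pytest.raises(ValueError, match="covariance"):
            self._spec(genetic_covariance=0.5, target_h2=0.3)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            self._spec(p_threshold=0.0005)

    def test_full_inclusion_threshold(self):
        # P_T = 1 includes every SNP: selection factor becomes the plain variance
        r2_half = expected_r2(self._spec(p_threshold=0.5))
        r2_all = expected_r2(self._spec(p_threshold=1.0))
        assert r2_all > 0 and r2_half > 0
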