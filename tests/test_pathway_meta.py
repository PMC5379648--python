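"""Pathway scan bookkeeping, correlated meta-combination, size-matched
permutation, and the random-effects meta-regression against a GLS oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcovpipe.pathway_meta import (
    MatchingError,
    MetaCombined,
    PathwayScanResult,
    _matched_random_set,
    boundary_z,
    combine_correlated,
    matched_permutation,
    meta_regress,
    pathway_scan,
    read_gmt,
)
from gcovpipe.transform import CorrelationMatrix, transform_measure


def scan_from(p_values, ses=None, traits=None, ages=None, var_set=None):
    k = len(p_values)
    return PathwayScanResult("pw", pd.DataFrame({
        "label": [f"m{i}" for i in range(k)],
        "trait": traits if traits is not None else ["A"] * k,
        "age": ages if ages is not None else list(range(k)),
        "var_set": var_set if var_set is not None else [0.1] * k,
        "se_var_set": ses if ses is not None else [0.05] * k,
        "lrt_p": p_values,
    }))


def corr_for(labels, rho=0.0):
    k = len(labels)
    return CorrelationMatrix(labels, np.full((k, k), rho) + (1 - rho) * np.eye(k))


@pytest.fixture(scope="module")
def scan_setup(small_panel, annotation, cohort):
    _, table, truth = cohort
    measures = [transform_measure(table, "SDQ-ADHD", a) for a in (12, 17)] + \
               [transform_measure(table, "SCDC", a) for a in (8,)]
    from gcovpipe.transform import correlation_matrix

    return measures, correlation_matrix(measures)


class TestPathwayScan:
    def test_row_count_conservation(self, small_panel, annotation, scan_setup):
        measures, _ = scan_setup
        genes = list(annotation.genes["gene_id"])
        results = pathway_scan(measures, small_panel, annotation,
                               {"p1": genes[:8], "p2": genes[20:28]})
        assert len(results) == 2
        assert all(len(r.rows) == 3 for r in results)

    def test_identical_measure_gives_identical_rows(self, small_panel, annotation, scan_setup):
        measures, _ = scan_setup
        genes = list(annotation.genes["gene_id"][:8])
        twice = [measures[0], measures[0]]
        res = pathway_scan(twice, small_panel, annotation, {"p": genes})[0]
        r = res.rows.drop(columns=["label"])
        assert r.iloc[0].equals(r.iloc[1])

    def test_empty_pathway_skipped(self, small_panel, annotation, scan_setup, caplog):
        measures, _ = scan_setup
        import pandas as pd

        from gcovpipe.datatypes import GeneAnnotation

        # a gene on an empty stretch far beyond every panel SNP
        ann2 = GeneAnnotation(pd.concat([
            annotation.genes,
            pd.DataFrame({"gene_id": ["desert"], "chrom": [22],
                          "start": [900_000_000], "end": [900_000_100]}),
        ], ignore_index=True))
        res = pathway_scan(measures[:1], small_panel, ann2, {"empty": ["desert"]})
        assert res == []


class TestCombineCorrelated:
    def test_single_measure_empirical_rule_reproduces_lrt_p(self):
        scan = scan_from([0.05])
        mc = combine_correlated(scan, corr_for(["m0"]), n_null=400_000, seed=5)
        assert mc.p_meta == pytest.approx(0.05, abs=0.002)
        z = boundary_z([0.05])[0]
        assert mc.statistic_q == pytest.approx(z**2)

    def test_identity_correlation_reduces_to_sum_oracle(self):
        ps = [0.03, 0.2, 0.6]
        scan = scan_from(ps)
        mc = combine_correlated(scan, corr_for(["m0", "m1", "m2"]), rule="chi2")
        q_oracle = float(np.sum(boundary_z(ps) ** 2))
        assert mc.statistic_q == pytest.approx(q_oracle, abs=1e-10)
        assert mc.p_meta == pytest.approx(stats.chi2.sf(q_oracle, 3))

    def test_equal_z_independent_measures_doubles_q(self):
        scan = scan_from([0.05, 0.05])
        mc = combine_correlated(scan, corr_for(["m0", "m1"]), rule="chi2")
        z = boundary_z([0.05])[0]
        assert mc.statistic_q == pytest.approx(2 * z**2)

    def test_bonferroni_adjustment(self):
        mc = combine_correlated(scan_from([0.01]), corr_for(["m0"]), rule="chi2")
        assert mc.p_adjusted == pytest.approx(min(1.0, mc.p_meta * 50))

    def test_null_p_meta_uniform_under_dependence(self):
        # 200 synthetic null scans of 6 correlated boundary tests
        rng = np.random.default_rng(17)
        k, rho = 6, 0.5
        R = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        L = np.linalg.cholesky(R)
        labels = [f"m{i}" for i in range(k)]
        corr = CorrelationMatrix(labels, R)
        pms = []
        for rep in range(200):
            zsigned = L @ rng.standard_normal(k)
            lrt = np.clip(zsigned, 0, None) ** 2
            p = np.where(lrt > 0, stats.norm.sf(np.sqrt(lrt)), 1.0)
            pms.append(combine_correlated(scan_from(list(p)), corr,
                                          n_null=50_000, seed=rep).p_meta)
        assert stats.kstest(pms, "uniform").pvalue > 0.01


class TestMatchedPermutation:
    def test_matching_respects_count_and_total_length(self, annotation):
        rng = np.random.default_rng(3)
        genes = annotation.genes
        lengths = (genes["end"] - genes["start"] + 1).to_numpy()
        bins = np.quantile(lengths, np.linspace(0.1, 0.9, 9))
        target = list(genes["gene_id"][:10])
        got = _matched_random_set(rng, annotation, target, bins)
        assert len(got) == 10 and not set(got) & set(target)
        t_len = lengths[genes["gene_id"].isin(target)].sum()
        g_len = lengths[genes["gene_id"].isin(got)].sum()
        assert abs(g_len - t_len) <= 0.10 * t_len

    def test_infeasible_matching_raises(self, annotation):
        rng = np.random.default_rng(4)
        genes = annotation.genes
        lengths = (genes["end"] - genes["start"] + 1).to_numpy()
        bins = np.quantile(lengths, np.linspace(0.1, 0.9, 9))
        # a target that consumes every gene leaves nothing to match from
        target = list(genes["gene_id"])
        with pytest.raises(MatchingError):
            _matched_random_set(rng, annotation, target, bins)

    def test_empirical_p_bounds_and_determinism(self, small_panel, annotation, scan_setup):
        measures, corr = scan_setup
        target = list(annotation.genes["gene_id"][:10])
        p1 = matched_permutation(small_panel, annotation, target, measures[:1], corr,
                                 n_perm=5, seed=9)
        p2 = matched_permutation(small_panel, annotation, target, measures[:1], corr,
                                 n_perm=5, seed=9)
        assert p1 == p2
        assert 1 / 6 <= p1 <= 1.0


class TestMetaRegress:
    def _corr(self, k, rho=0.3):
        return CorrelationMatrix([f"m{i}" for i in range(k)],
                                 np.full((k, k), rho) + (1 - rho) * np.eye(k))

    def test_gls_closed_form_at_zero_tau2(self):
        rng = np.random.default_rng(11)
        k = 9
        ages = np.array([7, 10, 12, 13, 17, 8, 11, 14, 17], float)
        traits = ["B"] * 5 + ["A"] * 4
        ses = np.full(k, 0.03)
        R = self._corr(k).values
        V = np.diag(ses) @ R @ np.diag(ses)
        beta_true = np.array([0.01, 0.003, -0.01, 0.0])
        tcode = np.array([1.0] * 5 + [0.0] * 4)  # alphabetical: A=0, B=1
        X = np.column_stack([np.ones(k), ages, tcode, ages * tcode])
        y = X @ beta_true + np.linalg.cholesky(V) @ rng.standard_normal(k)
        scan = scan_from([0.5] * k, ses=list(ses), traits=traits,
                         ages=list(ages), var_set=list(y))
        res = meta_regress(scan, self._corr(k))
        # independent GLS oracle (tau2 = 0)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        if res.tau2 < 1e-10:
            assert np.allclose(
                [res.beta_intercept, res.beta_age, res.beta_trait, res.beta_interaction],
                beta_gls, atol=1e-8)

    def test_age_slope_recovery(self):
        rng = np.random.default_rng(12)
        k = 9
        ages = np.array([7, 10, 12, 13, 17, 8, 11, 14, 17], float)
        traits = ["B"] * 5 + ["A"] * 4
        ses = np.full(k, 0.004)
        R = self._corr(k).values
        V = np.diag(ses) @ R @ np.diag(ses)
        y = 0.01 + 0.003 * ages + np.linalg.cholesky(V) @ rng.standard_normal(k)
        scan = scan_from([0.5] * k, ses=list(ses), traits=traits,
                         ages=list(ages), var_set=list(y))
        res = meta_regress(scan, self._corr(k), interaction=False)
        assert abs(res.beta_age - 0.003) <= 2 * res.se_age

    def test_constant_response_gives_null_slopes(self):
        k = 9
        ages = [7, 10, 12, 13, 17, 8, 11, 14, 17]
        traits = ["B"] * 5 + ["A"] * 4
        scan = scan_from([0.5] * k, ses=[0.05] * k, traits=traits, ages=ages,
                         var_set=[0.1] * k)
        res = meta_regress(scan, self._corr(k))
        assert abs(res.beta_age) < 1e-8
        assert abs(res.beta_trait) < 1e-8
        assert res.tau2 < 1e-8

    def test_needs_both_traits(self):
        scan = scan_from([0.5] * 4, traits=["A"] * 4, ages=[7, 10, 12, 13])
        with pytest.raises(ValueError):
            meta_regress(scan, self._corr(4))


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg4\n")
    sets = read_gmt(str(path))
    assert sets == {"SET_A": ["g1", "g2", "g3"], "SET_B": ["g4"]}
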