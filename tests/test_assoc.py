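"""Common-variant score tests and rare-variant burden/SKAT hybrid tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemgrowth.assoc_common import classify_signals, score_test_scan
from stemgrowth.assoc_rare import (
    GeneBurdenSet,
    beta_maf_weights,
    bonferroni_threshold,
    build_gene_burdens,
    classify_variant_severity,
    davies_pvalue,
    format_threshold,
    liu_mod_pvalue,
    rare_variant_scan,
    smmat_hybrid_test,
)
from stemgrowth.genotypes import GenotypeMatrix
from stemgrowth.varcomp import fit_reml_single_component


def _matrix(dosages, is_rare=False):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    pos = 100 * (np.arange(m) + 1)
    var = pd.DataFrame(
        {"chrom": "1", "pos": pos, "ref": "A", "alt": "G",
         "id": [f"1:{p}:A:G" for p in pos]}
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], var, d, is_rare_panel=is_rare)


@pytest.fixture(scope="module")
def ols_null():
    """Null model with K = I (no genetic variance): equals OLS projection."""
    rng = np.random.default_rng(10)
    n = 120
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
    nm = fit_reml_single_component(y, X, np.eye(n))
    return nm, X, y, rng


class TestScoreScan:
    def test_matches_ols_score_test(self, ols_null):
        nm, X, y, _ = ols_null
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, size=(len(y), 50)).astype(float)
        res = score_test_scan(nm, _matrix(g))
        # independent OLS score-test oracle
        H = X @ np.linalg.solve(X.T @ X, X.T)
        M = np.eye(len(y)) - H
        r = M @ y
        s2 = float(r @ r) / (len(y) - X.shape[1])
        for j in range(50):
            x = M @ g[:, j]
            t_ols = (x @ y) ** 2 / (s2 * (x @ x))
            p_ols = stats.chi2.sf(t_ols, 1)
            assert res["p"].iloc[j] == pytest.approx(p_ols, abs=1e-8)

    def test_covariate_collinear_variant_degenerate(self, ols_null):
        nm, X, _, _ = ols_null
        g = np.column_stack([X[:, 1] + 1.0])  # affine in a covariate column
        g = np.clip(g - g.min(), 0, 2)
        g = X[:, [1]] - X[:, 1].min()
        g = 2 * g / g.max()
        res = score_test_scan(nm, _matrix(g))
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert bool(res["degenerate"].iloc[0])

    def test_affine_transform_of_dosage_invariant(self, ols_null):
        nm, _, _, _ = ols_null
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.4, size=(nm.y.size, 1)).astype(float)
        t1 = score_test_scan(nm, _matrix(g))["stat"].iloc[0]
        t2 = score_test_scan(nm, _matrix(np.clip(0.5 * g + 0.5, 0, 2)))["stat"].iloc[0]
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_causal_variant_detected(self):
        rng = np.random.default_rng(13)
        n = 300
        g = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        y = 0.8 * g[:, 0] + rng.normal(size=n)
        nm = fit_reml_single_component(y, np.ones((n, 1)), np.eye(n))
        res = score_test_scan(nm, _matrix(g))
        assert res["p"].iloc[0] < 1e-8
        assert res["direction"].iloc[0] == 1


class TestTiers:
    @pytest.mark.parametrize(
        "p,tier", [(4e-8, "genome-wide"), (5e-7, "nominal"), (0.5, "none")]
    )
    def test_threshold_rules(self, p, tier):
        df = pd.DataFrame({"id": ["v"], "p": [p]})
        assert classify_signals(df)["tier"].iloc[0] == tier


class TestSeverity:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "gene_id", "consequence", "score", "maf"]
        )

    def test_plof_qualifies_regardless_of_score(self):
        ann = self._ann([("v1", "g", "stop_gained", 5.0, 0.001)])
        assert len(classify_variant_severity(ann)) == 1

    def test_missense_score_boundary(self):
        ann = self._ann(
            [("v1", "g", "missense_variant", 19.9, 0.001),
             ("v2", "g", "missense_variant", 20.0, 0.001)]
        )
        out = classify_variant_severity(ann, cadd_min=20)
        assert list(out["variant_id"]) == ["v2"]

    def test_maf_rule_excludes_common(self):
        ann = self._ann([("v1", "g", "missense_variant", 22.0, 0.02)])
        assert len(classify_variant_severity(ann)) == 0

    def test_unknown_consequence_nonqualifying(self):
        ann = self._ann([("v1", "g", "mystery_consequence", 30.0, 0.001)])
        assert len(classify_variant_severity(ann)) == 0

    def test_sensitivity_mode_is_subset(self, small_study):
        q20 = classify_variant_severity(small_study.annotations, cadd_min=20)
        q25 = classify_variant_severity(small_study.annotations, cadd_min=25)
        assert set(q25["variant_id"]) <= set(q20["variant_id"])


class TestBurdens:
    def test_toy_retention_rules(self):
        d = np.zeros((10, 3))
        d[0, 0] = 1.0  # gene A variants 0,1 carried by sample 0
        d[0, 1] = 1.0
        d[3, 2] = 1.0  # gene B single variant
        g = _matrix(d, is_rare=True)
        ann = pd.DataFrame(
            {
                "variant_id": list(g.variants["id"]),
                "gene_id": ["A", "A", "B"],
                "consequence": ["stop_gained"] * 3,
                "score": [30.0] * 3,
                "maf": [0.005] * 3,
            }
        )
        qual = classify_variant_severity(ann)
        sets = build_gene_burdens(g, qual, carrier_min=0.01)
        assert [s.gene_id for s in sets] == ["A"]
        assert sets[0].carrier_fraction == pytest.approx(0.1)

    def test_flat_weights_give_allele_count(self):
        d = np.array([[1.0, 2.0], [0.0, 1.0], [0.0, 0.0]])
        g = _matrix(d, is_rare=True)
        ann = pd.DataFrame(
            {
                "variant_id": list(g.variants["id"]),
                "gene_id": ["A", "A"],
                "consequence": ["stop_gained"] * 2,
                "score": [30.0] * 2,
                "maf": [0.005] * 2,
            }
        )
        sets = build_gene_burdens(g, classify_variant_severity(ann),
                                  carrier_min=0.0, flat_weights=True)
        np.testing.assert_allclose(sets[0].burden, [3.0, 1.0, 0.0])

    def test_beta_weights_upweight_rarer(self):
        w = beta_maf_weights(np.array([0.001, 0.009]))
        assert w[0] > w[1] > 0


class TestMixtureChi2:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_moment_vs_davies_agreement(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.2, 2.0, size=6)
        q = float(lam.sum() + 2 * np.sqrt(2 * (lam**2).sum()))
        p_m = liu_mod_pvalue(q, lam)
        p_d = davies_pvalue(q, lam)
        assert np.log(p_m) == pytest.approx(np.log(p_d), rel=0.15)

    def test_single_component_exact_chi2(self):
        # one eigenvalue: the mixture is lam * chi2_1 exactly
        for q in (0.5, 2.0, 6.0):
            assert davies_pvalue(q, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(q, 1), abs=1e-6
            )
            assert liu_mod_pvalue(q, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(q, 1), rel=1e-6
            )


class TestHybrid:
    def _null_model(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        return fit_reml_single_component(y, np.ones((n, 1)), np.eye(n)), rng

    def test_identical_variants_collapse_to_burden(self):
        nm, rng = self._null_model()
        col = rng.binomial(1, 0.05, nm.y.size).astype(float)
        g = _matrix(np.column_stack([col, col]), is_rare=True)
        bs = GeneBurdenSet("g", list(g.variants["id"]), np.ones(2),
                           g.dosages @ np.ones(2), float((col > 0).mean()))
        out = smmat_hybrid_test(bs, g, nm)
        assert out["p_skat"] == pytest.approx(1.0)
        assert out["p_hybrid"] == pytest.approx(out["p_burden"])

    def test_single_variant_equals_score_test(self):
        nm, rng = self._null_model(seed=6)
        col = rng.binomial(1, 0.08, nm.y.size).astype(float)
        g = _matrix(col[:, None], is_rare=True)
        bs = GeneBurdenSet("g", list(g.variants["id"]), np.ones(1), col,
                           float((col > 0).mean()))
        out = smmat_hybrid_test(bs, g, nm)
        res = score_test_scan(nm, g)
        assert out["p_hybrid"] == pytest.approx(res["p"].iloc[0], rel=1e-9)

    def test_burden_and_skat_components_near_independent(self):
        # empirical correlation of -ln p under the null should be weak
        nm, rng = self._null_model(n=300, seed=7)
        pb, ps = [], []
        for _ in range(300):
            d = rng.binomial(1, rng.uniform(0.01, 0.05, 4), size=(300, 4)).astype(float)
            if (d.sum(axis=0) == 0).any():
                continue
            w = np.ones(4)
            g = _matrix(d, is_rare=True)
            bs = GeneBurdenSet("g", list(g.variants["id"]), w, d @ w,
                               float(((d @ w) > 0).mean()))
            out = smmat_hybrid_test(bs, g, nm)
            if out["p_skat"] < 1.0:
                pb.append(-np.log(max(out["p_burden"], 1e-12)))
                ps.append(-np.log(max(out["p_skat"], 1e-12)))
        r = np.corrcoef(pb, ps)[0, 1]
        assert abs(r) < 0.15

    def test_signal_gene_detected(self, small_study):
        # inject a strong burden effect and verify the hybrid test finds it
        rng = np.random.default_rng(8)
        rare = small_study.rare
        ann = small_study.annotations
        qual = classify_variant_severity(ann)
        sets = build_gene_burdens(rare, qual, carrier_min=0.01)
        assert sets, "fixture must yield testable genes"
        target = sets[0]
        y = rng.normal(size=rare.n_samples) + 3.0 * target.burden
        nm = fit_reml_single_component(y, np.ones((rare.n_samples, 1)),
                                       np.eye(rare.n_samples))
        out = smmat_hybrid_test(target, rare, nm)
        assert out["p_hybrid"] < 1e-4


class TestBonferroni:
    def test_paper_scale_thresholds(self):
        assert format_threshold(bonferroni_threshold(8480)) == "5.90e-06"
        assert format_threshold(bonferroni_threshold(3441)) == "1.45e-05"

    def test_single_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def test_rare_scan_end_to_end(small_study):
    nm = fit_reml_single_component(
        small_study.phenotypes["y"].to_numpy(),
        np.ones((len(small_study.cohort), 1)),
        np.eye(len(small_study.cohort)),
    )
    res = rare_variant_scan(small_study.rare, small_study.annotations, nm)
    assert (res["p_hybrid"] <= 1.0).all()
    assert (res["n_variants"] >= 2).all()
    assert (res["carrier_fraction"] >= 0.01).all()
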