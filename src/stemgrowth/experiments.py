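"""Reproducibility experiments: parameter recovery, calibration, and oracle
agreement, each run end-to-end through the package on synthetic cohorts.

These are the seed-parameterized building blocks behind the validation
suite and ``scripts/acceptance.py``. Problem sizes are chosen so the whole
battery runs in minutes on one CPU.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import integrate, stats

from .assoc_common import score_test_scan
from .assoc_rare import rare_variant_scan
from .de import three_stage_de
from .growth import (
    GrowthFit,
    compute_gauc,
    derive_growth_phenotypes,
    fit_logistic_curve,
    icc_one_way,
    WellSeries,
)
from .power import PowerQuery, genotype_anova_power
from .qc import compute_grm, hwe_exact_test
from .synthetic import (
    SimulationConfig,
    logistic_curve,
    simulate_cohort,
    simulate_counts,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_study,
)
from .varcomp import fit_reml_single_component, reml_profile_loglik


def h2_recovery(seed: int, n_reps: int = 25, n_donors: int = 400,
                n_variants: int = 1000, h2_true: float = 0.7) -> Dict:
    """REML heritability recovery: mean estimate across replicate cohorts.

    The GRM covers the full simulated panel (MAF > 0.04) so every causal
    variant contributes to the relatedness estimate.
    """
    rng = np.random.default_rng(seed)
    ests = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = SimulationConfig(
            seed=rep_seed, n_donors=n_donors, n_common_variants=n_variants,
            n_twin_pairs=0, h2_true=h2_true,
        )
        cohort = simulate_cohort(cfg)
        common, _, _ = simulate_genotypes(cfg, cohort)
        pheno = simulate_phenotypes(cfg, cohort, common)
        grm = compute_grm(common, maf_min=0.04)
        nm = fit_reml_single_component(
            pheno["y"].to_numpy(), np.ones((n_donors, 1)), grm.matrix
        )
        ests.append(nm.h2)
    return {"h2_true": h2_true, "h2_mean": float(np.mean(ests)),
            "h2_sd": float(np.std(ests)), "n_reps": n_reps}


def score_test_calibration(seed: int, n_donors: int = 500,
                           n_test_variants: int = 2000) -> Dict:
    """Type-I error of the mixed-model score test on truly null variants.

    The phenotype carries h2 = 0.5 from a causal panel; an independent panel
    of the same size is scanned.
    """
    cfg = SimulationConfig(
        seed=seed, n_donors=n_donors, n_common_variants=2 * n_test_variants,
        n_twin_pairs=0, h2_true=0.5,
    )
    cohort = simulate_cohort(cfg)
    common, _, _ = simulate_genotypes(cfg, cohort)
    causal = common.select_variants(np.arange(n_test_variants))
    tested = common.select_variants(
        np.arange(n_test_variants, 2 * n_test_variants)
    )
    pheno = simulate_phenotypes(cfg, cohort, causal)
    grm = compute_grm(causal, maf_min=0.04)
    nm = fit_reml_single_component(
        pheno["y"].to_numpy(), np.ones((n_donors, 1)), grm.matrix
    )
    res = score_test_scan(nm, tested)
    return {
        "type1_at_005": float((res["p"] < 0.05).mean()),
        "n_variants": int(len(res)),
        "h2_hat": nm.h2,
    }


def hybrid_test_calibration(seed: int, n_donors: int = 500,
                            n_genes: int = 500, n_reps: int = 3) -> Dict:
    """Type-I error of the burden + adjusted-SKAT hybrid on null genes.

    Each replicate simulates ``n_genes`` genes; rejections are pooled across
    replicates so the empirical rate has a usefully small standard error.
    """
    rng = np.random.default_rng(seed)
    n_reject = n_tested = 0
    for _ in range(n_reps):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31 - 1)), n_donors=n_donors,
            n_common_variants=800, n_rare_variants=8 * n_genes,
            n_genes_rare=n_genes, n_twin_pairs=0, h2_true=0.3,
        )
        cohort = simulate_cohort(cfg)
        common, rare, annotations = simulate_genotypes(cfg, cohort)
        pheno = simulate_phenotypes(cfg, cohort, common)  # rare panel is null
        grm = compute_grm(common, maf_min=0.04)
        nm = fit_reml_single_component(
            pheno["y"].to_numpy(), np.ones((n_donors, 1)), grm.matrix
        )
        res = rare_variant_scan(rare, annotations, nm)
        n_reject += int((res["p_hybrid"] < 0.05).sum())
        n_tested += len(res)
    return {
        "type1_at_005": n_reject / n_tested,
        "n_genes_tested": int(n_tested),
    }


def growth_recovery(seed: int) -> Dict:
    """Noiseless logistic wells: parameter recovery and gAUC vs quadrature."""
    rng = np.random.default_rng(seed)
    k_err = r_err = 0.0
    gauc_err = 0.0
    for _ in range(20):
        k, n0, r = 1.0, rng.uniform(0.02, 0.2), rng.uniform(0.3, 1.5)
        t = np.arange(16, dtype=float)
        y = logistic_curve(t, k, n0, r)
        fit = fit_logistic_curve(
            WellSeries("w", "d", t, y), normalize=False
        )
        k_err = max(k_err, abs(fit.k - k) / k)
        r_err = max(r_err, abs(fit.r - r) / r)
        c = (fit.k - fit.n0) / fit.n0
        quad, _ = integrate.quad(
            lambda s: fit.k / (1 + c * np.exp(-fit.r * s)), 0, 15, limit=200
        )
        gauc_err = max(gauc_err, abs(compute_gauc(fit, 0, 15) - quad))
    return {"k_rel_err": k_err, "r_rel_err": r_err, "gauc_quad_abs_err": gauc_err}


def growth_artifact_detection(seed: int, n_donors: int = 60) -> Dict:
    """Sensitivity / false-removal of the QC cascade on injected artifacts."""
    cfg = SimulationConfig(
        seed=seed, n_donors=n_donors, wells_per_donor=8, n_twin_pairs=0,
        outlier_well_fraction=0.08, discordant_well_fraction=0.04,
        coverage_noise_sd=2.0,
    )
    study = simulate_study(cfg)
    fits, pheno, qc = derive_growth_phenotypes(study.wells)
    truth = study.well_truth.set_index("well_id")
    dropped = set(qc["well_id"])
    bad = truth.index[truth["kind"] != "clean"]
    clean = truth.index[truth["kind"] == "clean"]
    rho = stats.spearmanr(
        pheno.merge(study.phenotypes, on="donor_id")[["mean_gauc", "y"]]
    ).statistic
    return {
        "sensitivity": float(np.mean([w in dropped for w in bad])),
        "false_removal": float(np.mean([w in dropped for w in clean])),
        "latent_spearman": float(rho),
    }


def icc_regime(seed: int, n_groups: int = 400) -> Dict:
    """ICC(1,1) in a 24:1 between:within variance regime (expected 0.96)."""
    rng = np.random.default_rng(seed)
    groups = [
        rng.normal(mu, 1.0, size=int(rng.integers(3, 9)))
        for mu in rng.normal(0.0, np.sqrt(24.0), size=n_groups)
    ]
    icc, f, p = icc_one_way(groups)
    return {"icc": icc, "p": p}


def de_null_calibration(seed: int, n_donors: int = 150,
                        n_genes: int = 400) -> Dict:
    """Three-stage DE under the global null: BH discovery fraction."""
    cfg = SimulationConfig(
        seed=seed, n_donors=n_donors, n_expr_genes=n_genes, de_fraction=0.0,
        n_twin_pairs=0,
    )
    cohort = simulate_cohort(cfg)
    common, _, _ = simulate_genotypes(cfg, cohort)
    pheno = simulate_phenotypes(cfg, cohort, common)
    counts, truth, _ = simulate_counts(cfg, pheno)
    y = pheno["y"].to_numpy()
    z = (y - y.mean()) / y.std()
    stage3, stage1, _, _ = three_stage_de(counts, z)
    return {
        "null_discovery_fraction": float((stage3["q"] < 0.05).mean()),
        "n_genes": int(len(stage3)),
    }


def de_confounding(seed: int, n_donors: int = 200, n_genes: int = 1000) -> Dict:
    """Three-stage DE with an unwanted factor confounded with the phenotype
    (rho = 0.3): false-discovery proportions at stages 1 and 3."""
    cfg = SimulationConfig(
        seed=seed, n_donors=n_donors, n_expr_genes=n_genes, de_fraction=0.1,
        de_log_fc=1.0, nb_dispersion=0.1, unwanted_factor_sd=0.06,
        unwanted_confounding=0.3, n_twin_pairs=0,
    )
    cohort = simulate_cohort(cfg)
    common, _, _ = simulate_genotypes(cfg, cohort)
    pheno = simulate_phenotypes(cfg, cohort, common)
    counts, truth, _ = simulate_counts(cfg, pheno)
    y = pheno["y"].to_numpy()
    z = (y - y.mean()) / y.std()
    stage3, stage1, _, _ = three_stage_de(counts, z)
    de_set = set(truth.loc[truth["is_de"], "gene_id"])
    out = {}
    for tag, res in (("stage1", stage1), ("stage3", stage3)):
        disc = set(res.loc[res["q"] < 0.05, "gene_id"])
        out[f"{tag}_fdp"] = len(disc - de_set) / max(len(disc), 1)
        out[f"{tag}_discoveries"] = len(disc)
    return out


def power_mc_agreement(seed: int, reps: int = 20000) -> Dict:
    """Max |analytic - Monte-Carlo| ANOVA power over a (maf, delta) grid."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for maf in (0.1, 0.3, 0.5):
        for delta in (0.1, 0.2, 0.3):
            q = PowerQuery(maf=maf, delta=(delta, delta), sigma=0.4584, alpha=1e-3)
            n = 400
            p0 = 1.0 - q.maf
            f = np.array([p0**2, 2 * p0 * q.maf, q.maf**2])
            mu = np.array([0.0, delta, 2 * delta])
            geno = rng.choice(3, size=(reps, n), p=f)
            y = mu[geno] + rng.normal(0, q.sigma, size=(reps, n))
            cnt = np.stack([(geno == g).sum(axis=1) for g in range(3)], axis=1)
            sums = np.stack(
                [np.where(geno == g, y, 0).sum(axis=1) for g in range(3)], axis=1
            )
            ssq = np.stack(
                [np.where(geno == g, y**2, 0).sum(axis=1) for g in range(3)], axis=1
            )
            grand = sums.sum(1) / n
            gm = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0)
            ssb = (cnt * (gm - grand[:, None]) ** 2).sum(1)
            ssw = (ssq - cnt * gm**2).sum(1)
            kk = (cnt > 0).sum(1)
            fstat = (ssb / (kk - 1)) / (ssw / (n - kk))
            pv = stats.f.sf(fstat, kk - 1, n - kk)
            emp = float((pv < q.alpha).mean())
            worst = max(worst, abs(emp - genotype_anova_power(q, n)))
    return {"max_abs_power_diff": worst}


def hwe_oracle_agreement(seed: int, n_checks: int = 40) -> Dict:
    """Exact-test p vs an integer-arithmetic enumeration oracle (n <= 200)."""
    from scipy.special import comb

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_checks):
        n = int(rng.integers(5, 201))
        g = rng.binomial(2, rng.uniform(0.05, 0.5), size=n)
        counts = [int((g == k).sum()) for k in (0, 1, 2)]
        na = 2 * counts[0] + counts[1]
        nb = 2 * counts[2] + counts[1]
        if na == 0 or nb == 0:
            oracle = 1.0
        else:
            rare = min(na, nb)
            probs = {}
            for het in range(rare % 2, rare + 1, 2):
                hr = (rare - het) // 2
                hc = (max(na, nb) - het) // 2
                probs[het] = (
                    comb(n, hr, exact=True)
                    * comb(n - hr, hc, exact=True)
                    * comb(n - hr - hc, het, exact=True)
                    * 2**het
                )
            total = sum(probs.values())
            obs = probs[counts[1]]
            oracle = sum(v for v in probs.values() if v <= obs) / total
        worst = max(worst, abs(hwe_exact_test(*counts) - oracle))
    return {"max_abs_p_diff": worst}


def reml_grid_agreement(seed: int, n: int = 40) -> Dict:
    """Profile REML log-likelihood vs a dense-matrix oracle on a 21-pt grid."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 60)) / np.sqrt(60)
    K = z @ z.T
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    worst = 0.0
    for h2 in np.linspace(0.02, 0.98, 21):
        V0 = h2 * K + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V0)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / (n - 2)
        _, ld_v = np.linalg.slogdet(V0)
        _, ld_x = np.linalg.slogdet(XtVX)
        dense = -0.5 * (ld_v + ld_x + (n - 2) * np.log(s2) + (n - 2))
        worst = max(worst, abs(reml_profile_loglik(h2, y, X, K) - dense))
    return {"max_abs_loglik_diff": worst}


def score_vs_ols(seed: int, n: int = 150, m: int = 100) -> Dict:
    """Score test in the sigma_g^2 = 0 limit vs an OLS score-test oracle."""
    from .genotypes import GenotypeMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
    nm = fit_reml_single_component(y, X, np.eye(n))
    g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    pos = 100 * (np.arange(m) + 1)
    gm = GenotypeMatrix(
        [f"S{i}" for i in range(n)],
        pd.DataFrame({"chrom": "1", "pos": pos, "ref": "A", "alt": "G",
                      "id": [f"1:{p}:A:G" for p in pos]}),
        g,
    )
    res = score_test_scan(nm, gm)
    H = X @ np.linalg.solve(X.T @ X, X.T)
    M = np.eye(n) - H
    r = M @ y
    s2 = float(r @ r) / (n - X.shape[1])
    worst = 0.0
    for j in range(m):
        x = M @ g[:, j]
        p_ols = float(stats.chi2.sf((x @ y) ** 2 / (s2 * (x @ x)), 1))
        worst = max(worst, abs(float(res["p"].iloc[j]) - p_ols))
    return {"max_abs_p_diff": worst}
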