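"""Three-stage differential expression of gene counts against gAUC.

Stage 1: per-gene negative-binomial GLM (log link, median-of-ratios size
factors, method-of-moments dispersion) with a Wald test on the gAUC
coefficient. Stage 2: control genes (stage-1 raw p > 0.25) give a latent
unwanted-variation factor via the leading singular vector of their centered
log-normalized expression. Stage 3: the scan is re-run with the factor as an
additional fixed-effect covariate; BH q-values are reported.

This is a deliberately transparent NB pipeline: per-gene dispersions are
moment estimates with no trend or shrinkage.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import multiple_testing_adjust

logger = logging.getLogger(__name__)


def filter_expressed_genes(
    counts: pd.DataFrame,
    tpm: Optional[pd.DataFrame] = None,
    tpm_min: float = 0.5,
    frac_min: float = 0.5,
) -> pd.DataFrame:
    """Keep genes with abundance > ``tpm_min`` in >= ``frac_min`` of samples.

    Uses TPM when supplied; otherwise falls back to counts-per-million.
    """
    if tpm is None:
        logger.info("no TPM matrix supplied; using CPM for the expression filter")
        lib = counts.sum(axis=0)
        tpm = counts.div(lib, axis=1) * 1e6
    keep = (tpm > tpm_min).mean(axis=1) >= frac_min
    return counts.loc[keep.reindex(counts.index, fill_value=False)]


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
    finite = np.isfinite(logc).all(axis=1)
    if not finite.any():
        raise ValueError("no gene has positive counts in all samples")
    ref = logc[finite].mean(axis=1)
    sf = np.exp(np.median(logc[finite] - ref[:, None], axis=0))
    return sf


def _nb_irls(y, x, offset, alpha, max_iter=50, tol=1e-8):
    """NB GLM with log link and fixed dispersion alpha.

    Returns (beta, cov_beta, converged); var(y) = mu + alpha mu^2.
    """
    n, p = x.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.5)) - offset.mean()
    mu = np.exp(x @ beta + offset)
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        xw = x * w[:, None]
        # working response on the link scale: eta + (y - mu)/mu
        zz = x @ beta + (y - mu) / mu
        try:
            new = np.linalg.solve(x.T @ xw, x.T @ (w * zz))
        except np.linalg.LinAlgError:
            return beta, None, False
        if not np.all(np.isfinite(new)):
            return beta, None, False
        delta = np.max(np.abs(new - beta))
        beta = new
        mu = np.exp(np.clip(x @ beta + offset, -30, 30))
        if delta < tol:
            xw = x * (mu / (1.0 + alpha * mu))[:, None]
            try:
                cov = np.linalg.inv(x.T @ xw)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, None, False


def _mom_dispersion(y, mu, p):
    """Method-of-moments NB dispersion, floored at 1e-8.

    Gated on Dean's score test for overdispersion: when the data show no
    evidence of extra-Poisson variation the moment estimate is pure noise,
    so the Poisson limit (floor) is returned instead.
    """
    n = y.size
    den = np.sum(mu**2)
    if den <= 0:
        return 1e-8
    # Dean's N(0,1) statistic for H0: alpha = 0
    t_dean = np.sum((y - mu) ** 2 - y) / np.sqrt(2.0 * den)
    if t_dean < 2.3264:  # one-sided p > 0.01: treat as Poisson
        return 1e-8
    dof = max(n - p, 1)
    alpha = np.sum((y - mu) ** 2 - mu) / den * n / dof
    return float(max(alpha, 1e-8))


def nb_de_scan(
    counts: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    factor: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the phenotype coefficient.

    ``phenotype`` is the (inverse-normalized) gAUC per sample/column;
    ``covariates`` an optional n x c matrix; ``factor`` the optional
    unwanted-variation covariate. Returns gene_id, log2_fold_change, se,
    stat, p, q, converged.
    """
    n = counts.shape[1]
    if n < 20:
        raise ValueError("need >= 20 samples for the NB scan")
    cols = [np.ones(n), np.asarray(phenotype, dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    if factor is not None:
        cols.append(np.asarray(factor, dtype=float))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")

    sf = size_factors(counts)
    offset = np.log(sf)
    rows = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        # Poisson pilot fit for the dispersion estimate
        beta0, _, ok0 = _nb_irls(y, x, offset, alpha=0.0)
        mu0 = np.exp(np.clip(x @ beta0 + offset, -30, 30))
        alpha = _mom_dispersion(y, mu0, x.shape[1]) if ok0 else 1e-8
        beta, cov, ok = _nb_irls(y, x, offset, alpha=alpha)
        if not ok or cov is None:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, False))
            continue
        b = beta[1]
        se = np.sqrt(cov[1, 1])
        wald = b / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(wald)))
        rows.append((gene, b / np.log(2.0), se / np.log(2.0), wald, p, True))
    out = pd.DataFrame(
        rows, columns=["gene_id", "log2_fold_change", "se", "stat", "p", "converged"]
    )
    pmask = out["p"].notna()
    out["q"] = np.nan
    out.loc[pmask, "q"] = multiple_testing_adjust(out.loc[pmask, "p"].to_numpy())
    return out


def estimate_ruv_factor(
    counts: pd.DataFrame,
    control_genes: Sequence[str],
    k: int = 1,
) -> np.ndarray:
    """Latent unwanted-variation factor(s) from control-gene expression.

    The control submatrix is size-factor normalized, log(x+1) transformed,
    gene-centered; its leading ``k`` right singular vectors (per sample) are
    returned, shape (n_samples, k).
    """
    controls = [g for g in control_genes if g in counts.index]
    if len(controls) < 20:
        raise ValueError(
            f"only {len(controls)} control genes (<20); relax the control threshold"
        )
    sub = counts.loc[controls].to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = np.log(sub / sf[None, :] + 1.0)
    centered = norm - norm.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        raise ValueError("control-gene submatrix has zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:k].T * s[:k]


def three_stage_de(
    counts: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    control_p_min: float = 0.25,
    k: int = 1,
):
    """Stage-1 scan -> control genes (p > 0.25) -> factor -> stage-3 refit.

    Returns (stage3 results, stage1 results, control gene list, factor).
    """
    stage1 = nb_de_scan(counts, phenotype, covariates)
    controls = stage1.loc[stage1["p"] > control_p_min, "gene_id"].tolist()
    factor = estimate_ruv_factor(counts, controls, k=k)
    fac = factor[:, 0] if factor.ndim == 2 else factor
    extra = factor if k > 1 else fac
    stage3 = nb_de_scan(counts, phenotype, covariates, factor=extra)
    return stage3, stage1, controls, factor
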