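"""Single-component REML variance decomposition and mixed-model utilities.

The model is Y = X beta + g + eps with g ~ N(0, K sigma_g^2) and
eps ~ N(0, I sigma_e^2); heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

The restricted likelihood is profiled over h2 after an eigen-rotation of K:
with K = U L U', d_i(h2) = h2 l_i + (1 - h2), the GLS fit at fixed h2 gives
the profiled total variance, and a 1-D bounded Brent search over h2 finds the
REML optimum. The fitted object caches the whitening transform needed for
downstream score tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_H2_LO, _H2_HI = 1e-6, 1.0 - 1e-6


@dataclass
class NullModel:
    """Fitted variance components plus the projection cache for score tests."""

    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    h2_se: float
    loglik: float
    boundary: bool
    identifiable: bool
    sample_ids: list
    X: np.ndarray
    y: np.ndarray
    # cache: eigvecs U of K, per-eigenvalue total variances v_i,
    # whitened design Q (orthonormal), whitened projected phenotype
    eigvecs: np.ndarray = field(repr=False, default=None)
    eigvals: np.ndarray = field(repr=False, default=None)
    v: np.ndarray = field(repr=False, default=None)
    q: np.ndarray = field(repr=False, default=None)
    wy_resid: np.ndarray = field(repr=False, default=None)

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Map vectors/columns into the V^{-1/2}-whitened, X-projected space.

        For any column x, x'Py = whiten(x)' . wy_resid and
        x'Px = ||whiten(x)||^2 with P the REML projection matrix.
        """
        w = (self.eigvecs.T @ x) / np.sqrt(self.v)[:, None] if x.ndim == 2 else (
            self.eigvecs.T @ x
        ) / np.sqrt(self.v)
        return w - self.q @ (self.q.T @ w)


def _profile_fit(h2, lam, yr, xr, reml=True):
    """GLS at fixed h2 in the rotated basis; returns components of the
    profiled log-likelihood. d_i = h2 lam_i + (1 - h2)."""
    d = h2 * lam + (1.0 - h2)
    dinv = 1.0 / d
    xtdx = xr.T @ (xr * dinv[:, None])
    xtdy = xr.T @ (yr * dinv)
    beta = np.linalg.solve(xtdx, xtdy)
    resid = yr - xr @ beta
    quad = float(resid @ (resid * dinv))
    n, p = yr.size, xr.shape[1]
    dof = n - p if reml else n
    sigma2 = quad / dof
    ll = -0.5 * (np.log(d).sum() + dof * np.log(sigma2) + dof)
    if reml:
        sign, logdet = np.linalg.slogdet(xtdx)
        ll -= 0.5 * logdet
    return ll, beta, sigma2, d


def reml_profile_loglik(h2, y, X, K):
    """Profiled restricted log-likelihood at a given h2 (diagnostic surface).

    Convention: lR(h2) = -1/2 [ sum log d_i + log|X' D^-1 X| +
    (n-p) log sigma2_hat + (n-p) ], constants in X and 2*pi dropped.
    """
    lam, u = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    ll, *_ = _profile_fit(h2, lam, u.T @ np.asarray(y, float), u.T @ np.asarray(X, float))
    return ll


def fit_reml_single_component(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    sample_ids: Optional[Sequence] = None,
    reml: bool = True,
    tol: float = 1e-8,
) -> NullModel:
    """REML (or ML) fit of the single-GRM mixed model; returns a NullModel."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("dimension mismatch between y, X, K")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is singular")

    lam, u = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yr = u.T @ y
    xr = u.T @ X

    identifiable = float(lam.max() - lam.min()) > 1e-8
    if not identifiable:
        logger.warning("K is (a multiple of) the identity: h2 not identifiable")

    def neg_ll(h2):
        return -_profile_fit(h2, lam, yr, xr, reml=reml)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(_H2_LO, _H2_HI), method="bounded",
        options={"xatol": tol},
    )
    h2 = float(res.x)
    ll, beta, sigma2, d = _profile_fit(h2, lam, yr, xr, reml=reml)
    if sigma2 < 1e-12 * max(float(y @ y), 1.0):
        # y lies exactly in the column space of X: variance components vanish
        logger.warning("zero residual variance: variance components degenerate")
        h2, sigma2 = 0.0, max(sigma2, 0.0)
    boundary = h2 <= _H2_LO * 10 or h2 >= 1 - 1e-4

    # SE from the numerical curvature of the profiled likelihood
    if identifiable and not boundary:
        eps = 1e-4
        l0 = _profile_fit(h2, lam, yr, xr, reml=reml)[0]
        lp = _profile_fit(min(h2 + eps, _H2_HI), lam, yr, xr, reml=reml)[0]
        lm = _profile_fit(max(h2 - eps, _H2_LO), lam, yr, xr, reml=reml)[0]
        curv = (lp - 2 * l0 + lm) / eps**2
        h2_se = float(np.sqrt(-1.0 / curv)) if curv < 0 else np.inf
    else:
        h2_se = np.inf

    sigma_g2 = h2 * sigma2
    sigma_e2 = (1 - h2) * sigma2
    d = h2 * lam + (1.0 - h2)
    v = max(sigma2, 1e-30) * d  # total variance per rotated coordinate
    wsqrt = 1.0 / np.sqrt(v)
    xw = xr * wsqrt[:, None]
    q, _ = np.linalg.qr(xw)
    yw = yr * wsqrt
    wy_resid = yw - q @ (q.T @ yw)

    return NullModel(
        beta=beta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2=h2 if identifiable else np.nan,
        h2_se=h2_se,
        loglik=float(ll),
        boundary=boundary,
        identifiable=identifiable,
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(n)),
        X=X,
        y=y,
        eigvecs=u,
        eigvals=lam,
        v=v,
        q=q,
        wy_resid=wy_resid,
    )


# ---------------------------------------------------------------------------
# donor random-intercept LMM covariate scan
# ---------------------------------------------------------------------------


def _design(frame: pd.DataFrame, terms: Sequence[str]):
    """Intercept + treatment-coded columns for the given attribute terms.

    Returns (matrix, per-term column slices)."""
    cols = [np.ones(len(frame))]
    slices = {}
    at = 1
    for t in terms:
        col = frame[t]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            slices[t] = [at]
            at += 1
        else:
            levels = sorted(col.astype(str).unique())
            idx = []
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                idx.append(at)
                at += 1
            slices[t] = idx
    return np.column_stack(cols), slices


def lmm_covariate_scan(
    well_values: pd.DataFrame,
    attributes: pd.DataFrame,
    terms: Sequence[str] = ("sex", "media", "start_cell_type", "reprogramming_method"),
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test line attributes against per-well gAUC with donor random intercept.

    ``well_values`` needs columns donor_id and gauc; ``attributes`` is the
    cohort table keyed by donor_id. Each term's p-value is a likelihood-ratio
    test (ML fits, chi2 with df = levels - 1) of the full model against the
    model with that term dropped, with donor modelled through K = Z Z'.
    Returns a frame with term, chi2, df, p, q, significant.
    """
    df = well_values.merge(attributes, on="donor_id", how="inner")
    donors, zidx = np.unique(df["donor_id"], return_inverse=True)
    z = np.zeros((len(df), len(donors)))
    z[np.arange(len(df)), zidx] = 1.0
    K = z @ z.T
    y = df["gauc"].to_numpy(dtype=float)

    usable = [t for t in terms if df[t].astype(str).nunique() >= 2]
    for t in terms:
        if t not in usable:
            logger.warning("attribute %r constant; skipped", t)
    if not usable:
        return pd.DataFrame(columns=["term", "chi2", "df", "p", "q", "significant"])

    x_full, slices = _design(df, usable)
    full = fit_reml_single_component(y, x_full, K, reml=False)
    rows = []
    for t in usable:
        keep = [i for i in range(x_full.shape[1]) if i not in slices[t]]
        reduced = fit_reml_single_component(y, x_full[:, keep], K, reml=False)
        chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
        dfree = len(slices[t])
        p = float(stats.chi2.sf(chi2, dfree)) if dfree else 1.0
        rows.append({"term": t, "chi2": chi2, "df": dfree, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multiple_testing_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def multiple_testing_adjust(pvals, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method.upper() != "BH":
        raise ValueError(f"unsupported method {method!r}")
    return multipletests(p, method="fdr_bh")[1]
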