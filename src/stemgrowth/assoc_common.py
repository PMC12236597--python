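"""Mixed-model score-test scan of common variants.

Two-step testing: the null model (phenotype ~ covariates + GRM random effect)
is fitted once by REML; each variant is then scored through the cached
projection P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 without refitting variance
components. U = x'Py, V = x'Px, T = U^2/V ~ chi2(1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .varcomp import NullModel

GENOME_WIDE_P = 5e-8
NOMINAL_P = 1e-6


def score_test_scan(null_model: NullModel, g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant score tests against the shared null model.

    Missing dosages are mean-imputed. Variants that are monomorphic after
    projection (V <= 1e-12) get p = 1 and a flag.
    Returns a frame with id, chrom, pos, score_u, score_v, stat, p,
    direction, n_used, degenerate — position-sorted like the input.
    """
    d = g.imputed()
    if d.shape[0] != len(null_model.sample_ids):
        raise ValueError("genotype and null-model sample dimensions differ")
    w = null_model.whiten(d)  # n x m in whitened, projected space
    u_vec = w.T @ null_model.wy_resid
    v_vec = (w**2).sum(axis=0)
    degenerate = v_vec <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(degenerate, 0.0, u_vec**2 / np.where(degenerate, 1.0, v_vec))
    p = np.where(degenerate, 1.0, stats.chi2.sf(t_stat, 1))
    out = g.variants[["id", "chrom", "pos"]].copy()
    out["score_u"] = u_vec
    out["score_v"] = v_vec
    out["stat"] = t_stat
    out["p"] = p
    out["direction"] = np.sign(u_vec).astype(int)
    out["n_used"] = d.shape[0]
    out["degenerate"] = degenerate
    return out


def classify_signals(
    results: pd.DataFrame,
    genome_wide: float = GENOME_WIDE_P,
    nominal: float = NOMINAL_P,
) -> pd.DataFrame:
    """Label each variant {genome-wide, nominal, none} by the p thresholds."""
    out = results.copy()
    p = out["p"].to_numpy()
    tier = np.where(p < genome_wide, "genome-wide", np.where(p < nominal, "nominal", "none"))
    out["tier"] = tier
    return out
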