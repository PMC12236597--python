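"""Rare-variant severity classification, gene burdens, and the hybrid test.

Qualifying variants are pLoF of any deleteriousness, or missense with a
phred-scaled deleteriousness score >= 20 (25 in sensitivity mode), at
MAF < 0.01. Genes enter testing with >= 2 qualifying variants and a non-zero
burden in >= 1% of the cohort. The gene-level test combines a burden score
test with a burden-adjusted SKAT (variance-component) test through Fisher's
method (chi2, 4 df), mirroring the SMMAT hybrid construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .genotypes import GenotypeMatrix
from .varcomp import NullModel
from .synthetic import PLOF_CONSEQUENCES

logger = logging.getLogger(__name__)

_PLOF = set(PLOF_CONSEQUENCES) | {"pLoF"}


def classify_variant_severity(
    annotations: pd.DataFrame,
    cadd_min: float = 20.0,
    maf_max: float = 0.01,
) -> pd.DataFrame:
    """Return the qualifying subset of an annotation table.

    Qualifying: consequence in the pLoF list (any score) OR missense with
    score >= ``cadd_min``; always subject to MAF < ``maf_max``. Unknown
    consequence strings never qualify (logged).
    """
    cons = annotations["consequence"].astype(str)
    known = cons.isin(_PLOF) | cons.isin(["missense_variant", "missense"]) | cons.isin(
        ["synonymous_variant", "other", "intron_variant"]
    )
    for c in sorted(set(cons[~known])):
        logger.warning("unknown consequence %r treated as non-qualifying", c)
    is_plof = cons.isin(_PLOF)
    is_damaging_mis = cons.isin(["missense_variant", "missense"]) & (
        annotations["score"].astype(float) >= cadd_min
    )
    rare = annotations["maf"].astype(float) < maf_max
    return annotations[(is_plof | is_damaging_mis) & rare].reset_index(drop=True)


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1, 25) density weights on MAF (standard rare-variant upweighting)."""
    return stats.beta.pdf(np.clip(np.asarray(maf, float), 1e-12, 1 - 1e-12), a, b)


@dataclass
class GeneBurdenSet:
    gene_id: str
    variant_ids: List[str]
    weights: np.ndarray
    burden: np.ndarray  # per-sample weighted minor-allele dose
    carrier_fraction: float


def build_gene_burdens(
    g_rare: GenotypeMatrix,
    qualifying: pd.DataFrame,
    carrier_min: float = 0.01,
    flat_weights: bool = False,
) -> List[GeneBurdenSet]:
    """Per-gene weighted burdens over qualifying variants.

    Keeps genes with >= 2 qualifying variants present in the rare panel and a
    non-zero burden in at least ``carrier_min`` of samples.
    """
    vid_to_col = {v: i for i, v in enumerate(g_rare.variants["id"])}
    d = g_rare.imputed()
    out = []
    for gene, grp in qualifying.groupby("gene_id", sort=True):
        cols = [vid_to_col[v] for v in grp["variant_id"] if v in vid_to_col]
        if len(cols) < 2:
            continue
        sub = d[:, cols]
        maf = grp["maf"].to_numpy(dtype=float)[: len(cols)]
        w = np.ones(len(cols)) if flat_weights else beta_maf_weights(maf)
        burden = sub @ w
        carrier = float((burden > 0).mean())
        if carrier < carrier_min:
            continue
        out.append(
            GeneBurdenSet(
                gene_id=gene,
                variant_ids=[g_rare.variants["id"].iloc[c] for c in cols],
                weights=w,
                burden=burden,
                carrier_fraction=carrier,
            )
        )
    return out


# ---------------------------------------------------------------------------
# mixture-of-chi2 tail probabilities
# ---------------------------------------------------------------------------


def liu_mod_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Tail probability of sum lambda_i chi2_1 by the modified 4-moment
    match (Liu-Tang-Zhang with the Lee correction for s1^2 > s2)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        l = a**2 - 2 * delta
    else:
        delta = 0.0
        l = 1.0 / s2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x = l + delta
    sigma_x = np.sqrt(2 * (l + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, l, delta) if delta > 0 else stats.chi2.sf(t, l))


def davies_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Tail probability of sum lambda_i chi2_1 by numeric characteristic-
    function inversion (Imhof's formula)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:  # exact: lam * chi2_1
        return float(stats.chi2.sf(q / lam[0], 1))

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    return float(np.clip(0.5 + val / np.pi, 1e-300, 1.0))


# ---------------------------------------------------------------------------
# hybrid burden + adjusted-SKAT test
# ---------------------------------------------------------------------------


def smmat_hybrid_test(
    burden_set: GeneBurdenSet,
    g_rare: GenotypeMatrix,
    null_model: NullModel,
    method: str = "moment",
) -> Dict[str, float]:
    """Hybrid gene-level test: burden score test + adjusted SKAT, Fisher-combined.

    The per-variant weighted scores are orthogonalized against the burden
    direction; the residual kernel's eigenvalues give the adjusted SKAT null
    (mixture of chi2), evaluated by 4-moment matching (``method='moment'``)
    or Imhof inversion (``method='davies'``). The two p-values are combined
    as T = -2(ln p_burden + ln p_skat) ~ chi2(4).
    """
    cols = [
        int(np.where(g_rare.variants["id"] == v)[0][0]) for v in burden_set.variant_ids
    ]
    d = g_rare.imputed()[:, cols] * burden_set.weights[None, :]
    wg = null_model.whiten(d)  # n x q, whitened & covariate-projected
    scores = wg.T @ null_model.wy_resid  # U_j = w_j g_j' P y
    cmat = wg.T @ wg  # C_jk = w_j w_k g_j' P g_k

    ones = np.ones(len(cols))
    u_b = float(scores @ ones)
    v_b = float(ones @ cmat @ ones)
    if v_b <= 1e-12:
        return {
            "gene_id": burden_set.gene_id, "n_variants": len(cols),
            "carrier_fraction": burden_set.carrier_fraction,
            "p_burden": 1.0, "p_skat": 1.0, "p_hybrid": 1.0,
            "stat_burden": 0.0, "stat_skat": 0.0, "direction": 0,
        }
    stat_b = u_b**2 / v_b
    p_burden = float(stats.chi2.sf(stat_b, 1))

    # orthogonalize scores and kernel against the burden direction
    c1 = cmat @ ones
    scores_adj = scores - c1 * (u_b / v_b)
    k_adj = cmat - np.outer(c1, c1) / v_b
    q_stat = float(scores_adj @ scores_adj)
    lam = np.linalg.eigvalsh((k_adj + k_adj.T) / 2.0)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0:
        # degenerate kernel (single variant or one shared carrier pattern):
        # the set collapses to the burden direction; report its score-test p
        return {
            "gene_id": burden_set.gene_id, "n_variants": len(cols),
            "carrier_fraction": burden_set.carrier_fraction,
            "p_burden": p_burden, "p_skat": 1.0, "p_hybrid": p_burden,
            "stat_burden": stat_b, "stat_skat": 0.0,
            "direction": int(np.sign(u_b)),
        }
    if method == "davies":
        p_skat = davies_pvalue(q_stat, lam)
    else:
        p_skat = liu_mod_pvalue(q_stat, lam)
    p_skat = float(np.clip(p_skat, 1e-300, 1.0))

    t_fisher = -2.0 * (np.log(max(p_burden, 1e-300)) + np.log(p_skat))
    p_hybrid = float(stats.chi2.sf(t_fisher, 4))
    return {
        "gene_id": burden_set.gene_id, "n_variants": len(cols),
        "carrier_fraction": burden_set.carrier_fraction,
        "p_burden": p_burden, "p_skat": p_skat, "p_hybrid": p_hybrid,
        "stat_burden": stat_b, "stat_skat": q_stat,
        "direction": int(np.sign(u_b)),
    }


def rare_variant_scan(
    g_rare: GenotypeMatrix,
    annotations: pd.DataFrame,
    null_model: NullModel,
    cadd_min: float = 20.0,
    carrier_min: float = 0.01,
    alpha: float = 0.05,
    method: str = "moment",
) -> pd.DataFrame:
    """Severity classification -> gene burdens -> hybrid tests -> Bonferroni."""
    qual = classify_variant_severity(annotations, cadd_min=cadd_min)
    sets = build_gene_burdens(g_rare, qual, carrier_min=carrier_min)
    rows = [smmat_hybrid_test(s, g_rare, null_model, method=method) for s in sets]
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_variants", "carrier_fraction", "p_burden",
            "p_skat", "p_hybrid", "stat_burden", "stat_skat", "direction",
        ],
    )
    if len(out):
        thr = bonferroni_threshold(len(out), alpha=alpha)
        out["significant"] = out["p_hybrid"] < thr
        out.attrs["bonferroni_threshold"] = thr
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_threshold(threshold: float) -> str:
    """Scientific notation at 3 significant figures (e.g. 5.90e-06)."""
    return f"{threshold:.2e}"
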