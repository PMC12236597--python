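"""Variant/sample genotype QC, LD pruning, kinship, GRM, and ancestry PCA.

All operations act on :class:`~stemgrowth.genotypes.GenotypeMatrix`. Hard
calls are obtained from dosages by nearest-integer rounding where a counting
estimator (HWE, KING) requires discrete genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE test by enumeration over heterozygote counts.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count is computed in log space; the two-sided
    p-value sums configurations with probability <= that observed.
    Monomorphic sites return p = 1.
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa_hom1 + n_het  # copies of allele A
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n_a, n_b) - hets) // 2
    # log P(n_het | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(p[p <= obs[0] * (1 + 1e-12)].sum(), 1.0))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """HWE exact p per variant from rounded hard calls."""
    hard = g.hard_calls()
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = hard[:, j]
        col = col[col >= 0]
        out[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    n_fail_maf: int
    n_fail_hwe: int
    n_fail_missing: int
    n_fail_rsq: int
    n_retained: int


def apply_variant_filters(
    g: GenotypeMatrix,
    maf_min: Optional[float] = 0.05,
    maf_max: Optional[float] = None,
    hwe_p_min: Optional[float] = 1e-10,
    miss_max: Optional[float] = 0.05,
    rsq: Optional[np.ndarray] = None,
    rsq_min: Optional[float] = None,
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Retain variants passing all supplied thresholds.

    ``maf_max`` supports the rare-panel regime (MAF < maf_max). The
    imputation-quality filter applies only when an ``rsq`` vector is given.
    """
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    maf = g.maf()

    fail_maf = np.zeros(m, dtype=bool)
    if maf_min is not None:
        fail_maf |= maf <= maf_min
    if maf_max is not None:
        fail_maf |= maf >= maf_max

    fail_hwe = np.zeros(m, dtype=bool)
    if hwe_p_min is not None:
        fail_hwe = hwe_pvalues(g) <= hwe_p_min

    fail_miss = np.zeros(m, dtype=bool)
    if miss_max is not None:
        fail_miss = g.missingness() > miss_max

    fail_rsq = np.zeros(m, dtype=bool)
    if rsq_min is not None:
        if rsq is None:
            logger.info("no imputation-quality field available; r2 filter skipped")
        else:
            fail_rsq = np.asarray(rsq) <= rsq_min

    keep = ~(fail_maf | fail_hwe | fail_miss | fail_rsq)
    if not keep.any():
        logger.warning("variant filters removed every variant")
    report = FilterReport(
        n_input=m,
        n_fail_maf=int(fail_maf.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_fail_missing=int(fail_miss.sum()),
        n_fail_rsq=int(fail_rsq.sum()),
        n_retained=int(keep.sum()),
    )
    return g.select_variants(keep), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(
    g: GenotypeMatrix,
    window_bp: int = 1000,
    step_fraction: float = 0.8,
    r2_max: float = 0.1,
    exclude_regions: Optional[pd.DataFrame] = None,
) -> List[str]:
    """Sliding-window LD pruning on dosage correlation.

    Within each window, while any retained pair has r^2 >= ``r2_max`` the
    lower-MAF member is removed (tie: larger position removed). The window
    advances by ``step_fraction * window_bp``. ``exclude_regions`` is an
    optional BED-like frame (chrom, start, end; 0-based half-open) removed
    up front. Returns retained variant ids in input order.
    """
    var = g.variants
    d = g.imputed()
    maf = g.maf()
    alive = np.ones(g.n_variants, dtype=bool)

    if exclude_regions is not None and len(exclude_regions):
        for row in exclude_regions.itertuples(index=False):
            in_region = (
                (var["chrom"].astype(str) == str(row.chrom))
                & (var["pos"] > row.start)  # 1-based pos vs 0-based start
                & (var["pos"] <= row.end)
            )
            alive &= ~in_region.to_numpy()

    step = max(int(round(step_fraction * window_bp)), 1)
    for chrom in var["chrom"].unique():
        cidx = np.where((var["chrom"] == chrom).to_numpy() & alive)[0]
        if cidx.size < 2:
            continue
        pos = var["pos"].to_numpy()[cidx]
        lo = int(pos.min())
        hi = int(pos.max())
        start = lo
        while start <= hi:
            wmask = (pos >= start) & (pos < start + window_bp)
            widx = cidx[wmask]
            widx = widx[alive[widx]]
            if widx.size >= 2:
                sub = d[:, widx]
                sd = sub.std(axis=0)
                ok = sd > 0
                if ok.sum() >= 2:
                    cc = np.corrcoef(sub[:, ok].T) ** 2
                    live = widx[ok]
                    local_alive = np.ones(live.size, dtype=bool)
                    while True:
                        r2 = cc[np.ix_(local_alive, local_alive)]
                        np.fill_diagonal(r2, 0.0)
                        if r2.size == 0 or r2.max() < r2_max:
                            break
                        i, j = np.unravel_index(np.argmax(r2), r2.shape)
                        ids = live[local_alive]
                        a, b = ids[i], ids[j]
                        # drop the lower-MAF member; tie -> larger position
                        if (maf[a], -var["pos"].iloc[a]) >= (maf[b], -var["pos"].iloc[b]):
                            drop = b
                        else:
                            drop = a
                        alive[drop] = False
                        local_alive[np.where(live == drop)[0][0]] = False
            start += step
    return list(var["id"].to_numpy()[alive])


# ---------------------------------------------------------------------------
# KING kinship and duplicate removal
# ---------------------------------------------------------------------------


def king_kinship(g: GenotypeMatrix, prune_threshold: float = 0.354):
    """KING-robust pairwise kinship and duplicate pruning.

    phi_ij = (N_het,het - 2 N_opposite_hom) / (N_het(i) + N_het(j)) over
    variants called in both samples. Pairs above ``prune_threshold`` are
    collapsed, keeping the sample with less missingness (tie: first by id).
    Returns (phi matrix DataFrame, retained sample ids).
    """
    hard = g.hard_calls().astype(float)
    hard[hard < 0] = np.nan
    n = g.n_samples
    het = hard == 1
    hom0 = hard == 0
    hom2 = hard == 2
    valid = ~np.isnan(hard)

    het_i = het.astype(float)
    # pairwise counts via matrix products
    n_hh = het_i @ het_i.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    both = valid.astype(float)
    het_valid = het_i @ both.T  # het in i at sites valid in j

    denom = het_valid + het_valid.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    undefined = denom == 0
    if undefined.any():
        logger.warning("KING undefined for %d pairs (no heterozygotes); treated as unrelated",
                       int((undefined.sum() - n) // 2))
    phi = np.where(undefined, 0.0, phi)
    np.fill_diagonal(phi, 0.5)

    missing_rate = g.missing.mean(axis=1)
    order = np.arange(n)
    pruned = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if pruned[i] or pruned[j]:
                continue
            if phi[i, j] > prune_threshold:
                if missing_rate[i] < missing_rate[j]:
                    pruned[j] = True
                elif missing_rate[j] < missing_rate[i]:
                    pruned[i] = True
                else:
                    pruned[max(i, j, key=lambda k: str(g.sample_ids[k]))] = True
    retained = [g.sample_ids[i] for i in order if not pruned[i]]
    phi_df = pd.DataFrame(phi, index=g.sample_ids, columns=g.sample_ids)
    return phi_df, retained


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    sample_ids: list
    matrix: np.ndarray
    n_variants_used: int


def compute_grm(g: GenotypeMatrix, maf_min: float = 0.1) -> GRM:
    """Standardized-dosage GRM over variants with MAF > ``maf_min``.

    K_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)),
    with in-sample allele frequencies and mean-imputed missing dosages.
    """
    maf = g.maf()
    keep = maf > maf_min
    if not keep.any():
        raise ValueError(f"no variants with MAF > {maf_min}")
    d = g.imputed()[:, keep]
    p = d.mean(axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    ok = sd > 0
    z = (d[:, ok] - 2 * p[ok]) / sd[ok]
    m = int(ok.sum())
    k = (z @ z.T) / m
    k = (k + k.T) / 2.0
    return GRM(list(g.sample_ids), k, m)


# ---------------------------------------------------------------------------
# PCA projection + ancestry assignment
# ---------------------------------------------------------------------------


def pca_project_assign(
    target: GenotypeMatrix,
    reference: GenotypeMatrix,
    reference_groups: Sequence[str],
    n_pcs: int = 30,
):
    """Project target samples onto reference PCs; assign nearest group centroid.

    PCs come from the eigendecomposition of the reference's standardized
    dosages (allele frequencies from the reference); targets are projected
    with the same standardization and assigned to the closest reference-group
    centroid (Euclidean, first ``n_pcs`` PCs).
    Returns (target PCs array, assigned group labels, reference PCs array).
    """
    shared = reference.variants["id"][reference.variants["id"].isin(target.variants["id"])]
    ref = reference.select_variants(reference.variants["id"].isin(shared).to_numpy())
    tmap = {v: i for i, v in enumerate(target.variants["id"])}
    tidx = [tmap[v] for v in ref.variants["id"]]
    tar = target.select_variants(np.asarray(tidx, dtype=int))

    dref = ref.imputed()
    p = dref.mean(axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    ok = sd > 0
    zref = (dref[:, ok] - 2 * p[ok]) / sd[ok]
    ztar = (tar.imputed()[:, ok] - 2 * p[ok]) / sd[ok]

    max_pcs = min(zref.shape) - 1
    if n_pcs > max_pcs:
        logger.warning("reducing n_pcs from %d to %d (reference size)", n_pcs, max_pcs)
        n_pcs = max(max_pcs, 1)

    u, s, vt = np.linalg.svd(zref, full_matrices=False)
    loadings = vt[:n_pcs].T  # variants x pcs
    ref_pcs = zref @ loadings
    tar_pcs = ztar @ loadings

    groups = np.asarray(reference_groups)
    labels = np.unique(groups)
    centroids = np.vstack([ref_pcs[groups == lab].mean(axis=0) for lab in labels])
    d2 = ((tar_pcs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = labels[np.argmin(d2, axis=1)]
    return tar_pcs, list(assigned), ref_pcs


def genotype_pcs(g: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """In-sample genotype PCs (for use as fixed-effect covariates)."""
    d = g.imputed()
    p = d.mean(axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    ok = sd > 0
    z = (d[:, ok] - 2 * p[ok]) / sd[ok]
    n_pcs = min(n_pcs, min(z.shape) - 1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]
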