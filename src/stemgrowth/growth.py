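"""Well-coverage trajectories -> per-donor growth-AUC (gAUC) phenotype.

The QC cascade runs in a fixed order and only ever removes wells:

1. informative-well filter (>=3 coverage points within [30, 70] percent)
2. magnitude-shape functional outlier removal (directional outlyingness,
   robust Mahalanobis distance of (MO, VO) against an F-approximation cutoff)
3. replicate-concordance filter (drop wells with Pearson r < r_min against
   any same-donor replicate on day-aligned series)
4. per-well min-max normalization and logistic least-squares fit
5. residual filter (RSS > mean + k_sd * SD over the batch)
6. closed-form gAUC of the fitted curve, per-donor mean, inverse-normal
   transform across the cohort
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class WellSeries:
    """One well's time-stamped coverage trajectory (percent in [0, 100])."""

    well_id: str
    donor_id: str
    times: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.times.size != self.coverage.size:
            raise ValueError("times and coverage lengths differ")
        if self.times.size < 1:
            raise ValueError("empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthFit:
    """Logistic fit of one (min-max normalized) well trajectory."""

    well_id: str
    donor_id: str
    k: float
    r: float
    n0: float
    rss: float
    converged: bool
    t_start: float
    t_end: float
    gauc: float = np.nan


def wells_from_frame(df: pd.DataFrame) -> List[WellSeries]:
    """Build WellSeries objects from a long table
    (well_id, donor_id, time_days, coverage_pct)."""
    out = []
    for (wid, did), grp in df.groupby(["well_id", "donor_id"], sort=True):
        grp = grp.sort_values("time_days")
        out.append(
            WellSeries(wid, did, grp["time_days"].to_numpy(), grp["coverage_pct"].to_numpy())
        )
    return out


# ---------------------------------------------------------------------------
# 1. informative wells
# ---------------------------------------------------------------------------


def filter_informative_wells(
    series: Sequence[WellSeries], lo: float = 30.0, hi: float = 70.0, min_obs: int = 3
) -> List[WellSeries]:
    """Keep wells with at least ``min_obs`` coverage points within [lo, hi]."""
    return [
        s
        for s in series
        if int(np.sum((s.coverage >= lo) & (s.coverage <= hi))) >= min_obs
    ]


# ---------------------------------------------------------------------------
# 2. magnitude-shape outliers
# ---------------------------------------------------------------------------


def _aligned_matrix(group: Sequence[WellSeries]) -> Tuple[np.ndarray, np.ndarray]:
    """Interpolate a group of wells onto the shared integer-day grid."""
    lo = max(np.ceil(s.times.min()) for s in group)
    hi = min(np.floor(s.times.max()) for s in group)
    grid = np.arange(lo, hi + 1)
    mat = np.vstack([np.interp(grid, s.times, s.coverage) for s in group])
    return grid, mat


def directional_outlyingness(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-well mean (MO) and variation (VO) of pointwise directional
    outlyingness relative to the group median/MAD at each time point."""
    med = np.median(mat, axis=0)
    mad = stats.median_abs_deviation(mat, axis=0, scale="normal")
    mad = np.where(mad < 1e-9, 1e-9, mad)
    o = (mat - med) / mad
    return o.mean(axis=1), o.var(axis=1)


def detect_shape_outliers(
    series: Sequence[WellSeries],
    alpha: float = 0.007,
    group_by: str = "donor",
    min_group: int = 5,
) -> Dict[str, bool]:
    """Flag functional outliers from the (MO, VO) magnitude-shape summary.

    Pointwise outlyingness is each well's deviation from its own replicate
    group's median curve, standardized by a per-timepoint robust scale pooled
    across groups (a handful of replicates cannot estimate a stable MAD on
    their own). Each well's mean (MO) and variance (VO) of outlyingness are
    then screened by robust squared Mahalanobis distance (minimum covariance
    determinant) against an F-approximation cutoff at tail level ``alpha``.
    Groups with fewer than ``min_group`` wells are skipped and contribute no
    flags.
    """
    from sklearn.covariance import MinCovDet

    flags: Dict[str, bool] = {s.well_id: False for s in series}
    if group_by == "donor":
        groups: Dict[str, List[WellSeries]] = {}
        for s in series:
            groups.setdefault(s.donor_id, []).append(s)
        group_list = list(groups.values())
    else:
        group_list = [list(series)]

    ids: List[str] = []
    resids: List[np.ndarray] = []
    n_skipped = 0
    for group in group_list:
        if len(group) < min_group:
            n_skipped += 1
            continue
        _, mat = _aligned_matrix(group)
        med = np.median(mat, axis=0)
        ids.extend(s.well_id for s in group)
        resids.extend(mat - med)
    if n_skipped:
        logger.warning(
            "shape-outlier detection skipped for %d group(s) with <%d wells",
            n_skipped, min_group,
        )
    if len(ids) < min_group:
        return flags
    # common trailing length across groups (grids may differ slightly)
    tlen = min(r.size for r in resids)
    rmat = np.vstack([r[:tlen] for r in resids])
    scale = stats.median_abs_deviation(rmat, axis=0, scale="normal")
    scale = np.where(scale < 1e-9, 1e-9, scale)
    o = rmat / scale
    pts = list(zip(o.mean(axis=1), o.var(axis=1)))
    if len(pts) < min_group:
        return flags
    pts_arr = np.asarray(pts)
    if np.allclose(pts_arr.std(axis=0), 0.0):
        return flags
    n, p = len(pts), 2
    try:
        mcd = MinCovDet(random_state=0).fit(pts_arr)
        d2 = mcd.mahalanobis(pts_arr)
    except Exception:  # singular covariance: identical curves
        return flags
    # MCD robust distances are inflated relative to the classical chi2/F law;
    # anchor the bulk at the chi2 median, keep the F tail quantile
    scale = np.median(d2) / stats.chi2.median(p)
    cutoff = scale * p * (n - 1) / max(n - p, 1) * stats.f.ppf(
        1 - alpha, p, max(n - p, 1)
    )
    for wid, dist in zip(ids, d2):
        if dist > cutoff:
            flags[wid] = True
    return flags


# ---------------------------------------------------------------------------
# 3. replicate concordance
# ---------------------------------------------------------------------------


def _day_series(s: WellSeries) -> pd.Series:
    """Coverage indexed by nearest integer day (later duplicate wins)."""
    days = np.rint(s.times).astype(int)
    return pd.Series(s.coverage, index=days).groupby(level=0).last()


def filter_discordant_replicates(
    series: Sequence[WellSeries], r_min: float = 0.75, mode: str = "greedy"
) -> List[WellSeries]:
    """Remove replicate wells discordant (Pearson r < r_min) with their peers.

    Times are rounded to the nearest day and each pair compared on shared
    days; pairs with fewer than 3 shared days are treated as non-discordant.
    ``mode='greedy'`` (default) repeatedly removes the well involved in the
    most sub-threshold pairs (ties: lower mean r, then well id) until no pair
    violates — so one rogue well among concordant replicates is removed
    alone. ``mode='strict'`` removes, in a single simultaneous pass, every
    well with at least one sub-threshold pair.
    """
    by_donor: Dict[str, List[WellSeries]] = {}
    for s in series:
        by_donor.setdefault(s.donor_id, []).append(s)

    retained: List[WellSeries] = []
    for wells in by_donor.values():
        if len(wells) == 1:
            retained.extend(wells)
            continue
        day = [_day_series(s) for s in wells]
        n = len(wells)
        rmat = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                joined = pd.concat([day[i], day[j]], axis=1, join="inner").dropna()
                if len(joined) < 3:
                    logger.warning(
                        "wells %s/%s share <3 days; concordance undefined",
                        wells[i].well_id, wells[j].well_id,
                    )
                    continue
                a, b = joined.iloc[:, 0], joined.iloc[:, 1]
                if a.std() == 0 or b.std() == 0:
                    continue
                rmat[i, j] = rmat[j, i] = float(np.corrcoef(a, b)[0, 1])

        alive = np.ones(n, dtype=bool)
        if mode == "strict":
            bad = np.nansum(
                np.where(np.isnan(rmat), 0, rmat < r_min), axis=1
            ) > 0
            alive = ~bad
        else:
            while True:
                viol = (rmat < r_min) & alive[:, None] & alive[None, :]
                viol &= ~np.isnan(rmat)
                counts = viol.sum(axis=1)
                if counts.max(initial=0) == 0:
                    break
                worst = np.where(counts == counts.max())[0]
                if worst.size > 1:
                    with np.errstate(invalid="ignore"):
                        mean_r = np.array(
                            [np.nanmean(rmat[i, alive & (np.arange(n) != i)])
                             for i in worst]
                        )
                    worst = worst[np.lexsort((
                        [wells[i].well_id for i in worst], mean_r
                    ))]
                alive[worst[0]] = False
        retained.extend(s for s, a in zip(wells, alive) if a)
    return retained


# ---------------------------------------------------------------------------
# 4. logistic fit
# ---------------------------------------------------------------------------


def _logistic(t, k, n0, r):
    c = (k - n0) / n0
    return k / (1.0 + c * np.exp(-r * t))


def fit_logistic_curve(
    series: WellSeries,
    normalize: bool = True,
    max_nfev: int = 500,
) -> GrowthFit:
    """Least-squares logistic fit N(t) = K / (1 + ((K-n0)/n0) e^{-rt}).

    Coverage is min-max scaled to [0, 1] first (``normalize=True``, the
    pipeline default). Multi-start: a data-driven initial point plus two
    perturbations; bounds K in (0, 2], n0 in (1e-6, K), r in (1e-4, 20].
    """
    t = series.times - series.times.min()
    y = series.coverage.astype(float)
    if normalize:
        span = y.max() - y.min()
        if span <= 0:
            return GrowthFit(series.well_id, series.donor_id, np.nan, np.nan,
                             np.nan, np.inf, False, series.times.min(), series.times.max())
        y = (y - y.min()) / span
    if t.size < 4:
        return GrowthFit(series.well_id, series.donor_id, np.nan, np.nan,
                         np.nan, np.inf, False, series.times.min(), series.times.max())

    k0 = max(y.max(), 1e-3)
    n00 = float(np.clip(y[y > 0][0] if np.any(y > 0) else 1e-3, 1e-5, 0.9 * k0))
    # crude rate guess from the steepest log-growth segment
    dy = np.diff(y)
    r0 = float(np.clip(np.max(dy) / max(np.mean(np.diff(t)), 1e-9) * 4.0, 0.05, 5.0))
    starts = [
        (k0, n00, r0),
        (min(1.05 * k0, 2.0), max(0.5 * n00, 2e-6), 0.5 * r0),
        (min(1.2 * k0, 2.0), min(2 * n00, 0.5 * k0), min(2 * r0, 19.0)),
    ]
    lower = np.array([1e-6, 1e-6, 1e-4])
    upper = np.array([2.0, 2.0, 20.0])

    best = None
    for start in starts:
        x0 = np.clip(np.asarray(start, dtype=float), lower + 1e-9, upper - 1e-9)

        def resid(p):
            k, n0, r = p
            n0 = min(n0, k - 1e-9)
            return _logistic(t, k, n0, r) - y

        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lower, upper), xtol=1e-10, ftol=1e-10,
                gtol=1e-10, max_nfev=max_nfev,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return GrowthFit(series.well_id, series.donor_id, np.nan, np.nan,
                         np.nan, np.inf, False, series.times.min(), series.times.max())
    rss, sol = best
    k, n0, r = sol.x
    n0 = min(n0, k * (1 - 1e-9))
    converged = bool(sol.success) and k > 0 and r > 0 and 0 < n0 < k
    return GrowthFit(
        series.well_id, series.donor_id, float(k), float(r), float(n0),
        rss, converged, float(series.times.min()), float(series.times.max()),
    )


# ---------------------------------------------------------------------------
# 5/6. gAUC and residual filter
# ---------------------------------------------------------------------------


def compute_gauc(fit: GrowthFit, t_start: float = None, t_end: float = None) -> float:
    """Closed-form integral of the fitted logistic over [t_start, t_end].

    antiderivative: K t + (K/r) ln(1 + c e^{-rt}), c = (K - n0) / n0.
    Defaults to the well's own observation window (shifted to start at 0,
    matching the time origin used in the fit).
    """
    if not fit.converged:
        raise ValueError(f"well {fit.well_id}: cannot integrate a non-converged fit")
    if t_start is None:
        t_start = 0.0
    if t_end is None:
        t_end = fit.t_end - fit.t_start
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    k, r, n0 = fit.k, fit.r, fit.n0
    c = (k - n0) / n0

    def anti(t):
        # log1p of c*e^{-rt} computed stably for large c or rt
        x = np.log(c) - r * t
        return k * t + (k / r) * np.logaddexp(0.0, x)

    return float(anti(t_end) - anti(t_start))


def filter_poor_fits(fits: Sequence[GrowthFit], k_sd: float = 3.0) -> List[GrowthFit]:
    """Drop non-converged fits and fits with RSS > mean + k_sd * SD (global)."""
    conv = [f for f in fits if f.converged]
    if not conv:
        return []
    rss = np.array([f.rss for f in conv])
    mu, sd = rss.mean(), rss.std(ddof=0)
    cut = mu + k_sd * sd
    return [f for f in conv if f.rss <= cut]


# ---------------------------------------------------------------------------
# replicate concordance statistic and donor summary
# ---------------------------------------------------------------------------


def icc_one_way(groups: Iterable[Sequence[float]]) -> Tuple[float, float, float]:
    """ICC(1,1) from a one-way random-effects ANOVA on grouped values.

    For unbalanced groups the effective group size is
    k0 = (N - sum n_i^2 / N) / (g - 1); ICC = (MSB - MSW) / (MSB + (k0-1) MSW).
    Returns (icc, F, p) with F = MSB/MSW on (g-1, N-g) df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    g = len(groups)
    if g < 2:
        raise ValueError("need >=2 groups")
    sizes = np.array([len(x) for x in groups])
    n_total = int(sizes.sum())
    if n_total == g:
        raise ValueError("all groups singleton; within-group MS undefined")
    grand = np.concatenate(groups).mean()
    ssb = float(sum(n * (x.mean() - grand) ** 2 for n, x in zip(sizes, groups)))
    ssw = float(sum(((x - x.mean()) ** 2).sum() for x in groups))
    msb = ssb / (g - 1)
    msw = ssw / (n_total - g)
    k0 = (n_total - (sizes**2).sum() / n_total) / (g - 1)
    if msw == 0:
        icc = 1.0
        f = np.inf
        p = 0.0
    else:
        icc = (msb - msw) / (msb + (k0 - 1) * msw)
        f = msb / msw
        p = float(stats.f.sf(f, g - 1, n_total - g))
    return float(icc), float(f), p


def inverse_normal_transform(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset; ties share ranks."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    n = v.size
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def summarize_donor_phenotype(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    """Per-donor mean gAUC over retained wells + cohort-level INT values."""
    rows = {}
    for f in fits:
        rows.setdefault(f.donor_id, []).append(f.gauc)
    donors = sorted(rows)
    mean_gauc = np.array([float(np.mean(rows[d])) for d in donors])
    out = pd.DataFrame(
        {
            "donor_id": donors,
            "mean_gauc": mean_gauc,
            "n_wells_retained": [len(rows[d]) for d in donors],
        }
    )
    out["int_value"] = inverse_normal_transform(mean_gauc)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def derive_growth_phenotypes(
    wells: pd.DataFrame,
    alpha: float = 0.007,
    r_min: float = 0.75,
    k_sd: float = 3.0,
    gauc_horizon: Optional[float] = None,
):
    """Run the full QC cascade on a long well table.

    Returns (fits DataFrame, donor phenotype DataFrame, QC report DataFrame
    listing each dropped well with the stage and reason).
    """
    series = wells_from_frame(wells)
    report = []

    kept = filter_informative_wells(series)
    dropped = {s.well_id for s in series} - {s.well_id for s in kept}
    report += [(w, "informative", "fewer than 3 points in [30,70]%") for w in sorted(dropped)]

    flags = detect_shape_outliers(kept, alpha=alpha)
    kept2 = [s for s in kept if not flags[s.well_id]]
    report += [
        (s.well_id, "shape_outlier", "MS-plot outlyingness above cutoff")
        for s in kept
        if flags[s.well_id]
    ]

    kept3 = filter_discordant_replicates(kept2, r_min=r_min)
    dropped = {s.well_id for s in kept2} - {s.well_id for s in kept3}
    report += [(w, "concordance", f"Pearson r < {r_min} with a replicate") for w in sorted(dropped)]

    fits = [fit_logistic_curve(s) for s in kept3]
    good = filter_poor_fits(fits, k_sd=k_sd)
    good_ids = {f.well_id for f in good}
    for f in fits:
        if f.well_id not in good_ids:
            reason = "fit did not converge" if not f.converged else "RSS above mean + k*SD"
            report.append((f.well_id, "fit_quality", reason))

    horizons = []
    for f in good:
        t_end = gauc_horizon if gauc_horizon is not None else None
        f.gauc = compute_gauc(f, 0.0, t_end)
        horizons.append(f.t_end - f.t_start if t_end is None else t_end)
    if horizons:
        h = np.asarray(horizons)
        if h.max() > 1.2 * h.min():
            logger.warning(
                "gAUC windows differ by >20%% across wells (%.3g..%.3g days)",
                h.min(), h.max(),
            )

    fit_df = pd.DataFrame(
        [
            {
                "well_id": f.well_id,
                "donor_id": f.donor_id,
                "K": f.k,
                "r": f.r,
                "n0": f.n0,
                "rss": f.rss,
                "gauc": f.gauc,
            }
            for f in good
        ]
    )
    pheno = summarize_donor_phenotype(good) if good else pd.DataFrame(
        columns=["donor_id", "mean_gauc", "n_wells_retained", "int_value"]
    )
    qc = pd.DataFrame(report, columns=["well_id", "stage", "reason"])
    return fit_df, pheno, qc
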