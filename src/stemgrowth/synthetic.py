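"""Synthetic study generator.

Emulates the structure of a multi-donor iPSC growth study: a cohort table with
line attributes and monozygotic twin pairs, HWE genotypes on a common and a
rare panel, a donor latent growth phenotype with controllable SNP heritability,
daily well-coverage trajectories with injected artifact wells, and negative
binomial expression counts with an unwanted latent factor.

Every sub-simulator draws from its own RNG stream spawned from the master
seed, so enabling or resizing one component does not shift another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, variant_key

# Cohort attribute frequencies. Sex and media mirror the cohort scale the
# generator emulates (278/602 male lines; 347 mTeSR vs 255 Freedom); the
# remaining attributes have no published frequencies and default to balanced.
SEX_P_MALE = 278 / 602
MEDIA_P_MTESR = 347 / 602
START_P_BLOOD = 0.5
METHOD_P_MRNA = 0.5

PLOF_CONSEQUENCES = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Fractions are in [0, 1]; the master ``seed`` fixes all randomness.
    ``covariate_effects`` are additive shifts (phenotype SD units) applied to
    the non-reference level of each named cohort attribute.
    ``rare_causal_genes`` maps gene ids to per-unit burden effects.
    """

    seed: int = 0
    n_donors: int = 200
    n_common_variants: int = 1000
    n_rare_variants: int = 300
    n_genes_rare: int = 30
    n_twin_pairs: int = 4
    h2_true: float = 0.7
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    rare_causal_genes: Dict[str, float] = field(default_factory=dict)
    wells_per_donor: int = 8
    obs_days: int = 16
    coverage_noise_sd: float = 2.0
    outlier_well_fraction: float = 0.0
    discordant_well_fraction: float = 0.0
    n_expr_genes: int = 1000
    de_fraction: float = 0.1
    de_log_fc: float = 0.5
    nb_dispersion: float = 0.1
    unwanted_factor_sd: float = 0.0
    unwanted_confounding: float = 0.0
    # well-trajectory generative parameters: logistic carrying capacity /
    # inoculum on the coverage (percent) scale and the latent->rate map
    # r_d = rate_r0 * exp(rate_scale * z_d)
    logistic_k: float = 95.0
    logistic_n0: float = 4.0
    rate_r0: float = 0.45
    rate_scale: float = 0.12

    def __post_init__(self):
        for name in (
            "h2_true",
            "outlier_well_fraction",
            "discordant_well_fraction",
            "de_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_donors", "wells_per_donor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_twin_pairs < 0 or 2 * self.n_twin_pairs > self.n_donors:
            raise ValueError("n_twin_pairs * 2 must not exceed n_donors")

    def stream(self, name: str) -> np.random.Generator:
        """Named RNG stream derived from the master seed."""
        order = ("cohort", "genotypes", "phenotypes", "wells", "counts")
        if name not in order:
            raise KeyError(name)
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order.index(name)])


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the donor/line table with attributes and twin groups."""
    rng = config.stream("cohort")
    n = config.n_donors
    donors = [f"D{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < SEX_P_MALE, "M", "F")
    media = np.where(rng.random(n) < MEDIA_P_MTESR, "mTeSR", "Freedom")
    start = np.where(rng.random(n) < START_P_BLOOD, "blood", "fibroblast")
    method = np.where(rng.random(n) < METHOD_P_MRNA, "mRNA", "Sendai")
    twin_group = np.full(n, -1)
    if config.n_twin_pairs:
        chosen = rng.choice(n, size=2 * config.n_twin_pairs, replace=False)
        for k in range(config.n_twin_pairs):
            a, b = chosen[2 * k], chosen[2 * k + 1]
            twin_group[a] = twin_group[b] = k
    return pd.DataFrame(
        {
            "donor_id": donors,
            "sex": sex,
            "media": media,
            "start_cell_type": start,
            "reprogramming_method": method,
            "twin_group": twin_group,
        }
    )


def _twin_copy(dosages: np.ndarray, cohort: pd.DataFrame) -> None:
    """Make monozygotic twins share genotype rows (second twin := first)."""
    tg = cohort["twin_group"].to_numpy()
    for g in np.unique(tg[tg >= 0]):
        idx = np.where(tg == g)[0]
        dosages[idx[1:]] = dosages[idx[0]]


def simulate_genotypes(config: SimulationConfig, cohort: pd.DataFrame):
    """HWE genotypes: a common panel, a rare panel, and rare annotations.

    Returns (common GenotypeMatrix, rare GenotypeMatrix, annotation DataFrame
    with columns variant_id, gene_id, consequence, score, maf).
    """
    rng = config.stream("genotypes")
    n = len(cohort)
    samples = list(cohort["donor_id"])

    p_common = rng.uniform(0.05, 0.5, size=config.n_common_variants)
    common_dos = rng.binomial(2, p_common, size=(n, config.n_common_variants)).astype(float)
    _twin_copy(common_dos, cohort)
    common_vars = _variant_table("1", config.n_common_variants, start=10_000, spacing=250)
    common = GenotypeMatrix(samples, common_vars, common_dos)

    m_rare = config.n_rare_variants
    p_rare = rng.uniform(0.0005, 0.0099, size=m_rare)
    rare_dos = rng.binomial(2, p_rare, size=(n, m_rare)).astype(float)
    _twin_copy(rare_dos, cohort)
    rare_vars = _variant_table("2", m_rare, start=50_000, spacing=400)
    rare = GenotypeMatrix(samples, rare_vars, rare_dos, is_rare_panel=True)

    if m_rare:
        genes = np.array(
            [f"G{(j % max(config.n_genes_rare, 1)):04d}" for j in range(m_rare)]
        )
        cls = rng.choice(
            ["pLoF", "missense", "other"], size=m_rare, p=[0.15, 0.65, 0.20]
        )
        consequence = np.where(
            cls == "pLoF",
            rng.choice(list(PLOF_CONSEQUENCES), size=m_rare),
            np.where(cls == "missense", "missense_variant", "synonymous_variant"),
        )
        score = rng.uniform(0.0, 40.0, size=m_rare)
        maf = rare.maf()
        annotations = pd.DataFrame(
            {
                "variant_id": rare_vars["id"],
                "gene_id": genes,
                "consequence": consequence,
                "score": np.round(score, 3),
                "maf": maf,
            }
        )
    else:
        annotations = pd.DataFrame(
            columns=["variant_id", "gene_id", "consequence", "score", "maf"]
        )
    return common, rare, annotations


def _variant_table(chrom, m, start, spacing):
    pos = start + spacing * np.arange(m)
    refs = np.full(m, "A")
    alts = np.full(m, "G")
    ids = [variant_key(chrom, p, "A", "G") for p in pos]
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": refs, "alt": alts, "id": ids}
    )


def _code_attribute(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """0/1 coding of a two-level attribute (reference level -> 0)."""
    ref = {"sex": "M", "media": "mTeSR", "start_cell_type": "blood",
           "reprogramming_method": "mRNA"}.get(name)
    col = cohort[name]
    if ref is None:
        ref = sorted(col.unique())[0]
    return (col != ref).to_numpy(dtype=float)


def simulate_phenotypes(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    common: GenotypeMatrix,
    rare: Optional[GenotypeMatrix] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Donor latent phenotype y = covariates + polygenic + rare burden + noise.

    The polygenic component is empirically rescaled to a sample variance of
    exactly ``h2_true`` and the residual to ``1 - h2_true``, so the realized
    polygenic variance fraction of the (covariate-free) base phenotype matches
    ``h2_true`` in-sample.
    """
    if not 0.0 <= config.h2_true <= 1.0:
        raise ValueError("h2_true must be in [0, 1]")
    rng = config.stream("phenotypes")
    n = len(cohort)

    g = np.zeros(n)
    if config.h2_true > 0 and common.n_variants:
        d = common.imputed()
        p = d.mean(axis=0) / 2.0
        sd = np.sqrt(2 * p * (1 - p))
        ok = sd > 0
        z = (d[:, ok] - 2 * p[ok]) / sd[ok]
        b = rng.normal(size=ok.sum())
        g = z @ b
        gv = g.var()
        if gv > 0:
            g = g * np.sqrt(config.h2_true / gv)
    e = rng.normal(size=n)
    ev = e.var()
    if config.h2_true < 1 and ev > 0:
        e = (e - e.mean()) * np.sqrt((1 - config.h2_true) / ev)
    else:
        e = np.zeros(n)

    c = np.zeros(n)
    for attr, eff in config.covariate_effects.items():
        c += eff * _code_attribute(cohort, attr)

    burden_part = np.zeros(n)
    if config.rare_causal_genes and rare is not None and annotations is not None:
        for gene, eff in config.rare_causal_genes.items():
            vids = annotations.loc[annotations["gene_id"] == gene, "variant_id"]
            idx = rare.variants.index[rare.variants["id"].isin(vids)].to_numpy()
            if idx.size:
                burden_part += eff * rare.imputed()[:, idx].sum(axis=1)

    y = c + g + burden_part + e
    return pd.DataFrame(
        {
            "donor_id": cohort["donor_id"],
            "y": y,
            "genetic_value": g,
            "covariate_value": c,
            "burden_value": burden_part,
            "noise_value": e,
        }
    )


def logistic_curve(t, k, n0, r):
    """Standard logistic N(t) = K / (1 + ((K-n0)/n0) e^{-rt})."""
    c = (k - n0) / n0
    return k / (1.0 + c * np.exp(-r * np.asarray(t, dtype=float)))


def simulate_wells(config: SimulationConfig, phenotypes: pd.DataFrame):
    """Daily well-coverage trajectories per donor, with injected artifacts.

    Returns (wells DataFrame with columns well_id, donor_id, time_days,
    coverage_pct; truth DataFrame with well_id, donor_id, kind, r_true).
    Artifact kinds: 'clean', 'outlier_magnitude' (+20 coverage points),
    'outlier_warp' (compressed time axis), 'discordant' (reversed series).
    """
    if config.obs_days < 3:
        raise ValueError("obs_days must be >= 3")
    rng = config.stream("wells")
    z = phenotypes["y"].to_numpy()
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    rates = config.rate_r0 * np.exp(config.rate_scale * z)

    donors = phenotypes["donor_id"].to_numpy()
    n_wells = len(donors) * config.wells_per_donor
    kinds = np.array(["clean"] * n_wells, dtype=object)
    n_out = int(round(config.outlier_well_fraction * n_wells))
    n_disc = int(round(config.discordant_well_fraction * n_wells))
    special = rng.choice(n_wells, size=min(n_out + n_disc, n_wells), replace=False)
    for i, w in enumerate(special[:n_out]):
        kinds[w] = "outlier_magnitude" if i % 2 == 0 else "outlier_warp"
    for w in special[n_out:]:
        kinds[w] = "discordant"

    t = np.arange(config.obs_days, dtype=float)
    rows = []
    truth = []
    w = 0
    for d, r in zip(donors, rates):
        for _ in range(config.wells_per_donor):
            kind = kinds[w]
            if kind == "outlier_warp":
                cov = logistic_curve(1.8 * t, config.logistic_k, config.logistic_n0, r)
            else:
                cov = logistic_curve(t, config.logistic_k, config.logistic_n0, r)
            if kind == "outlier_magnitude":
                cov = cov + 20.0
            cov = cov + rng.normal(0.0, config.coverage_noise_sd, size=t.size)
            if kind == "discordant":
                cov = cov[::-1]
            cov = np.clip(cov, 0.0, 100.0)
            well_id = f"W{w:06d}"
            rows.append(
                pd.DataFrame(
                    {
                        "well_id": well_id,
                        "donor_id": d,
                        "time_days": t,
                        "coverage_pct": cov,
                    }
                )
            )
            truth.append((well_id, d, kind, r))
            w += 1
    wells = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth, columns=["well_id", "donor_id", "kind", "r_true"])
    return wells, truth


def simulate_counts(config: SimulationConfig, phenotypes: pd.DataFrame):
    """NB expression counts linked to the donor phenotype.

    log-mean_gi = baseline_g + b_g * z(y_i) + w_g * u_i, where u is an
    unwanted factor optionally correlated with z at ``unwanted_confounding``.
    Returns (counts DataFrame genes x samples, truth DataFrame with columns
    gene_id, is_de, log_fc, w_unwanted; and the per-sample factor u).
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = config.stream("counts")
    n = len(phenotypes)
    m = config.n_expr_genes
    y = phenotypes["y"].to_numpy()
    z = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)

    rho = config.unwanted_confounding
    u = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=n)

    base = rng.uniform(np.log(20.0), np.log(2000.0), size=m)
    n_de = int(round(config.de_fraction * m))
    is_de = np.zeros(m, dtype=bool)
    if n_de:
        de_idx = rng.choice(m, size=n_de, replace=False)
        is_de[de_idx] = True
    lfc = np.where(is_de, rng.choice([-1.0, 1.0], size=m) * config.de_log_fc, 0.0)
    w = (
        rng.normal(0.0, config.unwanted_factor_sd, size=m)
        if config.unwanted_factor_sd > 0
        else np.zeros(m)
    )

    mu = np.exp(base[:, None] + lfc[:, None] * z[None, :] + w[:, None] * u[None, :])
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    gene_ids = [f"E{g:05d}" for g in range(m)]
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"),
        columns=list(phenotypes["donor_id"]),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "log_fc": lfc, "w_unwanted": w}
    )
    return counts_df, truth, u


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    cohort: pd.DataFrame
    common: GenotypeMatrix
    rare: GenotypeMatrix
    annotations: pd.DataFrame
    phenotypes: pd.DataFrame
    wells: pd.DataFrame
    well_truth: pd.DataFrame
    counts: pd.DataFrame
    expr_truth: pd.DataFrame
    unwanted_factor: np.ndarray


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all sub-simulators in order and bundle the results."""
    cohort = simulate_cohort(config)
    common, rare, annotations = simulate_genotypes(config, cohort)
    phenotypes = simulate_phenotypes(config, cohort, common, rare, annotations)
    wells, well_truth = simulate_wells(config, phenotypes)
    counts, expr_truth, u = simulate_counts(config, phenotypes)
    return SimulatedStudy(
        config, cohort, common, rare, annotations, phenotypes,
        wells, well_truth, counts, expr_truth, u,
    )
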