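"""End-to-end orchestration: simulate -> growth -> qc/grm -> h2/covars ->
common scan -> rare scan -> DE -> power, from one flat config.

Every stage reads and writes plain TSV/VCF artifacts in the output
directory, so any stage can be re-entered from files produced elsewhere.
A JSON manifest records parameters, seeds, and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .assoc_common import classify_signals, score_test_scan
from .assoc_rare import format_threshold, rare_variant_scan
from .de import filter_expressed_genes, three_stage_de
from .genotypes import GenotypeMatrix, read_vcf, write_grm, write_vcf
from .growth import derive_growth_phenotypes, inverse_normal_transform
from .power import power_grid
from .qc import apply_variant_filters, compute_grm, genotype_pcs, king_kinship
from .synthetic import SimulationConfig, simulate_study
from .varcomp import fit_reml_single_component, lmm_covariate_scan

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "simulate", "growth", "qc", "h2", "covars", "cvas", "rvas", "de", "power",
)


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def _covariate_design(cohort: pd.DataFrame, pcs: Optional[np.ndarray], terms):
    cols = [np.ones(len(cohort))]
    for t in terms:
        if cohort[t].astype(str).nunique() < 2:
            continue
        levels = sorted(cohort[t].astype(str).unique())
        for lev in levels[1:]:
            cols.append((cohort[t].astype(str) == lev).to_numpy(dtype=float))
    x = np.column_stack(cols)
    if pcs is not None:
        x = np.column_stack([x, pcs])
    return x


def run_pipeline(config: Dict, out_dir) -> Dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(DEFAULT_STAGES))
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "stages": {}, "parameters": config}

    study = None
    if "simulate" in stages:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", seed)
        sim = SimulationConfig(**sim_kwargs)
        study = simulate_study(sim)
        write_vcf(study.common, out / "common.vcf")
        write_vcf(study.rare, out / "rare.vcf")
        n_wells = _write(study.wells, out / "wells.tsv")
        _write(study.cohort, out / "covariates.tsv")
        _write(study.annotations, out / "annotations.tsv")
        _write(study.well_truth, out / "well_truth.tsv")
        _write(study.expr_truth, out / "expression_truth.tsv")
        _write(study.phenotypes, out / "latent_phenotypes.tsv")
        study.counts.to_csv(out / "counts.tsv", sep="\t")
        manifest["stages"]["simulate"] = {
            "n_donors": sim.n_donors,
            "n_wells": int(study.wells["well_id"].nunique()),
            "n_records": n_wells,
            "config": asdict(sim),
        }

    cohort = pd.read_csv(out / "covariates.tsv", sep="\t") if (out / "covariates.tsv").exists() else None

    pheno = None
    if "growth" in stages:
        wells = pd.read_csv(config.get("wells", out / "wells.tsv"), sep="\t")
        fits, pheno, qc_report = derive_growth_phenotypes(
            wells,
            alpha=float(config.get("msplot_alpha", 0.007)),
            r_min=float(config.get("r_min", 0.75)),
            k_sd=float(config.get("rss_k_sd", 3.0)),
        )
        _write(fits, out / "well_fits.tsv")
        _write(pheno, out / "donor_phenotype.tsv")
        _write(qc_report, out / "growth_qc_report.tsv")
        manifest["stages"]["growth"] = {
            "wells_in": int(wells["well_id"].nunique()),
            "wells_retained": len(fits),
            "donors": len(pheno),
            "wells_dropped_by_stage": qc_report.groupby("stage").size().to_dict(),
        }
    elif (out / "donor_phenotype.tsv").exists() or "phenotype" in config:
        pheno = pd.read_csv(config.get("phenotype", out / "donor_phenotype.tsv"), sep="\t")

    common = grm = pcs = None
    if "qc" in stages:
        common = read_vcf(config.get("common_vcf", out / "common.vcf"))
        common, report = apply_variant_filters(
            common,
            maf_min=float(config.get("maf_min", 0.05)),
            hwe_p_min=float(config.get("hwe_p_min", 1e-10)),
            miss_max=float(config.get("miss_max", 0.05)),
        )
        phi, kept = king_kinship(common)
        if len(kept) < common.n_samples:
            logger.info("KING pruning removed %d duplicate samples",
                        common.n_samples - len(kept))
        common = common.select_samples(kept)
        grm = compute_grm(common, maf_min=float(config.get("grm_maf_min", 0.1)))
        write_grm(grm.sample_ids, grm.matrix, grm.n_variants_used, out / "study")
        pcs = genotype_pcs(common, n_pcs=int(config.get("n_pcs", 10)))
        pd.DataFrame(
            pcs, index=grm.sample_ids,
            columns=[f"PC{i+1}" for i in range(pcs.shape[1])],
        ).to_csv(out / "pcs.tsv", sep="\t")
        manifest["stages"]["qc"] = {
            "variants_in": report.n_input,
            "variants_retained": report.n_retained,
            "samples_retained": len(kept),
            "grm_variants": grm.n_variants_used,
        }

    # re-entrancy: reload artifacts produced by a previous invocation
    if grm is None and (out / "study.grm.id").exists():
        from .genotypes import read_grm
        from .qc import GRM as _GRM

        ids, mat, n_var = read_grm(out / "study")
        grm = _GRM(ids, mat, n_var)
        if (out / "pcs.tsv").exists():
            pcs_df = pd.read_csv(out / "pcs.tsv", sep="\t", index_col=0)
            pcs = pcs_df.loc[ids].to_numpy()
    if common is None and grm is not None and (out / "common.vcf").exists() and (
        "cvas" in stages
    ):
        common = read_vcf(config.get("common_vcf", out / "common.vcf"))
        common = common.select_samples(grm.sample_ids)

    null = None
    covar_terms = list(config.get(
        "covariate_terms", ["media", "start_cell_type", "reprogramming_method"]
    ))
    needs_null = bool({"h2", "cvas", "rvas"} & set(stages))
    if needs_null and pheno is not None and grm is not None:
        merged = pheno.merge(cohort, on="donor_id").set_index("donor_id").loc[grm.sample_ids]
        y = inverse_normal_transform(merged["mean_gauc"].to_numpy())
        x = _covariate_design(merged.reset_index(), pcs, covar_terms)
        null = fit_reml_single_component(y, x, grm.matrix, sample_ids=grm.sample_ids)
        if "h2" in stages:
            h2_row = pd.DataFrame(
                [{
                    "model": "all-samples",
                    "sigma_g2": null.sigma_g2, "sigma_e2": null.sigma_e2,
                    "h2": null.h2, "h2_se": null.h2_se, "logREML": null.loglik,
                    "boundary": null.boundary,
                }]
            )
            _write(h2_row, out / "variance_components.tsv")
            manifest["stages"]["h2"] = {"h2": null.h2, "h2_se": null.h2_se}

    if "covars" in stages and (out / "well_fits.tsv").exists() and cohort is not None:
        fits = pd.read_csv(out / "well_fits.tsv", sep="\t")
        scan = lmm_covariate_scan(fits[["donor_id", "gauc"]], cohort)
        _write(scan, out / "covariate_scan.tsv")
        manifest["stages"]["covars"] = {
            "terms_tested": len(scan),
            "significant": scan.loc[scan["significant"], "term"].tolist(),
        }

    if "cvas" in stages and null is not None and common is not None:
        results = classify_signals(score_test_scan(null, common))
        results = results.sort_values(["chrom", "pos"])
        _write(results, out / "common_assoc.tsv")
        manifest["stages"]["cvas"] = {
            "variants_tested": len(results),
            "genome_wide": int((results["tier"] == "genome-wide").sum()),
            "nominal": int((results["tier"] == "nominal").sum()),
        }

    if "rvas" in stages and null is not None:
        rare = read_vcf(config.get("rare_vcf", out / "rare.vcf"), is_rare_panel=True)
        rare = rare.select_samples(null.sample_ids)
        annotations = pd.read_csv(
            config.get("annotations", out / "annotations.tsv"), sep="\t"
        )
        res = rare_variant_scan(
            rare, annotations, null,
            cadd_min=float(config.get("cadd_min", 20.0)),
        )
        path = out / "rare_assoc.tsv"
        with open(path, "w") as fh:
            if "bonferroni_threshold" in res.attrs:
                fh.write(f"# bonferroni_threshold={format_threshold(res.attrs['bonferroni_threshold'])}\n")
            res.to_csv(fh, sep="\t", index=False)
        manifest["stages"]["rvas"] = {
            "genes_tested": len(res),
            "significant": int(res["significant"].sum()) if len(res) else 0,
        }

    if "de" in stages and pheno is not None and (out / "counts.tsv").exists():
        counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
        shared = [d for d in counts.columns if d in set(pheno["donor_id"])]
        counts = counts[shared]
        ph = pheno.set_index("donor_id").loc[shared]
        y = inverse_normal_transform(ph["mean_gauc"].to_numpy())
        cov = None
        if cohort is not None:
            co = cohort.set_index("donor_id").loc[shared].reset_index()
            cov = _covariate_design(co, None, ["start_cell_type", "reprogramming_method"])[:, 1:]
        counts = filter_expressed_genes(counts)
        stage3, stage1, controls, factor = three_stage_de(counts, y, cov)
        _write(stage3, out / "de_results.tsv")
        _write(stage1, out / "de_stage1.tsv")
        pd.DataFrame({"gene_id": controls}).to_csv(out / "de_control_genes.tsv", sep="\t", index=False)
        pd.DataFrame({"sample": shared, "factor": np.ravel(factor[:, 0] if factor.ndim == 2 else factor)}).to_csv(
            out / "de_factor.tsv", sep="\t", index=False
        )
        manifest["stages"]["de"] = {
            "genes_tested": len(stage3),
            "discoveries_q05": int((stage3["q"] < 0.05).sum()),
            "n_control_genes": len(controls),
        }

    if "power" in stages:
        grid = power_grid(
            mafs=config.get("power_mafs", [0.1, 0.3, 0.5]),
            deltas=config.get("power_deltas", [0.1, 0.2, 0.3, 0.4, 0.5]),
            sigma=float(config.get("power_sigma", 0.4584)),
            alpha=float(config.get("power_alpha", 5e-8)),
            ns=config.get("power_ns", [500, 1000, 2000, 4000, 6000]),
        )
        _write(grid, out / "power_grid.tsv")
        manifest["stages"]["power"] = {"grid_rows": len(grid)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
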