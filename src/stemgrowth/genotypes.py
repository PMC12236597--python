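"""Genotype containers and VCF / GRM text I/O.

Dosage matrices are stored samples x variants with values in [0, 2]
(alternate-allele dose). Missing entries are carried in an explicit mask and
mean-imputed only where an operation requires complete data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]


def variant_key(chrom, pos, ref, alt) -> str:
    """Normalized variant identifier (1-based VCF coordinates)."""
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Attributes
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos (1-based), ref, alt, id
    dosages : float array (n_samples, n_variants), values in [0, 2]
    missing : bool array, True where the call is missing
    is_rare_panel : whether this matrix holds the rare (sequencing) panel
    """

    sample_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray = None
    is_rare_panel: bool = False

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.dosages.shape, dtype=bool)
        if self.dosages.shape != self.missing.shape:
            raise ValueError("dosages and missing mask shapes differ")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample dimension mismatch")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant dimension mismatch")
        obs = self.dosages[~self.missing]
        if obs.size and (obs.min() < -1e-9 or obs.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        if not self.missing.any():
            return self.dosages.copy()
        d = np.where(self.missing, np.nan, self.dosages)
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(self.missing)
        d[idx] = col_mean[idx[1]]
        return d

    def maf(self) -> np.ndarray:
        """In-sample minor allele frequency per variant."""
        d = np.where(self.missing, np.nan, self.dosages)
        p = np.nanmean(d, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to {0,1,2}; missing entries become -1."""
        g = np.rint(self.dosages).astype(int)
        g = np.clip(g, 0, 2)
        g[self.missing] = -1
        return g

    def missingness(self) -> np.ndarray:
        """Per-variant missing-call fraction."""
        return self.missing.mean(axis=0)

    def select_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            missing=self.missing[:, idx],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return replace(
            self,
            sample_ids=list(sample_ids),
            dosages=self.dosages[idx],
            missing=self.missing[idx],
        )


# ---------------------------------------------------------------------------
# VCF I/O (4.2, GT + DS)
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=stemgrowth
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
"""


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 with GT and DS."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in g.variants["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        hard = g.hard_calls()
        for j, row in enumerate(g.variants.itertuples(index=False)):
            cells = []
            for i in range(g.n_samples):
                if g.missing[i, j]:
                    cells.append("./.:.")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(hard[i, j])]
                    cells.append(f"{gt}:{g.dosages[i, j]:.3f}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                "\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, is_rare_panel: bool = False) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; DS preferred, GT fallback."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages, missing = [], [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        vid = var.ID if var.ID not in (None, ".") else variant_key(
            var.CHROM, var.POS, var.REF, alt
        )
        rows.append((var.CHROM, var.POS, var.REF, alt, vid))
        ds = None
        try:
            fmt = var.format("DS")
            if fmt is not None:
                ds = np.asarray(fmt, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is not None:
            miss = ~np.isfinite(ds)
            ds = np.where(miss, 0.0, ds)
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0,1,2 alt copies; 3=missing... cyvcf2: 2=unknown
            # cyvcf2 gt_types: 0=HOM_REF,1=HET,2=UNKNOWN,3=HOM_ALT
            ds = np.select(
                [gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan
            )
            miss = ~np.isfinite(ds)
            ds = np.where(miss, 0.0, ds)
        dosages.append(ds)
        missing.append(miss)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if dosages:
        dos = np.column_stack(dosages)
        mis = np.column_stack(missing)
    else:
        dos = np.zeros((len(samples), 0))
        mis = np.zeros((len(samples), 0), dtype=bool)
    return GenotypeMatrix(samples, variants, dos, mis, is_rare_panel=is_rare_panel)


# ---------------------------------------------------------------------------
# GRM text I/O (GCTA-style triples)
# ---------------------------------------------------------------------------


def write_grm(sample_ids, matrix: np.ndarray, n_variants: int, prefix) -> None:
    """Write a GRM as GCTA-style text: lower-triangle triples + .grm.id."""
    prefix = str(prefix)
    n = len(sample_ids)
    with gzip.open(prefix + ".grm.gz", "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_variants}\t{matrix[i, j]:.8g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix):
    """Read a GCTA-style text GRM; returns (sample_ids, matrix, n_variants)."""
    prefix = str(prefix)
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1] if len(parts) > 1 else parts[0])
    n = len(ids)
    mat = np.zeros((n, n))
    n_var = 0
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            mat[i, j] = mat[j, i] = float(v)
            n_var = int(m)
    return ids, mat, n_var
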