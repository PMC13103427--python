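"""Reading and writing the pipeline's standard formats.

VCF v4.2 with per-sample AD (ref,alt depths) is the interchange format for
genotype/read-count data; metadata travels as CSV, panel tables and
posterior matrices as TSV.  VCF parsing goes through cyvcf2; writing is
plain VCF text (uncompressed, deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .hmm import ReadCountMatrix, SnpPanelTable

__all__ = ["VcfData", "read_vcf", "write_vcf", "naive_genotypes"]

GT_MISSING = -1  # genotype codes: -1 missing, 0 hom-ref, 1 het, 2 hom-alt


@dataclass
class VcfData:
    """Parsed site x sample arrays from one VCF."""

    sites: pd.DataFrame  # chrom, pos, qual, mq, is_biallelic_snp
    samples: list[str]
    gt: np.ndarray  # (n_sites, n_samples) codes
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def reads(self, panel_order: Optional[pd.DataFrame] = None) -> ReadCountMatrix:
        """Read counts as individuals x sites (transposed from VCF layout)."""
        return ReadCountMatrix(ref=self.ref_depth.T, alt=self.alt_depth.T,
                               ids=list(self.samples))


def read_vcf(path) -> VcfData:
    """Parse a VCF with AD format fields into dense arrays."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, quals, mqs, bis = [], [], [], [], []
    gts, refs, alts = [], [], []
    for i, var in enumerate(vcf):
        chroms.append(var.CHROM)
        poss.append(var.POS)
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        mq = var.INFO.get("MQ")
        mqs.append(float(mq) if mq is not None else np.nan)
        bis.append(var.is_snp and len(var.ALT) == 1)
        codes = np.full(len(samples), GT_MISSING, dtype=np.int8)
        types = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes[types == 0] = 0
        codes[types == 1] = 1
        codes[types == 3] = 2
        gts.append(codes)
        ad = var.format("AD")
        if ad is None:
            refs.append(np.zeros(len(samples), int))
            alts.append(np.zeros(len(samples), int))
        else:
            ad = np.where(ad < 0, 0, ad)
            refs.append(ad[:, 0])
            alts.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples), int))
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "qual": quals, "mq": mqs, "is_biallelic_snp": bis}
    )
    return VcfData(
        sites=sites,
        samples=samples,
        gt=np.array(gts, dtype=np.int8) if gts else np.empty((0, len(samples)), np.int8),
        ref_depth=np.array(refs, dtype=np.int64) if refs else np.empty((0, len(samples)), int),
        alt_depth=np.array(alts, dtype=np.int64) if alts else np.empty((0, len(samples)), int),
    )


def naive_genotypes(reads: ReadCountMatrix) -> np.ndarray:
    """Hard genotype calls straight from read counts (for simulated VCFs).

    Sites with no reads are missing; both alleles seen is a het; otherwise
    the homozygote of the observed allele.  (Real data would come with
    caller genotypes; this is only used to give simulator output GT fields.)
    """
    depth = reads.depth
    gt = np.full(depth.shape, GT_MISSING, dtype=np.int8)
    gt[(reads.ref > 0) & (reads.alt > 0)] = 1
    gt[(reads.ref > 0) & (reads.alt == 0)] = 0
    gt[(reads.ref == 0) & (reads.alt > 0)] = 2
    return gt


_GT_STR = {GT_MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, panels: SnpPanelTable, reads: ReadCountMatrix,
              qual: Optional[np.ndarray] = None, mq: Optional[np.ndarray] = None,
              seed: Optional[int] = None) -> None:
    """Write simulated read counts as a VCF v4.2 with GT:AD:DP per sample."""
    df = panels.df
    L = len(df)
    if reads.n_sites != L:
        raise ValueError("read matrix and panel table disagree on site count")
    qual = np.full(L, 50.0) if qual is None else np.asarray(qual, float)
    mq = np.full(L, 60.0) if mq is None else np.asarray(mq, float)
    gt = naive_genotypes(reads)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=contactzone-simulator\n")
        if seed is not None:
            fh.write(f"##contactzone_seed={seed}\n")
        for chrom in df["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(reads.ids) + "\n")
        for s in range(L):
            fields = [
                str(df["chrom"].iloc[s]), str(int(df["pos"].iloc[s])),
                str(df["site_id"].iloc[s]), "A", "T",
                f"{qual[s]:g}", "PASS", f"MQ={mq[s]:g}", "GT:AD:DP",
            ]
            for i in range(reads.n_individuals):
                r, a = int(reads.ref[i, s]), int(reads.alt[i, s])
                fields.append(f"{_GT_STR[int(gt[i, s])]}:{r},{a}:{r + a}")
            fh.write("\t".join(fields) + "\n")


def write_posteriors_tsv(path, posteriors: np.ndarray, panels: SnpPanelTable) -> None:
    """Per-site posterior weights (site, w_CC, w_HC, w_HH) for one individual."""
    out = pd.DataFrame(
        {
            "site_id": panels.df["site_id"],
            "w_CC": posteriors[:, 0],
            "w_HC": posteriors[:, 1],
            "w_HH": posteriors[:, 2],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
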