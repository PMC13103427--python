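"""Site and individual filters applied to a called-genotype VCF.

The filters mirror a standard reduced-representation (GBS) cleanup of a
low-depth call set, applied in a fixed, logged order:

1. individuals with too many missing sites;
2. sites with too many missing individuals;
3. scaffolds in the tails of the mean-depth distribution (paralog and
   low-coverage proxies);
4. 1-kb windows where too many selfer individuals are heterozygous at 10+
   sites (a selfer should be mostly homozygous; such windows flag
   collapsed paralogs or poor alignment);
5. low site quality (QUAL), low mapping quality (MQ) and excessive
   per-sample depth (FMT/DP);
6. restriction to biallelic SNPs;
7. a greedy left-to-right 200-bp spacing rule;
8. reference-panel coverage (at least 10 of 30 panel individuals with
   data, both taxa represented).

All internal interval arithmetic is half-open 0-based; VCF positions are
converted at the boundary.  Heterozygosity windows tile non-overlapping
1-kb bins from position 0.  Applying the filter twice is a no-op the
second time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import VcfData, GT_MISSING

__all__ = ["FilterConfig", "FilterResult", "apply_filters"]


@dataclass
class FilterConfig:
    max_site_missing: float = 0.25
    max_indiv_missing: float = 0.19
    depth_quantile_low: float = 0.05
    depth_quantile_high: float = 0.90
    het_window_bp: int = 1000
    het_sites_min: int = 10
    het_indiv_frac: float = 0.50
    min_QUAL: float = 30.0
    min_MQ: float = 30.0
    max_FMT_DP: float = 100.0
    min_spacing_bp: int = 200
    min_panel_n: int = 10

    def validate(self) -> None:
        for name in ("max_site_missing", "max_indiv_missing", "depth_quantile_low",
                     "depth_quantile_high", "het_indiv_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("het_window_bp", "het_sites_min", "min_spacing_bp", "min_panel_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterResult:
    site_mask: np.ndarray  # kept sites
    sample_mask: np.ndarray  # kept individuals
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def kept_sites(self) -> np.ndarray:
        return np.flatnonzero(self.site_mask)

    @property
    def kept_samples(self) -> np.ndarray:
        return np.flatnonzero(self.sample_mask)


def _spacing_keep(chrom: np.ndarray, pos: np.ndarray, active: np.ndarray,
                  min_bp: int) -> np.ndarray:
    """Greedy left-to-right spacing: keep a site only if it is at least
    min_bp beyond the last kept site on the chromosome (leftmost wins)."""
    keep = active.copy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero((chrom == c) & active)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        last = -np.inf
        for i in idx:
            if pos[i] - last < min_bp:
                keep[i] = False
            else:
                last = pos[i]
    return keep


def apply_filters(vcf: VcfData, config: FilterConfig, selfer_ids: list[str],
                  panel_coverage: Optional[pd.DataFrame] = None) -> FilterResult:
    """Apply the full filter stack; returns kept sets and per-rule removal counts.

    ``panel_coverage``, if given, must align with the VCF's site order and
    carry columns ``n_panel_out`` and ``n_panel_self`` (panel individuals
    with data per taxon); the coverage rule is skipped otherwise.
    """
    config.validate()
    unknown = set(selfer_ids) - set(vcf.samples)
    if unknown:
        raise ValueError(f"selfer ids not in VCF samples: {sorted(unknown)}")

    n_sites, n_samp = vcf.gt.shape
    site_mask = np.ones(n_sites, bool)
    sample_mask = np.ones(n_samp, bool)
    removed: dict[str, int] = {}
    missing = vcf.gt == GT_MISSING

    # 1. individual missingness
    if n_sites:
        ind_missing = missing.mean(axis=0)
        drop = ind_missing > config.max_indiv_missing
        removed["individual_missingness"] = int(drop.sum())
        sample_mask &= ~drop

    # 2. site missingness over retained individuals
    if sample_mask.any():
        site_missing = missing[:, sample_mask].mean(axis=1)
        drop = site_missing > config.max_site_missing
        removed["site_missingness"] = int((drop & site_mask).sum())
        site_mask &= ~drop

    chrom = vcf.sites["chrom"].to_numpy()
    pos = vcf.sites["pos"].to_numpy()

    # 3. scaffold mean-depth quantiles
    depth = vcf.depth[:, sample_mask] if sample_mask.any() else vcf.depth
    scaf_depth = pd.Series(depth.mean(axis=1)).groupby(chrom).mean()
    lo = scaf_depth.quantile(config.depth_quantile_low)
    hi = scaf_depth.quantile(config.depth_quantile_high)
    bad_scaf = set(scaf_depth.index[(scaf_depth < lo) | (scaf_depth > hi)])
    drop = np.isin(chrom, list(bad_scaf))
    removed["scaffold_depth_quantiles"] = int((drop & site_mask).sum())
    site_mask &= ~drop

    # 4. high-heterozygosity 1-kb windows among selfer individuals
    selfer_cols = np.array([vcf.samples.index(s) for s in selfer_ids], int)
    selfer_cols = selfer_cols[sample_mask[selfer_cols]]
    if len(selfer_cols):
        het = vcf.gt[:, selfer_cols] == 1
        win = pos // config.het_window_bp  # 0-based tiling windows
        drop = np.zeros(n_sites, bool)
        key = pd.DataFrame({"chrom": chrom, "win": win})
        for (c, w), idx in key.groupby(["chrom", "win"], sort=False).groups.items():
            idx = np.asarray(idx)
            het_counts = het[idx].sum(axis=0)  # per selfer individual
            frac = (het_counts >= config.het_sites_min).mean()
            if frac > config.het_indiv_frac:
                drop[idx] = True
        removed["heterozygosity_windows"] = int((drop & site_mask).sum())
        site_mask &= ~drop
    else:
        removed["heterozygosity_windows"] = 0

    # 5. QUAL / MQ / per-sample depth
    qual = vcf.sites["qual"].to_numpy(float)
    mq = vcf.sites["mq"].to_numpy(float)
    max_dp = (vcf.depth[:, sample_mask].max(axis=1) if sample_mask.any()
              else np.zeros(n_sites))
    drop = (qual < config.min_QUAL) | (mq < config.min_MQ) | (max_dp > config.max_FMT_DP)
    removed["qual_mq_dp"] = int((drop & site_mask).sum())
    site_mask &= ~drop

    # 6. biallelic SNPs only
    drop = ~vcf.sites["is_biallelic_snp"].to_numpy(bool)
    removed["non_biallelic"] = int((drop & site_mask).sum())
    site_mask &= ~drop

    # 7. 200-bp spacing (greedy, keeps leftmost)
    before = int(site_mask.sum())
    site_mask = _spacing_keep(chrom, pos, site_mask, config.min_spacing_bp)
    removed["spacing"] = before - int(site_mask.sum())

    # 8. panel coverage
    if panel_coverage is not None:
        n_out = panel_coverage["n_panel_out"].to_numpy(float)
        n_self = panel_coverage["n_panel_self"].to_numpy(float)
        drop = (n_out + n_self < config.min_panel_n) | (n_out < 1) | (n_self < 1)
        removed["panel_coverage"] = int((drop & site_mask).sum())
        site_mask &= ~drop

    return FilterResult(site_mask=site_mask, sample_mask=sample_mask,
                        removed_by_rule=removed)
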