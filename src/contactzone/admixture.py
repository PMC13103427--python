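"""Admixture summaries derived from ancestry-genotype posteriors.

Two genome-wide admixture estimators are computed per individual:

* ``alpha_hardcall`` — restrict to sites whose most likely ancestry
  genotype has posterior probability strictly greater than 0.9, hard-call
  each such site, map CC/HC/HH to 0/0.5/1 and average;
* ``alpha_weighted`` — average the posterior-weighted admixture score
  z = 0.5 w_HC + w_HH over all sites, confident or not.

Both express the heterospecific fraction relative to the individual's
field taxon label.  Triangle-plot coordinates (proportion outcrosser
ancestry on x, proportion of inter-ancestry heterozygous sites on y) and a
coarse hybrid classification are derived from the high-confidence calls,
and chloroplast-capture tallies from the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .hmm import AncestryPosteriorMatrix
from .simulate import IndividualRecord, records_to_frame

__all__ = [
    "HybridBoundaries",
    "AdmixtureEstimate",
    "alpha_hardcall",
    "alpha_weighted",
    "triangle_coordinates",
    "classify_hybrid",
    "chloroplast_capture_tally",
    "summarize_group",
]

HIGH_CONFIDENCE = 0.9
_X = np.array([0.0, 0.5, 1.0])  # admixture contribution of {CC, HC, HH}


@dataclass
class HybridBoundaries:
    """Configurable numeric boundaries of the triangle-plot hybrid classes."""

    f1_p_halfwidth: float = 0.1  # |p - 0.5| tolerance for F1s
    f1_h_min: float = 0.85
    parental_alpha_max: float = 0.05
    # Split recent (backcross/F2-like) from older admixture at H >= this
    # fraction of the triangle ceiling 2*min(p, 1-p).  Hardy-Weinberg
    # proportioned recent hybrids sit at ~0.5 of the ceiling, so the
    # boundary is placed below that with margin.
    recent_h_fraction: float = 0.35


@dataclass
class AdmixtureEstimate:
    """Per-individual admixture summary."""

    id: str
    alpha_all: float
    alpha_hc: Optional[float]
    n_hi_conf: int
    p_outcrosser: Optional[float]
    H_interancestry: Optional[float]
    hybrid_class: Optional[str]


def alpha_hardcall(posteriors: np.ndarray, threshold: float = HIGH_CONFIDENCE
                   ) -> tuple[Optional[float], int]:
    """Hard-call admixture proportion over high-confidence sites.

    Sites qualify when their maximum posterior is strictly greater than the
    threshold.  Returns (alpha, n_hi_conf); alpha is None when no site
    qualifies (the individual is then excluded downstream).
    """
    posteriors = np.asarray(posteriors)
    conf = posteriors.max(axis=1) > threshold
    n_hi = int(conf.sum())
    if n_hi == 0:
        return None, 0
    calls = posteriors[conf].argmax(axis=1)
    return float(_X[calls].mean()), n_hi


def alpha_weighted(posteriors: np.ndarray) -> float:
    """Posterior-weighted admixture proportion over all sites."""
    posteriors = np.asarray(posteriors)
    if posteriors.shape[0] == 0:
        raise ValueError("empty site set")
    z = posteriors @ _X
    return float(z.mean())


def triangle_coordinates(posteriors: np.ndarray, taxon_label: str,
                         threshold: float = HIGH_CONFIDENCE
                         ) -> tuple[Optional[float], Optional[float]]:
    """Triangle-plot coordinates (p_outcrosser, H) from high-confidence calls.

    x is the mean outcrosser allele fraction over confident sites (the HMM
    states count *heterospecific* copies, so the mapping depends on the
    individual's taxon label); y is the fraction of confident sites called
    inter-ancestry heterozygous (HC).
    """
    posteriors = np.asarray(posteriors)
    conf = posteriors.max(axis=1) > threshold
    if not conf.any():
        return None, None
    calls = posteriors[conf].argmax(axis=1)  # heterospecific copy count
    if taxon_label == "outcrosser":
        out_copies = 2 - calls
    elif taxon_label == "selfer":
        out_copies = calls
    else:
        raise ValueError(f"unknown taxon label {taxon_label!r}")
    p = float(out_copies.mean() / 2.0)
    h = float((calls == 1).mean())
    return p, h


def classify_hybrid(p: float, H: float,
                    boundaries: HybridBoundaries = HybridBoundaries()) -> str:
    """Coarse hybrid class from triangle coordinates.

    The class regions follow the standard reading of the triangle plot:
    F1s at the top corner (0.5, 1), parentals at the bottom corners,
    backcrosses along the lower edges, recent hybrid lineages (F2s etc.)
    in the upper middle, and old admixture low in the interior.  The
    numeric boundaries are conventions, configurable and reported.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= H <= 1.0):
        raise ValueError("(p, H) must lie inside the unit square")
    b = boundaries
    # heterospecific fraction relative to each parental corner
    alpha_self_side = p  # distance from the selfer corner (0, 0)
    alpha_out_side = 1.0 - p
    if abs(p - 0.5) <= b.f1_p_halfwidth and H >= b.f1_h_min:
        return "F1"
    if alpha_self_side <= b.parental_alpha_max and H <= b.parental_alpha_max * 2:
        return "parental_selfer"
    if alpha_out_side <= b.parental_alpha_max and H <= b.parental_alpha_max * 2:
        return "parental_outcrosser"
    ceiling = 2.0 * min(p, 1.0 - p)
    if H >= b.recent_h_fraction * ceiling:
        if abs(p - 0.5) <= b.f1_p_halfwidth:
            return "recent_hybrid"
        return "backcross_selfer" if p < 0.5 else "backcross_outcrosser"
    return "old_admixed"


def chloroplast_capture_tally(records: list[IndividualRecord] | pd.DataFrame
                              ) -> pd.DataFrame:
    """Counts and proportions of heterospecific chloroplasts per taxon x zone.

    Individuals without a chloroplast genotype are excluded from the
    denominator.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["chloroplast"].notna()].copy()
    rows = []
    for (zone, taxon), sub in df.groupby(["zone", "taxon"], sort=True):
        n = len(sub)
        n_het = int((sub["chloroplast"] != taxon).sum())
        rows.append(
            {
                "zone": zone,
                "taxon": taxon,
                "n_genotyped": n,
                "n_heterospecific_chloroplast": n_het,
                "prop_heterospecific_chloroplast": n_het / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_group(post: AncestryPosteriorMatrix, taxon_label: str,
                    threshold: float = HIGH_CONFIDENCE,
                    boundaries: HybridBoundaries = HybridBoundaries()
                    ) -> pd.DataFrame:
    """Per-individual admixture summary table for one fitted taxon/zone group."""
    rows = []
    for ind_id, fit in zip(post.ids, post.fits):
        a_all = alpha_weighted(fit.posteriors)
        a_hc, n_hi = alpha_hardcall(fit.posteriors, threshold)
        p, h = triangle_coordinates(fit.posteriors, taxon_label, threshold)
        cls = classify_hybrid(p, h, boundaries) if p is not None else None
        rows.append(
            asdict(
                AdmixtureEstimate(
                    id=ind_id, alpha_all=a_all, alpha_hc=a_hc, n_hi_conf=n_hi,
                    p_outcrosser=p, H_interancestry=h, hybrid_class=cls,
                )
            )
        )
    df = pd.DataFrame(rows)
    df["taxon"] = taxon_label
    return df
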