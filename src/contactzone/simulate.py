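"""Forward simulation of a selfer/outcrosser contact zone.

The generator emulates the data a genotyping-by-sequencing study of a
parapatric selfing/outcrossing taxon pair would produce:

* two reference panels with divergent allele frequencies (Balding-Nichols
  model, plus a configurable fraction of near-fixed differences);
* georeferenced individuals of both taxa in two spatial clusters;
* admixed nuclear ancestry from a single historical pulse followed by
  within-taxon mating at each taxon's selfing rate, with recombination as a
  Poisson process along the Morgan map;
* strictly maternal chloroplast inheritance;
* phenotypes that are linear in true admixture plus Gaussian noise, and a
  pink/white flower-colour polymorphism in the selfer;
* binomial read counts at low mean depth (2.7x by default).

Besides the forward pedigree mode, designed cohorts (F1, F2, BC1, BCk,
old_admixed with a target admixture range) can be requested directly; these
are built by explicit meioses from constructed parents so their pedigree
class is exact.

Every random draw flows from ``SimConfig.seed``; re-running with the same
config reproduces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .hmm import SnpPanelTable, ReadCountMatrix

__all__ = [
    "TraitModel",
    "SimConfig",
    "SimTruth",
    "IndividualRecord",
    "simulate_panels",
    "simulate_zone",
    "simulate_reads",
    "records_to_frame",
    "write_metadata_csv",
    "write_truth_tsv",
    "write_config_yaml",
]

OUTCROSSER, SELFER = 0, 1
TAXON_NAMES = {OUTCROSSER: "outcrosser", SELFER: "selfer"}


@dataclass
class TraitModel:
    """Linear ancestry model for one quantitative trait.

    trait = mean(taxon) + slope(taxon) * true_alpha + N(0, sd).
    """

    mean_outcrosser: float
    mean_selfer: float
    sd: float
    slope_outcrosser: float = 0.0
    slope_selfer: float = 0.0


def default_phenotype_model() -> dict[str, TraitModel]:
    # Taxon separations >= 4 SD for petal size, herkogamy and protandry
    # (strongly bimodal in a contact zone); flowering time overlaps fully.
    return {
        "petal_size": TraitModel(60.0, 12.0, 6.0, -10.0, 10.0),
        "herkogamy": TraitModel(5.0, 0.5, 0.7, -1.0, 1.0),
        "protandry": TraitModel(2.5, 0.2, 0.4, -0.5, 0.5),
        "flowering_time": TraitModel(9.0, 8.0, 4.0, 0.0, 2.0),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic contact zone."""

    n_sites: int = 1000
    n_chromosomes: int = 2
    map_length: float = 0.5  # Morgans per chromosome
    chrom_bp: int = 20_000_000  # physical length per chromosome
    panel_divergence: float = 0.3  # Balding-Nichols F
    fixed_diff_fraction: float = 0.1
    panel_n: int = 15  # diploid panel individuals per taxon
    n_outcrosser: int = 60
    n_selfer: int = 40
    # per-taxon breeding population carried through the forward generations;
    # the requested n individuals are sampled from it at the end.  Small
    # census sizes otherwise let drift swamp the pulse fraction.
    breeding_population: int = 150
    selfing_rate_selfer: float = 0.95
    selfing_rate_outcrosser: float = 0.1
    pollen_kernel_scale: float = 20.0  # meters
    seed_dispersal: float = 5.0  # meters, mother-to-offspring
    generations_since_pulse: int = 20
    pulse_fraction: float = 0.1
    depth_mean: float = 2.7
    error_rate: float = 0.01
    seed: int = 0
    cluster_centers: tuple = ((0.0, 0.0), (150.0, 0.0))  # outcrosser, selfer
    cluster_sd: float = 40.0
    phenotype_model: dict = field(default_factory=default_phenotype_model)
    color_freq_white: float = 0.3
    color_admixture_effect: float = 0.0  # percent-admixture shift for pink selfers
    pedigree_class: Optional[str] = None  # None=forward sim; else designed cohort
    cohort_taxon: str = "outcrosser"  # field label of designed cohorts
    backcross_generations: int = 1  # k for BCk cohorts
    alpha_range: tuple = (0.0, 0.25)  # old_admixed target admixture
    zone: str = "SIM"

    def validate(self) -> None:
        probs = {
            "panel_divergence": self.panel_divergence,
            "fixed_diff_fraction": self.fixed_diff_fraction,
            "selfing_rate_selfer": self.selfing_rate_selfer,
            "selfing_rate_outcrosser": self.selfing_rate_outcrosser,
            "pulse_fraction": self.pulse_fraction,
            "error_rate": self.error_rate,
            "color_freq_white": self.color_freq_white,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.panel_divergence >= 1.0:
            raise ValueError("panel_divergence must be < 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive")
        if self.generations_since_pulse < 1:
            raise ValueError("generations_since_pulse must be >= 1")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated data.

    ``ancestry_hap`` holds absolute haplotype ancestry (0 = outcrosser
    derived, 1 = selfer derived) with shape (n_individuals, 2, n_sites).
    ``true_ancestry`` counts heterospecific copies relative to each
    individual's taxon label (0 = CC, 1 = HC, 2 = HH).
    """

    ancestry_hap: np.ndarray
    taxon: np.ndarray  # 0/1 codes per individual
    true_alpha: np.ndarray
    pedigree_class: list[str]
    chloroplast_origin: np.ndarray  # 0/1 absolute origin codes
    pedigree: list = field(default_factory=list)  # per-generation (mother, father) arrays
    founder_chloroplast: Optional[np.ndarray] = None  # forward mode: founder origins
    sample_index: Optional[np.ndarray] = None  # forward mode: breeding-pop indices sampled

    def __post_init__(self) -> None:
        het = self.true_ancestry
        expect = het.mean(axis=1) / 2.0
        if not np.allclose(expect, self.true_alpha):
            raise ValueError("true_alpha inconsistent with true_ancestry")

    @property
    def n_individuals(self) -> int:
        return self.ancestry_hap.shape[0]

    @property
    def n_sites(self) -> int:
        return self.ancestry_hap.shape[2]

    @property
    def true_ancestry(self) -> np.ndarray:
        """Heterospecific copy count per individual x site, relative to taxon label."""
        selfer_copies = self.ancestry_hap.sum(axis=1)  # selfer-derived copies
        het = np.where(self.taxon[:, None] == OUTCROSSER, selfer_copies, 2 - selfer_copies)
        return het.astype(np.int8)


@dataclass
class IndividualRecord:
    """One georeferenced, phenotyped, chloroplast-genotyped individual."""

    id: str
    taxon: str
    zone: str
    lon: float
    lat: float
    petal_size: float
    herkogamy: float
    protandry: float
    flowering_time: float
    flower_color: str  # "pink" or "white"
    chloroplast: Optional[str]  # "outcrosser", "selfer" or None


# ---------------------------------------------------------------------------
# panels

def simulate_panels(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SnpPanelTable:
    """Draw per-site panel allele frequencies for the two ancestries.

    Under the Balding-Nichols model each taxon's frequency is a Beta draw
    around a shared ancestral frequency with divergence parameter F; at
    F = 0 the two taxa share the ancestral frequency exactly.  A fraction
    of sites is replaced by near-fixed differences (0.02 vs 0.98).  Site
    positions are laid out at least 200 bp apart along each chromosome and
    the Morgan position is proportional to bp.

    The table's allele counts are the expected counts ``2 * panel_n * f``;
    panel sampling noise is not modelled (the HMM adds its own pseudocount).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.n_sites
    F = config.panel_divergence

    p_anc = rng.uniform(0.05, 0.95, size=L)
    if F == 0.0:
        f_out = p_anc.copy()
        f_self = p_anc.copy()
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        f_out = rng.beta(a, b)
        f_self = rng.beta(a, b)

    n_fixed = int(round(config.fixed_diff_fraction * L))
    if n_fixed:
        idx = rng.choice(L, size=n_fixed, replace=False)
        direction = rng.random(n_fixed) < 0.5
        f_out[idx] = np.where(direction, 0.98, 0.02)
        f_self[idx] = np.where(direction, 0.02, 0.98)

    # site layout: n_sites spread over chromosomes, >= 200 bp apart
    chrom_of = np.arange(L) % config.n_chromosomes
    order = np.argsort(chrom_of, kind="stable")
    chrom_of = chrom_of[order]
    pos = np.empty(L, dtype=np.int64)
    for c in range(config.n_chromosomes):
        mask = chrom_of == c
        n_c = int(mask.sum())
        if n_c == 0:
            continue
        gaps = 200 + rng.integers(0, max(config.chrom_bp // max(n_c, 1) - 200, 1), size=n_c)
        pos[mask] = np.cumsum(gaps)
    morgan = pos / config.chrom_bp * config.map_length

    df = pd.DataFrame(
        {
            "site_id": [f"chr{c + 1}_{p}" for c, p in zip(chrom_of, pos)],
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": pos,
            "morgan": morgan,
            "ac_out": f_out * 2 * config.panel_n,
            "an_out": np.full(L, 2 * config.panel_n, dtype=float),
            "ac_self": f_self * 2 * config.panel_n,
            "an_self": np.full(L, 2 * config.panel_n, dtype=float),
        }
    )
    return SnpPanelTable(df)


def panel_site_map(panels: SnpPanelTable) -> tuple[np.ndarray, np.ndarray]:
    """(chromosome integer codes, Morgan positions) for meiosis bookkeeping."""
    chrom = pd.factorize(panels.df["chrom"])[0]
    morgan = panels.df["morgan"].to_numpy(float)
    return chrom, morgan


# ---------------------------------------------------------------------------
# meiosis and ancestry machinery

def _meiosis(hap_pair: np.ndarray, chrom: np.ndarray, morgan: np.ndarray,
             map_length: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent: Poisson crossovers per chromosome."""
    gamete = np.empty(hap_pair.shape[1], dtype=hap_pair.dtype)
    for c in np.unique(chrom):
        mask = chrom == c
        mg = morgan[mask]
        n_x = rng.poisson(map_length)
        breaks = np.sort(rng.uniform(0.0, map_length, size=n_x))
        start = rng.integers(0, 2)
        seg = (start + np.searchsorted(breaks, mg)) % 2
        gamete[mask] = hap_pair[seg, mask]
    return gamete


def _pulse_markov_haplotype(m: float, t: float, chrom: np.ndarray, morgan: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Haplotype ancestry under the single-pulse model.

    Recombination events since a pulse t generations ago form a Poisson
    process of rate t per Morgan; each tract's ancestry is an independent
    Bernoulli(m) draw (1 = heterospecific).
    """
    hap = np.empty(len(morgan), dtype=np.int8)
    for c in np.unique(chrom):
        mask = chrom == c
        mg = morgan[mask]
        span = mg[-1] - mg[0] if mg.size else 0.0
        n_b = rng.poisson(t * span)
        breaks = mg[0] + np.sort(rng.uniform(0.0, span, size=n_b)) if span > 0 else np.empty(0)
        seg_idx = np.searchsorted(breaks, mg, side="right")
        seg_anc = rng.random(n_b + 1) < m
        hap[mask] = seg_anc[seg_idx]
    return hap


# ---------------------------------------------------------------------------
# zone simulation

def _positions(config: SimConfig, rng: np.random.Generator, taxon: np.ndarray) -> np.ndarray:
    centers = np.asarray(config.cluster_centers, float)
    xy = rng.normal(0.0, config.cluster_sd, size=(len(taxon), 2))
    return xy + centers[taxon]


def _forward_pedigree(config: SimConfig, rng: np.random.Generator,
                      chrom: np.ndarray, morgan: np.ndarray):
    """Pulse + t generations of spatially explicit within-taxon mating.

    A breeding population of ``breeding_population`` individuals per taxon
    (at least the requested sample size) is simulated forward; the
    requested individuals are a random sample of the final generation.
    """
    if config.n_outcrosser == 0 or config.n_selfer == 0:
        raise ValueError("both taxa need at least one individual in forward mode")
    n_out = max(config.n_outcrosser, config.breeding_population)
    n_self = max(config.n_selfer, config.breeding_population)
    n = n_out + n_self
    taxon = np.concatenate([np.zeros(n_out, np.int64), np.ones(n_self, np.int64)])
    xy = _positions(config, rng, taxon)

    # founders: heterospecific immigrants at the pulse fraction
    immigrant = rng.random(n) < config.pulse_fraction
    founder_origin = np.where(immigrant, 1 - taxon, taxon)
    hap = np.repeat(founder_origin[:, None, None], 2, axis=1).astype(np.int8)
    hap = np.broadcast_to(hap, (n, 2, len(morgan))).copy()
    chloro = founder_origin.copy()
    founder_chloro = founder_origin.copy()

    selfing = np.where(taxon == SELFER, config.selfing_rate_selfer,
                       config.selfing_rate_outcrosser)
    pedigree = []
    for _ in range(config.generations_since_pulse):
        new_hap = np.empty_like(hap)
        new_chloro = np.empty_like(chloro)
        new_xy = np.empty_like(xy)
        mothers = np.empty(n, np.int64)
        fathers = np.empty(n, np.int64)
        for tx in (OUTCROSSER, SELFER):
            members = np.flatnonzero(taxon == tx)
            for i in members:
                mom = rng.choice(members)
                if rng.random() < selfing[mom]:
                    dad = mom
                else:
                    d = np.linalg.norm(xy[members] - xy[mom], axis=1)
                    w = np.exp(-d / config.pollen_kernel_scale)
                    w[members == mom] = 0.0
                    if w.sum() == 0:
                        dad = mom
                    else:
                        dad = rng.choice(members, p=w / w.sum())
                new_hap[i, 0] = _meiosis(hap[mom], chrom, morgan, config.map_length, rng)
                new_hap[i, 1] = _meiosis(hap[dad], chrom, morgan, config.map_length, rng)
                new_chloro[i] = chloro[mom]
                new_xy[i] = xy[mom] + rng.normal(0.0, config.seed_dispersal, 2)
                mothers[i], fathers[i] = mom, dad
        hap, chloro, xy = new_hap, new_chloro, new_xy
        pedigree.append((mothers, fathers))
    # sample the requested individuals from the final breeding generation
    sample_idx = np.concatenate([
        rng.choice(n_out, size=config.n_outcrosser, replace=False),
        n_out + rng.choice(n_self, size=config.n_selfer, replace=False),
    ])
    hap, taxon, chloro, xy = (hap[sample_idx], taxon[sample_idx],
                              chloro[sample_idx], xy[sample_idx])
    # class label: any heterospecific ancestry relative to own taxon
    selfer_copies = hap.sum(axis=1)
    het = np.where(taxon[:, None] == OUTCROSSER, selfer_copies, 2 - selfer_copies)
    classes = ["old-admixed" if h.any() else "parental" for h in het]
    return hap, taxon, chloro, xy, classes, pedigree, founder_chloro, sample_idx


def _designed_cohort(config: SimConfig, rng: np.random.Generator,
                     chrom: np.ndarray, morgan: np.ndarray, colors_pink: np.ndarray):
    """F1/F2/BC/old_admixed cohorts built from explicit meioses."""
    n = config.n_outcrosser + config.n_selfer
    tx_code = OUTCROSSER if config.cohort_taxon == "outcrosser" else SELFER
    taxon = np.full(n, tx_code, np.int64)
    L = len(morgan)
    hap = np.empty((n, 2, L), np.int8)
    cls = config.pedigree_class
    # F1s form on the selfer by default (maternal parent = selfer)
    chloro = np.full(n, SELFER, np.int64)

    pure = {OUTCROSSER: np.zeros((2, L), np.int8), SELFER: np.ones((2, L), np.int8)}
    f1 = np.stack([np.zeros(L, np.int8), np.ones(L, np.int8)])

    if cls == "F1":
        hap[:] = f1
    elif cls == "F2":
        for i in range(n):
            hap[i, 0] = _meiosis(f1, chrom, morgan, config.map_length, rng)
            hap[i, 1] = _meiosis(f1, chrom, morgan, config.map_length, rng)
    elif cls in ("BC1", "BCk"):
        k = 1 if cls == "BC1" else config.backcross_generations
        for i in range(n):
            parent = f1
            for _ in range(k):
                gamete = _meiosis(parent, chrom, morgan, config.map_length, rng)
                recurrent = _meiosis(pure[tx_code], chrom, morgan, config.map_length, rng)
                parent = np.stack([gamete, recurrent])
            hap[i] = parent
            # backcrossing into the recurrent taxon: chloroplast follows the
            # F1 maternal line (selfer by default)
    elif cls == "old_admixed":
        lo, hi = config.alpha_range
        target = rng.uniform(lo, hi, size=n)
        if config.color_admixture_effect:
            target = target + config.color_admixture_effect / 100.0 * colors_pink
            target = np.clip(target, 0.0, 1.0)
        for i in range(n):
            m_i = target[i]
            for c_ in range(2):
                h = _pulse_markov_haplotype(m_i, config.generations_since_pulse,
                                            chrom, morgan, rng)
                # heterospecific=1 relative to label; convert to absolute
                hap[i, c_] = h if tx_code == OUTCROSSER else 1 - h
        chloro = np.where(rng.random(n) < target, 1 - taxon, taxon)
    else:
        raise ValueError(f"unknown pedigree class {cls!r}")

    xy = _positions(config, rng, taxon)
    classes = [cls] * n
    return hap, taxon, chloro, xy, classes, [], None, None


def simulate_zone(config: SimConfig, panels: SnpPanelTable,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[list[IndividualRecord], SimTruth]:
    """Simulate the individuals of one contact zone.

    Default mode runs the forward pedigree (pulse + mating); setting
    ``config.pedigree_class`` requests a designed cohort instead.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom, morgan = panel_site_map(panels)

    n = config.n_outcrosser + config.n_selfer
    # flower colour drawn first so old_admixed can couple admixture to it
    taxon_pre = (
        np.full(n, OUTCROSSER if config.cohort_taxon == "outcrosser" else SELFER, np.int64)
        if config.pedigree_class
        else np.concatenate([np.zeros(config.n_outcrosser, np.int64),
                             np.ones(config.n_selfer, np.int64)])
    )
    white = (taxon_pre == SELFER) & (rng.random(n) < config.color_freq_white)
    colors_pink = (~white).astype(float)

    if config.pedigree_class:
        (hap, taxon, chloro, xy, classes, pedigree, founder_chloro,
         sample_idx) = _designed_cohort(config, rng, chrom, morgan, colors_pink)
    else:
        (hap, taxon, chloro, xy, classes, pedigree, founder_chloro,
         sample_idx) = _forward_pedigree(config, rng, chrom, morgan)

    selfer_copies = hap.sum(axis=1)
    het = np.where(taxon[:, None] == OUTCROSSER, selfer_copies, 2 - selfer_copies)
    true_alpha = het.mean(axis=1) / 2.0

    truth = SimTruth(
        ancestry_hap=hap,
        taxon=taxon,
        true_alpha=true_alpha,
        pedigree_class=classes,
        chloroplast_origin=chloro,
        pedigree=pedigree,
        founder_chloroplast=founder_chloro,
        sample_index=sample_idx,
    )

    records = []
    for i in range(n):
        tx = TAXON_NAMES[int(taxon[i])]
        traits = {}
        for name, tm in config.phenotype_model.items():
            mean = tm.mean_outcrosser if taxon[i] == OUTCROSSER else tm.mean_selfer
            slope = tm.slope_outcrosser if taxon[i] == OUTCROSSER else tm.slope_selfer
            traits[name] = mean + slope * true_alpha[i] + rng.normal(0.0, tm.sd)
        records.append(
            IndividualRecord(
                id=f"{config.zone}_{tx[:3]}_{i:04d}",
                taxon=tx,
                zone=config.zone,
                lon=float(xy[i, 0]),
                lat=float(xy[i, 1]),
                petal_size=traits["petal_size"],
                herkogamy=traits["herkogamy"],
                protandry=traits["protandry"],
                flowering_time=traits["flowering_time"],
                flower_color="white" if white[i] else "pink",
                chloroplast=TAXON_NAMES[int(chloro[i])],
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# reads

def simulate_reads(truth: SimTruth, panels: SnpPanelTable, config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   ids: Optional[list[str]] = None) -> ReadCountMatrix:
    """Binomial read counts given true ancestry and panel frequencies.

    Depth is Poisson(depth_mean) per individual x site (zero-depth sites
    are recorded as (0, 0), never dropped); each ancestry copy draws its
    allele from the matching panel frequency; alt reads are binomial with
    the per-read error rate folded in.
    """
    config.validate()
    if truth.n_sites != panels.n_sites:
        raise ValueError(
            f"truth has {truth.n_sites} sites but panel table has {panels.n_sites}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    freqs = np.stack([panels.df["ac_out"] / panels.df["an_out"],
                      panels.df["ac_self"] / panels.df["an_self"]])  # (2, L)
    n, _, L = truth.ancestry_hap.shape
    p_hap = freqs[truth.ancestry_hap, np.arange(L)[None, None, :]]  # (n, 2, L)
    alleles = rng.random((n, 2, L)) < p_hap
    g = alleles.sum(axis=1)  # alt-allele genotype 0/1/2
    depth = rng.poisson(config.depth_mean, size=(n, L))
    eps = config.error_rate
    p_alt = (g / 2.0) * (1 - eps) + (1 - g / 2.0) * eps
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    return ReadCountMatrix(ref=ref, alt=alt, ids=list(ids))


# ---------------------------------------------------------------------------
# output writers

def records_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_metadata_csv(records: list[IndividualRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_truth_tsv(truth: SimTruth, path, ids: Optional[list[str]] = None) -> None:
    n = truth.n_individuals
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "id": ids,
            "taxon": [TAXON_NAMES[int(t)] for t in truth.taxon],
            "true_alpha": truth.true_alpha,
            "pedigree_class": truth.pedigree_class,
            "chloroplast_origin": [TAXON_NAMES[int(c)] for c in truth.chloroplast_origin],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_config_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    d["phenotype_model"] = {k: asdict(v) if isinstance(v, TraitModel) else v
                            for k, v in config.phenotype_model.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
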