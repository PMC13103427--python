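"""Diploid local-ancestry HMM for low-depth, unphased read counts.

The chain runs along the SNP map of one individual.  Hidden states are the
three diploid ancestry genotypes, indexed

    0 = CC  (both copies conspecific),
    1 = HC  (one conspecific, one heterospecific copy),
    2 = HH  (both copies heterospecific),

where "conspecific" means the taxon the individual is labelled as in the
field, and "heterospecific" the other taxon.  Transitions follow a
single-pulse admixture model: an admixture pulse of proportion ``m``
occurred ``t`` generations ago, after which recombination breaks ancestry
into tracts as a Poisson process along the genetic (Morgan) map.  Emissions
marginalise the unobserved diploid allele genotype over the two reference
panels' allele frequencies and a binomial read-count model with a per-read
error rate.

An outer Baum-Welch-style loop (:func:`fit_individual`) feeds the
posterior-weighted admixture proportion back in as the pulse proportion
until input and output agree to within a tolerance (0.001 by default), and
picks the pulse time from a grid by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "SnpPanelTable",
    "ReadCountMatrix",
    "AncestryPosteriorMatrix",
    "IndividualFit",
    "haploid_transition",
    "diploid_transition",
    "genotype_prior",
    "emission_loglik",
    "forward_backward",
    "fit_individual",
    "fit_group",
    "DEFAULT_T_GRID",
]

DEFAULT_T_GRID: tuple[float, ...] = (2, 5, 10, 20, 50, 100, 200)

PANEL_COLUMNS = ["site_id", "chrom", "pos", "morgan", "ac_out", "an_out", "ac_self", "an_self"]


@dataclass
class SnpPanelTable:
    """Per-site reference-panel allele counts for the two ancestries.

    Wraps a DataFrame with columns ``site_id, chrom, pos, morgan, ac_out,
    an_out, ac_self, an_self`` where ``ac`` is the alt-allele count and
    ``an`` the total number of called alleles in that taxon's panel.
    Frequencies used by the HMM add a pseudocount of 0.5 per allele class
    so that no site is exactly fixed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            mg = sub["morgan"].to_numpy(float)
            if np.any(np.diff(mg) < 0):
                raise ValueError(f"Morgan positions decrease within chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def freq(self, taxon: str, pseudocount: float = 0.5) -> np.ndarray:
        """Alt-allele frequency of one panel with a per-class pseudocount."""
        if taxon not in ("outcrosser", "selfer"):
            raise ValueError(f"unknown taxon {taxon!r}")
        key = "out" if taxon == "outcrosser" else "self"
        ac = self.df[f"ac_{key}"].to_numpy(float)
        an = self.df[f"an_{key}"].to_numpy(float)
        return (ac + pseudocount) / (an + 2.0 * pseudocount)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpPanelTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ReadCountMatrix:
    """Per-individual, per-site (ref, alt) read counts sharing the panel's site index."""

    ref: np.ndarray  # (n_ind, n_sites)
    alt: np.ndarray  # (n_ind, n_sites)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt matrices differ in shape")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(self.ref.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.ref.shape[0]

    @property
    def n_sites(self) -> int:
        return self.ref.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


@dataclass
class IndividualFit:
    """Result of fitting one individual: posteriors plus the fitted pulse."""

    posteriors: np.ndarray  # (n_sites, 3) over {CC, HC, HH}
    alpha: float
    t: float
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        rows = self.posteriors.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")


@dataclass
class AncestryPosteriorMatrix:
    """Per-individual ancestry-genotype posteriors for a fitted group."""

    fits: list[IndividualFit]
    ids: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "alpha": [f.alpha for f in self.fits],
                "t": [f.t for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "iterations": [f.n_iter for f in self.fits],
                "converged": [f.converged for f in self.fits],
            }
        )


def haploid_transition(d: float, t: float, m: float) -> np.ndarray:
    """Single-copy transition matrix over {heterospecific, conspecific}.

    Over a map interval of ``d`` Morgans, ``t`` generations after a pulse of
    proportion ``m``, the chance that no recombination event since the pulse
    falls in the interval is exp(-t d); otherwise ancestry is redrawn from
    the stationary distribution (m, 1-m).
    """
    if d < 0:
        raise ValueError("map distance must be non-negative")
    if t < 1:
        raise ValueError("pulse time must be at least one generation")
    if not 0.0 <= m <= 1.0:
        raise ValueError("admixture proportion must lie in [0, 1]")
    stay = np.exp(-t * d)
    pi = np.array([m, 1.0 - m])
    return stay * np.eye(2) + (1.0 - stay) * np.tile(pi, (2, 1))


# Ordered pair (copy1, copy2), each in {H=0, C=1}; k = number of H copies.
_ORDERED_K = np.array([2, 1, 1, 0])  # HH, HC, CH, CC in kron order
# Representative ordered state for each unordered diploid state {CC, HC, HH}.
_REP = {0: 3, 1: 1, 2: 0}


def diploid_transition(d: float, t: float, m: float) -> np.ndarray:
    """3x3 transition over {CC, HC, HH}: two independent haploid copies, collapsed."""
    h = haploid_transition(d, t, m)
    t4 = np.kron(h, h)
    out = np.zeros((3, 3))
    for i in range(3):
        row = t4[_REP[i]]
        for j in range(3):
            out[i, j] = row[_ORDERED_K == j].sum()
    return out


def stationary_diploid(m: float) -> np.ndarray:
    """Hardy-Weinberg-on-ancestry stationary distribution over {CC, HC, HH}."""
    return np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])


def genotype_prior(f_con: np.ndarray, f_het: np.ndarray) -> np.ndarray:
    """P(alt-allele genotype g | ancestry state) per site.

    Returns array (n_sites, 3 states, 3 genotypes).  Each ancestry copy
    contributes one allele drawn from its own panel frequency.
    """
    f_con = np.atleast_1d(np.asarray(f_con, float))
    f_het = np.atleast_1d(np.asarray(f_het, float))
    n = f_con.shape[0]
    prior = np.empty((n, 3, 3))
    for k, (fa, fb) in enumerate([(f_con, f_con), (f_con, f_het), (f_het, f_het)]):
        prior[:, k, 0] = (1 - fa) * (1 - fb)
        prior[:, k, 1] = fa * (1 - fb) + fb * (1 - fa)
        prior[:, k, 2] = fa * fb
    return prior


def emission_loglik(
    ref: np.ndarray,
    alt: np.ndarray,
    f_con: np.ndarray,
    f_het: np.ndarray,
    error_rate: float = 0.01,
) -> np.ndarray:
    """Log-likelihood of the read counts under each ancestry state.

    Marginalises the unobserved diploid allele genotype g in {0, 1, 2}:
    P(reads | state) = sum_g P(g | state panels) Binom(alt | depth, p_g)
    with p_g = (g/2)(1-eps) + (1-g/2) eps.  Returns (n_sites, 3).
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must lie in [0, 1]")
    ref = np.atleast_1d(np.asarray(ref))
    alt = np.atleast_1d(np.asarray(alt))
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    p_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    # (n_sites, 3 genotypes) read likelihoods
    read_lik = binom.pmf(alt[:, None], depth[:, None], p_g[None, :])
    prior = genotype_prior(f_con, f_het)  # (n, 3 states, 3 genotypes)
    lik = np.einsum("nsg,ng->ns", prior, read_lik)
    with np.errstate(divide="ignore"):
        return np.log(lik)


# column-collapse matrix: ordered pair (kron order HH, HC, CH, CC) -> k het copies
_COLLAPSE = np.zeros((4, 3))
for _o, _k in enumerate(_ORDERED_K):
    _COLLAPSE[_o, _k] = 1.0
_REP_IDX = np.array([_REP[0], _REP[1], _REP[2]])


def _interval_transitions(morgan: np.ndarray, chrom: np.ndarray, t: float, m: float):
    """Per-interval 3x3 transition matrices; chromosome breaks reset to stationary."""
    L = len(morgan)
    if L < 2:
        return np.empty((0, 3, 3))
    d = np.diff(morgan)
    same = chrom[1:] == chrom[:-1]
    if np.any(d[same] < 0):
        raise ValueError("map positions must be non-decreasing within a chromosome")
    stay = np.exp(-t * np.where(same, d, np.inf))
    pi2 = np.array([m, 1.0 - m])
    # haploid per-interval matrices, then two independent copies collapsed
    h = stay[:, None, None] * np.eye(2) + (1.0 - stay)[:, None, None] * np.tile(pi2, (2, 1))
    t4 = np.einsum("nab,ncd->nacbd", h, h).reshape(L - 1, 4, 4)
    return t4[:, _REP_IDX, :] @ _COLLAPSE


def forward_backward(
    ref: np.ndarray,
    alt: np.ndarray,
    panels: SnpPanelTable,
    conspecific: str,
    t: float,
    m: float,
    error_rate: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Scaled forward-backward pass for one individual.

    ``conspecific`` is ``"outcrosser"`` or ``"selfer"`` (the individual's
    taxon label); the other taxon's panel supplies the heterospecific
    frequencies.  Returns (posteriors (L, 3), total log-likelihood).
    """
    other = {"outcrosser": "selfer", "selfer": "outcrosser"}[conspecific]
    f_con = panels.freq(conspecific)
    f_het = panels.freq(other)
    logE = emission_loglik(ref, alt, f_con, f_het, error_rate)
    L = logE.shape[0]
    if L == 0:
        raise ValueError("no sites to run the HMM over")
    # per-site scaling of emissions keeps linear-space recursions stable
    site_max = logE.max(axis=1)
    E = np.exp(logE - site_max[:, None])

    morgan = panels.df["morgan"].to_numpy(float)
    chrom = panels.df["chrom"].to_numpy()
    trans = _interval_transitions(morgan, chrom, t, m)
    pi3 = stationary_diploid(m)

    fwd = np.empty((L, 3))
    c = np.empty(L)
    a = pi3 * E[0]
    c[0] = a.sum()
    fwd[0] = a / c[0]
    for i in range(1, L):
        a = (fwd[i - 1] @ trans[i - 1]) * E[i]
        c[i] = a.sum()
        fwd[i] = a / c[i]

    bwd = np.empty((L, 3))
    bwd[L - 1] = 1.0
    for i in range(L - 2, -1, -1):
        bwd[i] = (trans[i] * (E[i + 1] * bwd[i + 1])[None, :]).sum(axis=1) / c[i + 1]

    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + site_max.sum())
    return post, loglik


def posterior_mean_admixture(posteriors: np.ndarray) -> float:
    """Mean posterior-weighted heterospecific fraction over sites."""
    z = 0.5 * posteriors[:, 1] + posteriors[:, 2]
    return float(z.mean())


def fit_individual(
    ref: np.ndarray,
    alt: np.ndarray,
    panels: SnpPanelTable,
    conspecific: str,
    error_rate: float = 0.01,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    alpha_init: float = 0.05,
    tol: float = 0.001,
    max_iter: int = 50,
) -> IndividualFit:
    """EM-style fit of one individual's admixture proportion and pulse time.

    Alternates forward-backward with re-estimation of the global admixture
    proportion (the posterior-weighted mean over sites) until input and
    output differ by less than ``tol``.  The pulse time is then chosen from
    ``t_grid`` by total log-likelihood, and the alpha loop re-run if the
    grid pick changed.  Non-convergence within ``max_iter`` is flagged, not
    fatal.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if len(t_grid) == 0:
        raise ValueError("t_grid must be non-empty")

    def run_alpha_loop(t: float, alpha0: float, iters_used: int):
        alpha_in = alpha0
        post, ll = None, -np.inf
        converged = False
        n_iter = iters_used
        while n_iter < max_iter:
            post, ll = forward_backward(ref, alt, panels, conspecific, t, alpha_in, error_rate)
            alpha_out = posterior_mean_admixture(post)
            n_iter += 1
            if abs(alpha_out - alpha_in) < tol:
                alpha_in = alpha_out
                converged = True
                break
            alpha_in = alpha_out
        return post, ll, alpha_in, n_iter, converged

    t0 = t_grid[len(t_grid) // 2]
    post, ll, alpha, n_iter, converged = run_alpha_loop(t0, alpha_init, 0)

    # pick t by likelihood at the fitted alpha
    best_t, best_ll, best_post = t0, ll, post
    for t in t_grid:
        if t == t0:
            continue
        p_t, ll_t = forward_backward(ref, alt, panels, conspecific, t, alpha, error_rate)
        if ll_t > best_ll:
            best_t, best_ll, best_post = t, ll_t, p_t
    if best_t != t0:
        post, ll, alpha, n_iter, converged = run_alpha_loop(best_t, alpha, n_iter)
        best_ll, best_post = ll, post

    return IndividualFit(
        posteriors=best_post,
        alpha=float(alpha),
        t=float(best_t),
        loglik=float(best_ll),
        n_iter=n_iter,
        converged=converged,
    )


def fit_group(
    reads: ReadCountMatrix,
    panels: SnpPanelTable,
    conspecific: str,
    error_rate: float = 0.01,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    alpha_init: float = 0.05,
    tol: float = 0.001,
    max_iter: int = 50,
) -> AncestryPosteriorMatrix:
    """Fit every individual of one taxon/zone group (shared panels and label)."""
    if reads.n_sites != panels.n_sites:
        raise ValueError(
            f"read matrix has {reads.n_sites} sites but panel table has {panels.n_sites}"
        )
    fits = [
        fit_individual(
            reads.ref[i],
            reads.alt[i],
            panels,
            conspecific,
            error_rate=error_rate,
            t_grid=t_grid,
            alpha_init=alpha_init,
            tol=tol,
            max_iter=max_iter,
        )
        for i in range(reads.n_individuals)
    ]
    return AncestryPosteriorMatrix(fits=fits, ids=list(reads.ids))
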