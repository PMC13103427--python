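"""Fine-scale spatial structure of genetic diversity and admixture.

Distances: geographic (haversine on lon/lat, Euclidean on planar
simulation coordinates), Nei (1972) standard genetic distance between
individuals treated as allele-frequency vectors (dosages 0/0.5/1 per
locus), and the same Nei computation on hard-called ancestry genotypes
("ancestry distance" — near zero both for two unadmixed conspecifics and
for two individuals admixed at the same sites).  A seeded Mantel
permutation test (1000 permutations, one-sided greater) relates the
matrices; per-individual mean distance to the three nearest
heterospecifics feeds linear and quadratic admixture-by-distance models
compared by a nested F-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "MantelResult",
    "geographic_distance",
    "nei_distance",
    "ancestry_distance",
    "mantel",
    "dist_to_heterospecifics",
    "admixture_vs_distance",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("Mantel r must lie in [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("permutation p must lie in (0, 1]")


def _check_square(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    return mat


def geographic_distance(lon: np.ndarray, lat: np.ndarray, planar: bool = False
                        ) -> np.ndarray:
    """Pairwise geographic distance in meters.

    ``planar=True`` treats the inputs as planar x/y meters (simulation
    output); otherwise great-circle haversine distance on WGS84 lon/lat.
    """
    pts = np.column_stack([lon, lat]).astype(float)
    if planar:
        return cdist(pts, pts)
    lam, phi = np.radians(pts[:, 0]), np.radians(pts[:, 1])
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi[:, None]) * np.cos(phi[None, :]) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def nei_distance(dosages: np.ndarray) -> np.ndarray:
    """Nei (1972) standard distance between individuals.

    Each individual is a per-locus two-allele frequency vector (dosage x
    for the alt allele, 1-x for the ref), aggregated over loci:
    D = -ln( J_xy / sqrt(J_x J_y) ) with J summed over loci and alleles.
    Missing entries are an error — apply the complete-case filter first.
    """
    X = np.asarray(dosages, float)
    if np.isnan(X).any():
        raise ValueError("dosage matrix contains missing data; complete cases required")
    if X.ndim != 2:
        raise ValueError("dosage matrix must be individuals x loci")
    # J_xy = sum_l [x y + (1-x)(1-y)] via two rank-n products
    J = X @ X.T + (1 - X) @ (1 - X).T
    diag = np.diag(J)
    norm = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore"):
        D = -np.log(np.clip(J / norm, 1e-300, 1.0))
    np.fill_diagonal(D, 0.0)
    return D


def ancestry_distance(ancestry_calls: np.ndarray) -> np.ndarray:
    """Nei distance on hard-called ancestry genotypes (dosages 0/0.5/1)."""
    calls = np.asarray(ancestry_calls, float)
    if np.isnan(calls).any():
        raise ValueError("ancestry calls contain missing data; complete cases required")
    if calls.max() > 1.0:  # {0,1,2} copy counts: convert to dosage
        calls = calls / 2.0
    return nei_distance(calls)


def mantel(matA: np.ndarray, matB: np.ndarray, n_perm: int = 1000,
           seed: int = 0) -> MantelResult:
    """Mantel test: Pearson r over lower triangles, permutation p-value.

    One matrix's rows/columns are shuffled simultaneously; the one-sided
    (greater) p-value uses the +1 correction, so its resolution is
    1 / (n_perm + 1).
    """
    A = _check_square(matA, "matA")
    B = _check_square(matB, "matB")
    if A.shape != B.shape:
        raise ValueError("matrices are not conformable")
    tri = np.tril_indices_from(A, k=-1)
    a, b = A[tri], B[tri]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])

    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(a, B[np.ix_(perm, perm)][tri])[0, 1]
        if r_p >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


def dist_to_heterospecifics(records: pd.DataFrame, k: int = 3,
                            planar: bool = False) -> pd.Series:
    """Mean geographic distance to the k nearest heterospecific individuals.

    ``records`` needs columns id, taxon, lon, lat.  Raises when any
    individual has fewer than k heterospecifics available.
    """
    D = geographic_distance(records["lon"].to_numpy(), records["lat"].to_numpy(),
                            planar=planar)
    taxa = records["taxon"].to_numpy()
    out = np.empty(len(records))
    for i in range(len(records)):
        hetero = np.flatnonzero(taxa != taxa[i])
        if len(hetero) < k:
            raise ValueError(
                f"individual {records['id'].iloc[i]} has only {len(hetero)} "
                f"heterospecifics, needs {k}"
            )
        d = np.sort(D[i, hetero])[:k]
        out[i] = d.mean()
    return pd.Series(out, index=records.index, name="dist_to_heterospecifics")


@dataclass
class DistanceModelReport:
    slope: float
    linear_F: float
    linear_p: float
    quadratic_F: float | None
    quadratic_p: float | None
    n: int


def admixture_vs_distance(alpha: np.ndarray, d3: np.ndarray,
                          quadratic: bool = False) -> DistanceModelReport:
    """Linear (and optionally quadratic) model of admixture on distance.

    The quadratic term is judged by the nested-model F-test
    F = ((SSE_1 - SSE_2)/1) / (SSE_2/(n-3)) against the linear fit.
    """
    alpha = np.asarray(alpha, float)
    d3 = np.asarray(d3, float)
    n = len(alpha)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.std(d3) == 0:
        raise ValueError("distance predictor has no variance")
    X1 = sm.add_constant(d3)
    m1 = sm.OLS(alpha, X1).fit()
    sse1 = float((m1.resid**2).sum())
    lin_F = float(m1.fvalue)
    lin_p = float(m1.f_pvalue)
    quad_F = quad_p = None
    if quadratic:
        X2 = sm.add_constant(np.column_stack([d3, d3**2]))
        m2 = sm.OLS(alpha, X2).fit()
        sse2 = float((m2.resid**2).sum())
        quad_F = ((sse1 - sse2) / 1.0) / (sse2 / (n - 3))
        quad_p = float(stats.f.sf(quad_F, 1, n - 3))
    return DistanceModelReport(
        slope=float(m1.params[1]), linear_F=lin_F, linear_p=lin_p,
        quadratic_F=quad_F, quadratic_p=quad_p, n=n,
    )
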