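"""Cluster-count (modality) testing with BIC-gated Gaussian mixtures.

A contact zone that contains only the two parental taxa is bimodal; early
generation hybrids or within-taxon substructure add modes.  Mixtures with
K = 1..9 components are fitted by EM and the next more complex model is
accepted only when it lowers BIC = -2 logL + k log n by at least 10 —
"very strong evidence" on the usual BIC evidence scale.  Genomic inputs
are reduced to leading principal components before fitting; a one-way
ANOVA then asks whether the clusters found differ in admixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "ModalityResult",
    "accepts_richer_model",
    "fit_gmm_path",
    "genomic_modality",
    "cluster_admixture_anova",
]

DELTA_BIC = 10.0


def accepts_richer_model(bic_current: float, bic_richer: float,
                         delta: float = DELTA_BIC) -> bool:
    """The BIC gate: accept the richer model only on a decrease of >= delta."""
    return bic_current - bic_richer >= delta


@dataclass
class ModalityResult:
    """Outcome of the BIC-gated mixture path for one dataset."""

    K_best: int
    bic_path: dict[int, float]
    assignments: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    data_kind: str = "unspecified"
    covariance_type: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.K_best <= 9:
            raise ValueError("K_best must lie in 1..9")
        for k, b in self.bic_path.items():
            if not np.isfinite(b):
                raise ValueError(f"non-finite BIC at K={k}")


def _fit_best_family(data: np.ndarray, k: int, families: list[str],
                     restarts: int, seed: int) -> tuple[GaussianMixture, float, str]:
    best = None
    for fam in families:
        gm = GaussianMixture(
            n_components=k,
            covariance_type=fam,
            n_init=restarts,
            init_params="k-means++",
            # variance floor: 1e-3 of the average feature variance guards
            # against single-point covariance collapse at small n
            reg_covar=max(1e-6, 1e-3 * float(np.var(data, axis=0).mean())),
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(data)
        except Exception as exc:  # EM failure at this K/family: skip it
            warnings.warn(f"GMM fit failed at K={k} ({fam}): {exc}")
            continue
        bic = gm.bic(data)
        if best is None or bic < best[1]:
            best = (gm, bic, fam)
    if best is None:
        raise RuntimeError(f"all mixture fits failed at K={k}")
    return best


def fit_gmm_path(data: np.ndarray, K_max: int = 9, delta: float = DELTA_BIC,
                 restarts: int = 20, seed: int = 0,
                 data_kind: str = "unspecified") -> ModalityResult:
    """Walk K upward, accepting K+1 only on a BIC decrease of at least ``delta``.

    Univariate data are fitted with equal- and unequal-variance families,
    multivariate data with diagonal and full covariances; the better BIC
    wins within each K.  Returns the first K at which improvement stalls.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if np.isnan(data).any():
        raise ValueError("missing values present; filter to complete cases first")
    n = data.shape[0]
    if n < K_max:
        raise ValueError(f"need at least K_max={K_max} observations, got {n}")
    families = ["tied", "full"] if data.shape[1] == 1 else ["diag", "full"]

    bic_path: dict[int, float] = {}
    cov_used: dict[int, str] = {}
    models: dict[int, GaussianMixture] = {}
    k_best = 1
    for k in range(1, K_max + 1):
        try:
            gm, bic, fam = _fit_best_family(data, k, families, restarts, seed)
        except RuntimeError as exc:
            warnings.warn(str(exc))
            continue
        bic_path[k] = float(bic)
        cov_used[k] = fam
        models[k] = gm
        if k == 1:
            continue
        if accepts_richer_model(bic_path[k_best], bic, delta):
            k_best = k
        else:
            break  # improvement stalled

    best_model = models[k_best]
    return ModalityResult(
        K_best=k_best,
        bic_path=bic_path,
        assignments=best_model.predict(data),
        means=best_model.means_,
        covariances=best_model.covariances_,
        data_kind=data_kind,
        covariance_type=cov_used,
    )


def genomic_modality(genotypes: np.ndarray, K_max: int = 9, delta: float = DELTA_BIC,
                     var_explained: float = 0.9, max_components: int = 10,
                     restarts: int = 20, seed: int = 0) -> ModalityResult:
    """Mixture modality of a complete-case SNP matrix.

    The matrix (individuals x SNPs, allele dosages) is reduced to the
    leading principal components explaining ``var_explained`` of the
    variance before the mixture path runs, capped at ``max_components``
    and at one dimension per ten individuals so an unstructured sample
    cannot hand the mixture enough noise axes to overfit.
    """
    genotypes = np.asarray(genotypes, float)
    if np.isnan(genotypes).any():
        raise ValueError(
            "genotype matrix contains missing data; apply the complete-case filter first"
        )
    n = genotypes.shape[0]
    pca = PCA(n_components=min(n - 1, genotypes.shape[1]), random_state=seed)
    scores = pca.fit_transform(genotypes)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_explained) + 1)
    n_comp = min(n_comp, max_components, scores.shape[1], max(1, n // 10))
    reduced = scores[:, :n_comp]
    return fit_gmm_path(reduced, K_max=K_max, delta=delta, restarts=restarts,
                        seed=seed, data_kind="genomic")


def cluster_admixture_anova(assignments: np.ndarray, alpha: np.ndarray
                            ) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of admixture proportion on cluster label.

    Clusters with fewer than two members are excluded with a warning.
    Returns (F, df1, df2, p).
    """
    assignments = np.asarray(assignments)
    alpha = np.asarray(alpha, float)
    groups = []
    for lab in np.unique(assignments):
        vals = alpha[assignments == lab]
        if len(vals) < 2:
            warnings.warn(f"cluster {lab} has fewer than 2 members; excluded")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two clusters with >= 2 members")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(f), df1, df2, float(p)


def modality_report(results: dict[str, ModalityResult]) -> pd.DataFrame:
    """Flatten named ModalityResults into a report table (one row per dataset)."""
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "dataset": name,
                "data_kind": res.data_kind,
                "K_best": res.K_best,
                "bic_path": ";".join(f"{k}:{v:.2f}" for k, v in sorted(res.bic_path.items())),
            }
        )
    return pd.DataFrame(rows)
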