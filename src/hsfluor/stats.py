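"""Dimensionality reduction and the pairwise two-sample KS significance battery.

PCA reports the *variance explained*: the ratio of the sum of the n largest
covariance eigenvalues to total variance, quantifying how much information an
n-component projection retains.  The KS battery tests, per fluorophore and per
unordered class pair, the null that abundances of the two classes come from
the same distribution, and collects the (pair, fluorophore) combinations that
fail to reject at the chosen level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .spectral import FLUOROPHORES

__all__ = ["PCAResult", "KSReport", "pca_variance_explained", "tsne_embed",
           "ks_battery", "ks_report_frame"]


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition summary of mean-centered data."""

    components: np.ndarray  # (n_components, d) loadings (rows orthonormal)
    eigenvalues: np.ndarray  # all covariance eigenvalues, non-increasing
    n_selected: int
    variance_explained: float  # sum of selected eigenvalues / total variance
    mean: np.ndarray

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data) - self.mean) @ self.components[: self.n_selected].T


def pca_variance_explained(data: np.ndarray, n: int) -> PCAResult:
    """n-component PCA of the covariance of mean-centered data.

    ``variance_explained`` is the sum of the n largest eigenvalues over the
    total variance (the trace of the covariance matrix).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need an (m, d) table with m >= 2")
    d = data.shape[1]
    if not 1 <= n <= d:
        raise ValueError(f"component count must be in [1, {d}]")
    total = np.var(data, axis=0, ddof=1).sum()
    if total <= 0:
        raise ValueError("data has zero total variance; PCA is undefined")
    pca = PCA(n_components=min(data.shape[0], d), svd_solver="full")
    pca.fit(data)
    eig = np.zeros(d)
    eig[: pca.explained_variance_.size] = pca.explained_variance_
    ve = float(eig[:n].sum() / eig.sum())
    return PCAResult(
        components=pca.components_,
        eigenvalues=eig,
        n_selected=n,
        variance_explained=ve,
        mean=pca.mean_,
    )


def tsne_embed(
    data: np.ndarray,
    dims: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Seeded t-SNE embedding for visualization (never used as features)."""
    data = np.asarray(data, dtype=float)
    if dims not in (2, 3):
        raise ValueError("embedding dimension must be 2 or 3")
    if data.shape[0] <= 3 * perplexity:
        raise ValueError("need more than 3 * perplexity samples for t-SNE")
    tsne = TSNE(
        n_components=dims, perplexity=perplexity, random_state=seed, init="pca",
        method="barnes_hut" if dims == 2 else "exact",
    )
    return tsne.fit_transform(data)


@dataclass
class KSReport:
    """Pairwise two-sample KS results per fluorophore."""

    task: str
    classes: tuple[str, ...]
    fluorophores: tuple[str, ...]
    d_matrices: dict[str, np.ndarray]  # fluorophore -> (K, K) symmetric, zero diagonal
    p_matrices: dict[str, np.ndarray]  # fluorophore -> (K, K) symmetric, unit diagonal
    alpha: float = 0.01
    exceptions: list[tuple[str, str, str, float]] = field(default_factory=list)
    # exceptions entries: (class_a, class_b, fluorophore, p_value)

    def n_significant_fluorophores(self, class_a: str, class_b: str) -> int:
        i, j = self.classes.index(class_a), self.classes.index(class_b)
        return int(sum(self.p_matrices[f][i, j] < self.alpha for f in self.fluorophores))


def ks_battery(
    abundances: np.ndarray,
    labels,
    alpha: float = 0.01,
    fluorophores=FLUOROPHORES,
    method: str = "auto",
    task: str = "",
) -> KSReport:
    """Two-sample KS tests for every fluorophore and unordered class pair.

    Sample sizes may differ between classes.  ``method`` is passed to
    :func:`scipy.stats.ks_2samp` ("auto" uses the exact null distribution for
    small samples and the asymptotic Kolmogorov distribution otherwise).
    Classes with fewer than two samples are excluded with a warning.
    """
    abundances = np.asarray(abundances, dtype=float)
    labels = np.asarray(labels)
    if abundances.ndim != 2 or abundances.shape[1] != len(fluorophores):
        raise ValueError("abundances must be (m, n_fluorophores)")
    classes = []
    for c in pd.unique(labels):
        if (labels == c).sum() < 2:
            warnings.warn(f"class {c!r} has fewer than 2 samples; excluded from KS battery")
        else:
            classes.append(c)
    if len(classes) < 2:
        raise ValueError("need at least two classes with >= 2 samples")
    classes = tuple(str(c) for c in classes)
    k = len(classes)
    d_mats = {f: np.zeros((k, k)) for f in fluorophores}
    p_mats = {f: np.eye(k) for f in fluorophores}
    exceptions = []
    for (i, a), (j, b) in itertools.combinations(enumerate(classes), 2):
        xa = abundances[labels.astype(str) == a]
        xb = abundances[labels.astype(str) == b]
        for fi, f in enumerate(fluorophores):
            res = sps.ks_2samp(xa[:, fi], xb[:, fi], method=method)
            d_mats[f][i, j] = d_mats[f][j, i] = res.statistic
            p_mats[f][i, j] = p_mats[f][j, i] = res.pvalue
            if res.pvalue >= alpha:
                exceptions.append((a, b, f, float(res.pvalue)))
    return KSReport(
        task=task, classes=classes, fluorophores=tuple(fluorophores),
        d_matrices=d_mats, p_matrices=p_mats, alpha=alpha, exceptions=exceptions,
    )


def ks_report_frame(report: KSReport) -> pd.DataFrame:
    """Long-format export: task,fluorophore,class_a,class_b,D,p_value,significant."""
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(report.classes), 2):
        for f in report.fluorophores:
            p = report.p_matrices[f][i, j]
            rows.append(
                dict(task=report.task, fluorophore=f, class_a=a, class_b=b,
                     D=report.d_matrices[f][i, j], p_value=p,
                     significant=bool(p < report.alpha))
            )
    return pd.DataFrame(rows)
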