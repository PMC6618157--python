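"""Statistical summaries over distance tables and tree collections.

Covers the downstream analyses of the simulation experiments: Spearman
rank-correlation matrices across measures, plug-in mutual information
between a distance and a model parameter (optionally on a constrained
slice of parameter space), a pairing randomization test for collections of
host/pathogen tree pairs scored by a kernel, and a standardized PCA with
an MI-based column filter for biplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CophyloError, SampleSizeError
from .kernels import KernelConfig, kernel_matrix, kernel_score, cosine_normalize
from .treecore import TimeTree

__all__ = [
    "MIResult",
    "RandTestResult",
    "PCAResult",
    "spearman_matrix",
    "mutual_information",
    "cross_score_matrix",
    "pairing_randomization_test",
    "pca_biplot",
]


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between table columns.

    Ties are handled by average ranks; a constant column yields NaN
    entries (undefined correlation) rather than an error.
    """
    if len(table) < 3:
        raise CophyloError("need at least 3 rows for rank correlations")
    data = table.to_numpy(dtype=float)
    ranks = np.apply_along_axis(sps.rankdata, 0, data)  # average ranks on ties
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    out = pd.DataFrame(rho, index=table.columns, columns=table.columns)
    np.fill_diagonal(out.values, 1.0)
    for col in table.columns:
        if table[col].nunique() <= 1:
            out.loc[col, :] = np.nan
            out.loc[:, col] = np.nan
    return out


@dataclass
class MIResult:
    """Plug-in mutual information between a distance and a parameter."""

    mi: float  # nats
    n: int
    bins: int
    x_name: str = "distance"
    y_name: str = "parameter"
    constraint: str | None = None


def mutual_information(
    x,
    y,
    bins: int = 10,
    constraint=None,
    min_points: int = 50,
    x_name: str = "distance",
    y_name: str = "parameter",
    constraint_label: str | None = None,
) -> MIResult:
    """Plug-in MI with equal-width binning, in nats.

    Both variables are discretized into ``bins`` equal-width bins over
    their observed ranges; the estimate is the double sum
    ``sum_ij p_ij log(p_ij / (p_i p_j))`` over the 2-D histogram.
    ``constraint`` is an optional boolean mask selecting the rows to keep
    (e.g. ``P > 0.8``); at least ``min_points`` rows must survive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CophyloError("x and y must have equal lengths")
    if constraint is not None:
        mask = np.asarray(constraint, dtype=bool)
        x, y = x[mask], y[mask]
    if len(x) < min_points:
        raise SampleSizeError(
            f"only {len(x)} points after filtering (need >= {min_points})"
        )
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * np.log(p / (px * py))
    mi = float(np.nansum(terms))
    return MIResult(mi=max(mi, 0.0), n=len(x), bins=bins,
                    x_name=x_name, y_name=y_name, constraint=constraint_label)


@dataclass
class RandTestResult:
    """Outcome of the pairing randomization test."""

    observed: float
    null_means: np.ndarray
    percentile: float  # of the observed mean within the null
    p_empirical: float  # (1 + #{null >= observed}) / (n_null + 1)
    p_normal: float  # upper tail under a normal fit to the null

    def __repr__(self):  # pragma: no cover
        return (
            f"RandTestResult(observed={self.observed:.4f}, "
            f"percentile={self.percentile:.1f}, p_emp={self.p_empirical:.4g}, "
            f"p_norm={self.p_normal:.4g})"
        )


def cross_score_matrix(
    hosts: list[TimeTree],
    pathogens: list[TimeTree],
    cfg: KernelConfig | None = None,
) -> np.ndarray:
    """Cosine-normalized kernel scores for every host x pathogen pair."""
    cfg = cfg or KernelConfig()
    nh, np_ = len(hosts), len(pathogens)
    self_h = [kernel_score(t, t, cfg) for t in hosts]
    self_p = [kernel_score(t, t, cfg) for t in pathogens]
    S = np.zeros((nh, np_))
    for i in range(nh):
        for j in range(np_):
            S[i, j] = cosine_normalize(kernel_score(hosts[i], pathogens[j], cfg),
                                       self_h[i], self_p[j])
    return S


def pairing_randomization_test(
    hosts: list[TimeTree] | None = None,
    pathogens: list[TimeTree] | None = None,
    cfg: KernelConfig | None = None,
    score_matrix: np.ndarray | None = None,
    n_null: int = 1000,
    seed: int | None = None,
) -> RandTestResult:
    """Are true host-pathogen pairs closer in kernel space than random ones?

    The observed statistic is the mean normalized kernel score over the
    true pairings (the diagonal of the cross-score matrix).  The null
    distribution consists of ``n_null`` means under uniformly random
    permutations of the pathogen list (the identity permutation is
    allowed, which is conservative).  Reports the observed percentile, an
    empirical p-value and a normal-approximation p-value; similarity
    scores are tested in the upper tail.
    """
    if score_matrix is None:
        if hosts is None or pathogens is None:
            raise CophyloError("provide trees or a precomputed score matrix")
        if len(hosts) != len(pathogens):
            raise CophyloError("hosts and pathogens must have equal lengths")
        if len(hosts) < 2:
            raise CophyloError("need at least 2 tree pairs")
        score_matrix = cross_score_matrix(hosts, pathogens, cfg)
    S = np.asarray(score_matrix, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise CophyloError("score matrix must be square (one row per pairing)")
    n = S.shape[0]
    rng = np.random.default_rng(seed)
    observed = float(np.diag(S).mean())
    idx = np.arange(n)
    null = np.empty(n_null)
    for b in range(n_null):
        perm = rng.permutation(n)
        null[b] = S[idx, perm].mean()
    percentile = float(100.0 * np.mean(null < observed)
                       + 50.0 * np.mean(null == observed))
    p_emp = (1 + int(np.sum(null >= observed))) / (n_null + 1)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    p_norm = float(sps.norm.sf(observed, loc=mu, scale=sd)) if sd > 0 else (
        0.5 if observed == mu else float(observed < mu)
    )
    return RandTestResult(observed=observed, null_means=null,
                          percentile=percentile, p_empirical=p_emp,
                          p_normal=p_norm)


@dataclass
class PCAResult:
    """Standardized PCA of a distance table."""

    scores: pd.DataFrame
    loadings: pd.DataFrame  # orthonormal columns
    explained_variance_ratio: np.ndarray
    retained: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def pca_biplot(
    table: pd.DataFrame,
    mi_values: dict[str, float] | None = None,
    mi_threshold: float = 0.1,
    n_components: int = 2,
) -> PCAResult:
    """PCA on standardized columns, excluding uninformative measures.

    Columns whose mutual information (as supplied in ``mi_values``) falls
    below ``mi_threshold`` are dropped and reported in ``excluded``.
    Columns are standardized to zero mean and unit variance before the
    singular value decomposition.
    """
    if len(table) < 3:
        raise CophyloError("need at least 3 rows for a PCA")
    excluded = []
    retained = list(table.columns)
    if mi_values is not None:
        excluded = [c for c in retained if mi_values.get(c, np.inf) < mi_threshold]
        retained = [c for c in retained if c not in excluded]
    if len(retained) < 2:
        raise CophyloError("fewer than 2 columns remain after the MI filter")
    X = table[retained].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U * s)[:, :k], index=table.index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=retained, columns=comps)
    evr = (s**2) / np.sum(s**2)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=evr[:k],
                     retained=retained, excluded=excluded)
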