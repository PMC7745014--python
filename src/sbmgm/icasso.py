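"""ICASSO-style stability analysis of repeated Infomax runs.

ICA is run ``runs`` times from different random initializations, the
pooled sources are clustered by absolute Pearson correlation (average
linkage, cut at exactly K clusters), and each cluster is summarized by

* the quality index ``Iq`` = mean intra-cluster similarity minus mean
  extra-cluster similarity (in [0, 1]; 1 = perfectly stable), and
* its centrotype, the member with maximal total similarity to the
  cluster, which becomes the reported component.

Centrotype loadings are recomputed by regressing the centered data onto
the centrotype sources, so the final mixing matrix refers to one
consistent set of maps rather than to any single run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DivergenceError, StabilityError
from .sbmcore import (
    ICADecomposition,
    InfomaxICA,
    _as_matrix,
    _fix_sign_and_order,
    center,
    infomax_ica,
    whiten,
)


@dataclass
class StabilityReport:
    """Clustered repeated-run components and their quality indices."""

    runs: int
    k: int
    all_sources: np.ndarray  # (runs*K, V) pooled sources
    similarity: np.ndarray  # pooled |corr|, symmetric, unit diagonal
    cluster_of: np.ndarray  # pooled component -> cluster id (0..K-1)
    iq: np.ndarray  # per-cluster quality index, cluster order = output order
    cluster_sizes: np.ndarray
    centrotype_sources: np.ndarray  # (K, V)
    centrotype_mixing: np.ndarray  # (N, K)
    run_seeds: list[int] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def to_summary(self) -> dict[str, Any]:
        return {
            "runs": self.runs,
            "k": self.k,
            "iq": [float(v) for v in self.iq],
            "cluster_sizes": [int(v) for v in self.cluster_sizes],
            "run_seeds": list(self.run_seeds),
        }


def iq_index(similarity: np.ndarray, members: np.ndarray) -> float:
    """Cluster quality: mean intra-cluster minus mean extra-cluster
    similarity.  A singleton's intra term is 1 by convention."""
    members = np.asarray(members)
    if members.size == 0:
        raise StabilityError("iq_index needs a nonempty member set")
    n = similarity.shape[0]
    inside = np.zeros(n, dtype=bool)
    inside[members] = True
    if members.size == 1:
        intra = 1.0
    else:
        block = similarity[np.ix_(members, members)]
        m = members.size
        intra = float((block.sum() - np.trace(block)) / (m * (m - 1)))
    outside = ~inside
    if outside.any():
        extra = float(similarity[np.ix_(members, np.where(outside)[0])].mean())
    else:
        extra = 0.0
    return max(0.0, min(1.0, intra - extra))


def _abs_correlation(sources: np.ndarray) -> np.ndarray:
    sim = np.abs(np.corrcoef(sources))
    np.fill_diagonal(sim, 1.0)
    return np.clip((sim + sim.T) / 2.0, 0.0, 1.0)


def cluster_components(similarity: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage clustering on 1 - similarity, cut at k clusters."""
    dist = np.clip(1.0 - similarity, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust") - 1
    return labels


def run_icasso(
    whitened: np.ndarray,
    dewhitening: np.ndarray,
    k: int,
    runs: int = 20,
    base_seed: int = 0,
    *,
    seeds: list[int] | None = None,
    xc: np.ndarray | None = None,
    **ica_params,
) -> StabilityReport:
    """Repeat Infomax with seeds ``base_seed .. base_seed+runs-1`` (or an
    explicit ``seeds`` list), pool and cluster the sources, and extract
    centrotypes.

    ``xc`` (centered subjects x voxels data) is used for the centrotype
    loading regression; when omitted the rank-K reconstruction
    ``dewhitening @ whitened`` stands in, which is identical up to the
    discarded variance.
    """
    run_seeds = list(seeds) if seeds is not None else [
        base_seed + i for i in range(runs)
    ]
    if len(run_seeds) < 2:
        raise StabilityError("ICASSO needs at least 2 runs")
    decomps: list[ICADecomposition] = []
    seeds_used: list[int] = []
    for seed in run_seeds:
        try:
            decomps.append(
                infomax_ica(whitened, dewhitening, seed=seed, **ica_params)
            )
            seeds_used.append(seed)
        except DivergenceError as exc:  # pragma: no cover - rare path
            warnings.warn(f"ICA run with seed {seed} diverged and was dropped: {exc}")
    if len(decomps) < 2:
        raise StabilityError("fewer than 2 ICA runs survived")

    pooled = np.vstack([d.sources for d in decomps])
    sim = _abs_correlation(pooled)
    labels = cluster_components(sim, k)

    iqs = np.empty(k)
    centro_idx = np.empty(k, dtype=int)
    sizes = np.empty(k, dtype=int)
    for c in range(k):
        members = np.where(labels == c)[0]
        if members.size == 0:
            raise StabilityError(f"cluster {c} is empty")
        sizes[c] = members.size
        iqs[c] = iq_index(sim, members)
        within = sim[np.ix_(members, members)].sum(axis=1)
        centro_idx[c] = members[np.argmax(within)]

    centrotypes = pooled[centro_idx]
    data = xc if xc is not None else dewhitening @ np.asarray(whitened)
    mixing = data @ centrotypes.T @ np.linalg.inv(centrotypes @ centrotypes.T)
    mixing, centrotypes = _fix_sign_and_order(mixing, centrotypes)
    # keep iq/sizes aligned with the reordered centrotypes
    order = _recover_order(pooled[centro_idx], centrotypes)
    return StabilityReport(
        runs=len(decomps),
        k=k,
        all_sources=pooled,
        similarity=sim,
        cluster_of=labels,
        iq=iqs[order],
        cluster_sizes=sizes[order],
        centrotype_sources=centrotypes,
        centrotype_mixing=mixing,
        run_seeds=seeds_used,
    )


def _recover_order(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """Permutation mapping output component i back to its pre-ordering row."""
    corr = np.abs(np.corrcoef(after, before)[: after.shape[0], after.shape[0] :])
    return np.argmax(corr, axis=1)


class IcassoICA(InfomaxICA):
    """Stabilized decomposition: Infomax repeated ``runs`` times, reported
    through ICASSO centrotypes.

    Fitted attributes mirror :class:`InfomaxICA` (``components_`` are the
    centrotype sources, ``mixing_`` the regressed loadings) plus ``iq_``,
    ``cluster_sizes_`` and the full ``stability_report_``.
    """

    def __init__(
        self,
        n_components: int | str = "mdl",
        runs: int = 20,
        learning_rate: float | None = None,
        batch_size: int | None = None,
        anneal_deg: float = 60.0,
        anneal_factor: float = 0.9,
        tol: float = 1e-6,
        max_iter: int = 512,
        extended: bool = False,
        random_state: int | None = 0,
    ):
        super().__init__(
            n_components=n_components,
            learning_rate=learning_rate,
            batch_size=batch_size,
            anneal_deg=anneal_deg,
            anneal_factor=anneal_factor,
            tol=tol,
            max_iter=max_iter,
            extended=extended,
            random_state=random_state,
        )
        self.runs = runs

    def fit(self, X, y=None):
        x = _as_matrix(X)
        k = self._resolve_order(x)
        z, dewhitening, eigvals, discarded = whiten(x, k)
        xc, row_means, mean_map = center(x)
        report = run_icasso(
            z,
            dewhitening,
            k,
            runs=self.runs,
            base_seed=self.random_state if self.random_state is not None else 0,
            xc=xc,
            lr=self.learning_rate,
            batch=self.batch_size,
            anneal_deg=self.anneal_deg,
            anneal_factor=self.anneal_factor,
            tol=self.tol,
            max_iter=self.max_iter,
            extended=self.extended,
        )
        self.stability_report_ = report
        self.components_ = report.centrotype_sources
        self.mixing_ = report.centrotype_mixing
        self.n_components_ = k
        self.iq_ = report.iq
        self.cluster_sizes_ = report.cluster_sizes
        self.mean_map_ = mean_map
        self.decomposition_ = ICADecomposition(
            mixing=report.centrotype_mixing,
            sources=report.centrotype_sources,
            k=k,
            eigenvalues=eigvals,
            discarded_variance=discarded,
            convergence={"runs": report.runs},
            seed=self.random_state,
            row_means=row_means,
            mean_map=mean_map,
        )
        return self
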