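"""Model-order selection, whitening, and Infomax spatial ICA.

The decomposition is spatial, as in source-based morphometry: the
subjects x voxels matrix ``X`` is modeled as ``X ~ A @ S`` with sources
``S`` independent over voxels.  Order ``K`` comes from the minimum
description length criterion on the subject-space covariance eigenvalues
(Wax-Kailath form), the data are whitened by the top-``K`` principal
components, and unmixing is learned by natural-gradient Infomax with a
logistic nonlinearity (optionally the extended variant that also handles
sub-Gaussian sources).

Conventions fixed here so that downstream statistics are reproducible:

* each source row has unit variance; its mixing column absorbs the scale,
  so loading coefficients are in data units;
* each source is flipped so its skewness is positive (GM networks are
  positive-going blobs); ties on skewness flip so the largest-magnitude
  voxel is positive;
* components are ordered by descending variance explained in subject
  space.

:class:`InfomaxICA` wraps the whole chain as a scikit-learn estimator;
the module-level functions expose the individual steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit
from scipy.stats import kurtosis, skew
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DivergenceError,
    InsufficientDataError,
    RankError,
)
from .gmio import GMDataMatrix

_EIG_FLOOR = 1e-12


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, GMDataMatrix):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def center(
    x, remove_mean_map: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove each subject's row mean, then the across-subject mean map.

    Returns ``(centered, row_means, mean_map)``; the removed mean map is
    the cohort's mean GM profile.  ``remove_mean_map=False`` skips the
    second step (useful when rows are signal channels rather than a
    subject cohort; it costs one rank when on).
    """
    x = _as_matrix(x)
    row_means = x.mean(axis=1, keepdims=True)
    xc = x - row_means
    if remove_mean_map:
        mean_map = xc.mean(axis=0)
        xc = xc - mean_map
    else:
        mean_map = np.zeros(x.shape[1])
    return xc, row_means.ravel(), mean_map


def subject_eigenvalues(x) -> np.ndarray:
    """Descending eigenvalues of the subject-space covariance ``Xc Xc'/V``."""
    xc, _, _ = center(x)

    n, v = xc.shape
    cov = xc @ xc.T / v
    lam = np.linalg.eigvalsh(cov)[::-1]
    return np.maximum(lam, 0.0)


def mdl_curve(x) -> np.ndarray:
    """MDL(k) for k = 0 .. p-1, with p = N-1 after centering.

    MDL(k) = -(p-k) * M * log(G_k / A_k) + 0.5 * k * (2p - k + 1) * log M,
    where G_k and A_k are the geometric/arithmetic means of the trailing
    eigenvalues lambda_{k+1..p} and M is the number of voxels observed.
    """
    xm = _as_matrix(x)
    n, m = xm.shape
    if n < 3:
        raise InsufficientDataError(
            f"MDL order estimation needs >= 3 subjects, got {n}"
        )
    p = n - 1
    lam = subject_eigenvalues(xm)[:p]
    lam = np.maximum(lam, _EIG_FLOOR * max(lam.max(), 1.0))
    log_lam = np.log(lam)
    out = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        log_g = log_lam[k:].mean()
        log_a = math.log(tail.mean())
        out[k] = -(p - k) * m * (log_g - log_a) + 0.5 * k * (
            2 * p - k + 1
        ) * math.log(m)
    return out


def estimate_order_mdl(
    x,
    subsample_fraction: float | None = None,
    subsample_seed: int = 0,
) -> int:
    """Model order by minimum description length; at least 1.

    The classic criterion assumes i.i.d. observations across voxels.
    Spatially smoothed noise violates that and inflates the order; passing
    ``subsample_fraction`` (e.g. 0.1) evaluates the criterion on a random
    voxel subset, whose members are mostly far apart and hence nearly
    independent — the usual i.i.d.-sampling correction.
    """
    xm = _as_matrix(x)
    if subsample_fraction is not None:
        if not 0 < subsample_fraction <= 1:
            raise InsufficientDataError("subsample_fraction must be in (0, 1]")
        rng = np.random.default_rng(subsample_seed)
        n_cols = max(xm.shape[0] * 3, int(subsample_fraction * xm.shape[1]))
        n_cols = min(n_cols, xm.shape[1])
        xm = xm[:, rng.choice(xm.shape[1], size=n_cols, replace=False)]
    return max(1, int(np.argmin(mdl_curve(xm))))


def whiten(
    x, k: int, remove_mean_map: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Project centered data onto the top-``k`` PCs with unit covariance.

    Returns ``(z, dewhitening, eigenvalues, discarded_fraction)`` where
    ``z`` is K x V with ``z z' / V = I`` and ``dewhitening`` (N x K) maps
    whitened rows back to subject space: ``Xc ~ dewhitening @ z``.
    Cohort centering costs one rank, hence ``k <= N - 1``; with
    ``remove_mean_map=False`` (channel data) ``k <= N`` is allowed.
    """
    xm = _as_matrix(x)
    n, v = xm.shape
    k_max = n - 1 if remove_mean_map else n
    if not 1 <= k <= k_max:
        raise RankError(f"k must satisfy 1 <= k <= {k_max}, got {k}")
    xc, _, _ = center(xm, remove_mean_map=remove_mean_map)
    cov = xc @ xc.T / v
    lam, vecs = np.linalg.eigh(cov)
    lam, vecs = lam[::-1], vecs[:, ::-1]
    lam = np.maximum(lam, 0.0)
    rank_tol = max(lam.max(), 1.0) * n * np.finfo(float).eps
    if lam[k - 1] <= rank_tol:
        raise RankError(
            f"requested order {k} exceeds the numerical rank of the data"
        )
    keep = lam[:k]
    z = (vecs[:, :k] / np.sqrt(keep)).T @ xc
    dewhitening = vecs[:, :k] * np.sqrt(keep)
    total = lam[:k_max].sum()
    discarded = float(1.0 - keep.sum() / total) if total > 0 else 0.0
    return z, dewhitening, keep, discarded


@dataclass
class ICADecomposition:
    """Mixing (loadings) and source matrices with provenance.

    ``mixing @ sources`` reconstructs the retained-rank part of the
    centered data; the relative Frobenius error is bounded by the
    discarded-variance fraction.
    """

    mixing: np.ndarray  # N x K, loading coefficients
    sources: np.ndarray  # K x V, unit-variance rows
    k: int
    eigenvalues: np.ndarray
    discarded_variance: float
    convergence: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    row_means: np.ndarray | None = None
    mean_map: np.ndarray | None = None


def _default_lr(k: int) -> float:
    return 0.015 / math.log(k) if k > 1 else 0.01


def _default_batch(v: int) -> int:
    return min(v, int(math.sqrt(v)) * 8)


def _infomax_unmix(
    z: np.ndarray,
    rng: np.random.Generator,
    lr: float,
    batch: int,
    anneal_deg: float,
    anneal_factor: float,
    tol: float,
    max_iter: int,
    extended: bool,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Natural-gradient Infomax on whitened data; returns (W, info)."""
    k, v = z.shape
    if k == 1:
        return np.ones((1, 1)), {"n_iter": 0, "final_change": 0.0, "lr": [lr]}
    # random orthonormal start so repeated runs explore different basins
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    w = q * np.sign(np.diag(r))
    eye = np.eye(k)
    signs = np.ones(k)  # +1 super-Gaussian, -1 sub-Gaussian (extended mode)
    old_w = w.copy()
    old_delta: np.ndarray | None = None
    old_change = 0.0
    lr_trace = [lr]
    n_iter = 0
    change = np.inf
    for n_iter in range(1, max_iter + 1):
        perm = rng.permutation(v)
        if extended:
            # re-estimate source kurtosis signs once per sweep
            u_all = w @ z[:, perm[: min(v, 4096)]]
            kur = kurtosis(u_all, axis=1, fisher=True)
            signs = np.where(kur >= 0, 1.0, -1.0)
        for start in range(0, v - batch + 1, batch):
            u = w @ z[:, perm[start : start + batch]]
            if extended:
                y = np.tanh(u)
                grad = eye - (signs[:, None] * y) @ u.T / batch - u @ u.T / batch
            else:
                y = expit(u)
                grad = eye + (1.0 - 2.0 * y) @ u.T / batch
            w = w + lr * (grad @ w)
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e8:
                raise DivergenceError(
                    "Infomax weights diverged; retry with a smaller "
                    "learning rate"
                )
        delta = (w - old_w).ravel()
        change = float(delta @ delta)
        if old_delta is not None and change > 0 and old_change > 0:
            cosang = float(old_delta @ delta) / math.sqrt(change * old_change)
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle > anneal_deg:
                lr *= anneal_factor
                lr_trace.append(lr)
        old_delta, old_change, old_w = delta, change, w.copy()
        if change < tol:
            break
    info = {
        "n_iter": n_iter,
        "final_change": change,
        "converged": bool(change < tol),
        "lr": lr_trace,
    }
    return w, info


def _fix_sign_and_order(
    mixing: np.ndarray, sources: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance sources, positive skew, descending explained variance."""
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    sources = sources / sd[:, None]
    mixing = mixing * sd[None, :]
    sk = skew(sources, axis=1)
    flips = np.ones(len(sk))
    for i, s in enumerate(sk):
        if abs(s) < 1e-12:
            j = np.argmax(np.abs(sources[i]))
            flips[i] = 1.0 if sources[i, j] >= 0 else -1.0
        else:
            flips[i] = 1.0 if s > 0 else -1.0
    sources = sources * flips[:, None]
    mixing = mixing * flips[None, :]
    order = np.argsort(-np.sum(mixing**2, axis=0), kind="stable")
    return mixing[:, order], sources[order]


def infomax_ica(
    whitened: np.ndarray,
    dewhitening: np.ndarray,
    seed: int | None = 0,
    *,
    lr: float | None = None,
    batch: int | None = None,
    anneal_deg: float = 60.0,
    anneal_factor: float = 0.9,
    tol: float = 1e-6,
    max_iter: int = 512,
    extended: bool = False,
    eigenvalues: np.ndarray | None = None,
    discarded_variance: float = 0.0,
) -> ICADecomposition:
    """Run Infomax on pre-whitened data and map back to subject space."""
    z = np.asarray(whitened, dtype=float)
    k, v = z.shape
    rng = np.random.default_rng(seed)
    w, info = _infomax_unmix(
        z,
        rng,
        lr if lr is not None else _default_lr(k),
        batch if batch is not None else _default_batch(v),
        anneal_deg,
        anneal_factor,
        tol,
        max_iter,
        extended,
    )
    sources = w @ z
    mixing = dewhitening @ np.linalg.inv(w)
    mixing, sources = _fix_sign_and_order(mixing, sources)
    return ICADecomposition(
        mixing=mixing,
        sources=sources,
        k=k,
        eigenvalues=(
            np.asarray(eigenvalues) if eigenvalues is not None else np.array([])
        ),
        discarded_variance=discarded_variance,
        convergence=info,
        seed=seed,
    )


def amari_index(a_est: np.ndarray, a_true: np.ndarray) -> float:
    """Permutation/scale-invariant separation error in [0, 1].

    With ``P = |pinv(A_est) @ A_true|``::

        (1 / (2K(K-1))) * [ sum_i (sum_j P_ij / max_j P_ij - 1)
                          + sum_j (sum_i P_ij / max_i P_ij - 1) ]

    Zero iff ``P`` is a scaled permutation matrix.
    """
    a_est = np.asarray(a_est, dtype=float)
    a_true = np.asarray(a_true, dtype=float)
    if a_est.shape != a_true.shape:
        raise RankError("amari_index requires matching shapes")
    if np.linalg.matrix_rank(a_est) < a_est.shape[1]:
        raise RankError("A_est is column-rank deficient")
    p = np.abs(np.linalg.pinv(a_est) @ a_true)
    k = p.shape[0]
    if k < 2:
        return 0.0
    rows = (p.sum(axis=1) / p.max(axis=1) - 1.0).sum()
    cols = (p.sum(axis=0) / p.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * k * (k - 1)))


class InfomaxICA(BaseEstimator, TransformerMixin):
    """Source-based morphometry decomposition as a sklearn estimator.

    Parameters
    ----------
    n_components : int or "mdl", default "mdl"
        Number of components; ``"mdl"`` selects the order by the minimum
        description length criterion.
    learning_rate : float or None
        Infomax step size; defaults to ``0.015 / ln(K)``.
    batch_size : int or None
        Voxels per natural-gradient step; defaults to ``8 * floor(sqrt(V))``.
    anneal_deg, anneal_factor : float
        Anneal the learning rate by ``anneal_factor`` whenever the angle
        between successive weight updates exceeds ``anneal_deg`` degrees.
    tol : float
        Stop when the summed squared weight change per sweep falls below.
    max_iter : int
        Maximum sweeps through the voxel set.
    extended : bool
        Switch tanh/kurtosis-sign updates on to separate sub-Gaussian
        sources as well (plain logistic Infomax by default).
    random_state : int or None
        Seed for the weight initialization and voxel shuffling.

    Attributes
    ----------
    components_ : (K, V) ndarray — unit-variance spatial sources.
    mixing_ : (N, K) ndarray — loading coefficients of the fitted cohort.
    n_components_ : int — retained order.
    decomposition_ : ICADecomposition — full record incl. convergence.
    mean_map_ : (V,) ndarray — removed across-subject mean GM profile.
    """

    def __init__(
        self,
        n_components: int | str = "mdl",
        learning_rate: float | None = None,
        batch_size: int | None = None,
        anneal_deg: float = 60.0,
        anneal_factor: float = 0.9,
        tol: float = 1e-6,
        max_iter: int = 512,
        extended: bool = False,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.anneal_deg = anneal_deg
        self.anneal_factor = anneal_factor
        self.tol = tol
        self.max_iter = max_iter
        self.extended = extended
        self.random_state = random_state

    def _resolve_order(self, x: np.ndarray) -> int:
        if self.n_components == "mdl":
            return estimate_order_mdl(x)
        k = int(self.n_components)
        if k < 1:
            raise RankError("n_components must be >= 1")
        return k

    def fit(self, X, y=None):
        x = _as_matrix(X)
        if x.shape[0] < 3:
            raise InsufficientDataError("need >= 3 subjects to fit an ICA")
        k = self._resolve_order(x)
        z, dewhitening, eigvals, discarded = whiten(x, k)
        decomp = infomax_ica(
            z,
            dewhitening,
            seed=self.random_state,
            lr=self.learning_rate,
            batch=self.batch_size,
            anneal_deg=self.anneal_deg,
            anneal_factor=self.anneal_factor,
            tol=self.tol,
            max_iter=self.max_iter,
            extended=self.extended,
            eigenvalues=eigvals,
            discarded_variance=discarded,
        )
        xc, row_means, mean_map = center(x)
        decomp.row_means = row_means
        decomp.mean_map = mean_map
        self.decomposition_ = decomp
        self.components_ = decomp.sources
        self.mixing_ = decomp.mixing
        self.n_components_ = decomp.k
        self.mean_map_ = mean_map
        self.n_iter_ = decomp.convergence["n_iter"]
        return self

    def transform(self, X) -> np.ndarray:
        """Loading coefficients of (possibly new) subjects by regression
        of their centered maps onto the fitted sources."""
        if not hasattr(self, "components_"):
            raise RankError("estimator is not fitted")
        x = _as_matrix(X)
        xc = x - x.mean(axis=1, keepdims=True) - self.mean_map_
        s = self.components_
        return xc @ s.T @ np.linalg.inv(s @ s.T)

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.mixing_
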