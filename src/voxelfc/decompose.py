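"""Per-subject spatial ICA with MDL model-order estimation and multi-run
stability selection.

The generative model is ``X = M S``: the observed T×V matrix is a mixture of
``N`` statistically independent *spatial* maps (rows of ``S``, one value per
in-mask voxel) weighted by time courses (columns of ``M``).  Each voxel is a
sample of the T-dimensional mixing space, so the fixed-point ICA runs on the
voxel dimension after PCA whitening.

The number of components is chosen by the minimum-description-length
criterion on the eigenvalues of the temporal covariance (Wax–Kailath form
with T channels and V samples), the standard choice in fMRI ICA practice.
Stability selection reruns ICA with randomized initialisation (optionally
bootstrap-resampled timepoints), clusters the pooled maps by absolute
correlation and keeps each cluster's centrotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import (
    DegenerateComponentError,
    IcaConvergenceWarning,
    NumericalError,
    ParameterError,
    SelectionError,
)
from .io_nifti import SubjectMatrix

__all__ = [
    "IcaDecomposition",
    "ZMaps",
    "estimate_order_mdl",
    "mdl_curve",
    "run_spatial_ica",
    "stability_select",
    "zscore_maps",
]

_SEED_MOD = 2**31


@dataclass
class IcaDecomposition:
    """Spatial ICA result: ``mixing @ spatial_maps`` approximates the
    rank-``n_components`` part of the (voxel-wise demeaned) input."""

    subject_id: str
    n_components: int
    spatial_maps: np.ndarray  # N x V, rows = independent components
    mixing: np.ndarray  # T x N, columns = component time courses
    seed: int
    stability_index: np.ndarray | None = None  # per-component, in [0, 1]-ish


@dataclass
class ZMaps:
    """Z-scored spatial maps: each row has zero mean and unit population
    standard deviation over in-mask voxels."""

    subject_id: str
    z: np.ndarray  # N x V


def _demean_voxels(data: np.ndarray) -> np.ndarray:
    # remove each voxel's temporal mean; no variance normalization, so
    # downstream correlations stay defined on the original series
    return data - data.mean(axis=0, keepdims=True)


def mdl_curve(subject: SubjectMatrix, max_order: int) -> np.ndarray:
    """MDL(k) for k = 1..max_order (index 0 ↔ k=1).

    MDL(k) = −V·(T−k)·log(g_k/a_k) + ½·k·(2T−k)·log(V), with g_k and a_k the
    geometric and arithmetic means of the T−k smallest eigenvalues of the
    temporal covariance of the demeaned data.
    """
    t_points, n_vox = subject.data.shape
    if max_order >= min(t_points, n_vox):
        raise ParameterError(
            f"max_order={max_order} must be < min(T, V) = {min(t_points, n_vox)}"
        )
    x = _demean_voxels(subject.data)
    cov = x @ x.T / n_vox
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    if not np.all(np.isfinite(eigvals)):
        raise NumericalError("non-finite eigenvalues in temporal covariance")
    eigvals = np.clip(eigvals, np.finfo(float).tiny, None)
    log_eig = np.log(eigvals)
    curve = np.empty(max_order)
    for k in range(1, max_order + 1):
        tail = eigvals[: t_points - k]
        log_g = log_eig[: t_points - k].mean()
        a_k = tail.mean()
        curve[k - 1] = (
            -n_vox * (t_points - k) * (log_g - np.log(a_k))
            + 0.5 * k * (2 * t_points - k) * np.log(n_vox)
        )
    return curve


def estimate_order_mdl(subject: SubjectMatrix, max_order: int = 30) -> int:
    """Number of independent components minimizing the MDL criterion."""
    curve = mdl_curve(subject, max_order)
    return int(np.argmin(curve)) + 1


def _order_by_explained_variance(
    maps: np.ndarray, mixing: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # component j explains ||m_j||^2 * var(s_j) of the data sum of squares
    power = np.sum(mixing**2, axis=0) * np.var(maps, axis=1)
    order = np.argsort(-power, kind="stable")
    return maps[order], mixing[:, order], order


def run_spatial_ica(
    subject: SubjectMatrix,
    n_components: int,
    seed: int = 0,
    *,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> IcaDecomposition:
    """FastICA on the voxel dimension after PCA whitening.

    Deterministic given ``seed``; components are returned in decreasing
    order of explained variance of their mixing column.  Component sign is
    free (activity detection uses absolute values downstream).
    """
    t_points, n_vox = subject.data.shape
    if not 1 <= n_components <= min(t_points, n_vox):
        raise ParameterError(
            f"n_components={n_components} outside [1, {min(t_points, n_vox)}]"
        )
    x = _demean_voxels(subject.data)
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=int(seed) % _SEED_MOD,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x.T)  # (V, N)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"FastICA did not converge within {max_iter} iterations "
                f"(n_iter={ica.n_iter_}); returning best estimate",
                IcaConvergenceWarning,
                stacklevel=2,
            )
    maps = sources.T  # N x V, unit variance rows
    mixing = ica.mixing_  # T x N
    maps, mixing, _ = _order_by_explained_variance(maps, mixing)
    return IcaDecomposition(
        subject_id=subject.subject_id,
        n_components=n_components,
        spatial_maps=maps,
        mixing=mixing,
        seed=int(seed),
    )


def _refit_mixing(subject: SubjectMatrix, maps: np.ndarray) -> np.ndarray:
    """Least-squares time courses for given spatial maps on the original
    (demeaned) data — needed when maps come from bootstrap runs."""
    x = _demean_voxels(subject.data)
    # solve M = X S^T (S S^T)^-1
    gram = maps @ maps.T
    return np.linalg.solve(gram, maps @ x.T).T


def stability_select(
    subject: SubjectMatrix,
    n_components: int,
    n_runs: int = 20,
    base_seed: int = 0,
    bootstrap: bool = True,
) -> IcaDecomposition:
    """ICASSO-style reliable components.

    Runs ICA ``n_runs`` times with varying seeds (resampling timepoints with
    replacement when ``bootstrap``), pools all spatial maps, clusters them by
    average-linkage on dissimilarity 1−|r| into ``n_components`` clusters and
    returns each cluster's centrotype (the member with maximal summed
    within-cluster |r|).  ``stability_index`` is the mean within-cluster |r|
    minus the mean between-cluster |r| per cluster.  With ``n_runs == 1``
    this degrades to plain ICA with ``stability_index`` absent.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if n_runs == 1:
        return run_spatial_ica(subject, n_components, seed=base_seed)

    import dataclasses as _dc

    pooled: list[np.ndarray] = []
    for r in range(n_runs):
        seed = (int(base_seed) + r) % _SEED_MOD
        run_subject = subject
        if bootstrap and r > 0:  # run 0 keeps the original sampling
            rng = np.random.default_rng(seed)
            rows = rng.integers(0, subject.t_points, size=subject.t_points)
            run_subject = _dc.replace(subject, data=subject.data[rows])
        dec = run_spatial_ica(run_subject, n_components, seed=seed)
        pooled.append(dec.spatial_maps)
    all_maps = np.vstack(pooled)  # (n_runs * N) x V
    if all_maps.shape[0] < n_components:
        raise SelectionError(
            f"{all_maps.shape[0]} pooled components < {n_components} clusters"
        )

    sim = np.abs(np.corrcoef(all_maps))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    labels = fcluster(
        linkage(squareform(dist, checks=False), method="average"),
        t=n_components,
        criterion="maxclust",
    )

    centro_rows: list[int] = []
    stability: list[float] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        within = sim[np.ix_(members, members)]
        score = within.sum(axis=1)
        centro_rows.append(int(members[np.argmax(score)]))
        if members.size > 1:
            iu = np.triu_indices(members.size, k=1)
            w_mean = within[iu].mean()
        else:
            w_mean = 1.0
        outside = np.setdiff1d(np.arange(all_maps.shape[0]), members)
        b_mean = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        stability.append(float(w_mean - b_mean))

    maps = all_maps[centro_rows]
    mixing = _refit_mixing(subject, maps)
    maps, mixing, order = _order_by_explained_variance(maps, mixing)
    stability_arr = np.asarray(stability)[order]
    return IcaDecomposition(
        subject_id=subject.subject_id,
        n_components=n_components,
        spatial_maps=maps,
        mixing=mixing,
        seed=int(base_seed),
        stability_index=stability_arr,
    )


def zscore_maps(decomp: IcaDecomposition) -> ZMaps:
    """Center and scale each spatial map to zero mean / unit population SD
    over in-mask voxels (the scale on which the activity threshold acts)."""
    maps = decomp.spatial_maps
    sd = maps.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateComponentError(
            f"component(s) {bad.tolist()} have zero variance and cannot be z-scored"
        )
    z = (maps - maps.mean(axis=1, keepdims=True)) / sd[:, None]
    return ZMaps(subject_id=decomp.subject_id, z=z)
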