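"""Two-cohort synthetic resting-state fMRI generator with ground truth.

Each subject's 4-D volume follows the linear mixing model ``X = M S`` that
the decomposition stage assumes: a handful of spherical "activation" blobs
(the spatial sources) are driven by smooth band-limited time courses
(0.01–0.08 Hz at TR = 3 s, matching filtered BOLD), with per-subject
amplitude jitter and white Gaussian noise.

Differential connectivity is planted at specific voxel pairs so edge-level
recovery is exactly scoreable: each planted voxel receives a fixed extra
variance budget split between a component *shared* with its partner voxel
and a private component.  The split ratio sets the pair's correlation to the
cohort's target, while the budget itself (and hence the voxel's total
variance and its correlation to every other voxel) is identical in both
cohorts — only the planted pair differs between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FeasibilityError, ParameterError
from .io_nifti import BrainMask, SubjectMatrix, VolumeGrid

__all__ = [
    "SphericalBlob",
    "SynthConfig",
    "GroundTruth",
    "SyntheticSubject",
    "generate_cohorts",
    "subjects_from_arrays",
    "write_dataset",
    "recovery_score",
]

_MAX_TARGET_R = 0.95


@dataclass(frozen=True)
class SphericalBlob:
    center: tuple[float, float, float]
    radius: float = 2.0
    amplitude: float = 1.0


def _default_blobs(shape, n_sources, radius=2.0, amplitude=1.0):
    anchors = [
        (0.27, 0.27, 0.27), (0.70, 0.27, 0.70), (0.27, 0.70, 0.70),
        (0.70, 0.70, 0.27), (0.50, 0.50, 0.50), (0.27, 0.27, 0.70),
        (0.70, 0.27, 0.27), (0.27, 0.70, 0.27),
    ]
    if n_sources > len(anchors):
        raise ParameterError(f"at most {len(anchors)} default sources supported")
    return tuple(
        SphericalBlob(
            center=tuple(round(f * (s - 1)) for f, s in zip(anchors[j], shape)),
            radius=radius,
            amplitude=amplitude,
        )
        for j in range(n_sources)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic two-cohort experiment.

    Defaults emulate a small-scale version of a resting-state protocol:
    T = 130 retained volumes at TR = 3 s on a 12×12×12 grid, four blob
    sources, 20 subjects per cohort, relative noise SD 0.05, and ten planted
    differential edges with cohort correlations 0.55 vs 0.15 (Δr = 0.4).
    """

    shape: tuple[int, int, int] = (12, 12, 12)
    t_points: int = 130
    tr_seconds: float = 3.0
    band: tuple[float, float] = (0.01, 0.08)
    n_sources: int = 4
    blobs: tuple[SphericalBlob, ...] | None = None
    subjects_per_cohort: tuple[int, int] = (20, 20)
    group_labels: tuple[str, str] = ("HC", "AD")
    noise_sd: float = 0.05
    subject_jitter: float = 0.1
    n_diff_edges: int = 10
    diff_corr: tuple[float, float] = (0.55, 0.15)  # cohort A vs cohort B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_points < 20:
            raise ParameterError("t_points must be >= 20")
        ra, rb = self.diff_corr
        if max(abs(ra), abs(rb)) > _MAX_TARGET_R:
            raise FeasibilityError(
                f"|target correlation| must be <= {_MAX_TARGET_R}; "
                f"requested {self.diff_corr}"
            )
        blobs = self.blobs or _default_blobs(self.shape, self.n_sources)
        for b in blobs:
            for c, s in zip(b.center, self.shape):
                if c - b.radius < -0.5 or c + b.radius > s - 0.5:
                    raise ParameterError(f"blob {b} extends outside the grid")
        object.__setattr__(self, "blobs", tuple(blobs))


@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: str
    volume: np.ndarray  # (x, y, z, t)


@dataclass
class GroundTruth:
    """What the generator planted, on the flat grid (canonical F-order
    linear indices), independent of any later mask."""

    grid: VolumeGrid
    active_voxels: np.ndarray  # flat indices of all blob voxels
    blob_voxels: list[np.ndarray]  # per source
    diff_edges: list[tuple[int, int, float, float]]  # (v1, v2, r_A, r_B)
    source_time_courses: dict[str, np.ndarray] = field(default_factory=dict)
    source_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)


def _blob_flat_indices(shape, blob: SphericalBlob) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    dist2 = ((x - blob.center[0]) ** 2 + (y - blob.center[1]) ** 2
             + (z - blob.center[2]) ** 2)
    inside = dist2 <= blob.radius**2
    return np.flatnonzero(inside.ravel(order="F"))


def _bandlimited(rng: np.random.Generator, n_series: int, t_points: int,
                 tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance series with support restricted to the frequency band."""
    freqs = np.fft.rfftfreq(t_points, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ParameterError("frequency band is empty at this T and TR")
    coef = np.zeros((n_series, freqs.size), dtype=complex)
    coef[:, keep] = rng.standard_normal((n_series, keep.sum())) \
        + 1j * rng.standard_normal((n_series, keep.sum()))
    x = np.fft.irfft(coef, n=t_points, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _plan_diff_edges(config: SynthConfig, blob_voxels: list[np.ndarray],
                     rng: np.random.Generator):
    """Pick planted edge voxels: two distinct blobs per edge, each voxel used
    by at most one edge."""
    n_edges = config.n_diff_edges
    if n_edges == 0:
        return []
    n_blobs = len(blob_voxels)
    if n_blobs < 2:
        raise FeasibilityError("need at least two sources to plant edges")
    pools = [rng.permutation(v).tolist() for v in blob_voxels]
    ra, rb = config.diff_corr
    edges = []
    for e in range(n_edges):
        b1 = e % n_blobs
        b2 = (e + 1) % n_blobs
        if not pools[b1] or not pools[b2]:
            raise FeasibilityError(
                "not enough distinct blob voxels for the requested edges"
            )
        edges.append((int(pools[b1].pop()), int(pools[b2].pop()),
                      float(ra), float(rb)))
    return edges


def generate_cohorts(config: SynthConfig) -> tuple[list[SyntheticSubject], GroundTruth]:
    """Generate both cohorts' 4-D volumes plus the planted ground truth.

    Deterministic: the same config (seed included) reproduces the volumes
    bitwise.
    """
    shape = config.shape
    n_grid = int(np.prod(shape))
    blob_voxels = [_blob_flat_indices(shape, b) for b in config.blobs]
    planner_rng = np.random.default_rng([int(config.seed) % 2**31, 9999])
    edges = _plan_diff_edges(config, blob_voxels, planner_rng)

    truth = GroundTruth(
        grid=VolumeGrid(shape=shape),
        active_voxels=np.unique(np.concatenate(blob_voxels)),
        blob_voxels=blob_voxels,
        diff_edges=edges,
    )

    subjects: list[SyntheticSubject] = []
    for gi, (label, k) in enumerate(zip(config.group_labels,
                                        config.subjects_per_cohort)):
        for si in range(k):
            rng = np.random.default_rng([int(config.seed) % 2**31, gi, si])
            sid = f"{label}_{si:03d}"
            # per-subject source amplitudes (jittered, kept positive)
            amps = np.array([
                max(b.amplitude * (1.0 + config.subject_jitter
                                   * rng.standard_normal()), 0.1 * b.amplitude)
                for b in config.blobs
            ])
            courses = _bandlimited(rng, len(config.blobs), config.t_points,
                                   config.tr_seconds, config.band)
            maps = np.zeros((len(config.blobs), n_grid))
            for j, vox in enumerate(blob_voxels):
                maps[j, vox] = amps[j]
            x = courses.T @ maps  # T x n_grid

            # plant differential edges: fixed extra-variance budget per voxel,
            # shared/private split sets the cohort's correlation
            signal_var = np.sum(maps**2, axis=0)
            r_max = max(abs(edges[0][2]), abs(edges[0][3])) if edges else 0.0
            for (v1, v2, ra, rb) in edges:
                r = ra if gi == 0 else rb
                extra = _bandlimited(rng, 3, config.t_points,
                                     config.tr_seconds, config.band)
                w, u1, u2 = extra
                for v, u, sgn in ((v1, u1, 1.0), (v2, u2, np.sign(r) or 1.0)):
                    v0 = signal_var[v] + config.noise_sd**2
                    budget = r_max / (1.0 - r_max) * v0
                    g = np.sqrt(abs(r) * (v0 + budget))
                    h = np.sqrt(max(budget - g**2, 0.0))
                    x[:, v] += sgn * g * w + h * u

            x += config.noise_sd * rng.standard_normal(x.shape)
            vol = x.T.reshape(shape + (config.t_points,), order="F")
            subjects.append(SyntheticSubject(subject_id=sid, group_label=label,
                                             volume=vol))
            truth.source_time_courses[sid] = courses
            truth.source_amplitudes[sid] = amps
    return subjects, truth


def subjects_from_arrays(synthetic: list[SyntheticSubject]) -> tuple[list[SubjectMatrix], BrainMask]:
    """Build the analysis mask from the generated volumes and extract each
    subject's in-mask matrix (disk-free path into the pipeline)."""
    from .io_nifti import build_group_mask, load_subject_volume

    mask = build_group_mask([s.volume for s in synthetic])
    matrices = [
        load_subject_volume(s.volume, mask, s.group_label, subject_id=s.subject_id)
        for s in synthetic
    ]
    return matrices, mask


def write_dataset(config: SynthConfig, out_dir) -> "Path":
    """Write NIfTI volumes, a cohort manifest TSV, a toy blob atlas and the
    ground truth as JSON; returns the dataset directory."""
    import json
    from pathlib import Path

    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, truth = generate_cohorts(config)
    rows = []
    for s in subjects:
        path = out / f"{s.subject_id}.nii.gz"
        nib.save(nib.Nifti1Image(s.volume, np.eye(4)), str(path))
        rows.append({"subject_id": s.subject_id, "group": s.group_label,
                     "path": str(path)})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)

    atlas_flat = np.zeros(int(np.prod(config.shape)), dtype=np.int16)
    for j, vox in enumerate(truth.blob_voxels):
        atlas_flat[vox] = j + 1
    atlas = atlas_flat.reshape(config.shape, order="F")
    nib.save(nib.Nifti1Image(atlas, np.eye(4)), str(out / "atlas.nii.gz"))

    gt = {
        "shape": list(config.shape),
        "active_voxels": truth.active_voxels.tolist(),
        "blob_voxels": [v.tolist() for v in truth.blob_voxels],
        "diff_edges": [list(e) for e in truth.diff_edges],
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    return out


def recovery_score(ground_truth: GroundTruth, dfci_edge_voxels, cavl) -> dict:
    """Score recovered structure against the planted one.

    Parameters
    ----------
    dfci_edge_voxels : (k, 2) array of in-mask voxel positions of the
        selected edges (e.g. ``edge_index.edge_voxels()[result.dfci]``).
    cavl : VoxelSet
        Recovered common-activity set (typically the joint set of both
        cohorts).

    Returns voxel-level sensitivity and false-positive fraction (share of
    recovered voxels outside the planted set) plus edge-level sensitivity
    and precision against the planted edges.
    """
    mask = cavl.mask
    if mask.grid.shape != ground_truth.grid.shape:
        raise ParameterError("mask grid does not match the ground-truth grid")
    recovered_flat = set(mask.flat_indices[cavl.indices].tolist())
    true_set = set(ground_truth.active_voxels.tolist())
    n_rec = len(recovered_flat)
    voxel_sens = len(recovered_flat & true_set) / len(true_set) if true_set else 1.0
    voxel_fp = len(recovered_flat - true_set) / n_rec if n_rec else 0.0

    planted = {frozenset((v1, v2)) for v1, v2, _, _ in ground_truth.diff_edges}
    dfci_edge_voxels = np.asarray(dfci_edge_voxels, dtype=int).reshape(-1, 2)
    found = {
        frozenset(mask.flat_indices[pair].tolist()) for pair in dfci_edge_voxels
    }
    hits = len(found & planted)
    edge_sens = hits / len(planted) if planted else 1.0
    edge_prec = hits / len(found) if found else (1.0 if not planted else 0.0)
    return {
        "voxel_sensitivity": voxel_sens,
        "voxel_fp_fraction": voxel_fp,
        "edge_sensitivity": edge_sens,
        "edge_precision": edge_prec,
    }
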