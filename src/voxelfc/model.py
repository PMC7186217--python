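"""Statsmodels-style front end: a model object built from two cohorts of
subject data whose :meth:`VoxelFC.fit` runs the full pipeline —

    per-subject spatial ICA (order by MDL, optional stability selection)
    → z-scored maps → activity voxels at |z| ≥ θ
    → cohort common sets → joint common set
    → per-subject FC feature vectors over all joint-voxel pairs
    → edge-wise t-tests with BH-FDR at level α → differential-FC selection
    → paired repeated hold-out SVM evaluation of all-FC vs DFC features

— and returns a :class:`VoxelFCResults` carrying every stage's dimensions,
the per-edge statistics, the classification reports and a ``summary()``
table.  Threshold sweeps and multi-classifier comparisons hang off the
results object and reuse the fitted decompositions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, classify, connectivity, decompose, diffstats
from .classify import EvalProtocol, PairedComparison
from .errors import ConfigurationError, GroupingError
from .io_nifti import AtlasLabels, SubjectMatrix, bandpass_detrend

__all__ = ["VoxelFC", "VoxelFCResults"]

logger = logging.getLogger("voxelfc")

_SEED_MOD = 2**31


def _subject_cache_key(subject: SubjectMatrix, params: dict) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(subject.data).tobytes())
    h.update(json.dumps(params, sort_keys=True).encode())
    return h.hexdigest()[:16]


class VoxelFC:
    """Activity-voxel functional-connectivity discrimination model.

    Parameters
    ----------
    subjects : list of SubjectMatrix
        All subjects of both cohorts (each carries its cohort label).
    theta : float
        Activation threshold on |z| of the z-scored spatial maps.
    alpha : float
        Significance level for the FDR-corrected edge selection.
    ica_order : "mdl" or int
        Per-subject number of independent components, estimated by the MDL
        criterion or fixed.
    ica_runs : int
        Stability-selection runs per subject (1 = plain FastICA; the
        reference protocol uses 20).
    bootstrap : bool
        Resample timepoints across stability runs.
    protocol : EvalProtocol
        Hold-out evaluation settings.
    atlas : AtlasLabels, optional
        For region summaries; with ``restrict_to_atlas`` the joint common
        set is limited to atlas-labelled (e.g. gray-matter) voxels before
        FC extraction.
    bandpass : tuple (low_hz, high_hz, tr_seconds), optional
        Opt-in detrend + band-pass of the subject matrices.
    """

    def __init__(
        self,
        subjects: list[SubjectMatrix],
        *,
        theta: float = 2.0,
        alpha: float = 0.05,
        ica_order: str | int = "mdl",
        max_order: int = 30,
        ica_runs: int = 20,
        bootstrap: bool = True,
        protocol: EvalProtocol | None = None,
        atlas: AtlasLabels | None = None,
        restrict_to_atlas: bool = False,
        bandpass: tuple[float, float, float] | None = None,
        seed: int = 0,
    ):
        if not subjects:
            raise ConfigurationError("no subjects given")
        labels = sorted({s.group_label for s in subjects})
        if len(labels) != 2:
            raise ConfigurationError(
                f"exactly two cohort labels required, got {labels}"
            )
        mask = subjects[0].mask
        for s in subjects:
            if s.mask is not mask and s.mask != mask:
                raise GroupingError("subjects do not share a brain mask")
        self.subjects = list(subjects)
        self.mask = mask
        self.group_labels = tuple(labels)
        self.theta = float(theta)
        self.alpha = float(alpha)
        self.ica_order = ica_order
        self.max_order = int(max_order)
        self.ica_runs = int(ica_runs)
        self.bootstrap = bool(bootstrap)
        self.protocol = protocol or EvalProtocol(positive_label=labels[-1])
        self.atlas = atlas
        self.restrict_to_atlas = bool(restrict_to_atlas)
        self.bandpass = bandpass
        self.seed = int(seed)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_synthetic(cls, config=None, **kwargs) -> "VoxelFC":
        """Build the model from the synthetic generator's output (the
        ground truth is attached as ``model.ground_truth``)."""
        from .synthgen import SynthConfig, generate_cohorts, subjects_from_arrays

        config = config or SynthConfig()
        synthetic, truth = generate_cohorts(config)
        subjects, _ = subjects_from_arrays(synthetic)
        if "protocol" not in kwargs or kwargs["protocol"] is None:
            # second cohort label is the "patient" group by convention
            kwargs = {**kwargs,
                      "protocol": EvalProtocol(positive_label=config.group_labels[1])}
        model = cls(subjects, **kwargs)
        model.ground_truth = truth
        return model

    @classmethod
    def from_manifest(cls, manifest_path, mask_path=None, **kwargs) -> "VoxelFC":
        """Build from a cohort manifest TSV with columns
        (subject_id, group, path)."""
        from .io_nifti import build_group_mask, load_subject_volume

        table = pd.read_csv(manifest_path, sep="\t")
        required = {"subject_id", "group", "path"}
        if not required.issubset(table.columns):
            raise ConfigurationError(f"manifest needs columns {sorted(required)}")
        if table["group"].nunique() != 2:
            raise ConfigurationError("manifest must contain exactly two cohorts")
        mask = build_group_mask(list(table["path"]), explicit_mask=mask_path)
        subjects = [
            load_subject_volume(r.path, mask, r.group, subject_id=str(r.subject_id))
            for r in table.itertuples()
        ]
        return cls(subjects, **kwargs)

    # ------------------------------------------------------------------ #
    def _decompose_subject(self, subject: SubjectMatrix, seed: int,
                           cache_dir: Path | None):
        params = {
            "order": self.ica_order, "max_order": self.max_order,
            "runs": self.ica_runs, "bootstrap": self.bootstrap, "seed": seed,
        }
        cache_file = None
        if cache_dir is not None:
            cache_dir.mkdir(parents=True, exist_ok=True)
            key = _subject_cache_key(subject, params)
            cache_file = cache_dir / f"{subject.subject_id}_{key}.npz"
            if cache_file.exists():
                with np.load(cache_file, allow_pickle=False) as npz:
                    stability = npz["stability"] if npz["has_stability"] else None
                    return decompose.IcaDecomposition(
                        subject_id=subject.subject_id,
                        n_components=int(npz["n_components"]),
                        spatial_maps=npz["maps"], mixing=npz["mixing"],
                        seed=seed, stability_index=stability,
                    )
        if self.ica_order == "mdl":
            max_order = min(self.max_order, min(subject.data.shape) - 1)
            order = decompose.estimate_order_mdl(subject, max_order)
        else:
            order = int(self.ica_order)
        dec = decompose.stability_select(
            subject, order, n_runs=self.ica_runs, base_seed=seed,
            bootstrap=self.bootstrap,
        )
        if cache_file is not None:
            np.savez(
                cache_file, maps=dec.spatial_maps, mixing=dec.mixing,
                n_components=dec.n_components,
                has_stability=dec.stability_index is not None,
                stability=(dec.stability_index
                           if dec.stability_index is not None else np.zeros(0)),
            )
        return dec

    def fit(self, cache_dir=None, keep_decompositions: bool = False,
            evaluate: bool = True) -> "VoxelFCResults":
        """Run the full pipeline and return the results object.

        ``evaluate=False`` stops after the differential-FC selection
        (useful when only the selection or recovery scores are needed).
        """
        cache_dir = Path(cache_dir) if cache_dir is not None else None
        subjects = self.subjects
        if self.bandpass is not None:
            low, high, tr = self.bandpass
            subjects = [bandpass_detrend(s, low, high, tr) for s in subjects]

        zmaps_list, orders, decomps = [], [], []
        for i, subject in enumerate(subjects):
            seed = (self.seed * 10007 + i) % _SEED_MOD
            dec = self._decompose_subject(subject, seed, cache_dir)
            orders.append(dec.n_components)
            zmaps_list.append(decompose.zscore_maps(dec))
            if keep_decompositions:
                decomps.append(dec)
            logger.info("subject %s: N_i=%d components",
                        subject.subject_id, dec.n_components)

        g1, g2 = self.group_labels
        avls = {g1: [], g2: []}
        for zm, s in zip(zmaps_list, subjects):
            avls[s.group_label].append(
                activity.subject_active_voxels(zm, self.theta, self.mask)
            )
        cavl1 = activity.group_common_voxels(avls[g1])
        cavl2 = activity.group_common_voxels(avls[g2])
        cavl12 = activity.joint_common_voxels(cavl1, cavl2)
        if self.restrict_to_atlas:
            if self.atlas is None:
                raise ConfigurationError("restrict_to_atlas requires an atlas")
            labelled = np.flatnonzero(self.atlas.inmask_labels > 0)
            kept = np.intersect1d(cavl12.indices, labelled)
            cavl12 = activity.VoxelSet(indices=kept, mask=self.mask,
                                       provenance="joint_cavl12")
        logger.info("K1=%d K2=%d N1=%d N2=%d N12=%d",
                    len(avls[g1]), len(avls[g2]), cavl1.n, cavl2.n, cavl12.n)

        subj1 = [s for s in subjects if s.group_label == g1]
        subj2 = [s for s in subjects if s.group_label == g2]
        fc1 = connectivity.stack_group_fc(subj1, cavl12)
        fc2 = connectivity.stack_group_fc(subj2, cavl12)
        result = diffstats.select_dfc(fc1, fc2, alpha=self.alpha)
        logger.info("edges=%d |DFCI|=%d", fc1.edge_count, result.dfci.size)

        all_fc = np.vstack([fc1.matrix, fc2.matrix])
        labels = np.asarray([g1] * len(subj1) + [g2] * len(subj2))
        comparison = None
        all_fc_report = None
        if not evaluate:
            pass
        elif result.is_empty:
            # documented fallback: evaluate all-FC features only
            all_fc_report = classify.evaluate(
                all_fc, labels, self.protocol, feature_label="all_fc"
            )
        else:
            dfc = np.vstack([result.dfc1, result.dfc2])
            comparison = classify.compare_feature_sets(
                all_fc, dfc, labels, self.protocol
            )

        return VoxelFCResults(
            model=self,
            subjects=subjects,
            subject_ids=[s.subject_id for s in subjects],
            labels=labels,
            zmaps=zmaps_list,
            orders=orders,
            decompositions=decomps or None,
            avl_sizes={g1: [a.n for a in avls[g1]], g2: [a.n for a in avls[g2]]},
            cavl1=cavl1,
            cavl2=cavl2,
            cavl12=cavl12,
            fc1=fc1,
            fc2=fc2,
            diff=result,
            comparison=comparison,
            all_fc_report=all_fc_report,
        )


@dataclass
class VoxelFCResults:
    """Fitted-pipeline results: stage dimensions, per-edge statistics, the
    selected differential connections and the paired classification
    reports."""

    model: VoxelFC
    subjects: list[SubjectMatrix]
    subject_ids: list[str]
    labels: np.ndarray
    zmaps: list
    orders: list[int]
    decompositions: list | None
    avl_sizes: dict[str, list[int]]
    cavl1: activity.VoxelSet
    cavl2: activity.VoxelSet
    cavl12: activity.VoxelSet
    fc1: connectivity.GroupFcMatrix
    fc2: connectivity.GroupFcMatrix
    diff: diffstats.DiffFcResult
    comparison: PairedComparison | None
    all_fc_report: classify.ClassificationReport | None

    # ------------------------------------------------------------------ #
    @property
    def dimensions(self) -> dict:
        g1, g2 = self.model.group_labels
        return {
            "K1": int(np.sum(self.labels == g1)),
            "K2": int(np.sum(self.labels == g2)),
            "orders": list(map(int, self.orders)),
            "N1": self.cavl1.n,
            "N2": self.cavl2.n,
            "N12": self.cavl12.n,
            "edge_count": self.fc1.edge_count,
            "n_dfci": int(self.diff.dfci.size),
        }

    @property
    def selection_empty(self) -> bool:
        return self.diff.is_empty

    def metric_table(self) -> pd.DataFrame:
        """Mean ± SD of accuracy/sensitivity/specificity per feature set."""
        rows = []
        reports = []
        if self.comparison is not None:
            reports = [self.comparison.report_a, self.comparison.report_b]
        elif self.all_fc_report is not None:
            reports = [self.all_fc_report]
        for rep in reports:
            row = {"features": rep.feature_label}
            for m in classify.METRICS:
                row[f"{m}_mean"] = rep.summary.loc[m, "mean"]
                row[f"{m}_std"] = rep.summary.loc[m, "std"]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        dims = self.dimensions
        g1, g2 = self.model.group_labels
        lines = [
            "Activity-voxel functional-connectivity discrimination",
            "=" * 56,
            f"cohorts: {g1} (K1={dims['K1']})  vs  {g2} (K2={dims['K2']})",
            f"theta={self.model.theta}  alpha={self.model.alpha}  "
            f"ICA runs={self.model.ica_runs}",
            f"common activity voxels: N1={dims['N1']}  N2={dims['N2']}  "
            f"N12={dims['N12']}",
            f"FC features: {dims['edge_count']}   selected (DFCI): {dims['n_dfci']}",
        ]
        if self.selection_empty:
            lines.append("no edge survived FDR correction; all-FC fallback used")
        table = self.metric_table()
        if not table.empty:
            lines.append("")
            lines.append(table.to_string(index=False, float_format="%.4f"))
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        out = {"dimensions": self.dimensions,
               "theta": self.model.theta, "alpha": self.model.alpha,
               "selection_empty": self.selection_empty,
               "metrics": {}}
        table = self.metric_table()
        for _, row in table.iterrows():
            out["metrics"][row["features"]] = {
                k: float(row[k]) for k in row.index if k != "features"
            }
        return out

    # ------------------------------------------------------------------ #
    def threshold_sweep(self, theta_values=None, protocol=None) -> pd.DataFrame:
        """Robustness sweep over the activation threshold, reusing the
        per-subject decompositions (default grid 1.5:0.1:2.5)."""
        if theta_values is None:
            theta_values = [round(1.5 + 0.1 * i, 1) for i in range(11)]
        return classify.threshold_sweep(
            self.zmaps, self.subjects, theta_values,
            alpha=self.model.alpha,
            protocol=protocol or self.model.protocol,
            mask=self.model.mask,
        )

    def compare_classifiers(self, algorithms=classify.ALGORITHMS,
                            features: str = "dfc", protocol=None) -> pd.DataFrame:
        """Multi-algorithm comparison on the selected (or all-FC) features."""
        if features == "dfc" and not self.selection_empty:
            x = np.vstack([self.diff.dfc1, self.diff.dfc2])
        else:
            x = np.vstack([self.fc1.matrix, self.fc2.matrix])
        return classify.compare_classifiers(
            x, self.labels, protocol or self.model.protocol, algorithms
        )

    def region_summary(self, which: str = "cavl12", atlas=None,
                       min_count: int = 10, min_fraction: float = 0.01) -> pd.DataFrame:
        atlas = atlas or self.model.atlas
        if atlas is None:
            raise ConfigurationError("no atlas available for region summaries")
        voxels = {"cavl1": self.cavl1, "cavl2": self.cavl2,
                  "cavl12": self.cavl12}[which]
        return activity.summarize_regions(voxels, atlas, min_count, min_fraction)

    def recovery(self, ground_truth=None) -> dict:
        """Score recovery against planted ground truth (synthetic data)."""
        from .synthgen import recovery_score

        truth = ground_truth or getattr(self.model, "ground_truth", None)
        if truth is None:
            raise ConfigurationError("no ground truth attached to this model")
        selected = self.fc1.edge_index.edge_voxels()[self.diff.dfci]
        return recovery_score(truth, selected, self.cavl12)

    def plot_metrics(self, ax=None):
        """Bar plot of mean metrics for all-FC vs DFC features."""
        import matplotlib.pyplot as plt

        table = self.metric_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        metrics = list(classify.METRICS)
        width = 0.35
        xs = np.arange(len(metrics))
        for i, (_, row) in enumerate(table.iterrows()):
            vals = [row[f"{m}_mean"] for m in metrics]
            errs = [row[f"{m}_std"] for m in metrics]
            ax.bar(xs + i * width, vals, width, yerr=errs, capsize=3,
                   label=row["features"])
        ax.set_xticks(xs + width / 2)
        ax.set_xticklabels(metrics)
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("mean over splits")
        ax.legend()
        return ax

    def save(self, out_dir) -> Path:
        """Write summary JSON, per-edge statistics, FC matrices and
        voxel-set exports under ``out_dir``."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(self.to_summary_dict(), indent=2, sort_keys=True)
        )
        self.diff.to_frame(self.fc1).to_csv(out / "edges.tsv", sep="\t", index=False)
        self.fc1.to_frame().to_csv(out / "fc_group1.tsv", sep="\t")
        self.fc2.to_frame().to_csv(out / "fc_group2.tsv", sep="\t")
        np.savetxt(out / "cavl12_indices.txt", self.cavl12.indices, fmt="%d")
        flags = self.cavl12.to_flags()
        vol = self.model.mask.unmask(flags.astype(np.uint8))
        nib.save(nib.Nifti1Image(vol, self.model.mask.grid.affine),
                 str(out / "cavl12_mask.nii.gz"))
        if self.comparison is not None:
            self.comparison.report_a.per_run.to_csv(
                out / "per_run_all_fc.tsv", sep="\t", index=False)
            self.comparison.report_b.per_run.to_csv(
                out / "per_run_dfc.tsv", sep="\t", index=False)
        return out
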