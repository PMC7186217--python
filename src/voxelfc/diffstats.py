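"""Edge-wise two-sample tests with FDR correction and selection of the
significantly different functional connections.

Each edge's feature values are compared between cohorts with a two-sided
pooled-variance Student t-test (Welch available as an option), p-values are
adjusted by Benjamini–Hochberg step-up over the full edge family, and the
selected index set contains exactly the edges with adjusted p strictly below
the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import VoxelSet
from .connectivity import GroupFcMatrix
from .errors import ParameterError, SampleSizeError
from .io_nifti import AtlasLabels

__all__ = [
    "DiffFcResult",
    "edgewise_ttest",
    "fdr_adjust",
    "select_dfc",
    "aggregate_dfc_by_region",
]


@dataclass
class DiffFcResult:
    """Per-edge statistics plus the selected differential-FC feature blocks."""

    t_stats: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    dfci: np.ndarray  # increasing edge indices with p_adj < alpha
    alpha: float
    dfc1: np.ndarray  # group-1 features restricted to dfci columns
    dfc2: np.ndarray
    degenerate_edges: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def is_empty(self) -> bool:
        """True when no edge survives correction — a typed outcome, not an
        error, so callers can fall back to all-FC features."""
        return self.dfci.size == 0

    def to_frame(self, fc1: GroupFcMatrix | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "edge": np.arange(self.t_stats.size),
                "t": self.t_stats,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "selected": np.isin(np.arange(self.t_stats.size), self.dfci),
            }
        )
        if fc1 is not None:
            ev = fc1.edge_index.edge_voxels()
            df.insert(1, "voxel_p", ev[:, 0])
            df.insert(2, "voxel_q", ev[:, 1])
        return df


def edgewise_ttest(
    fc1: GroupFcMatrix | np.ndarray,
    fc2: GroupFcMatrix | np.ndarray,
    *,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided two-sample t per edge.

    Returns (t, p, degenerate_edges).  Zero pooled variance with equal means
    gives t=0, p=1; with unequal means p=0 and the edge is flagged
    degenerate.
    """
    a = fc1.matrix if isinstance(fc1, GroupFcMatrix) else np.asarray(fc1, float)
    b = fc2.matrix if isinstance(fc2, GroupFcMatrix) else np.asarray(fc2, float)
    if a.shape[1] != b.shape[1]:
        raise ParameterError("edge counts differ between groups")
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("need at least 2 subjects per group")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se2 == 0
    degenerate = np.flatnonzero(zero_var & (diff != 0))
    t = np.where(zero_var & (diff == 0), 0.0, t)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    p = np.where(zero_var & (diff != 0), 0.0, p)
    return t, p, degenerate


def fdr_adjust(p_raw: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (default) adjusted p-values over the whole family."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw < 0) | (p_raw > 1) | ~np.isfinite(p_raw)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p_raw, method=method)
    return p_adj


def select_dfc(
    fc1: GroupFcMatrix | np.ndarray,
    fc2: GroupFcMatrix | np.ndarray,
    alpha: float = 0.05,
    *,
    welch: bool = False,
    fisher_z: bool = False,
) -> DiffFcResult:
    """Differential-FC selection: t-test per edge, BH adjustment, keep edges
    with adjusted p strictly below ``alpha``.

    ``fisher_z`` applies atanh to the correlations before testing (off by
    default: the feature itself is the raw r).  The selected columns of the
    two group matrices are returned untransformed either way.
    """
    raw1 = fc1.matrix if isinstance(fc1, GroupFcMatrix) else np.asarray(fc1, float)
    raw2 = fc2.matrix if isinstance(fc2, GroupFcMatrix) else np.asarray(fc2, float)
    a, b = raw1, raw2
    if fisher_z:
        clip = 1.0 - 1e-12
        a = np.arctanh(np.clip(a, -clip, clip))
        b = np.arctanh(np.clip(b, -clip, clip))
    t, p, degenerate = edgewise_ttest(a, b, welch=welch)
    p_adj = fdr_adjust(p)
    dfci = np.flatnonzero(p_adj < alpha)
    return DiffFcResult(
        t_stats=t,
        p_raw=p,
        p_adj=p_adj,
        dfci=dfci,
        alpha=alpha,
        dfc1=raw1[:, dfci],
        dfc2=raw2[:, dfci],
        degenerate_edges=degenerate,
    )


def aggregate_dfc_by_region(
    result: DiffFcResult,
    cavl12: VoxelSet,
    atlas: AtlasLabels,
) -> pd.DataFrame:
    """Count selected edges per unordered atlas-region pair (same-region
    edges on the diagonal); voxels with label 0 fall in an explicit
    "unlabeled" pseudo-region.  Returns a square symmetric table."""
    labels = atlas.inmask_labels[cavl12.indices]
    names = {0: "unlabeled", **atlas.region_names}
    n = cavl12.n
    p_idx, q_idx = np.triu_indices(n, k=1)
    region_labels = sorted(set(np.unique(labels)))
    name_list = [names.get(lab, f"region_{lab}") for lab in region_labels]
    pos = {lab: i for i, lab in enumerate(region_labels)}
    counts = np.zeros((len(region_labels), len(region_labels)), dtype=int)
    for k in result.dfci:
        la, lb = labels[p_idx[k]], labels[q_idx[k]]
        i, j = sorted((pos[la], pos[lb]))
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return pd.DataFrame(counts, index=name_list, columns=name_list)
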