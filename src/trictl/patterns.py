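"""Virtual patterns and the tricluster -> feature-space transformation.

A tricluster's *virtual pattern* is its per-feature prototype: the mean of
the cell values over all (object, context) cells for numeric and ordinal
features, the mode for categorical features (ties broken by first occurrence
in object-then-context scan order).  Patterns can be computed for the whole
tricluster (3D) or for each of its time slices after *detaching* (2D); a
detached slice pattern at position ``pos`` of tricluster ``tid`` is named
``Tric_<tid>_<pos>``, position 0 being the earliest context.

An object is compared with a pattern through the *virtual distance* (the
Euclidean distance between the object's reduced per-feature vector and the
prototype) or the *virtual correlation* (their Pearson correlation).  A
matrix of such similarities — one row per learning example, one column per
detached pattern — is the feature space handed to the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ThreeWayDataset
from .mining import Tricluster

logger = logging.getLogger(__name__)

__all__ = [
    "VirtualPattern",
    "FeatureMatrix",
    "virtual_pattern",
    "reduce_object",
    "virtual_distance",
    "virtual_correlation",
    "detach",
    "render_pattern_name",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class VirtualPattern:
    """Per-feature prototype of a tricluster or one of its slices.

    ``entries[e]`` is the mean (tag ``"mean"``) or mode (tag ``"mode"``) of
    the source subspace's cells for the e-th feature of ``feature_ids``.
    """

    entries: tuple
    feature_ids: tuple
    aggregators: tuple  # per entry: "mean" | "mode"
    tricluster_id: int | None = None
    slice_position: int | None = None

    def __len__(self):
        return len(self.entries)

    def vector(self) -> np.ndarray:
        return np.asarray(self.entries, dtype=float)


@dataclass
class FeatureMatrix:
    """Similarities between learning examples and detached patterns."""

    data: pd.DataFrame
    mode: str  # "distance" | "correlation"

    def __post_init__(self):
        if self.mode not in ("distance", "correlation"):
            raise ValueError("mode must be 'distance' or 'correlation'")
        if self.data.columns.duplicated().any():
            raise ValueError("pattern column names must be unique")
        if self.data.isna().any().any():
            raise ValueError("feature matrix must have no missing cells")


def _mode_first_occurrence(values) -> float:
    """Mode of a sequence; ties resolved by first occurrence order."""
    counts: dict = {}
    order: list = []
    for v in values:
        if v not in counts:
            counts[v] = 0
            order.append(v)
        counts[v] += 1
    best = max(counts.values())
    for v in order:
        if counts[v] == best:
            return v
    raise ValueError("empty sequence has no mode")


def _aggregate(cells_by_feature, kinds):
    """Apply mean/mode per feature; cells scanned object-major then context."""
    entries, tags = [], []
    for cells, kind in zip(cells_by_feature, kinds):
        if len(cells) == 0:
            raise ValueError("empty subspace has no virtual pattern")
        if kind == "categorical":
            entries.append(_mode_first_occurrence(list(cells)))
            tags.append("mode")
        else:
            entries.append(float(np.mean(cells)))
            tags.append("mean")
    return tuple(entries), tuple(tags)


def virtual_pattern(
    subspace: Tricluster,
    data: ThreeWayDataset,
    slice_position: int | None = None,
    tricluster_id: int | None = None,
) -> VirtualPattern:
    """Prototype of a tricluster (or, with ``slice_position``, one slice).

    One entry per feature ``j`` of the subspace: the mean over all cells
    ``(i, k)`` in ``I x K`` for numeric/ordinal features, the mode for
    categorical features (first-occurrence tie-break, object-then-context
    scan).  With ``slice_position`` set, ``K`` is just that context.
    """
    I = sorted(subspace.object_ids)
    J = sorted(subspace.feature_ids)
    if slice_position is not None:
        K = [sorted(subspace.context_ids)[slice_position]]
    else:
        K = sorted(subspace.context_ids)
    if not I or not J or not K:
        raise ValueError("empty subspace has no virtual pattern")
    if data.missing_mask[np.ix_(I, J, K)].any():
        raise ValueError("virtual pattern undefined over missing cells")
    kinds = [data.features[j].kind for j in J]
    cells_by_feature = []
    for j in J:
        # object-major, then context order
        cells_by_feature.append([data.values[i, j, k] for i in I for k in K])
    entries, tags = _aggregate(cells_by_feature, kinds)
    return VirtualPattern(entries, tuple(J), tags, tricluster_id, slice_position)


def reduce_object(
    object_subarray: np.ndarray, feature_kinds, pattern: VirtualPattern | None = None
) -> np.ndarray:
    """Reduce one object's (contexts x features) sub-array to a per-feature vector.

    Applies the same aggregators as :func:`virtual_pattern` — mean over the
    contexts for numeric/ordinal features, first-occurrence mode for
    categoricals — so the result is comparable entrywise with a 3D pattern.
    """
    arr = np.asarray(object_subarray, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if len(feature_kinds) != arr.shape[1]:
        raise ValueError("feature kinds do not match sub-array width")
    if pattern is not None and len(pattern) != arr.shape[1]:
        raise ValueError(
            f"sub-array width {arr.shape[1]} does not match pattern length {len(pattern)}"
        )
    out = []
    for e, kind in enumerate(feature_kinds):
        col = arr[:, e]
        if kind == "categorical":
            out.append(_mode_first_occurrence(col.tolist()))
        else:
            out.append(float(col.mean()))
    return np.asarray(out, dtype=float)


def virtual_distance(object_vector, pattern: VirtualPattern | np.ndarray) -> float:
    """Euclidean distance between an object's reduced vector and a prototype."""
    p = pattern.vector() if isinstance(pattern, VirtualPattern) else np.asarray(pattern, float)
    v = np.asarray(object_vector, dtype=float)
    if v.shape != p.shape:
        raise ValueError(f"length mismatch: object {v.shape} vs pattern {p.shape}")
    return float(np.sqrt(np.sum((v - p) ** 2)))


def virtual_correlation(object_vector, pattern: VirtualPattern | np.ndarray) -> float:
    """Pearson correlation between an object's reduced vector and a prototype.

    Returns 0 (with a logged warning) when either vector is constant, since
    the correlation is then undefined.
    """
    p = pattern.vector() if isinstance(pattern, VirtualPattern) else np.asarray(pattern, float)
    v = np.asarray(object_vector, dtype=float)
    if v.shape != p.shape:
        raise ValueError(f"length mismatch: object {v.shape} vs pattern {p.shape}")
    if v.size < 2:
        raise ValueError("correlation needs vectors of length >= 2")
    if np.ptp(v) == 0 or np.ptp(p) == 0:
        logger.warning("virtual correlation of a constant vector is undefined; returning 0")
        return 0.0
    return float(np.corrcoef(v, p)[0, 1])


def detach(
    tricluster: Tricluster, data: ThreeWayDataset, tricluster_id: int | None = None
) -> list[tuple[VirtualPattern, int]]:
    """Split a tricluster into its per-context slice patterns.

    Returns ``|K|`` pairs ``(pattern, position)`` with positions 0..|K|-1 in
    context order; each pattern is the 2D virtual pattern of one slice.
    """
    return [
        (virtual_pattern(tricluster, data, slice_position=pos, tricluster_id=tricluster_id), pos)
        for pos in range(len(tricluster.context_ids))
    ]


def render_pattern_name(tricluster_id: int, position: int) -> str:
    """Canonical pattern name: ``Tric_<id>_<position>`` (position 0 = earliest)."""
    return f"Tric_{tricluster_id}_{position}"


def build_feature_matrix(
    examples,
    triclusters,
    data: ThreeWayDataset,
    mode: str = "distance",
    detached: bool = True,
) -> FeatureMatrix:
    """Similarity matrix between learning examples and tricluster patterns.

    ``examples`` is a sequence of (contexts x features) arrays over the FULL
    feature axis of ``data`` (rows = consecutive snapshots, most recent
    last); ``triclusters`` were mined on ``data``.  Patterns are anchored to
    the END of each example window: a detached pattern at offset ``o`` from
    its tricluster's last context is matched with the example row ``o`` steps
    before the window's last row.  Examples too short to reach a pattern's
    row get the degenerate value (the column's maximum distance, or
    correlation 0) and a log entry.

    With ``detached=False`` one column per tricluster is produced instead,
    comparing each example's reduced sub-array with the 3D pattern.
    """
    if mode not in ("distance", "correlation"):
        raise ValueError("mode must be 'distance' or 'correlation'")
    sim = virtual_distance if mode == "distance" else virtual_correlation

    columns: dict[str, list] = {}
    kinds_all = [f.kind for f in data.features]

    def example_rows(ex):
        arr = np.asarray(ex, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(data.features):
            raise ValueError(
                f"example width {arr.shape[1]} does not cover the {len(data.features)} features"
            )
        if np.isnan(arr).any():
            raise ValueError("example contains missing features; impute upstream")
        return arr

    mats = [example_rows(ex) for ex in examples]

    if detached:
        for tid, t in enumerate(triclusters):
            J = sorted(t.feature_ids)
            kinds = [kinds_all[j] for j in J]
            nk = len(t.context_ids)
            for pattern, pos in detach(t, data, tricluster_id=tid):
                name = render_pattern_name(tid, pos)
                offset = nk - 1 - pos  # steps before the window's last snapshot
                col = []
                for arr in mats:
                    row = arr.shape[0] - 1 - offset
                    if row < 0:
                        col.append(None)  # degenerate: window too short
                    else:
                        vec = reduce_object(arr[row : row + 1, J], kinds, pattern)
                        col.append(sim(vec, pattern))
                columns[name] = col
    else:
        for tid, t in enumerate(triclusters):
            J = sorted(t.feature_ids)
            kinds = [kinds_all[j] for j in J]
            nk = len(t.context_ids)
            pattern = virtual_pattern(t, data, tricluster_id=tid)
            name = f"Tric_{tid}"
            col = []
            for arr in mats:
                if arr.shape[0] < nk:
                    col.append(None)
                else:
                    vec = reduce_object(arr[arr.shape[0] - nk :, J], kinds, pattern)
                    col.append(sim(vec, pattern))
            columns[name] = col

    df = pd.DataFrame(columns)
    for name in df.columns:
        if df[name].isna().any():
            logger.warning("examples too short for pattern %s; degenerate fill", name)
            if mode == "distance":
                fill = df[name].max()
                df[name] = df[name].fillna(0.0 if pd.isna(fill) else fill)
            else:
                df[name] = df[name].fillna(0.0)
    return FeatureMatrix(df, mode)
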