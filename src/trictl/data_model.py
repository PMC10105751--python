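"""Containers and I/O for three-way (object x feature x time) datasets.

A three-way dataset ``D`` holds ``n`` objects, ``m`` features and ``p``
ordered contexts (time points), with one real-or-categorical value
``d[i, j, k]`` per cell.  Categorical values are integer-coded against an
explicit category list; missing cells are tracked with a boolean mask, never
with sentinel values.  The on-disk form is long-format delimited text (one
row per object x context), which keeps irregular follow-up data honest:
an absent row is a missing slice, not a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

FEATURE_KINDS = ("numeric", "ordinal", "categorical")


@dataclass(frozen=True)
class Feature:
    """A feature descriptor: name, kind and (for categoricals) category list."""

    name: str
    kind: str
    categories: tuple | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and self.categories is None:
            raise ValueError(f"categorical feature {self.name!r} needs a category list")


@dataclass
class ThreeWayDataset:
    """An ``n x m x p`` tensor of clinical values over ordered time contexts.

    Attributes
    ----------
    objects : list
        Object (patient / example) identifiers, order fixed.
    features : list of :class:`Feature`
        Feature descriptors; ordinal features are integer-coded and treated
        numerically downstream, categoricals are coded against ``categories``.
    contexts : list
        Context identifiers in strict ascending time order.
    values : ndarray, shape (n, m, p)
        Cell values as floats (category codes for categoricals).
    missing_mask : ndarray of bool, shape (n, m, p)
        True where the cell is missing.
    """

    objects: list
    features: list
    contexts: list
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        n, m, p = len(self.objects), len(self.features), len(self.contexts)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (n, m, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m}, {p})")
        if self.missing_mask.shape != (n, m, p):
            raise ValueError("missing_mask shape mismatch")
        if len(set(self.contexts)) != p:
            raise ValueError("contexts must be distinct")
        if sorted(self.contexts) != list(self.contexts):
            raise ValueError("contexts must be in ascending order")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def slice_at(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, missing) for context position ``k`` as n x m arrays."""
        return self.values[:, :, k], self.missing_mask[:, :, k]


@dataclass(frozen=True)
class EvaluationRecord:
    """One clinical evaluation: a named test performed on a patient on a date.

    ``measurements`` maps feature names to values (ALSFRS-R questions Q1..Q12
    as integers in 0..4, FVC as percent-predicted).
    """

    patient_id: str
    date: date
    test_name: str
    measurements: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for q in (f"Q{i}" for i in range(1, 13)):
            v = self.measurements.get(q)
            if v is not None and (v != int(v) or not 0 <= v <= 4):
                raise ValueError(
                    f"{q}={v!r} out of range for patient {self.patient_id} on {self.date}"
                )


def _parse_manifest(manifest_path) -> list[Feature]:
    with open(manifest_path) as fh:
        raw = yaml.safe_load(fh)
    feats = []
    for name, decl in raw.items():
        if isinstance(decl, str):
            kind, cats = decl, None
        else:
            kind, cats = decl["kind"], decl.get("categories")
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r} for feature {name!r}")
        feats.append(Feature(name, kind, tuple(cats) if cats is not None else None))
    return feats


def _encode(feature: Feature, raw_value):
    if feature.kind == "categorical":
        try:
            return float(feature.categories.index(raw_value))
        except ValueError:
            # numeric-looking CSV round trips: try the coded form
            try:
                code = float(raw_value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"value {raw_value!r} not in categories of {feature.name!r}"
                ) from None
            if not 0 <= code < len(feature.categories):
                raise ValueError(
                    f"value {raw_value!r} not in categories of {feature.name!r}"
                )
            return code
    return float(raw_value)


def load_three_way(records_path, manifest_path) -> ThreeWayDataset:
    """Read a long-format tensor file plus feature manifest.

    The records file is a CSV with header ``object,context,<feature...>``; the
    manifest maps each feature name to its kind (``numeric``/``ordinal``/
    ``categorical``, the latter with a category list).  Contexts are sorted
    ascending; (object, context) rows that are absent yield missing cells.

    Raises
    ------
    ValueError
        On a duplicate (object, context) row (named in the message) or an
        unknown feature kind.
    """
    features = _parse_manifest(manifest_path)
    df = pd.read_csv(records_path)
    expected = {"object", "context"} | {f.name for f in features}
    missing_cols = expected - set(df.columns)
    if missing_cols:
        raise ValueError(f"records file lacks columns {sorted(missing_cols)}")
    dup = df.duplicated(subset=["object", "context"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["object", "context"]].iloc[0]
        raise ValueError(
            f"duplicate (object, context) row: ({pair['object']!r}, {pair['context']!r})"
        )
    objects = list(pd.unique(df["object"]))
    contexts = sorted(pd.unique(df["context"]))
    n, m, p = len(objects), len(features), len(contexts)
    values = np.zeros((n, m, p))
    mask = np.ones((n, m, p), dtype=bool)
    obj_pos = {o: i for i, o in enumerate(objects)}
    ctx_pos = {c: k for k, c in enumerate(contexts)}
    for _, row in df.iterrows():
        i, k = obj_pos[row["object"]], ctx_pos[row["context"]]
        for j, feat in enumerate(features):
            raw = row[feat.name]
            if pd.isna(raw):
                continue
            values[i, j, k] = _encode(feat, raw)
            mask[i, j, k] = False
    return ThreeWayDataset(objects, features, contexts, values, mask)


def write_three_way(ds: ThreeWayDataset, records_path, manifest_path) -> None:
    """Write a dataset back to long-format CSV + YAML manifest (round-trip safe)."""
    rows = []
    for i, obj in enumerate(ds.objects):
        for k, ctx in enumerate(ds.contexts):
            if ds.missing_mask[i, :, k].all():
                continue
            row = {"object": obj, "context": ctx}
            for j, feat in enumerate(ds.features):
                if ds.missing_mask[i, j, k]:
                    row[feat.name] = np.nan
                elif feat.kind == "categorical":
                    row[feat.name] = feat.categories[int(ds.values[i, j, k])]
                else:
                    row[feat.name] = ds.values[i, j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(records_path, index=False)
    manifest = {}
    for feat in ds.features:
        if feat.kind == "categorical":
            manifest[feat.name] = {"kind": feat.kind, "categories": list(feat.categories)}
        else:
            manifest[feat.name] = feat.kind
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def impute_locf(series: Sequence, fallback=None) -> list:
    """Last-observation-carried-forward imputation of one time-ordered sequence.

    Each missing entry (None or NaN) takes the nearest earlier non-missing
    value; leading missings take ``fallback`` (the training-set mean or mode
    of the feature).  Idempotent.

    Raises
    ------
    ValueError
        If the sequence starts missing and no fallback is given, or the
        sequence is missing everywhere and no fallback is given.
    """

    def _is_missing(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    out = []
    last = None
    for v in series:
        if _is_missing(v):
            if last is not None:
                out.append(last)
            elif fallback is not None and not _is_missing(fallback):
                out.append(fallback)
                last = fallback
            else:
                raise ValueError("leading missing value with no fallback statistic")
        else:
            out.append(v)
            last = v
    return out


def locf_frame(df: pd.DataFrame, fallbacks: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Column-wise LOCF over a time-ordered frame (rows = successive snapshots).

    ``fallbacks`` supplies the per-feature statistic (mean/mode fitted on
    training data) used for leading missings; a column missing everywhere
    with no fallback is a hard error.
    """
    fallbacks = fallbacks or {}
    out = df.copy()
    for col in out.columns:
        fb = fallbacks.get(col)
        if fb is None and out[col].isna().all():
            raise ValueError(f"feature {col!r} missing everywhere and no fallback given")
        out[col] = impute_locf(out[col].tolist(), fb)
    return out
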