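"""The subjects-by-features table that every pipeline stage exchanges.

A :class:`FeatureTable` holds one imaging modality's region-of-interest
features (gray-matter volumes, SUVR values, FA/MD, ...) for a cohort of
subjects, together with the binary diagnosis label (CN = 0, AD = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

CN, AD = 0, 1
LABEL_NAMES = {CN: "CN", AD: "AD"}


@dataclass(frozen=True)
class FeatureTable:
    """Immutable subjects × named-features matrix with binary labels.

    Attributes
    ----------
    subject_ids : unique subject identifiers, one per row
    labels : 0/1 diagnosis per subject (CN = 0, AD = 1); both classes present
    feature_names : unique feature (ROI metric) names, one per column
    values : float matrix, shape ``(n_subjects, n_features)``, no missing
    """

    subject_ids: tuple[str, ...]
    labels: np.ndarray
    feature_names: tuple[str, ...]
    values: np.ndarray
    require_both_classes: bool = field(default=True, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        labels = np.asarray(self.labels, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, p = values.shape
        if len(self.subject_ids) != n or labels.shape != (n,):
            raise DataError("subject_ids, labels and values row count must agree")
        if len(self.feature_names) != p:
            raise DataError("feature_names and values column count must agree")
        if len(set(self.subject_ids)) != n:
            dup = _first_duplicate(self.subject_ids)
            raise DataError(f"duplicate subject id: {dup!r}")
        if len(set(self.feature_names)) != p:
            dup = _first_duplicate(self.feature_names)
            raise DataError(f"duplicate feature name: {dup!r}")
        if not np.isfinite(values).all():
            raise DataError("values contain missing or non-finite entries")
        if not np.isin(labels, (CN, AD)).all():
            raise DataError("labels must be 0 (CN) or 1 (AD)")
        if self.require_both_classes and len(np.unique(labels)) < 2:
            raise DataError("both diagnostic classes must be present")
        labels.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    # -- shape ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    # -- subsetting ----------------------------------------------------
    def select_features(self, names) -> "FeatureTable":
        """Column subset (reordered to ``names``); unknown name is an error."""
        names = list(names)
        pos = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise DataError(f"unknown feature(s): {missing}")
        cols = [pos[f] for f in names]
        return FeatureTable(
            self.subject_ids,
            self.labels,
            tuple(names),
            self.values[:, cols],
            require_both_classes=self.require_both_classes,
        )

    def take_subjects(self, index) -> "FeatureTable":
        """Row subset by positional index array."""
        index = np.asarray(index, dtype=np.int64)
        ids = tuple(self.subject_ids[i] for i in index)
        return FeatureTable(
            ids,
            self.labels[index],
            self.feature_names,
            self.values[index],
            require_both_classes=self.require_both_classes,
        )

    def take_subject_ids(self, ids) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise DataError(f"unknown subject id(s): {missing[:5]}")
        return self.take_subjects([pos[s] for s in ids])

    # -- pandas bridge -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Subject id as index, ``label`` first column, features after."""
        df = pd.DataFrame(self.values, columns=list(self.feature_names),
                          index=pd.Index(self.subject_ids, name="subject_id"))
        df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, require_both_classes: bool = True) -> "FeatureTable":
        if "label" not in df.columns:
            raise DataError("missing 'label' column")
        labels = df["label"].to_numpy()
        feats = [c for c in df.columns if c != "label"]
        return cls(tuple(df.index.astype(str)), labels, tuple(feats),
                   df[feats].to_numpy(dtype=np.float64),
                   require_both_classes=require_both_classes)


def _first_duplicate(seq) -> str:
    seen = set()
    for x in seq:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover


def join_subjects(tables: dict[str, FeatureTable]) -> list[str]:
    """Ordered inner join of subject ids across modality tables.

    Order follows the first table; labels must agree for shared subjects.
    """
    if not tables:
        raise DataError("no tables to join")
    names = list(tables)
    common = set(tables[names[0]].subject_ids)
    for m in names[1:]:
        common &= set(tables[m].subject_ids)
    joined = [s for s in tables[names[0]].subject_ids if s in common]
    if not joined:
        raise DataError("empty subject intersection across modalities")
    ref = tables[names[0]]
    ref_lab = {s: l for s, l in zip(ref.subject_ids, ref.labels)}
    for m in names[1:]:
        t = tables[m]
        for s, l in zip(t.subject_ids, t.labels):
            if s in common and ref_lab[s] != l:
                raise DataError(f"label mismatch for subject {s!r} between modalities")
    return joined
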