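"""Readers and writers for feature tables, configs and result artifacts.

Table dialect: CSV with a header row, UTF-8, "." decimal separator.
First column is the subject identifier, second the diagnosis label
(``CN``/``AD`` or ``0``/``1``), remaining columns are numeric features.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import AggregateMetrics
from .errors import DataError
from .tables import FeatureTable

log = logging.getLogger("roifuse")

_LABEL_MAP = {"CN": 0, "AD": 1, "0": 0, "1": 1, 0: 0, 1: 1}


def read_feature_table(path, *, require_both_classes: bool = True) -> FeatureTable:
    """Read a modality feature table from CSV (dialect above)."""
    path = Path(path)
    # check the raw header before pandas de-duplicates repeated names
    import csv
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    seen = set()
    for c in header:
        if c in seen:
            raise DataError(f"{path}: duplicated column header {c!r}")
        seen.add(c)
    df = pd.read_csv(path, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a subject id column, a label column "
                        "and at least one feature column")
    cols = list(df.columns)
    id_col, label_col = cols[0], cols[1]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate subject id {dup!r}")
    raw_labels = df[label_col]
    labels = []
    for v in raw_labels:
        key = v.strip() if isinstance(v, str) else v
        if key not in _LABEL_MAP:
            raise DataError(f"{path}: unparseable label {v!r} "
                            "(expected CN/AD or 0/1)")
        labels.append(_LABEL_MAP[key])
    if raw_labels.dtype == object:
        log.info("%s: parsed string labels with mapping CN->0, AD->1", path)
    feat = df[cols[2:]]
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feat.notna()
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy() | bad.to_numpy())[0]
        raise DataError(f"{path}: non-numeric or missing value in column "
                        f"{cols[2 + c]!r}, row {r + 2}")
    return FeatureTable(tuple(ids), np.asarray(labels), tuple(cols[2:]),
                        numeric.to_numpy(dtype=np.float64),
                        require_both_classes=require_both_classes)


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    df["label"] = np.where(df["label"] == 1, "AD", "CN")
    df.to_csv(path, index=True)


def write_cohort(tables: dict[str, FeatureTable], out_dir, config,
                 prefix: str = "cohort") -> list[Path]:
    """Write one CSV per modality plus a JSON sidecar with the full config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{prefix}_{name}.csv"
        write_feature_table(table, p)
        paths.append(p)
    sidecar = out_dir / f"{prefix}_config.json"
    write_json(config.to_dict(), sidecar)
    paths.append(sidecar)
    return paths


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_metrics_csv(aggregate: AggregateMetrics, path) -> None:
    rows = [{"metric": k, "mean": aggregate.mean[k], "std": aggregate.std[k]}
            for k in aggregate.mean]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_roc_csv(aggregate: AggregateMetrics, path) -> None:
    pd.DataFrame({
        "fpr": aggregate.fpr_grid,
        "mean_tpr": aggregate.mean_tpr,
        "std_tpr": aggregate.std_tpr,
    }).to_csv(path, index=False)


def combination_report_frame(singles: dict, combos: dict) -> pd.DataFrame:
    """Tabulate single-modality baselines and fused combinations."""
    rows = []
    for name, res in singles.items():
        rows.append(_report_row(name, res))
    for subset, res in combos.items():
        rows.append(_report_row("+".join(subset), res))
    return pd.DataFrame(rows)


def _report_row(label: str, res) -> dict:
    m = res.metrics
    return {
        "modalities": label,
        "n_subjects": len(res.subject_ids),
        "accuracy": m["accuracy"],
        "sensitivity": m["sensitivity"],
        "specificity": m["specificity"],
        "balanced_accuracy": m["balanced_accuracy"],
        "auc": res.auc,
    }


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataError(f"{path}: config must be a YAML mapping")
    return data
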