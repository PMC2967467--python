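"""Plain-text I/O: matrix TSVs, cohort manifests, metrics tables,
key-value run manifests and YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sl import SyncMatrix
from .synthetic import RegionalTimeSeries

__all__ = [
    "write_subject_tsv", "read_subject_tsv",
    "write_sync_matrix", "read_sync_matrix",
    "write_manifest_tsv", "read_manifest_tsv",
    "write_keyvalue", "read_keyvalue",
    "load_yaml_config",
]


def write_subject_tsv(subject: RegionalTimeSeries, path) -> None:
    """Regions x timepoints matrix TSV with region labels as row names."""
    labels = subject.region_labels or [
        f"region_{k:03d}" for k in range(subject.n_regions)]
    df = pd.DataFrame(subject.values, index=list(labels))
    df.to_csv(path, sep="\t", header=False, float_format="%.10g")


def read_subject_tsv(path, subject_id: str, group: str,
                     tr_seconds: float = 2.85) -> RegionalTimeSeries:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return RegionalTimeSeries(subject_id=subject_id, group=group,
                              values=df.to_numpy(dtype=float),
                              tr_seconds=tr_seconds,
                              region_labels=tuple(df.index.astype(str)))


def write_sync_matrix(matrix: SyncMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.region_labels),
                      columns=list(matrix.region_labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_sync_matrix(path) -> SyncMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SyncMatrix(values=df.to_numpy(dtype=float),
                      region_labels=tuple(df.index.astype(str)))


def write_manifest_tsv(subjects, path) -> None:
    pd.DataFrame({"subject_id": [s.subject_id for s in subjects],
                  "group": [s.group for s in subjects]}
                 ).to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_keyvalue(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def read_keyvalue(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            k, _, v = line.partition("\t")
            out[k] = v
    return out


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
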