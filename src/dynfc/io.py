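"""Plain-text readers and writers.

Cohorts are exchanged as one delimited matrix per subject (rows =
components, columns = time points; tab or comma delimited), a labels CSV
(``subject_id,label`` with labels in {GAD, NC} or {+1, -1}), and an
optional ground-truth JSON.  Motion parameters use the whitespace-
delimited 6-column SPM ``rp_*.txt`` dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ComponentTimeSeriesSet
from .errors import InvalidInputError
from .synthetic import GroundTruth

__all__ = [
    "read_timeseries_matrix",
    "read_motion_params",
    "read_labels",
    "write_cohort",
    "read_cohort",
]

_LABEL_MAP = {"GAD": 1, "NC": -1, "1": 1, "-1": -1, "+1": 1}


def read_timeseries_matrix(path: str | Path) -> np.ndarray:
    """Read one subject's components x time matrix from delimited text.

    Tab and comma dialects are sniffed; ragged rows and non-finite cells
    are rejected with their location.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            cells = [c for c in line.split(sep) if c != ""]
            if rows and len(cells) != len(rows[0]):
                raise InvalidInputError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(cells)} cells, expected {len(rows[0])})"
                )
            rows.append(cells)
    if not rows:
        raise InvalidInputError(f"{path}: empty file")
    start = 0
    try:
        [float(c) for c in rows[0]]
    except ValueError:
        start = 1  # header row
    try:
        mat = np.array([[float(c) for c in row] for row in rows[start:]], dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric cell ({exc})") from exc
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        r, c = bad[0]
        raise InvalidInputError(
            f"{path}: non-finite value at row {r + 1 + start}, column {c + 1}"
        )
    return mat


def read_motion_params(path: str | Path) -> np.ndarray:
    """Whitespace-delimited 6-column rigid-motion parameter file."""
    mat = np.loadtxt(path, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 6:
        raise InvalidInputError(f"{path}: expected 6 columns of motion parameters")
    if not np.all(np.isfinite(mat)):
        raise InvalidInputError(f"{path}: non-finite motion parameters")
    return mat


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Labels CSV ``subject_id,label``; labels GAD/NC map to +1/-1."""
    df = pd.read_csv(path, dtype=str)
    if not {"subject_id", "label"} <= set(df.columns):
        raise InvalidInputError(f"{path}: need columns subject_id,label")
    labels = []
    for v in df["label"].str.strip():
        if v not in _LABEL_MAP:
            raise InvalidInputError(f"{path}: unknown label {v!r}")
        labels.append(_LABEL_MAP[v])
    return df["subject_id"].tolist(), np.array(labels, dtype=int)


def write_cohort(
    tsset: ComponentTimeSeriesSet,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
) -> None:
    """One TSV per subject + labels.csv (+ ground_truth.json if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(tsset.subject_ids):
        np.savetxt(out / f"{sid}.tsv", tsset.data[s], delimiter="\t", fmt="%.10g")
    pd.DataFrame({
        "subject_id": tsset.subject_ids,
        "label": ["GAD" if v == 1 else "NC" for v in tsset.labels],
    }).to_csv(out / "labels.csv", index=False)
    meta = {"tr": tsset.tr, "networks": tsset.networks,
            "component_names": tsset.component_names}
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        gt = {
            "planted_pairs": [list(p) for p in truth.planted_pairs],
            "disease_components": list(truth.disease_components),
            "h_by_group": {str(k): v.tolist() for k, v in truth.h_by_group.items()},
            "var_by_group": {str(k): v.tolist() for k, v in truth.var_by_group.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def read_cohort(in_dir: str | Path) -> ComponentTimeSeriesSet:
    """Read a cohort written by :func:`write_cohort` (or hand-assembled in
    the same layout)."""
    in_dir = Path(in_dir)
    subject_ids, labels = read_labels(in_dir / "labels.csv")
    mats = [read_timeseries_matrix(in_dir / f"{sid}.tsv") for sid in subject_ids]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise InvalidInputError(f"inconsistent matrix shapes across subjects: {shapes}")
    meta_path = in_dir / "meta.json"
    tr, networks, names = 3.0, [], []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        tr = float(meta.get("tr", 3.0))
        networks = meta.get("networks", [])
        names = meta.get("component_names", [])
    return ComponentTimeSeriesSet(
        data=np.stack(mats), labels=labels, tr=tr,
        subject_ids=subject_ids, component_names=names, networks=networks,
    )
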