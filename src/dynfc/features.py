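"""Subject x feature table assembly.

Three feature types per component pair: the corrected Hurst exponent and
the unbiased variance of the pair's dynamic (phase-synchronization) FC
series, and the Fisher-z static FC.  For 44 components that is
3 x C(44, 2) = 2838 features.  Ordering is deterministic: type-major
(hurst, variance, static_fc), then pair index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DynFCTensor, StaticFCMatrix
from .errors import EstimationError, InvalidInputError
from .hurst import _hurst_batch, default_window_grid

__all__ = ["FeatureTable", "build_feature_table", "FEATURE_TYPES"]

FEATURE_TYPES = ("hurst", "variance", "static_fc")
_TYPE_PREFIX = {"hurst": "hurst", "variance": "var", "static_fc": "sfc"}


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-feature descriptors.

    ``info`` has one row per feature: ``feature_id`` (e.g. ``hurst__12_37``),
    ``ftype``, ``pair_id``, ``comp_i``, ``comp_j``.
    """

    values: np.ndarray
    info: pd.DataFrame
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.info):
            raise InvalidInputError("values/info shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("feature table contains non-finite values")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def types(self) -> list[str]:
        seen: list[str] = []
        for t in self.info["ftype"]:
            if t not in seen:
                seen.append(t)
        return seen

    def type_indices(self, ftype: str) -> np.ndarray:
        """Column indices of one feature type, in table order."""
        idx = np.flatnonzero((self.info["ftype"] == ftype).to_numpy())
        if idx.size == 0:
            raise InvalidInputError(f"no features of type {ftype!r}")
        return idx

    def pairs_of(self, ftype: str) -> np.ndarray:
        idx = self.type_indices(ftype)
        return self.info.iloc[idx][["comp_i", "comp_j"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.info["feature_id"])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        subject_ids = df["subject_id"].astype(str).tolist()
        labels = df["label"].to_numpy(dtype=int)
        feat = df.drop(columns=["subject_id", "label"])
        info = _info_from_ids(list(feat.columns))
        return cls(values=feat.to_numpy(dtype=float), info=info,
                   labels=labels, subject_ids=subject_ids)


def _info_from_ids(feature_ids: list[str]) -> pd.DataFrame:
    rev = {v: k for k, v in _TYPE_PREFIX.items()}
    rows = []
    for fid in feature_ids:
        prefix, rest = fid.split("__")
        i, j = (int(v) for v in rest.split("_"))
        rows.append((fid, rev[prefix], i, j))
    info = pd.DataFrame(rows, columns=["feature_id", "ftype", "comp_i", "comp_j"])
    info["pair_id"] = _pair_ids(info[["comp_i", "comp_j"]].to_numpy())
    return info


def _pair_ids(pairs: np.ndarray) -> np.ndarray:
    # rank of (i, j) in i-major upper-triangular order, recomputed from i, j
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    ids = np.empty(len(pairs), dtype=int)
    ids[order] = np.arange(len(pairs))
    return ids


def build_feature_table(
    dynfc: DynFCTensor,
    static: StaticFCMatrix | None = None,
    window_grid: np.ndarray | None = None,
) -> FeatureTable:
    """Hurst + variance of every dynamic FC series (plus static z if given).

    Any (subject, pair) whose Hurst regression fails is a hard error
    listing the offenders; a finished table never carries missing values.
    """
    s, p, t = dynfc.data.shape
    if window_grid is None:
        window_grid = default_window_grid(t)
    flat = dynfc.data.reshape(s * p, t)
    h, _, _ = _hurst_batch(flat, np.asarray(window_grid, dtype=int))
    if np.any(~np.isfinite(h)):
        bad = np.argwhere(~np.isfinite(h.reshape(s, p)))
        listing = ", ".join(
            f"(subject {dynfc.subject_ids[i]}, pair {tuple(dynfc.pairs[j])})"
            for i, j in bad[:10]
        )
        raise EstimationError(
            f"Hurst estimation failed for {len(bad)} series: {listing}"
            + (" ..." if len(bad) > 10 else "")
        )
    hmat = h.reshape(s, p)
    vmat = dynfc.data.var(axis=-1, ddof=1)

    blocks = [hmat, vmat]
    types = ["hurst", "variance"]
    pair_sets = [dynfc.pairs, dynfc.pairs]
    if static is not None:
        if static.values.shape != (s, p) or not np.array_equal(static.pairs, dynfc.pairs):
            raise InvalidInputError("static FC inconsistent with dynamic FC tensor")
        blocks.append(static.values)
        types.append("static_fc")
        pair_sets.append(static.pairs)

    values = np.hstack(blocks)
    rows = []
    for ftype, pairs in zip(types, pair_sets):
        prefix = _TYPE_PREFIX[ftype]
        for pid, (i, j) in enumerate(pairs):
            rows.append((f"{prefix}__{i}_{j}", ftype, int(i), int(j), pid))
    info = pd.DataFrame(rows, columns=["feature_id", "ftype", "comp_i", "comp_j", "pair_id"])
    return FeatureTable(
        values=values, info=info, labels=dynfc.labels,
        subject_ids=list(dynfc.subject_ids),
    )
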