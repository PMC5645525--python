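"""Hilbert-phase dynamic functional connectivity and Fisher-z static FC.

Each post-processed component signal is Hilbert transformed; the dynamic
connectivity of a component pair is the normalized magnitude of their
instantaneous phase difference,

    d(t) = |wrap(phi_i(t) - phi_j(t))| / pi  in [0, 1],

with 0 meaning perfect synchronization and 1 perfect anti-synchronization.
The linear map in |delta phi| is the simplest one satisfying those two
endpoint semantics; an alternative (1 - cos delta phi)/2 would satisfy
them too but is not the shipped default.  Static FC is the Fisher-z
transformed Pearson correlation of the full-length signals.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .cohort import ComponentTimeSeriesSet, DynFCTensor, StaticFCMatrix, component_pairs
from .errors import DegenerateSeriesError, InvalidInputError

__all__ = ["analytic_phase", "phase_sync_series", "dynamic_fc_tensor", "static_fc"]


def analytic_phase(series: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of the analytic signal.

    The series is demeaned internally before the Hilbert transform; an
    all-zero (or all-constant) series has no defined phase.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 16:
        raise InvalidInputError("need at least 16 samples for a meaningful phase")
    x = series - series.mean(axis=-1, keepdims=True)
    if np.any(np.all(x == 0.0, axis=-1)):
        raise DegenerateSeriesError("constant series has undefined instantaneous phase")
    return np.angle(hilbert(x, axis=-1))


def phase_sync_series(phase1: np.ndarray, phase2: np.ndarray) -> np.ndarray:
    """Normalized instantaneous phase difference of two phase series.

    ``d(t) = |wrap(phi1 - phi2)| / pi``: 0 iff identical phase, 1 iff
    anti-phase; symmetric in argument order and invariant to adding a
    common constant to both phases.
    """
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise InvalidInputError("phase series must have equal length")
    delta = phase1 - phase2
    wrapped = np.mod(delta + np.pi, 2.0 * np.pi) - np.pi
    return np.abs(wrapped) / np.pi


def dynamic_fc_tensor(tsset: ComponentTimeSeriesSet, trim: int = 0) -> DynFCTensor:
    """Phase-synchronization series for every unordered component pair.

    44 components give C(44, 2) = 946 pair series per subject.  ``trim``
    symmetrically removes edge samples after computation (Hilbert edge
    effects); the default keeps the full series.
    """
    phases = analytic_phase(tsset.data)  # (S, C, T)
    pairs = component_pairs(tsset.n_components)
    i, j = pairs[:, 0], pairs[:, 1]
    d = phase_sync_series(phases[:, i, :], phases[:, j, :])
    if trim < 0 or 2 * trim >= d.shape[-1]:
        raise InvalidInputError(f"invalid trim {trim} for length {d.shape[-1]}")
    if trim:
        d = d[..., trim:-trim]
    return DynFCTensor(
        data=d,
        pairs=pairs,
        labels=tsset.labels,
        tr=tsset.tr,
        subject_ids=list(tsset.subject_ids),
        trim=trim,
    )


def static_fc(tsset: ComponentTimeSeriesSet) -> StaticFCMatrix:
    """Fisher-z transformed Pearson correlation for every component pair.

    ``z = atanh(r)`` with ``|r|`` clipped below 1 so perfectly collinear
    signals stay finite.
    """
    pairs = component_pairs(tsset.n_components)
    sd = tsset.data.std(axis=-1)
    if np.any(sd == 0.0):
        s, c = np.argwhere(sd == 0.0)[0]
        raise DegenerateSeriesError(
            f"zero-variance component {tsset.component_names[c]} "
            f"(subject {tsset.subject_ids[s]}): correlation undefined"
        )
    z = np.empty((tsset.n_subjects, pairs.shape[0]))
    iu = (pairs[:, 0], pairs[:, 1])
    for s in range(tsset.n_subjects):
        r = np.corrcoef(tsset.data[s])[iu]
        z[s] = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    return StaticFCMatrix(
        values=z, pairs=pairs, labels=tsset.labels, subject_ids=list(tsset.subject_ids)
    )
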