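"""In-memory containers for component time courses and derived tensors.

The central object is :class:`ComponentTimeSeriesSet`: a cohort of
per-subject matrices of ICA component time courses (components x time),
with diagnostic labels (+1 patient / -1 control), the repetition time of
the acquisition, and component/network annotations.  Downstream stages
(:mod:`dynfc.phase`, :mod:`dynfc.features`) consume and produce the
pair-indexed tensors defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: The eight intrinsic connectivity networks used for component annotation:
#: auditory, basal ganglia, sensorimotor, posterior insula, visual,
#: cognitive control, cerebellar, default mode.
NETWORKS = ("AUD", "BG", "SM", "PINS", "VIS", "CC", "CB", "DM")

#: Number of components per network in the default 44-component annotation.
#: The split is a plausible stand-in (the source atlas is not deposited);
#: it only matters for labelling, never for computation.
_DEFAULT_NETWORK_SIZES = {
    "AUD": 2, "BG": 3, "SM": 6, "PINS": 2,
    "VIS": 6, "CC": 13, "CB": 4, "DM": 8,
}


def default_networks(n_components: int = 44) -> list[str]:
    """Per-component network labels for the default annotation.

    For 44 components the split follows ``_DEFAULT_NETWORK_SIZES``;
    other sizes are labelled round-robin.
    """
    if n_components == sum(_DEFAULT_NETWORK_SIZES.values()):
        out: list[str] = []
        for net in NETWORKS:
            out.extend([net] * _DEFAULT_NETWORK_SIZES[net])
        return out
    return [NETWORKS[i % len(NETWORKS)] for i in range(n_components)]


def component_pairs(n_components: int) -> np.ndarray:
    """All unordered component pairs (i < j), i-major order, shape (P, 2)."""
    iu = np.triu_indices(n_components, k=1)
    return np.column_stack(iu)


@dataclass
class ComponentTimeSeriesSet:
    """Cohort of per-subject component-by-time matrices.

    Attributes
    ----------
    data : ndarray, shape (n_subjects, n_components, n_timepoints)
    labels : ndarray of +1 (patient) / -1 (control), shape (n_subjects,)
    subject_ids : list of str
    tr : float
        Sampling interval in seconds.
    component_names, networks : per-component annotation.
    """

    data: np.ndarray
    labels: np.ndarray
    tr: float
    subject_ids: list[str] = field(default_factory=list)
    component_names: list[str] = field(default_factory=list)
    networks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"data must be (subjects, components, time); got shape {self.data.shape}"
            )
        n_sub, n_comp, _ = self.data.shape
        if self.labels.shape != (n_sub,):
            raise InvalidInputError("one label per subject required")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise InvalidInputError("labels must be +1 (patient) or -1 (control)")
        if not self.tr > 0:
            raise InvalidInputError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("non-finite values in component time courses")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(n_sub)]
        if not self.component_names:
            self.component_names = [f"IC{i + 1:02d}" for i in range(n_comp)]
        if not self.networks:
            self.networks = default_networks(n_comp)
        if len(self.subject_ids) != n_sub:
            raise InvalidInputError("subject_ids length mismatch")
        if len(self.component_names) != n_comp or len(self.networks) != n_comp:
            raise InvalidInputError("component annotation length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class DynFCTensor:
    """Per-subject, per-pair phase-synchronization time series in [0, 1].

    ``data[s, p, t]`` is the normalized instantaneous phase difference of
    pair ``pairs[p]`` for subject ``s``: 0 = perfect synchronization,
    1 = perfect anti-synchronization.
    """

    data: np.ndarray  # (n_subjects, n_pairs, n_time_eff)
    pairs: np.ndarray  # (n_pairs, 2), i < j
    labels: np.ndarray
    tr: float
    subject_ids: list[str] = field(default_factory=list)
    trim: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.data.ndim != 3 or self.pairs.shape != (self.data.shape[1], 2):
            raise InvalidInputError("inconsistent dynamic FC tensor shapes")
        if self.data.size and (self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12):
            raise InvalidInputError("phase-synchronization values must lie in [0, 1]")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]


@dataclass
class StaticFCMatrix:
    """Fisher-z-transformed Pearson correlation per subject and pair."""

    values: np.ndarray  # (n_subjects, n_pairs)
    pairs: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.values.ndim != 2 or self.pairs.shape != (self.values.shape[1], 2):
            raise InvalidInputError("inconsistent static FC shapes")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("non-finite static FC values")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(self.values.shape[0])]
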