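"""Activation-pattern interpretation of fold-wise classifier weights.

Linear classifier weights are not interpretable feature-wise: a feature
statistically independent of the labels can carry a large weight if it
suppresses noise shared with informative features.  The generative-
direction transform

    A = cov(X) . W / var(S)

(X the training feature matrix actually fed to the classifier, W its
weights, S the +/-1 training labels) converts the weight vector into an
activation pattern whose entries carry the effect direction and strength
of the label in each feature.  Per LOOCV fold the activation of every
selected feature is computed (unselected features set to zero); the
elementwise mean of |A| across folds is each feature's *standard
activation value*.  A component's activation is the sum of standard
activation values over its incident features; components at or above
mean + 2 SD of all component values are flagged important.  Features
selected in every fold are *consensus connections*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import CVResult
from .errors import InvalidInputError
from .features import FeatureTable

__all__ = [
    "fold_activation",
    "activation_patterns",
    "standard_activation",
    "component_importance",
    "consensus_connections",
    "analyze_activation",
    "ActivationResult",
]


def fold_activation(
    x_train: np.ndarray,
    labels_train: np.ndarray,
    weights: np.ndarray,
    selected: np.ndarray | None = None,
    n_features: int | None = None,
) -> np.ndarray:
    """Activation pattern of one fold: ``cov(X) . W / var(S)``.

    ``x_train`` holds only the selected columns (the matrix the classifier
    saw, i.e. z-scored where applicable); ``weights`` aligns with its
    columns.  If ``selected``/``n_features`` are given the result is
    scattered into a full-length vector with zeros at unselected indices.
    Sample (n-1) covariances throughout.
    """
    x_train = np.asarray(x_train, dtype=float)
    labels_train = np.asarray(labels_train, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x_train.shape[1] != weights.size:
        raise InvalidInputError("one weight per selected feature required")
    var_s = labels_train.var(ddof=1)
    if var_s == 0.0:
        raise InvalidInputError("single-class fold: var(S) = 0, activation undefined")
    xc = x_train - x_train.mean(axis=0)
    a_sel = (xc.T @ xc) @ weights / (len(labels_train) - 1) / var_s
    if selected is None:
        return a_sel
    if n_features is None:
        raise InvalidInputError("n_features required when scattering")
    a = np.zeros(n_features)
    a[np.asarray(selected, dtype=int)] = a_sel
    return a


def activation_patterns(table: FeatureTable, cv: CVResult) -> np.ndarray:
    """Per-fold full-length activation patterns, shape (n_folds, n_features).

    Each fold's z-scored training matrix is rebuilt from the stored
    selection and normalization statistics, so A lives in the model's
    input space.
    """
    n = table.n_subjects
    patterns = np.empty((len(cv.folds), table.n_features))
    for f, fold in enumerate(cv.folds):
        train = np.delete(np.arange(n), fold.test_index)
        x = table.values[np.ix_(train, fold.selected_union)].copy()
        x = (x - fold.train_mean) / fold.train_sd
        patterns[f] = fold_activation(
            x, cv.labels[train], fold.weights,
            selected=fold.selected_union, n_features=table.n_features,
        )
    return patterns


def standard_activation(patterns: np.ndarray) -> np.ndarray:
    """Elementwise mean of |A| across folds (zeros of unselected folds included)."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] < 1:
        raise InvalidInputError("at least one fold required")
    return np.abs(patterns).mean(axis=0)


def component_importance(
    feature_values: np.ndarray,
    pairs: np.ndarray,
    n_components: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum feature activations onto incident components; flag outliers.

    Returns (component_values, important_component_indices).  A component
    is important iff its value >= mean + 2 SD (n-1 denominator) over all
    components; a flat profile (SD = 0) flags none, with a warning.
    """
    feature_values = np.asarray(feature_values, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.shape != (feature_values.size, 2):
        raise InvalidInputError("one component pair per feature required")
    comp = np.zeros(n_components)
    np.add.at(comp, pairs[:, 0], feature_values)
    np.add.at(comp, pairs[:, 1], feature_values)
    sd = comp.std(ddof=1)
    if sd == 0.0:
        warnings.warn("flat component activation profile: no important components",
                      stacklevel=2)
        return comp, np.array([], dtype=int)
    threshold = comp.mean() + 2.0 * sd
    return comp, np.flatnonzero(comp >= threshold)


def consensus_connections(cv: CVResult) -> dict[str, np.ndarray]:
    """Per feature type, the features selected in every LOOCV fold."""
    if not cv.folds:
        raise InvalidInputError("at least one fold required")
    out: dict[str, np.ndarray] = {}
    for ftype in cv.folds[0].selected:
        sets = [set(fold.selected[ftype].tolist()) for fold in cv.folds]
        out[ftype] = np.array(sorted(set.intersection(*sets)), dtype=int)
    return out


@dataclass
class ActivationResult:
    """Aggregate activation analysis of one cross-validated model."""

    standard_values: np.ndarray            # per feature, mean |A| over folds
    signed_mean: np.ndarray                # per feature, mean A over folds
    component_values: dict[str, np.ndarray]      # per type
    important_components: dict[str, np.ndarray]  # per type
    consensus: dict[str, np.ndarray]             # per type, feature indices
    group_diff_sign: np.ndarray = field(default=None)  # sign of patient-control mean diff


def analyze_activation(table: FeatureTable, cv: CVResult) -> ActivationResult:
    """Full activation analysis: standard values, per-component importance
    per feature type, consensus connections, and both effect-sign exports
    (signed mean activation, and the sign of the patient-minus-control
    group mean difference of each raw feature)."""
    patterns = activation_patterns(table, cv)
    std_vals = standard_activation(patterns)
    signed = patterns.mean(axis=0)
    n_components = int(table.info[["comp_i", "comp_j"]].to_numpy().max()) + 1
    comp_values: dict[str, np.ndarray] = {}
    important: dict[str, np.ndarray] = {}
    for ftype in cv.folds[0].selected:
        idx = table.type_indices(ftype)
        comp, imp = component_importance(std_vals[idx], table.pairs_of(ftype), n_components)
        comp_values[ftype] = comp
        important[ftype] = imp
    diff = (table.values[table.labels == 1].mean(axis=0)
            - table.values[table.labels == -1].mean(axis=0))
    return ActivationResult(
        standard_values=std_vals,
        signed_mean=signed,
        component_values=comp_values,
        important_components=important,
        consensus=consensus_connections(cv),
        group_diff_sign=np.sign(diff),
    )
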