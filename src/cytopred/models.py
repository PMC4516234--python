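"""Classifiers and similarity functions for mixed clinical/cytokine data.

Three classifier contracts are provided: a random forest on the raw
(imputed) feature matrix, a soft-margin SVM on a precomputed Gram matrix,
and a 1-nearest-neighbour rule driven by the same kernel. The kernel
combines a cosine-normalised linear part on standardised cytokine features
with a *clinical kernel* for mixed-type clinical variables: per variable,
continuous/ordinal similarity is (r - |x - z|)/r on the training range r,
binary/nominal similarity is the equality indicator, and the kernel is the
unweighted mean over variables. Performance is summarised by the Balanced
Classification Rate, (sensitivity + specificity)/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .cohort import VariableSpec

logger = logging.getLogger(__name__)

CLASSIFIERS = ("random_forest", "svm", "one_nn")


class DegenerateTrainingError(ValueError):
    """Raised when the training labels contain a single class."""


class UndefinedBCRError(ValueError):
    """Raised when a truth class is absent from the test fold."""


# ---------------------------------------------------------------------------
# metric


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()), fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()), fp=int(((t == 0) & (p == 1)).sum()))


def bcr(counts: ConfusionCounts) -> float:
    """Balanced Classification Rate = (Se + Sp)/2."""
    pos, neg = counts.tp + counts.fn, counts.tn + counts.fp
    if pos < 1 or neg < 1:
        raise UndefinedBCRError("a truth class is absent from the test fold")
    se = counts.tp / pos
    sp = counts.tn / neg
    return (se + sp) / 2


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class KernelSpec:
    """Which kernel parts are active and how they are combined.

    ``combination`` is ``average`` (arithmetic mean of the active parts),
    ``cytokine_only`` or ``clinical_only``.
    """

    combination: str = "average"

    def __post_init__(self):
        if self.combination not in ("average", "cytokine_only", "clinical_only"):
            raise ValueError(f"unknown combination {self.combination!r}")


@dataclass
class KernelRanges:
    """Training-fold statistics the kernels depend on."""

    cyto_mean: np.ndarray | None = None
    cyto_sd: np.ndarray | None = None
    clin_min: np.ndarray | None = None
    clin_max: np.ndarray | None = None
    clin_vtypes: tuple = ()


def clinical_kernel_matrix(A: np.ndarray, B: np.ndarray, vtypes: Sequence[str],
                           lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mean per-variable clinical similarity between rows of A and rows of B.

    ``lo``/``hi`` are per-variable training minima/maxima. Continuous and
    ordinal variables contribute (r - |x - z|)/r clipped to [0,1] (1 when
    r = 0); binary/nominal contribute the equality indicator.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("clinical kernel requires complete (imputed) data")
    n, m = A.shape[0], B.shape[0]
    K = np.zeros((n, m))
    for j, vt in enumerate(vtypes):
        a, b = A[:, j][:, None], B[:, j][None, :]
        if vt in ("continuous", "ordinal"):
            r = hi[j] - lo[j]
            if r <= 0:
                K += 1.0
            else:
                K += np.clip((r - np.abs(a - b)) / r, 0.0, 1.0)
        else:
            K += (a == b).astype(float)
    return K / len(vtypes)


def clinical_kernel_value(x, z, vtypes, lo, hi) -> float:
    """Scalar clinical-kernel similarity between two profiles."""
    return float(clinical_kernel_matrix(np.atleast_2d(x), np.atleast_2d(z),
                                        vtypes, np.asarray(lo, float),
                                        np.asarray(hi, float))[0, 0])


def _cosine_linear(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosine-normalised linear kernel; zero-norm rows get similarity 0."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (A @ B.T) / np.outer(na, nb)
    K[~np.isfinite(K)] = 0.0
    return K


def fit_kernel_ranges(train_cyto: np.ndarray | None,
                      train_clin: np.ndarray | None,
                      clin_vtypes: Sequence[str] = ()) -> KernelRanges:
    """Standardisation/range statistics from the training fold only.

    Zero-variance cytokine features are excluded from the linear part with
    a warning (their SD is set to NaN and the column is masked out).
    """
    kr = KernelRanges(clin_vtypes=tuple(clin_vtypes))
    if train_cyto is not None and train_cyto.shape[1] > 0:
        mean = train_cyto.mean(axis=0)
        sd = train_cyto.std(axis=0, ddof=0)
        if (sd == 0).any():
            warnings.warn("zero-variance cytokine feature(s) excluded from "
                          "the linear kernel part")
            sd = np.where(sd == 0, np.nan, sd)
        kr.cyto_mean, kr.cyto_sd = mean, sd
    if train_clin is not None and train_clin.shape[1] > 0:
        kr.clin_min = train_clin.min(axis=0)
        kr.clin_max = train_clin.max(axis=0)
    return kr


def combined_kernel_matrix(cyto_A, cyto_B, clin_A, clin_B, spec: KernelSpec,
                           ranges: KernelRanges) -> np.ndarray:
    """Gram matrix combining the active kernel parts.

    The cytokine part is the cosine kernel on training-standardised
    features; the clinical part is the clinical kernel on training ranges;
    ``average`` takes their unweighted mean. Symmetric with unit diagonal
    on train x train.
    """
    parts = []
    want_cyto = spec.combination in ("average", "cytokine_only")
    want_clin = spec.combination in ("average", "clinical_only")
    if want_cyto and ranges.cyto_mean is not None:
        keep = ~np.isnan(ranges.cyto_sd)
        sa = (cyto_A[:, keep] - ranges.cyto_mean[keep]) / ranges.cyto_sd[keep]
        sb = (cyto_B[:, keep] - ranges.cyto_mean[keep]) / ranges.cyto_sd[keep]
        parts.append(_cosine_linear(sa, sb))
    if want_clin and ranges.clin_min is not None:
        parts.append(clinical_kernel_matrix(clin_A, clin_B, ranges.clin_vtypes,
                                            ranges.clin_min, ranges.clin_max))
    if not parts:
        raise ValueError("no active kernel part for this feature set")
    return sum(parts) / len(parts)


# ---------------------------------------------------------------------------
# classifiers


@dataclass(frozen=True)
class Hyperparameters:
    rf_n_trees: int = 500
    rf_max_features: str = "sqrt"
    svm_c: float = 1.0


def _one_nn_from_kernel(K_train: np.ndarray, K_cross: np.ndarray,
                        y_train: np.ndarray) -> np.ndarray:
    """1-NN on the kernel-induced distance d = sqrt(kxx + kzz - 2 kxz).

    The nearest training sample's label wins; distance ties go to the
    smallest training-sample index. Monotone transforms of d (hence using
    d^2, hence maximising kxz given unit self-similarity) leave the
    prediction unchanged; we use d^2 directly.
    """
    d2 = np.diag(K_train)[None, :] - 2 * K_cross  # + kzz, constant per test row
    nearest = np.argmin(d2, axis=1)               # first minimum = smallest index
    return y_train[nearest]


def train_predict(classifier: str, X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, specs: Sequence[VariableSpec],
                  kernel_spec: KernelSpec | None = None,
                  hyper: Hyperparameters = Hyperparameters(),
                  seed: int = 0) -> np.ndarray:
    """Fit one classifier on the (complete, imputed) training fold and
    predict binary labels for the test fold.

    ``specs`` describes the signature's variables and drives the split
    into cytokine and clinical kernel blocks. Deterministic given the
    seed; the random-forest path canonicalises training-row order so that
    permuting training samples cannot change predictions.
    """
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        raise ValueError("matrices must be imputed before classification")

    if classifier == "random_forest":
        order = np.lexsort(np.vstack([y_train, X_train.T[::-1]]))
        rf = RandomForestClassifier(
            n_estimators=hyper.rf_n_trees, max_features=hyper.rf_max_features,
            random_state=int(seed) % (2 ** 31))
        rf.fit(X_train[order], y_train[order])
        return rf.predict(X_test).astype(int)

    if classifier not in ("svm", "one_nn"):
        raise ValueError(f"unknown classifier {classifier!r}")

    is_cyto = np.array([v.provenance == "cytokine" for v in specs])
    clin_vtypes = [v.vtype for v in specs if v.provenance == "clinical"]
    if kernel_spec is None:
        if is_cyto.all():
            kernel_spec = KernelSpec("cytokine_only")
        elif not is_cyto.any():
            kernel_spec = KernelSpec("clinical_only")
        else:
            kernel_spec = KernelSpec("average")
    ranges = fit_kernel_ranges(
        X_train[:, is_cyto] if is_cyto.any() else None,
        X_train[:, ~is_cyto] if (~is_cyto).any() else None,
        clin_vtypes)
    K_train = combined_kernel_matrix(X_train[:, is_cyto], X_train[:, is_cyto],
                                     X_train[:, ~is_cyto], X_train[:, ~is_cyto],
                                     kernel_spec, ranges)
    K_cross = combined_kernel_matrix(X_test[:, is_cyto], X_train[:, is_cyto],
                                     X_test[:, ~is_cyto], X_train[:, ~is_cyto],
                                     kernel_spec, ranges)
    if classifier == "svm":
        clf = SVC(C=hyper.svm_c, kernel="precomputed")
        clf.fit(K_train, y_train)
        return clf.predict(K_cross).astype(int)
    return _one_nn_from_kernel(K_train, K_cross, y_train).astype(int)
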