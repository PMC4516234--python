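"""Assay preprocessing: background subtraction, inter-plate QC, sparse
feature exclusion, and the leakage-aware two-regime imputation.

Imputation follows the train/test asymmetry used by the evaluation
protocol: missing training cells are replaced class-conditionally (mean or
mode of same-class training samples), while missing test cells only ever
see the *global* training statistic, so the test labels and the test rows
of other patients cannot leak into a prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, SchemaError, VariableSpec

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """Raised when preprocessing removes every variable."""


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(stimulated, unstimulated, clamp: bool = False):
    """Net secretion = stimulated - unstimulated (pg/ml).

    Accepts scalars or aligned arrays/DataFrames; missing values propagate.
    Negative net values are preserved unless ``clamp`` is set, in which
    case they are floored at zero.
    """
    net = stimulated - unstimulated
    if clamp:
        net = np.maximum(net, 0.0)
    return net


def subtract_background_wells(raw, clamp: bool = False) -> Cohort:
    """Apply background subtraction to a paired-well container.

    ``raw`` is a :class:`cytopred.synthetic.RawWells`-like object with
    ``stimulated``/``unstimulated`` DataFrames, ``variables`` and
    ``labels3``; returns a net-concentration :class:`Cohort`.
    """
    net = subtract_background(raw.stimulated, raw.unstimulated, clamp=clamp)
    return Cohort(net, list(raw.variables), raw.labels3.copy())


# ---------------------------------------------------------------------------
# inter-plate QC


@dataclass(frozen=True)
class QCReport:
    """Inter-plate variability verdict for one cytokine."""

    cytokine: str
    ratio: float                # max/min of positive controls after outlier removal
    retained: bool
    threshold: float
    n_outliers_removed: int = 0
    reason: str = ""


def _iqr_survivors(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]


def interplate_qc(controls: Mapping[str, Sequence[float]],
                  threshold: float = 5.0) -> list[QCReport]:
    """Flag cytokines whose positive control varies too much across plates.

    Per cytokine, plate-control outliers are removed by the 1.5 x IQR fence
    rule, the max/min ratio of the survivors is computed, and the cytokine
    is retained iff the ratio is finite and <= ``threshold``. An all-zero
    control series has an undefined ratio; it is reported and dropped
    rather than raising.
    """
    reports = []
    for cytokine, vals in controls.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < 2:
            raise ValueError(f"{cytokine}: need >= 2 control values")
        survivors = _iqr_survivors(vals)
        removed = vals.size - survivors.size
        mn, mx = survivors.min(), survivors.max()
        if mx == 0.0:
            reports.append(QCReport(cytokine, float("nan"), False, threshold,
                                    removed, reason="undefined ratio (all-zero controls)"))
            continue
        ratio = np.inf if mn <= 0 else mx / mn
        retained = bool(np.isfinite(ratio) and ratio <= threshold)
        reports.append(QCReport(cytokine, float(ratio), retained, threshold, removed))
    return reports


def qc_report_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    """CSV-ready QC table (cytokine, ratio, retained)."""
    return pd.DataFrame(
        [{"cytokine": r.cytokine, "ratio": r.ratio, "retained": r.retained,
          "n_outliers_removed": r.n_outliers_removed} for r in reports])


# ---------------------------------------------------------------------------
# sparse features


def drop_sparse_features(cohort: Cohort, min_available_fraction: float = 0.5
                         ) -> tuple[Cohort, list[str]]:
    """Remove variables without more than ``min_available_fraction`` data.

    A variable is kept iff its observed fraction is strictly greater than
    the threshold ("more than 50% available data"); survivor order is
    preserved.
    """
    if not 0 < min_available_fraction <= 1:
        raise ValueError("min_available_fraction must be in (0,1]")
    frac = cohort.values.notna().mean(axis=0)
    keep = [v.name for v in cohort.variables if frac[v.name] > min_available_fraction]
    dropped = [n for n in cohort.variable_names if n not in keep]
    if not keep:
        raise EmptyCohortError("all variables dropped as too sparse")
    if dropped:
        logger.info("dropped %d sparse variables", len(dropped))
    return cohort.subset_variables(keep), dropped


# ---------------------------------------------------------------------------
# imputation


@dataclass
class ImputationStats:
    """Training-fold imputation statistics.

    ``class_stats[c]`` maps variable -> mean (continuous) or mode
    (discrete) of the class-``c`` training samples; ``global_stats`` holds
    the same over the whole training fold, used for test-set imputation.
    """

    class_stats: dict[int, pd.Series]
    global_stats: pd.Series
    vtypes: dict[str, str]
    fallback_variables: dict[int, list[str]] = field(default_factory=dict)


def _mode_smallest(values: np.ndarray) -> float:
    """Statistical mode; ties broken toward the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts ascending


def _column_stat(col: np.ndarray, vtype: str) -> float:
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return np.nan
    return float(obs.mean()) if vtype == "continuous" else _mode_smallest(obs)


def impute_train(train: pd.DataFrame, labels: np.ndarray,
                 specs: Sequence[VariableSpec]
                 ) -> tuple[pd.DataFrame, ImputationStats]:
    """Class-conditional training imputation.

    Missing continuous cells take the mean of observed same-class training
    values, discrete cells the mode (ties toward the smallest value). A
    class with no observed value for some variable falls back to the
    global training statistic (logged). Returns the completed matrix and
    the statistics needed to impute a matching test fold.
    """
    vtypes = {v.name: v.vtype for v in specs}
    unknown = [c for c in train.columns if c not in vtypes]
    if unknown:
        raise SchemaError(f"variables without metadata: {unknown}")
    labels = np.asarray(labels)
    X = train.to_numpy(dtype=float, copy=True)
    global_stats = pd.Series(
        {c: _column_stat(X[:, j], vtypes[c]) for j, c in enumerate(train.columns)})
    class_stats: dict[int, pd.Series] = {}
    fallbacks: dict[int, list[str]] = {}
    for cls in (0, 1):
        rows = labels == cls
        stats = {}
        for j, c in enumerate(train.columns):
            s = _column_stat(X[rows, j], vtypes[c])
            if np.isnan(s):
                s = global_stats[c]
                fallbacks.setdefault(cls, []).append(c)
            stats[c] = s
        class_stats[cls] = pd.Series(stats)
        fill = class_stats[cls].to_numpy()
        miss = np.isnan(X) & rows[:, None]
        X[miss] = np.broadcast_to(fill, X.shape)[miss]
    for cls, cols in fallbacks.items():
        logger.info("class %d: global fallback for %d variables", cls, len(cols))
    completed = pd.DataFrame(X, index=train.index, columns=train.columns)
    return completed, ImputationStats(class_stats, global_stats, vtypes, fallbacks)


def impute_test(test: pd.DataFrame, stats: ImputationStats) -> pd.DataFrame:
    """Fill missing test cells with the *global* training statistic.

    A pure function of the test matrix and the training statistics: test
    labels are never consulted and other test rows cannot influence a
    row's imputed values.
    """
    unknown = [c for c in test.columns if c not in stats.global_stats.index]
    if unknown:
        raise SchemaError(f"variables absent from training statistics: {unknown}")
    X = test.to_numpy(dtype=float, copy=True)
    fill = stats.global_stats[list(test.columns)].to_numpy()
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(fill, X.shape)[miss]
    return pd.DataFrame(X, index=test.index, columns=test.columns)
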