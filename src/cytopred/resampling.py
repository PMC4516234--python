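"""Repeated random subsampling evaluation of filter-then-classify models.

The evaluation engine repeats, J = 200 times by default: draw a stratified
90/10 train/test split; impute the training fold class-conditionally; rank
features univariately on the training fold only; keep the s best
(the *signature*); impute the test fold with global training statistics;
train the classifier; record the Balanced Classification Rate on the held
out 10%. Mean BCR over repeats is reported with a 95% confidence interval
built from the resampling-corrected variance (1/J + n_test/n_train) * s^2,
which inflates the naive variance to account for overlap between the
resampled training sets.

The engine is exposed as a model/results pair:

>>> model = ResamplingEvaluation(cohort, ProtocolConfig(task=ige_task()))
>>> res = model.fit()
>>> res.summary()
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, LabelTask, binarize, ige_task
from .models import (
    CLASSIFIERS,
    Hyperparameters,
    UndefinedBCRError,
    bcr,
    confusion,
    train_predict,
)
from .preprocess import impute_test, impute_train
from .univariate import rank_from_pvalues, univariate_scan

logger = logging.getLogger(__name__)

FEATURE_SETS = ("cytokines_only", "clinical_only", "all")

DEFAULT_SIGNATURE_SIZES = (1, 2, 3, 4, 6, 8, 12, 16, 24, 32)


class ProtocolError(RuntimeError):
    """Raised when the resampling protocol cannot draw valid splits."""


@dataclass
class ProtocolConfig:
    """Parameters of the repeated-subsampling protocol."""

    task: LabelTask = field(default_factory=ige_task)
    J: int = 200
    train_fraction: float = 0.9
    signature_sizes: tuple = DEFAULT_SIGNATURE_SIZES
    classifiers: tuple = CLASSIFIERS
    feature_sets: tuple = FEATURE_SETS
    seed: int = 0
    alpha: float = 0.05
    stratified: bool = True
    welch: bool = False
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self):
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if any(s < 1 for s in self.signature_sizes):
            raise ValueError("signature sizes must be >= 1")
        bad = set(self.classifiers) - set(CLASSIFIERS)
        if bad:
            raise ValueError(f"unknown classifiers {sorted(bad)}")
        bad = set(self.feature_sets) - set(FEATURE_SETS)
        if bad:
            raise ValueError(f"unknown feature sets {sorted(bad)}")


@dataclass
class ResamplingResult:
    """Per-repeat BCRs and summary for one classifier x s x feature set."""

    classifier: str
    s: int
    feature_set: str
    task_id: str
    bcrs: np.ndarray
    signatures: list
    n_train: int
    n_test: int
    alpha: float
    n_redraws: int = 0

    @property
    def mean_bcr(self) -> float:
        return float(np.mean(self.bcrs))

    @property
    def ci(self) -> tuple[float, float]:
        return nadeau_ci(self.bcrs, self.n_train, self.n_test, self.alpha)

    @property
    def signature_frequency(self) -> Counter:
        c: Counter = Counter()
        for sig in self.signatures:
            c.update(sig)
        return c

    @property
    def descriptor(self) -> tuple:
        return (self.classifier, self.s, self.feature_set, self.task_id)


def nadeau_ci(bcrs: Sequence[float], n_train: int, n_test: int,
              alpha: float = 0.05) -> tuple[float, float]:
    """Resampling-corrected t confidence interval for the mean BCR.

    The per-repeat sample variance s^2 is inflated to
    V = (1/J + n_test/n_train) * s^2 before forming the symmetric t
    interval mean +/- t_{J-1, 1-alpha/2} * sqrt(V), clipped to [0,1]. The
    correction accounts for the dependence induced by overlapping training
    sets; the interval is never narrower than the naive one.
    """
    b = np.asarray(bcrs, dtype=float)
    J = b.size
    if J < 2:
        raise ValueError("need at least 2 repeats for a variance estimate")
    if n_train < 1 or n_test < 1:
        raise ValueError("split sizes must be >= 1")
    s2 = float(np.var(b, ddof=1))
    v = (1.0 / J + n_test / n_train) * s2
    half = float(sps.t.ppf(1 - alpha / 2, J - 1) * np.sqrt(v))
    mean = float(b.mean())
    return (max(0.0, mean - half), min(1.0, mean + half))


def summarize_signatures(result: ResamplingResult) -> pd.DataFrame:
    """Signature-inclusion counts, most frequent first (ties by name)."""
    freq = result.signature_frequency
    rows = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["variable", "count"])


def select_best(results: Sequence[ResamplingResult]
                ) -> tuple[ResamplingResult, str]:
    """Highest mean BCR; ties to smaller s, then classifier name.

    Returns the winner plus a note listing competitors whose confidence
    intervals overlap the winner's (differences not significant).
    """
    if not results:
        raise ValueError("no results to select from")
    best = min(results, key=lambda r: (-r.mean_bcr, r.s, r.classifier))
    lo, hi = best.ci
    overlapping = [r.descriptor for r in results
                   if r is not best and r.ci[1] >= lo and r.ci[0] <= hi]
    note = (f"best {best.descriptor} mean BCR {best.mean_bcr:.3f}; "
            f"{len(overlapping)} competing configuration(s) have overlapping "
            f"confidence intervals (differences not significant)")
    return best, note


# ---------------------------------------------------------------------------
# model / results pair


class ResamplingEvaluation:
    """Evaluate filter-then-classify models of allergy on a cohort.

    Parameters
    ----------
    cohort : Cohort
        Preprocessed cohort (sparse features already excluded).
    config : ProtocolConfig
        Protocol parameters, including the label task and master seed.
    """

    def __init__(self, cohort: Cohort, config: ProtocolConfig | None = None):
        self.cohort = cohort
        self.config = config or ProtocolConfig()

    # -- internals --------------------------------------------------------

    def _feature_columns(self, feature_set: str) -> list[str]:
        if feature_set == "cytokines_only":
            return [v.name for v in self.cohort.variables if v.provenance == "cytokine"]
        if feature_set == "clinical_only":
            return [v.name for v in self.cohort.variables if v.provenance == "clinical"]
        return list(self.cohort.variable_names)

    def _draw_split(self, y: np.ndarray, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
        n = y.size
        frac = self.config.train_fraction
        if self.config.stratified:
            train_idx = []
            for cls in (0, 1):
                idx = np.flatnonzero(y == cls)
                n_tr = int(np.floor(frac * idx.size))
                n_tr = min(max(n_tr, 1), idx.size - 1)
                train_idx.append(rng.permutation(idx)[:n_tr])
            train = np.sort(np.concatenate(train_idx))
        else:
            n_tr = min(max(int(np.floor(frac * n)), 1), n - 1)
            train = np.sort(rng.permutation(n)[:n_tr])
        test = np.setdiff1d(np.arange(n), train)
        return train, test

    def fit(self) -> "ResamplingResults":
        """Run the full protocol; bit-reproducible from ``config.seed``."""
        cfg = self.config
        y_all, mask = binarize(self.cohort, cfg.task)
        sub = self.cohort.subset_patients(np.asarray(self.cohort.patients)[mask])
        X_all = sub.values
        specs = {v.name: v for v in sub.variables}

        fs_cols = {fs: self._feature_columns(fs) for fs in cfg.feature_sets}
        sizes = {fs: [s for s in cfg.signature_sizes if s <= len(fs_cols[fs])]
                 for fs in cfg.feature_sets}
        for fs in cfg.feature_sets:
            skipped = sorted(set(cfg.signature_sizes) - set(sizes[fs]))
            if skipped:
                logger.info("%s: skipping signature sizes %s (> %d variables)",
                            fs, skipped, len(fs_cols[fs]))

        combos = [(clf, s, fs) for fs in cfg.feature_sets
                  for s in sizes[fs] for clf in cfg.classifiers]
        bcrs = {c: np.empty(cfg.J) for c in combos}
        signatures = {c: [] for c in combos}

        streams = np.random.SeedSequence(cfg.seed).spawn(cfg.J)
        redraws = 0
        n_train = n_test = 0
        for j, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            for attempt in range(11):
                train_idx, test_idx = self._draw_split(y_all, rng)
                y_tr, y_te = y_all[train_idx], y_all[test_idx]
                if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
                    break
                redraws += 1
                if redraws > 10 * cfg.J:
                    raise ProtocolError("too many degenerate splits")
            else:
                raise ProtocolError("could not draw a non-degenerate split")
            clf_seed = int(rng.integers(2 ** 31))

            X_tr_raw = X_all.iloc[train_idx]
            X_te_raw = X_all.iloc[test_idx]
            n_train, n_test = len(train_idx), len(test_idx)

            # training-fold-only statistics: ranking on raw (pairwise-deleted)
            # values, imputation statistics from the same fold
            p_train = univariate_scan(X_tr_raw, y_tr, list(specs.values()),
                                      welch=cfg.welch)
            X_tr_imp, imp_stats = impute_train(X_tr_raw, y_tr, list(specs.values()))
            X_te_imp = impute_test(X_te_raw, imp_stats)

            for fs in cfg.feature_sets:
                ranking = rank_from_pvalues(p_train[fs_cols[fs]])
                for s in sizes[fs]:
                    sig = tuple(ranking[:s])
                    sig_specs = [specs[n] for n in sig]
                    Xtr = X_tr_imp[list(sig)].to_numpy()
                    Xte = X_te_imp[list(sig)].to_numpy()
                    for clf in cfg.classifiers:
                        pred = train_predict(clf, Xtr, y_tr, Xte, sig_specs,
                                             hyper=cfg.hyper, seed=clf_seed)
                        bcrs[(clf, s, fs)][j] = bcr(confusion(y_te, pred))
                        signatures[(clf, s, fs)].append(sig)

        results = {
            c: ResamplingResult(classifier=c[0], s=c[1], feature_set=c[2],
                                task_id=cfg.task.task_id, bcrs=bcrs[c],
                                signatures=signatures[c], n_train=n_train,
                                n_test=n_test, alpha=cfg.alpha,
                                n_redraws=redraws)
            for c in combos}
        if redraws:
            logger.info("protocol: %d degenerate splits redrawn", redraws)
        return ResamplingResults(self, results)


class ResamplingResults:
    """Results container: per-combination estimates, CIs and signatures."""

    def __init__(self, model: ResamplingEvaluation,
                 results: dict[tuple, ResamplingResult]):
        self.model = model
        self.results = results

    def __getitem__(self, key: tuple) -> ResamplingResult:
        return self.results[key]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (clf, s, fs), r in self.results.items():
            lo, hi = r.ci
            rows.append({"classifier": clf, "s": s, "feature_set": fs,
                         "task": r.task_id, "mean_bcr": r.mean_bcr,
                         "ci_low": lo, "ci_high": hi, "J": r.bcrs.size,
                         "n_train": r.n_train, "n_test": r.n_test})
        return (pd.DataFrame(rows)
                .sort_values("mean_bcr", ascending=False)
                .reset_index(drop=True))

    def summary(self) -> str:
        """Human-readable summary table, best configuration first."""
        df = self.summary_frame()
        best, note = self.best()
        lines = [f"Resampling evaluation ({df['task'].iloc[0]} task, "
                 f"J={df['J'].iloc[0]}, "
                 f"{df['n_train'].iloc[0]}/{df['n_test'].iloc[0]} split)",
                 df.to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"),
                 note]
        return "\n".join(lines)

    def best(self) -> tuple[ResamplingResult, str]:
        return select_best(list(self.results.values()))

    def signature_table(self, key: tuple) -> pd.DataFrame:
        return summarize_signatures(self.results[key])


def run_protocol(cohort: Cohort, config: ProtocolConfig) -> ResamplingResults:
    """Functional alias for ``ResamplingEvaluation(cohort, config).fit()``."""
    return ResamplingEvaluation(cohort, config).fit()
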