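"""Cohort container, variable metadata and label tasks.

A cohort is a patient-by-variable table. Variables are either clinical
(mixed type: continuous, binary, ordinal or nominal) or cytokine
concentrations (always continuous, in pg/ml after background subtraction),
the latter indexed by cytokine x stimulation (LPS/PHA) x stimulation
duration (24h/96h) x sampling timepoint (cord blood, 2, 6, 18 months).
Each patient carries one of three labels: non-allergic, non-IgE-mediated
allergic or uncertain, and IgE-mediated allergic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# vocabulary

NONALL = "NONALL"
NONIGE_OR_UNCERTAIN = "NONIGE_OR_UNCERTAIN"
IGE = "IGE"
LABELS3 = (NONALL, NONIGE_OR_UNCERTAIN, IGE)

VTYPES = ("continuous", "binary", "ordinal", "nominal")
STIMULATIONS = ("LPS", "PHA")
DURATIONS_H = (24, 96)
TIMEPOINTS = ("CB", "2m", "6m", "18m")

#: The 18 cytokines/chemokines retained after inter-plate QC of the 27-plex
#: panel (ASCII-sanitised names).
CYTOKINES = (
    "IL1b", "IL1ra", "IL2", "IL4", "IL7", "IL9", "IL10", "IL12p70",
    "IL15", "IL17", "Eotaxin", "FGF", "GCSF", "GMCSF", "IFNg", "IP10",
    "TNFa", "VEGF",
)


class SchemaError(ValueError):
    """Raised when a cohort file or matrix violates the schema."""


class DegenerateTaskError(ValueError):
    """Raised when a label task leaves zero positives or zero negatives."""


# ---------------------------------------------------------------------------
# variable metadata


@dataclass(frozen=True)
class VariableSpec:
    """Type and provenance of one cohort variable.

    Cytokine variables carry all four grid coordinates and are continuous;
    clinical variables carry none.
    """

    name: str
    vtype: str
    provenance: str
    cytokine: str | None = None
    stimulation: str | None = None
    duration_h: int | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise SchemaError(f"{self.name}: unknown vtype {self.vtype!r}")
        if self.provenance == "cytokine":
            coords = (self.cytokine, self.stimulation, self.duration_h, self.timepoint)
            if any(c is None for c in coords):
                raise SchemaError(f"{self.name}: cytokine variable missing coordinates")
            if self.vtype != "continuous":
                raise SchemaError(f"{self.name}: cytokine variables must be continuous")
            if self.stimulation not in STIMULATIONS:
                raise SchemaError(f"{self.name}: bad stimulation {self.stimulation!r}")
            if self.duration_h not in DURATIONS_H:
                raise SchemaError(f"{self.name}: bad duration {self.duration_h!r}")
            if self.timepoint not in TIMEPOINTS:
                raise SchemaError(f"{self.name}: bad timepoint {self.timepoint!r}")
        elif self.provenance == "clinical":
            if any(c is not None for c in
                   (self.cytokine, self.stimulation, self.duration_h, self.timepoint)):
                raise SchemaError(f"{self.name}: clinical variable with cytokine coordinates")
        else:
            raise SchemaError(f"{self.name}: unknown provenance {self.provenance!r}")

    def to_dict(self) -> dict:
        d = {"name": self.name, "vtype": self.vtype, "provenance": self.provenance}
        if self.provenance == "cytokine":
            d.update(cytokine=self.cytokine, stimulation=self.stimulation,
                     duration_h=self.duration_h, timepoint=self.timepoint)
        return d


def cytokine_variable_name(cytokine: str, stimulation: str, duration_h: int,
                           timepoint: str) -> str:
    """Deterministic, sortable name: ``<cytokine>_<stim>_<dur>h_<tp>``."""
    return f"{cytokine}_{stimulation}_{duration_h}h_{timepoint}"


def cytokine_grid(cytokines: Sequence[str] = CYTOKINES) -> list[VariableSpec]:
    """All cytokine x stimulation x duration x timepoint conditions.

    With the default 18-cytokine panel this yields 288 variables.
    """
    specs = []
    for ck in cytokines:
        for stim in STIMULATIONS:
            for dur in DURATIONS_H:
                for tp in TIMEPOINTS:
                    specs.append(VariableSpec(
                        name=cytokine_variable_name(ck, stim, dur, tp),
                        vtype="continuous", provenance="cytokine",
                        cytokine=ck, stimulation=stim, duration_h=dur,
                        timepoint=tp))
    return specs


def clinical_variables() -> list[VariableSpec]:
    """The 8 clinical factors used alongside the cytokine grid.

    Number of allergic first-degree relatives; maternal tobacco exposure
    during pregnancy; exclusive breastfeeding at the birth, 2-, 6- and
    12-month visits; delivery mode; presence of pets during pregnancy.
    """
    c = lambda n, vt: VariableSpec(name=n, vtype=vt, provenance="clinical")
    return [
        c("famhist_first_degree", "ordinal"),
        c("tobacco_pregnancy", "binary"),
        c("breastfeeding_birth", "binary"),
        c("breastfeeding_2m", "binary"),
        c("breastfeeding_6m", "binary"),
        c("breastfeeding_12m", "binary"),
        c("delivery_mode", "nominal"),
        c("pets_pregnancy", "binary"),
    ]


def default_variable_grid() -> list[VariableSpec]:
    """288 cytokine conditions plus the 8 clinical factors (296 total)."""
    return cytokine_grid() + clinical_variables()


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Patient-by-variable matrix with metadata and 3-class labels.

    ``values`` is a float DataFrame indexed by patient id with one column
    per variable; missing cells are NaN. Discrete variables are stored
    numerically (binary in {0,1}, ordinal as non-negative integers, nominal
    as small integer codes).
    """

    values: pd.DataFrame
    variables: list[VariableSpec]
    labels3: pd.Series

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dup}")
        if list(self.values.columns) != names:
            raise SchemaError("values columns do not match variable metadata")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate patient ids: {dup}")
        if not self.labels3.index.equals(self.values.index):
            raise SchemaError("labels index does not match patient ids")
        bad = set(self.labels3.unique()) - set(LABELS3)
        if bad:
            raise SchemaError(f"labels outside vocabulary {LABELS3}: {sorted(bad)}")
        self.values = self.values.astype(float)
        for v in self.variables:
            col = self.values[v.name]
            obs = col.dropna()
            if v.vtype == "binary" and not obs.isin([0.0, 1.0]).all():
                raise SchemaError(f"{v.name}: binary values outside {{0,1}}")
            if v.vtype == "ordinal":
                if ((obs < 0) | (obs != obs.round())).any():
                    raise SchemaError(f"{v.name}: ordinal values must be non-negative integers")

    # -- convenience ------------------------------------------------------

    @property
    def patients(self) -> list:
        return list(self.values.index)

    @property
    def n_patients(self) -> int:
        return len(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def spec_of(self, name: str) -> VariableSpec:
        try:
            return next(v for v in self.variables if v.name == name)
        except StopIteration:
            raise SchemaError(f"unknown variable {name!r}") from None

    def class_counts(self) -> dict[str, int]:
        vc = self.labels3.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS3}

    def subset_variables(self, names: Sequence[str]) -> "Cohort":
        specs = {v.name: v for v in self.variables}
        missing = [n for n in names if n not in specs]
        if missing:
            raise SchemaError(f"unknown variables {missing}")
        return Cohort(self.values[list(names)].copy(),
                      [specs[n] for n in names], self.labels3.copy())

    def subset_patients(self, ids: Sequence) -> "Cohort":
        return Cohort(self.values.loc[list(ids)].copy(), list(self.variables),
                      self.labels3.loc[list(ids)].copy())

    def equals(self, other: "Cohort") -> bool:
        """Cell-wise equality including the missingness pattern."""
        return (self.variables == other.variables
                and self.labels3.equals(other.labels3)
                and self.values.index.equals(other.values.index)
                and bool(((self.values == other.values)
                          | (self.values.isna() & other.values.isna())).all().all()))


# ---------------------------------------------------------------------------
# label tasks


@dataclass(frozen=True)
class LabelTask:
    """Binary classification task defined on the 3-class labels."""

    task_id: str
    positive_classes: frozenset
    negative_classes: frozenset

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_classes), set(self.negative_classes)
        if not pos or not neg:
            raise DegenerateTaskError(f"{self.task_id}: empty class set")
        if pos & neg:
            raise DegenerateTaskError(f"{self.task_id}: overlapping class sets")
        if not (pos | neg) <= set(LABELS3):
            raise SchemaError(f"{self.task_id}: classes outside {LABELS3}")


def ige_task() -> LabelTask:
    """IgE-mediated allergic children vs the rest of the cohort."""
    return LabelTask("IGE", frozenset({IGE}),
                     frozenset({NONIGE_OR_UNCERTAIN, NONALL}))


def allergy_task(include_uncertain: bool = True) -> LabelTask:
    """Allergic (IgE- and non-IgE-mediated) vs non-allergic children.

    Whether children with an uncertain status count as allergic is
    configurable; the default pools them with the allergic group, mirroring
    the pooled 30-patient non-IgE-or-uncertain class.
    """
    if include_uncertain:
        return LabelTask("ALLERGY", frozenset({IGE, NONIGE_OR_UNCERTAIN}),
                         frozenset({NONALL}))
    return LabelTask("ALLERGY_STRICT", frozenset({IGE}), frozenset({NONALL}))


def binarize(cohort: Cohort, task: LabelTask) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for ``task``: (y, mask).

    ``mask`` is a boolean array over ``cohort.patients`` marking patients
    whose 3-class label belongs to the task; ``y`` is the {0,1} vector
    aligned to the retained patients (1 = positive). Patients outside the
    task's classes are dropped with a logged count.
    """
    labs = cohort.labels3.to_numpy()
    pos = np.isin(labs, list(task.positive_classes))
    neg = np.isin(labs, list(task.negative_classes))
    mask = pos | neg
    dropped = int((~mask).sum())
    if dropped:
        logger.info("task %s: dropped %d/%d patients outside the task classes",
                    task.task_id, dropped, len(labs))
    y = pos[mask].astype(np.int8)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateTaskError(
            f"{task.task_id}: task leaves {int(y.sum())} positives and "
            f"{int(y.size - y.sum())} negatives")
    return y, mask


# ---------------------------------------------------------------------------
# i/o


def write_cohort(cohort: Cohort, path: str | Path, schema_path: str | Path) -> None:
    """Write the cohort CSV and its YAML variable-metadata sidecar.

    Missing cells are written as empty fields; no numeric sentinels.
    """
    df = cohort.values.copy()
    df.insert(0, "label", cohort.labels3)
    df.index.name = "patient_id"
    df.to_csv(path, na_rep="")
    with open(schema_path, "w") as fh:
        yaml.safe_dump({"variables": [v.to_dict() for v in cohort.variables]},
                       fh, sort_keys=False)


def read_cohort(path: str | Path, schema_path: str | Path) -> Cohort:
    """Read a cohort CSV plus YAML sidecar and validate it.

    Raises :class:`SchemaError` naming the offending column on duplicate
    patient ids, unknown labels, or metadata/column mismatch.
    """
    with open(schema_path) as fh:
        meta = yaml.safe_load(fh)
    variables = [VariableSpec(**d) for d in meta["variables"]]
    df = pd.read_csv(path, dtype={"patient_id": str})
    for required in ("patient_id", "label"):
        if required not in df.columns:
            raise SchemaError(f"missing required column {required!r}")
    df = df.set_index("patient_id")
    labels = df.pop("label").astype(str)
    expected = [v.name for v in variables]
    if list(df.columns) != expected:
        extra = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise SchemaError(f"metadata/column mismatch: extra={extra} missing={missing}")
    return Cohort(df, variables, labels)
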