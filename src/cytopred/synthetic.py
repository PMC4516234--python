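"""Synthetic birth-cohort generator.

Emulates the data structure the analysis pipeline assumes: 131 children in
three allergy classes (86 non-allergic, 30 non-IgE-mediated allergic or
uncertain, 15 IgE-mediated allergic), 288 cytokine conditions (18 analytes
x LPS/PHA x 24h/96h x four sampling timepoints) plus 8 clinical factors,
per-timepoint block missingness, and group mean differences for the
conditions the study reported as discriminant.

Concentrations are drawn log-normally on a shifted scale (value + shift),
which keeps the right skew of multiplex immunoassay data while allowing
the small near-zero net values that background subtraction produces.
Default effect means are the printed group means; the free dispersions are
fixed once by calibration: each effect's common within-group SD is chosen
so that the expected pooled t statistic at the expected complete-case
sample sizes matches the significance level the study printed for that
condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    IGE,
    LABELS3,
    NONALL,
    NONIGE_OR_UNCERTAIN,
    TIMEPOINTS,
    Cohort,
    SchemaError,
    clinical_variables,
    default_variable_grid,
)

# group aliases usable in Effect.group
REST = "REST"            # everyone but the IgE-mediated class
ALLERGIC = "ALLERGIC"    # IgE- and non-IgE-mediated allergic (incl. uncertain)
_ALIASES = {
    REST: (NONALL, NONIGE_OR_UNCERTAIN),
    ALLERGIC: (IGE, NONIGE_OR_UNCERTAIN),
}


class ConfigError(ValueError):
    """Raised for invalid synthetic-cohort configurations."""


@dataclass(frozen=True)
class Effect:
    """Group-specific mean/SD (pg/ml) for one cytokine condition."""

    variable: str
    group: str          # a 3-class label or an alias (REST, ALLERGIC)
    mean: float
    sd: float

    def classes(self) -> tuple[str, ...]:
        if self.group in _ALIASES:
            return _ALIASES[self.group]
        if self.group in LABELS3:
            return (self.group,)
        raise ConfigError(f"unknown effect group {self.group!r}")


def default_effects() -> list[Effect]:
    """Default group means for the discriminant conditions.

    Means are the printed cord-blood/6m/18m group means; dispersion is
    multiplicative (per-group SD proportional to the group mean, the
    natural noise model for log-normal concentration data), with each
    variable's common CV fixed by the t-statistic calibration described in
    the module docstring (see also docs/methods.md). IL-15 PHA 96h CB gets
    per-class means because it is discriminant under both the allergy and
    the IgE grouping.
    """
    e = Effect
    return [
        # IgE-mediated vs rest
        e("IL15_PHA_24h_CB", IGE, 5.30, 2.78), e("IL15_PHA_24h_CB", REST, 19.21, 8.93),
        e("IL12p70_LPS_96h_CB", IGE, 0.71, 0.64), e("IL12p70_LPS_96h_CB", REST, 2.34, 1.25),
        e("IL15_PHA_96h_CB", IGE, 3.74, 2.66),
        e("IL15_PHA_96h_CB", NONIGE_OR_UNCERTAIN, 14.81, 8.88),
        e("IL15_PHA_96h_CB", NONALL, 25.06, 14.64),
        e("IL1b_LPS_24h_6m", IGE, 290.36, 159.0), e("IL1b_LPS_24h_6m", REST, 1374.43, 750.7),
        e("IL1b_LPS_96h_6m", IGE, 183.17, 122.0), e("IL1b_LPS_96h_6m", REST, 847.64, 562.2),
        e("VEGF_LPS_96h_18m", IGE, 1.57, 2.22), e("VEGF_LPS_96h_18m", REST, 93.0, 81.0),
        # allergic (pooled) vs non-allergic
        e("TNFa_LPS_24h_CB", ALLERGIC, 3115.18, 2185.9), e("TNFa_LPS_24h_CB", NONALL, 6059.83, 4251.5),
        e("TNFa_PHA_24h_CB", ALLERGIC, 3862.2, 2947.5), e("TNFa_PHA_24h_CB", NONALL, 6854.98, 5231.0),
        e("IL17_PHA_96h_CB", ALLERGIC, 39.14, 31.7), e("IL17_PHA_96h_CB", NONALL, 73.77, 59.1),
        e("FGF_PHA_96h_CB", ALLERGIC, 18.38, 16.3), e("FGF_PHA_96h_CB", NONALL, 35.8, 30.9),
    ]


@dataclass(frozen=True)
class ClinicalEffect:
    """Per-class parameter of one clinical variable.

    ``kind`` is ``poisson`` (ordinal count), ``bernoulli`` (binary) or
    ``nominal`` (two-category code drawn Bernoulli). ``params`` maps each
    3-class label to the distribution parameter (Poisson mean or success
    probability).
    """

    name: str
    kind: str
    params: dict[str, float]


def default_clinical_model() -> list[ClinicalEffect]:
    """Clinical-variable distributions anchored to the printed frequencies.

    Number of allergic first-degree relatives: Poisson, mean 0.88 in
    non-allergic vs 1.37 in allergic children. Delivery mode: caesarean in
    19.1% vs 27.9%. Pets during pregnancy and late exclusive breastfeeding
    are less frequent in allergic children; variables with no printed
    difference are class-independent.
    """
    def ce(name, kind, nonall, allergic):
        return ClinicalEffect(name, kind, {
            NONALL: nonall, NONIGE_OR_UNCERTAIN: allergic, IGE: allergic})

    return [
        ce("famhist_first_degree", "poisson", 0.88, 1.37),
        ce("tobacco_pregnancy", "bernoulli", 0.20, 0.20),
        ce("breastfeeding_birth", "bernoulli", 0.90, 0.90),
        ce("breastfeeding_2m", "bernoulli", 0.60, 0.60),
        ce("breastfeeding_6m", "bernoulli", 0.145, 0.071),
        ce("breastfeeding_12m", "bernoulli", 0.060, 0.010),
        ce("delivery_mode", "nominal", 0.191, 0.279),
        ce("pets_pregnancy", "bernoulli", 0.17, 0.02),
    ]


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generator.

    ``missing_block_rate`` is the per-(patient, timepoint) probability that
    the whole blood sample is missing, wiping out the 72 cytokine variables
    of that timepoint. The default 0.435 puts the median complete-case
    count per condition at 74 of 131 patients.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {NONALL: 86, NONIGE_OR_UNCERTAIN: 30, IGE: 15})
    effects: list[Effect] = field(default_factory=default_effects)
    clinical_model: list[ClinicalEffect] = field(default_factory=default_clinical_model)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.62   # CV ~0.68, the median calibrated effect CV
    shift: float = 1.0          # pg/ml offset of the shifted log-normal
    missing_block_rate: float = 0.435
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ConfigError("class counts must be >= 0")
        if not 0 <= self.missing_block_rate < 1:
            raise ConfigError("missing_block_rate must be in [0,1)")
        if self.baseline_log_sd <= 0:
            raise ConfigError("baseline_log_sd must be > 0")
        for eff in self.effects:
            if eff.sd <= 0:
                raise ConfigError(f"{eff.variable}: SD must be > 0")
            eff.classes()  # validates the group alias

    def without_effects(self) -> "SyntheticConfig":
        """Copy with one shared distribution per variable (global null).

        Removes the cytokine effects and the clinical class shifts (every
        class gets the non-allergic parameter), so no variable carries any
        label association.
        """
        flat_clinical = [
            ClinicalEffect(ce.name, ce.kind,
                           {lab: ce.params[NONALL] for lab in LABELS3})
            for ce in self.clinical_model]
        return dataclasses.replace(self, effects=[], clinical_model=flat_clinical)


@dataclass
class RawWells:
    """Paired stimulated/unstimulated concentrations before subtraction."""

    stimulated: pd.DataFrame
    unstimulated: pd.DataFrame
    variables: list
    labels3: pd.Series


# ---------------------------------------------------------------------------


def _lognormal_params(mean: np.ndarray, sd: np.ndarray, shift: float):
    """Moment-match a shifted log-normal: E[X]-shift=mean, SD[X]=sd."""
    m = mean + shift
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def _labels(config: SyntheticConfig) -> pd.Series:
    labs = []
    for lab in (NONALL, NONIGE_OR_UNCERTAIN, IGE):
        labs.extend([lab] * config.n_per_class.get(lab, 0))
    ids = [f"P{i + 1:03d}" for i in range(len(labs))]
    return pd.Series(labs, index=pd.Index(ids, name="patient_id"))


def _cell_params(config: SyntheticConfig, labels: pd.Series, var_names: list[str]):
    """Per-cell (mu, sigma) matrices of the shifted log-normal."""
    n, p = len(labels), len(var_names)
    col = {name: j for j, name in enumerate(var_names)}
    # baseline: identical for every class
    base_mean = np.exp(config.baseline_log_mean + config.baseline_log_sd ** 2 / 2)
    base_sd = base_mean * np.sqrt(np.expm1(config.baseline_log_sd ** 2))
    mean = np.full((n, p), base_mean - config.shift)
    sd = np.full((n, p), base_sd)
    labs = labels.to_numpy()
    for eff in config.effects:
        if eff.variable not in col:
            raise ConfigError(
                f"effect references {eff.variable!r}, outside the cytokine grid")
        rows = np.isin(labs, eff.classes())
        mean[rows, col[eff.variable]] = eff.mean
        sd[rows, col[eff.variable]] = eff.sd
    return _lognormal_params(mean, sd, config.shift)


def _draw_clinical(config: SyntheticConfig, labels: pd.Series,
                   rng: np.random.Generator) -> pd.DataFrame:
    out = {}
    labs = labels.to_numpy()
    for ce in config.clinical_model:
        p = np.array([ce.params[lab] for lab in labs])
        if ce.kind == "poisson":
            out[ce.name] = rng.poisson(p).astype(float)
        elif ce.kind in ("bernoulli", "nominal"):
            out[ce.name] = (rng.random(len(labs)) < p).astype(float)
        else:
            raise ConfigError(f"unknown clinical kind {ce.kind!r}")
    return pd.DataFrame(out, index=labels.index)


def _block_missing_mask(config: SyntheticConfig, labels: pd.Series,
                        variables, rng: np.random.Generator) -> np.ndarray:
    """Boolean (patients x cytokine variables) mask of missing cells.

    Missingness is block-structured: a missing (patient, timepoint) draw
    wipes all conditions of that timepoint.
    """
    n = len(labels)
    block_missing = rng.random((n, len(TIMEPOINTS))) < config.missing_block_rate
    tp_idx = {tp: k for k, tp in enumerate(TIMEPOINTS)}
    cols = np.array([tp_idx[v.timepoint] for v in variables])
    return block_missing[:, cols]


def generate(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort; bit-reproducible from the seed."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_net, _rng_wells, rng_clin, rng_miss = map(np.random.default_rng, ss.spawn(4))

    labels = _labels(config)
    variables = default_variable_grid()
    cyto_vars = [v for v in variables if v.provenance == "cytokine"]
    names = [v.name for v in cyto_vars]

    mu, sigma = _cell_params(config, labels, names)
    net = rng_net.lognormal(mean=mu, sigma=sigma) - config.shift
    net[_block_missing_mask(config, labels, cyto_vars, rng_miss)] = np.nan

    cyto = pd.DataFrame(net, index=labels.index, columns=names)
    clin = _draw_clinical(config, labels, rng_clin)
    values = pd.concat([cyto, clin], axis=1)
    return Cohort(values, variables, labels)


def generate_raw_wells(config: SyntheticConfig, seed: int | None = None) -> RawWells:
    """Paired stimulated/unstimulated wells whose difference is ``generate``.

    The unstimulated well is a small non-negative log-normal background
    (inflated where needed so the stimulated well stays non-negative); the
    stimulated well is background + net, so subtracting the two recovers
    the ``generate`` cohort of the same seed cell-for-cell.
    """
    seed = config.seed if seed is None else seed
    net_cohort = generate(config, seed=seed)
    ss = np.random.SeedSequence(seed)
    rng_wells = np.random.default_rng(ss.spawn(4)[1])

    cyto_vars = [v for v in net_cohort.variables if v.provenance == "cytokine"]
    names = [v.name for v in cyto_vars]
    net = net_cohort.values[names].to_numpy()
    background = rng_wells.lognormal(mean=1.0, sigma=0.5, size=net.shape)
    background = np.maximum(background, np.where(np.isnan(net), 0.0, -net))
    stim = net + background
    background = np.where(np.isnan(net), np.nan, background)

    idx = net_cohort.values.index
    return RawWells(
        stimulated=pd.DataFrame(stim, index=idx, columns=names),
        unstimulated=pd.DataFrame(background, index=idx, columns=names),
        variables=cyto_vars,
        labels3=net_cohort.labels3,
    )


def permute_labels(cohort: Cohort, seed: int) -> Cohort:
    """Null cohort: the 3-class labels are randomly reassigned to patients."""
    rng = np.random.default_rng(seed)
    permuted = cohort.labels3.to_numpy()[rng.permutation(cohort.n_patients)]
    return Cohort(cohort.values.copy(), list(cohort.variables),
                  pd.Series(permuted, index=cohort.values.index))
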