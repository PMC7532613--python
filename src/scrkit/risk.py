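"""Organ equivalent dose (OED) and excess absolute risk (EAR) models.

The organ equivalent dose is the uniform dose that would induce the same
secondary-cancer incidence as an inhomogeneous dose distribution.  It is
computed from the differential DVH with one of three dose-response curves
(volume fractions ``v_i`` at bin-centre doses ``D_i``):

* ``linear``:               OED = sum_i v_i * D_i               (= mean dose)
* ``linear_exponential``:   OED = sum_i v_i * D_i * exp(-alpha*D_i)
* ``linear_plateau``:       OED = sum_i v_i * (1 - exp(-delta*D_i)) / delta

with alpha = 0.044 / Gy and delta = 0.139 / Gy from a combined fit to
A-bomb-survivor and Hodgkin-lymphoma-survivor data.  The linear model is
known to overestimate risk above a few Gy and is reported for reference
only; the linear-exponential (bell-shaped) and linear-plateau curves bound
the no-repair and full-repair assumptions.

The excess absolute risk then follows by direct proportionality,

    EAR = EAR0 * OED,

where EAR0 is the organ- and age-dependent low-dose baseline coefficient
(cases per 10,000 persons per year per Gy) from the A-bomb survivor
analyses.  The attained age is fixed at 70 years; exposure ages 30 and 50
are tabulated by default.  95% CI bounds on EAR0 propagate multiplicatively
(EAR_low = CI_low * OED); no distributional assumption is added.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import yaml

from .dvh import DoseVolumeHistogram, as_differential
from .errors import ConfigurationError, InputError, ParameterError

LINEAR = "linear"
LINEAR_EXPONENTIAL = "linear_exponential"
LINEAR_PLATEAU = "linear_plateau"
MODELS = (LINEAR, LINEAR_EXPONENTIAL, LINEAR_PLATEAU)

#: Accepted spellings for the dose-response models (config files, CLI).
MODEL_ALIASES = {
    "linear": LINEAR,
    "lin": LINEAR,
    "linear_exponential": LINEAR_EXPONENTIAL,
    "linear-exponential": LINEAR_EXPONENTIAL,
    "linear_exp": LINEAR_EXPONENTIAL,
    "linear-exp": LINEAR_EXPONENTIAL,
    "lin-exp": LINEAR_EXPONENTIAL,
    "lin_exp": LINEAR_EXPONENTIAL,
    "bell": LINEAR_EXPONENTIAL,
    "bell_shape": LINEAR_EXPONENTIAL,
    "bell-shape": LINEAR_EXPONENTIAL,
    "linear_plateau": LINEAR_PLATEAU,
    "linear-plateau": LINEAR_PLATEAU,
    "lin-plat": LINEAR_PLATEAU,
    "lin_plat": LINEAR_PLATEAU,
    "plateau": LINEAR_PLATEAU,
}

DEFAULT_ALPHA = 0.044  # 1/Gy
DEFAULT_DELTA = 0.139  # 1/Gy

ATTAINED_AGE = 70


def canonical_model(name: str) -> str:
    try:
        return MODEL_ALIASES[name.strip().lower()]
    except KeyError:
        raise ParameterError(
            f"unknown dose-response model {name!r}; known: {sorted(set(MODEL_ALIASES))}"
        ) from None


@dataclasses.dataclass(frozen=True)
class RiskModelParams:
    """Dose-response model identifier plus its shape parameters (1/Gy)."""

    model: str = LINEAR
    alpha: float = DEFAULT_ALPHA
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", canonical_model(self.model))
        if self.alpha <= 0 or self.delta <= 0:
            raise ParameterError("alpha and delta must be > 0")


def dose_response(dose, params: RiskModelParams):
    """Evaluate the model's dose-response kernel f(D) elementwise (Gy -> Gy)."""
    dose = np.asarray(dose, dtype=float)
    if params.model == LINEAR:
        return dose
    if params.model == LINEAR_EXPONENTIAL:
        return dose * np.exp(-params.alpha * dose)
    if params.model == LINEAR_PLATEAU:
        return -np.expm1(-params.delta * dose) / params.delta
    raise ParameterError(f"unknown model {params.model!r}")


def oed(dvh: DoseVolumeHistogram, params: RiskModelParams) -> float:
    """Organ equivalent dose in Gy for one organ DVH under one model."""
    d = as_differential(dvh)
    return float(np.dot(d.bin_values, dose_response(d.bin_centres, params)))


# ---------------------------------------------------------------------------
# Baseline risk coefficients
# ---------------------------------------------------------------------------

LUNG = "lung"
BREAST = "breast"


@dataclasses.dataclass(frozen=True)
class Ear0Entry:
    """EAR0 in cases per 10,000 persons per year per Gy, with its 95% CI."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low < self.value < self.ci_high):
            raise ParameterError(
                f"EAR0 CI must bracket the value: {self.ci_low} < {self.value} < {self.ci_high}"
            )


#: Female A-bomb-survivor low-dose coefficients at attained age 70.
DEFAULT_EAR0 = {
    (LUNG, 30, 70): Ear0Entry(7.5, 5.1, 10.0),
    (BREAST, 30, 70): Ear0Entry(9.2, 6.8, 12.0),
    (LUNG, 50, 70): Ear0Entry(7.8, 4.6, 12.0),
    (BREAST, 50, 70): Ear0Entry(3.7, 2.1, 5.9),
}


@dataclasses.dataclass
class BaselineRiskTable:
    """EAR0 coefficients keyed by (organ class, exposure age, attained age)."""

    entries: dict[tuple[str, int, int], Ear0Entry] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EAR0)
    )

    @classmethod
    def default(cls) -> "BaselineRiskTable":
        return cls()

    def lookup(
        self, organ_class: str, age_exposure: int, age_attained: int = ATTAINED_AGE
    ) -> Ear0Entry:
        key = (organ_class, int(age_exposure), int(age_attained))
        try:
            return self.entries[key]
        except KeyError:
            raise ConfigurationError(
                f"no EAR0 entry for {key}; supply extended entries to use other ages"
            ) from None

    @property
    def exposure_ages(self) -> tuple[int, ...]:
        return tuple(sorted({k[1] for k in self.entries}))


def organ_class(organ_id: str) -> str:
    """Map an organ label to its baseline-coefficient class.

    Both lungs map to the lung coefficients and the contralateral breast to
    the breast coefficients; no laterality adjustment is applied.
    """
    name = organ_id.strip().lower()
    if "lung" in name:
        return LUNG
    if "breast" in name:
        return BREAST
    raise ConfigurationError(f"no baseline-risk class for organ {organ_id!r}")


# ---------------------------------------------------------------------------
# EAR
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RiskEstimate:
    """EAR for one organ of one patient under one model and one exposure age.

    ``ear`` and its CI bounds are in cases per 10,000 persons per year,
    kept at full precision; round for table display only.
    """

    patient_id: str
    organ_id: str
    model: str
    oed: float
    ear: float
    age_exposure: int
    age_attained: int = ATTAINED_AGE
    ear_ci: tuple[float, float] | None = None


def ear_from_oed(oed_gy: float, ear0: float) -> float:
    """EAR = EAR0 * OED, in cases per 10,000 persons per year."""
    if oed_gy < 0:
        raise ParameterError("OED must be >= 0")
    if ear0 <= 0:
        raise ParameterError("EAR0 must be > 0")
    return ear0 * oed_gy


def risk_estimate(
    dvh: DoseVolumeHistogram,
    params: RiskModelParams,
    table: BaselineRiskTable,
    age_exposure: int,
    age_attained: int = ATTAINED_AGE,
) -> RiskEstimate:
    """Full Eq.-chain for one DVH: OED under ``params`` times the EAR0 entry."""
    entry = table.lookup(organ_class(dvh.organ_id), age_exposure, age_attained)
    oed_gy = oed(dvh, params)
    return RiskEstimate(
        patient_id=dvh.patient_id,
        organ_id=dvh.organ_id,
        model=params.model,
        oed=oed_gy,
        ear=ear_from_oed(oed_gy, entry.value),
        age_exposure=int(age_exposure),
        age_attained=int(age_attained),
        ear_ci=(entry.ci_low * oed_gy, entry.ci_high * oed_gy),
    )


def cumulative_ear(estimates: Iterable[RiskEstimate]) -> float:
    """Sum of organ EARs for one patient, one model, one exposure age."""
    estimates = list(estimates)
    if not estimates:
        return 0.0
    first = estimates[0]
    organs = set()
    for est in estimates:
        if (est.patient_id, est.model, est.age_exposure, est.age_attained) != (
            first.patient_id,
            first.model,
            first.age_exposure,
            first.age_attained,
        ):
            raise InputError(
                "cumulative EAR requires a single patient, model and age pair"
            )
        if est.organ_id in organs:
            raise InputError(f"duplicate organ {est.organ_id!r} in cumulative EAR")
        organs.add(est.organ_id)
    return float(sum(est.ear for est in estimates))


def delta_ear(ear_30_70: RiskEstimate, ear_50_70: RiskEstimate) -> float:
    """Age-dependence difference dEAR = EAR(30->70) - EAR(50->70).

    Both estimates must come from the same organ DVH and model, differing
    only in the exposure age (hence only in EAR0).
    """
    a, b = ear_30_70, ear_50_70
    if (a.patient_id, a.organ_id, a.model, a.age_attained) != (
        b.patient_id,
        b.organ_id,
        b.model,
        b.age_attained,
    ):
        raise InputError("delta EAR requires matching patient/organ/model")
    if (a.age_exposure, b.age_exposure) != (30, 50):
        raise InputError("delta EAR is defined as EAR(30-70) minus EAR(50-70)")
    return a.ear - b.ear


# ---------------------------------------------------------------------------
# Risk configuration
# ---------------------------------------------------------------------------

DISPERSION_SD = "sd"
DISPERSION_SEM = "sem"


@dataclasses.dataclass
class RiskConfig:
    """Run-level risk configuration; the defaults reproduce the study setup."""

    models: tuple[RiskModelParams, ...] = dataclasses.field(
        default_factory=lambda: tuple(RiskModelParams(m) for m in MODELS)
    )
    ear0_table: BaselineRiskTable = dataclasses.field(
        default_factory=BaselineRiskTable.default
    )
    ages_exposure: tuple[int, ...] = (30, 50)
    age_attained: int = ATTAINED_AGE
    dispersion: str = DISPERSION_SD

    def __post_init__(self) -> None:
        if self.dispersion not in (DISPERSION_SD, DISPERSION_SEM):
            raise ConfigurationError("dispersion must be 'sd' or 'sem'")


def load_risk_config(path=None) -> RiskConfig:
    """Load a YAML risk configuration; ``None`` gives the study defaults.

    Recognised keys: ``models`` (list of names), ``alpha``, ``delta``,
    ``ages_exposure``, ``age_attained``, ``dispersion``, and ``ear0`` as
    ``{organ: {age: {value: v, ci95: [lo, hi]}}}`` overrides.
    """
    if path is None:
        return RiskConfig()
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    alpha = float(raw.get("alpha", DEFAULT_ALPHA))
    delta = float(raw.get("delta", DEFAULT_DELTA))
    names = raw.get("models", list(MODELS))
    models = tuple(RiskModelParams(n, alpha=alpha, delta=delta) for n in names)
    age_attained = int(raw.get("age_attained", ATTAINED_AGE))
    table = BaselineRiskTable.default()
    for organ, by_age in (raw.get("ear0") or {}).items():
        for age, spec in by_age.items():
            value = float(spec["value"])
            lo, hi = (float(x) for x in spec.get("ci95", (value * 0.5, value * 1.5)))
            table.entries[(organ, int(age), age_attained)] = Ear0Entry(value, lo, hi)
    ages = tuple(int(a) for a in raw.get("ages_exposure", (30, 50)))
    for age in ages:
        for organ in (LUNG, BREAST):
            table.lookup(organ, age, age_attained)  # fail fast on missing entries
    return RiskConfig(
        models=models,
        ear0_table=table,
        ages_exposure=ages,
        age_attained=age_attained,
        dispersion=str(raw.get("dispersion", DISPERSION_SD)).lower(),
    )
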