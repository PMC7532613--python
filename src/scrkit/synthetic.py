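"""Synthetic DVH cohorts with the statistical structure of the study plans.

No per-patient clinical DVHs are published for the breast-radiotherapy
study this package analyses; this module generates stand-in cohorts so the
whole pipeline is exercisable and testable.  Each organ DVH is a
two-component mixture:

* a **high-dose component** — a scaled Beta distribution over
  ``(0, D_presc]`` carrying the volume fraction ``f_h`` adjacent to the
  target (steep photon/proton fall-off region);
* a **low-dose bath** — an exponential distribution truncated at
  ``D_presc`` carrying the remaining ``1 - f_h`` (scatter and
  out-of-field dose; wide for photon techniques, near zero for protons).

Per patient, the organ mean dose is drawn lognormally around the study
mean with a coefficient of variation matching the study's printed
dispersion, and the free mixture parameter (Beta mean, or bath scale for
bath-only organs) is solved numerically so that the *binned* DVH mean
equals the drawn value exactly.  Cohort draws use stratified lognormal
quantiles (one patient per probability stratum, strata shuffled), so even
a five-patient cohort is representative of the inter-patient distribution
and large-cohort means converge rapidly to the configured values.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .dvh import (
    DEFAULT_BIN_WIDTH,
    DoseVolumeHistogram,
    require_valid,
    write_dvh_csv,
)
from .errors import ConfigurationError

ORGANS = ("ipsilateral_lung", "contralateral_lung", "contralateral_breast")

PRESCRIPTION_GY = 50.0  # 2 Gy/fraction study prescription

#: Study organ mean doses in Gy as (mean, SEM with n=5) per
#: (group, technique, setup).  Proton doses are RBE-weighted (constant 1.1).
STUDY_MEAN_DOSES: dict[tuple[int, str, str], dict[str, tuple[float, float]]] = {
    (1, "PT", "FB"): {
        "ipsilateral_lung": (5.9, 2.1),
        "contralateral_lung": (0.08, 0.10),
        "contralateral_breast": (0.08, 0.03),
    },
    (1, "3DCRT", "FB"): {
        "ipsilateral_lung": (11.5, 1.1),
        "contralateral_lung": (0.6, 0.1),
        "contralateral_breast": (0.9, 0.1),
    },
    (2, "PT", "FB"): {
        "ipsilateral_lung": (8.4, 0.3),
        "contralateral_lung": (0.3, 0.1),
        "contralateral_breast": (0.09, 0.02),
    },
    (2, "VMAT", "FB"): {
        "ipsilateral_lung": (16.4, 1.6),
        "contralateral_lung": (7.3, 0.4),
        "contralateral_breast": (4.7, 0.3),
    },
    (2, "PT", "DIBH"): {
        "ipsilateral_lung": (7.4, 0.8),
        "contralateral_lung": (0.15, 0.02),
        "contralateral_breast": (0.07, 0.01),
    },
    (2, "VMAT", "DIBH"): {
        "ipsilateral_lung": (14.6, 0.9),
        "contralateral_lung": (6.2, 0.3),
        "contralateral_breast": (4.8, 0.3),
    },
}

STUDY_N = 5  # patients per group in the study


@dataclasses.dataclass
class OrganDoseProfile:
    """Dose-distribution shape and inter-patient statistics for one organ.

    ``high_dose_fraction`` and ``bath_mean`` set the mixture shape;
    ``kappa`` is the Beta concentration (a+b).  ``mean_dose`` is the cohort
    mean in Gy; ``cv`` the inter-patient coefficient of variation of the
    organ mean dose.  For bath-only organs (``high_dose_fraction = 0``) the
    bath scale is the calibrated free parameter and ``bath_mean`` is
    ignored.
    """

    organ_id: str
    mean_dose: float
    cv: float = 0.0
    high_dose_fraction: float = 0.0
    bath_mean: float = 0.0
    kappa: float = 3.0
    rbe_weighted: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.high_dose_fraction <= 1:
            raise ConfigurationError("high_dose_fraction must be in [0, 1]")
        if self.mean_dose < 0 or self.cv < 0 or self.bath_mean < 0:
            raise ConfigurationError("mean_dose, cv and bath_mean must be >= 0")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")


def default_profiles(
    group: int, technique: str, setup: str
) -> dict[str, OrganDoseProfile]:
    """Study-calibrated profiles for one (group, technique, setup) arm.

    Organ means and inter-patient CVs come from the study's dose table
    (CV = SEM * sqrt(5) / mean).  Shape parameters encode the qualitative
    DVH forms: ipsilateral lungs mix a target-adjacent high-dose component
    with a bath; contralateral organs are bath-only, with a near-zero bath
    for protons and an extended low-/intermediate-dose bath for photons.
    Combinations outside the study design raise a configuration error.
    """
    key = (int(group), technique.upper(), setup.upper())
    if key not in STUDY_MEAN_DOSES:
        raise ConfigurationError(
            f"combination {key} is outside the study design; valid: "
            f"{sorted(STUDY_MEAN_DOSES)}"
        )
    is_proton = key[1] == "PT"
    shapes = {
        "ipsilateral_lung": dict(
            high_dose_fraction=0.20 if is_proton else 0.35,
            bath_mean=0.3 if is_proton else 2.0,
            kappa=3.0,
        ),
        "contralateral_lung": dict(high_dose_fraction=0.0),
        "contralateral_breast": dict(high_dose_fraction=0.0),
    }
    profiles = {}
    for organ, (mean, sem) in STUDY_MEAN_DOSES[key].items():
        cv = sem * np.sqrt(STUDY_N) / mean
        profiles[organ] = OrganDoseProfile(
            organ_id=organ,
            mean_dose=mean,
            cv=float(cv),
            rbe_weighted=is_proton,
            **shapes[organ],
        )
    return profiles


@dataclasses.dataclass
class SyntheticCohortConfig:
    """One synthetic treatment arm: who is emulated and at what resolution."""

    group: int
    technique: str
    setup: str
    n_patients: int = STUDY_N
    prescription_gy: float = PRESCRIPTION_GY
    bin_width: float = DEFAULT_BIN_WIDTH
    seed: int = 0
    profiles: dict[str, OrganDoseProfile] | None = None
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.bin_width <= 0 or self.prescription_gy <= 0:
            raise ConfigurationError("bin_width and prescription_gy must be > 0")
        if self.profiles is None:
            self.profiles = default_profiles(self.group, self.technique, self.setup)

    @property
    def label(self) -> str:
        return f"Group{self.group}-{self.technique.upper()}-{self.setup.upper()}"

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            raw: Mapping = yaml.safe_load(fh) or {}
        kwargs = {
            k: raw[k]
            for k in (
                "group",
                "technique",
                "setup",
                "n_patients",
                "prescription_gy",
                "bin_width",
                "seed",
                "stratified",
            )
            if k in raw
        }
        if "profiles" in raw:
            kwargs["profiles"] = {
                organ: OrganDoseProfile(organ_id=organ, **spec)
                for organ, spec in raw["profiles"].items()
            }
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad synthetic-cohort config: {exc}") from None


# ---------------------------------------------------------------------------
# Mixture discretisation and calibration
# ---------------------------------------------------------------------------

def _grid(prescription: float, width: float) -> np.ndarray:
    n = int(np.ceil(prescription / width - 1e-9))
    return width * np.arange(n + 1)


def _bath_mass(edges: np.ndarray, scale: float) -> np.ndarray:
    """Exponential bath truncated at the last edge, renormalised per bin."""
    cdf = -np.expm1(-edges / scale)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:  # scale -> 0 underflow: everything in the first bin
        mass = np.zeros(len(edges) - 1)
        mass[0] = 1.0
        return mass
    return mass / total


def _beta_mass(edges: np.ndarray, mean: float, kappa: float) -> np.ndarray:
    """Scaled-Beta high-dose component over [0, D_presc], given its mean."""
    top = edges[-1]
    m = np.clip(mean / top, 1e-6, 1 - 1e-6)
    a, b = kappa * m, kappa * (1 - m)
    cdf = stats.beta.cdf(edges / top, a, b)
    mass = np.diff(cdf)
    return mass / mass.sum()


def _disc_mean(mass: np.ndarray, centres: np.ndarray) -> float:
    return float(np.dot(mass, centres))


def _solve_bath_scale(edges, centres, target: float) -> np.ndarray:
    """Bath mass whose binned mean equals ``target`` (monotone in scale)."""
    lo, hi = edges[1] / 100.0, 1e6
    f = lambda s: _disc_mean(_bath_mass(edges, s), centres) - target
    low, high = f(lo), f(hi)
    if low >= 0:  # target at/below the first-bin centre: all mass there
        return _bath_mass(edges, lo)
    if high <= 0:
        return _bath_mass(edges, hi)
    scale = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    return _bath_mass(edges, scale)


def _solve_beta_mean(edges, centres, kappa: float, target: float) -> np.ndarray:
    top = edges[-1]
    lo, hi = 0.002 * top, 0.985 * top
    f = lambda m: _disc_mean(_beta_mass(edges, m, kappa), centres) - target
    scale = optimize.brentq(f, lo, hi, xtol=1e-10)
    return _beta_mass(edges, scale, kappa)


def dvh_from_mean(
    profile: OrganDoseProfile,
    mu: float,
    *,
    prescription_gy: float = PRESCRIPTION_GY,
    bin_width: float = DEFAULT_BIN_WIDTH,
    patient_id: str = "",
) -> DoseVolumeHistogram:
    """Deterministic mixture DVH whose binned mean dose equals ``mu``.

    The free parameter is the Beta-component mean when the profile has a
    high-dose component, otherwise the bath scale.  If the required Beta
    mean exceeds the prescription-bounded range, the high-dose fraction is
    raised instead (keeping the mean exact); means below the reachable
    range fall back to a bath-only distribution.  A requested mean outside
    ``[0, D_presc)`` is a configuration error.

    For nearly unirradiated organs (mean below ten bin widths) the grid is
    refined to a tenth of the mean and, for bath-only profiles, truncated
    where the exponential tail vanishes, mirroring the fine low-dose
    resolution a planning system uses for out-of-field organs.
    """
    if mu < 0 or mu >= prescription_gy:
        raise ConfigurationError(
            f"infeasible mean dose {mu} Gy for prescription {prescription_gy} Gy"
        )
    meta = dict(
        organ_id=profile.organ_id,
        patient_id=patient_id,
        dose_is_rbe_weighted=profile.rbe_weighted,
    )
    if mu == 0:
        return DoseVolumeHistogram.uniform(0.0, **meta)
    if mu < 10 * bin_width:
        bin_width = mu / 10.0
    top = prescription_gy
    if profile.high_dose_fraction == 0:
        top = min(prescription_gy, max(60.0 * mu, 100.0 * bin_width))
    edges = _grid(top, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    f_h = profile.high_dose_fraction

    if f_h == 0:
        values = _solve_bath_scale(edges, centres, mu)
    else:
        bath = _bath_mass(edges, max(profile.bath_mean, 1e-6))
        bath_mean = _disc_mean(bath, centres)
        beta_lo = _disc_mean(_beta_mass(edges, 0.002 * edges[-1], profile.kappa), centres)
        beta_hi = _disc_mean(_beta_mass(edges, 0.985 * edges[-1], profile.kappa), centres)
        required = (mu - (1 - f_h) * bath_mean) / f_h
        if required > beta_hi:
            # steeper-than-profile patient: grow the high-dose fraction
            f_h = min(1.0, (mu - bath_mean) / (beta_hi - bath_mean))
            beta = _beta_mass(edges, 0.985 * edges[-1], profile.kappa)
        elif required < beta_lo:
            # mean dominated by the bath: drop the high-dose component
            return dvh_from_mean(
                dataclasses.replace(profile, high_dose_fraction=0.0),
                mu,
                prescription_gy=prescription_gy,
                bin_width=bin_width,
                patient_id=patient_id,
            )
        else:
            beta = _solve_beta_mean(edges, centres, profile.kappa, required)
        values = f_h * beta + (1 - f_h) * bath
    values = values / values.sum()
    return require_valid(DoseVolumeHistogram(bin_edges=edges, bin_values=values, **meta))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _feasible_range(prescription_gy: float, bin_width: float) -> tuple[float, float]:
    # the grid refines adaptively below ten bin widths, so only a token
    # positive floor is needed on the low side
    return 1e-6, 0.985 * prescription_gy


def sample_patient_means(
    profile: OrganDoseProfile,
    n: int,
    rng: np.random.Generator,
    *,
    stratified: bool = True,
    prescription_gy: float = PRESCRIPTION_GY,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Draw ``n`` per-patient organ mean doses (lognormal around the profile mean).

    With ``stratified=True`` one draw is taken per probability stratum
    (strata randomly assigned to patients), which keeps small cohorts
    representative.  Draws are clipped to the binned-DVH feasible range;
    the profile mean itself must be feasible.
    """
    lo, hi = _feasible_range(prescription_gy, bin_width)
    if profile.mean_dose > 0 and not (profile.mean_dose < hi):
        raise ConfigurationError(
            f"profile mean {profile.mean_dose} Gy cannot be represented below "
            f"the {prescription_gy} Gy prescription"
        )
    if profile.mean_dose == 0:
        return np.zeros(n)
    if profile.cv == 0:
        return np.full(n, profile.mean_dose)
    mu_ln, sigma = _lognormal_params(profile.mean_dose, profile.cv)
    if stratified:
        u = (np.arange(n) + rng.random(n)) / n
        u = rng.permutation(u)
        draws = stats.lognorm.ppf(u, s=sigma, scale=np.exp(mu_ln))
    else:
        draws = rng.lognormal(mean=mu_ln, sigma=sigma, size=n)
    return np.clip(draws, lo, hi)


def generate_patient_dvh(
    profile: OrganDoseProfile,
    rng: np.random.Generator,
    *,
    prescription_gy: float = PRESCRIPTION_GY,
    bin_width: float = DEFAULT_BIN_WIDTH,
    patient_id: str = "",
) -> DoseVolumeHistogram:
    """One independent patient draw: lognormal organ mean, calibrated mixture."""
    mu = sample_patient_means(
        profile,
        1,
        rng,
        stratified=False,
        prescription_gy=prescription_gy,
        bin_width=bin_width,
    )[0]
    return dvh_from_mean(
        profile,
        float(mu),
        prescription_gy=prescription_gy,
        bin_width=bin_width,
        patient_id=patient_id,
    )


def generate_cohort(config: SyntheticCohortConfig, out_dir=None):
    """Generate one synthetic treatment arm.

    Returns ``(cohort, manifest)`` where the cohort is a
    :class:`~scrkit.cohort.Cohort` and the manifest a DataFrame in the
    standard layout.  With ``out_dir`` set, per-organ DVH CSV files and a
    ``manifest.csv`` are written there; outputs are byte-reproducible for a
    fixed seed.
    """
    from .cohort import Cohort, PatientPlan  # local import to avoid a cycle

    master = np.random.SeedSequence(config.seed)
    organ_seqs = master.spawn(len(ORGANS))
    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    organ_dvhs: dict[str, list[DoseVolumeHistogram]] = {}
    for organ, seq in zip(ORGANS, organ_seqs):
        profile = config.profiles[organ]
        rng = np.random.default_rng(seq)
        means = sample_patient_means(
            profile,
            config.n_patients,
            rng,
            stratified=config.stratified,
            prescription_gy=config.prescription_gy,
            bin_width=config.bin_width,
        )
        organ_dvhs[organ] = [
            dvh_from_mean(
                profile,
                float(mu),
                prescription_gy=config.prescription_gy,
                bin_width=config.bin_width,
                patient_id=pid,
            )
            for pid, mu in zip(patient_ids, means)
        ]

    patients = [
        PatientPlan(
            patient_id=pid,
            dvhs={organ: organ_dvhs[organ][i] for organ in ORGANS},
        )
        for i, pid in enumerate(patient_ids)
    ]
    cohort = Cohort(
        label=config.label,
        group=config.group,
        technique=config.technique.upper(),
        setup=config.setup.upper(),
        patients=patients,
    )

    rows = []
    for patient in patients:
        for organ in ORGANS:
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "group": config.group,
                    "technique": cohort.technique,
                    "setup": cohort.setup,
                    "organ": organ,
                    "dvh_file": f"{patient.patient_id}_{organ}.csv",
                }
            )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for patient in patients:
            for organ in ORGANS:
                write_dvh_csv(
                    patient.dvhs[organ],
                    os.path.join(out_dir, f"{patient.patient_id}_{organ}.csv"),
                )
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        with open(os.path.join(out_dir, "provenance.yaml"), "w") as fh:
            yaml.safe_dump(
                {
                    "label": config.label,
                    "seed": config.seed,
                    "n_patients": config.n_patients,
                    "bin_width": config.bin_width,
                    "prescription_gy": config.prescription_gy,
                    "stratified": config.stratified,
                },
                fh,
                sort_keys=True,
            )
    return cohort, manifest


def fit_mixture(
    dvh: DoseVolumeHistogram,
    *,
    beta_mean: float,
    kappa: float = 3.0,
) -> tuple[float, float]:
    """Recover ``(high_dose_fraction, bath_mean)`` from a mixture DVH.

    Least-squares fit of the two-component model to the differential bin
    masses, with the Beta component's mean and concentration held at their
    known values.  The returned bath mean is the fitted exponential scale,
    directly comparable to :attr:`OrganDoseProfile.bath_mean`.  Used for
    generator self-consistency checks.
    """
    from .dvh import as_differential

    d = as_differential(dvh)
    edges = d.bin_edges
    beta = _beta_mass(edges, beta_mean, kappa)

    def residuals(theta):
        f_h, bath_scale = theta
        model = f_h * beta + (1 - f_h) * _bath_mass(edges, bath_scale)
        return model - d.bin_values

    result = optimize.least_squares(
        residuals,
        x0=[0.5, 1.0],
        bounds=([0.0, 1e-4], [1.0, 50.0]),
    )
    f_h, bath_scale = result.x
    return float(f_h), float(bath_scale)
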