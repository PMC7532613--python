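"""Cohort-level aggregation and treatment-technique comparison.

Summarises per-patient organ EARs into cohort tables (mean with SD and
SEM), computes cumulative EAR per patient (sum over the three organs at
risk), compares paired cohorts with relative risk factors and two-tail
paired Student t tests, and renders the report tables.

Two relative-factor conventions are computed for each comparison — the
ratio of cohort cumulative means (the headline value) and the mean +/- SEM
of per-patient cumulative ratios — because published "factor +/- error"
figures can follow either convention.  No multiple-testing correction is
applied; the report states the number of tests performed.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import DoseVolumeHistogram, mean_dose, read_dvh_csv
from .errors import InputError
from .risk import (
    BaselineRiskTable,
    RiskConfig,
    RiskEstimate,
    RiskModelParams,
    cumulative_ear,
    risk_estimate,
)

ORGANS = ("ipsilateral_lung", "contralateral_lung", "contralateral_breast")

SIGNIFICANCE_LEVEL = 0.05


@dataclasses.dataclass
class PatientPlan:
    """One patient's organ DVHs for one treatment plan."""

    patient_id: str
    dvhs: dict[str, DoseVolumeHistogram]


@dataclasses.dataclass
class Cohort:
    """A set of patients planned with one technique/setup for one group."""

    label: str
    group: int
    technique: str
    setup: str
    patients: list[PatientPlan]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise InputError(f"duplicate patient ids in cohort {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


def _require_organs(cohort: Cohort, organs: Sequence[str]) -> None:
    for patient in cohort.patients:
        for organ in organs:
            if organ not in patient.dvhs:
                raise InputError(
                    f"patient {patient.patient_id!r} in cohort {cohort.label!r} "
                    f"has no DVH for organ {organ!r}"
                )


def patient_estimates(
    cohort: Cohort,
    params: RiskModelParams,
    table: BaselineRiskTable,
    age_exposure: int,
    organs: Sequence[str] = ORGANS,
) -> dict[str, dict[str, RiskEstimate]]:
    """Per-patient, per-organ risk estimates for one model and exposure age."""
    _require_organs(cohort, organs)
    return {
        patient.patient_id: {
            organ: risk_estimate(patient.dvhs[organ], params, table, age_exposure)
            for organ in organs
        }
        for patient in cohort.patients
    }


@dataclasses.dataclass
class CohortSummary:
    """Per-organ and cumulative EAR statistics over one cohort.

    Means are arithmetic over patients; both SD (ddof=1) and SEM = SD/sqrt(n)
    are carried.  Cumulative EAR is summed per patient then averaged, which
    by linearity equals the sum of the organ means.
    """

    label: str
    model: str
    age_exposure: int
    n: int
    patient_ids: list[str]
    organ_ear: pd.DataFrame  # index organ, columns mean/sd/sem
    organ_ear_per_patient: pd.DataFrame  # index patient, columns organ
    cumulative_per_patient: np.ndarray
    cumulative_mean: float
    cumulative_sd: float
    cumulative_sem: float


def summarize_cohort(
    cohort: Cohort,
    params: RiskModelParams,
    table: BaselineRiskTable,
    age_exposure: int,
    organs: Sequence[str] = ORGANS,
) -> CohortSummary:
    if cohort.n < 2:
        raise InputError(
            f"cohort {cohort.label!r} has {cohort.n} patient(s); dispersion "
            "statistics need at least 2"
        )
    estimates = patient_estimates(cohort, params, table, age_exposure, organs)
    per_patient = pd.DataFrame(
        {
            pid: {organ: est.ear for organ, est in by_organ.items()}
            for pid, by_organ in estimates.items()
        }
    ).T.loc[cohort.patient_ids, list(organs)]
    cumulative = np.array(
        [cumulative_ear(by_organ.values()) for by_organ in estimates.values()]
    )
    organ_stats = pd.DataFrame(
        {
            "mean": per_patient.mean(axis=0),
            "sd": per_patient.std(axis=0, ddof=1),
            "sem": per_patient.sem(axis=0, ddof=1),
        }
    )
    return CohortSummary(
        label=cohort.label,
        model=params.model,
        age_exposure=age_exposure,
        n=cohort.n,
        patient_ids=cohort.patient_ids,
        organ_ear=organ_stats,
        organ_ear_per_patient=per_patient,
        cumulative_per_patient=cumulative,
        cumulative_mean=float(cumulative.mean()),
        cumulative_sd=float(cumulative.std(ddof=1)),
        cumulative_sem=float(cumulative.std(ddof=1) / np.sqrt(cohort.n)),
    )


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    dof: int
    degenerate: bool = False  # all pairwise differences identical

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


def paired_t_test(a: Iterable[float], b: Iterable[float]) -> PairedTResult:
    """Two-tail paired Student t test on per-patient values.

    Zero-variance differences (e.g. identical synthetic patients) are a
    degenerate case: p = 1 is returned with the ``degenerate`` flag set
    rather than raising, so pipelines over synthetic data keep running.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise InputError("paired t test needs equal-length paired samples")
    n = len(a)
    if n < 2:
        raise InputError("paired t test needs at least 2 pairs")
    diff = a - b
    if np.allclose(diff, diff[0], rtol=0.0, atol=1e-12 * max(1.0, np.abs(diff).max())):
        return PairedTResult(t=np.nan, p=1.0, dof=n - 1, degenerate=True)
    res = sps.ttest_rel(a, b)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), dof=n - 1)


@dataclasses.dataclass
class ComparisonResult:
    """Relative risk of cohort A versus cohort B under one model."""

    label_a: str
    label_b: str
    model: str
    age_exposure: int
    factor_ratio_of_means: float
    factor_per_patient_mean: float
    factor_per_patient_sem: float
    t_test: PairedTResult
    organ_t_tests: dict[str, PairedTResult]

    @property
    def p_value(self) -> float:
        return self.t_test.p

    @property
    def significant(self) -> bool:
        return self.t_test.significant


def relative_factor(ears_a: Iterable[float], ears_b: Iterable[float]):
    """Both relative-factor conventions for paired per-patient EARs (A / B).

    Returns ``(ratio_of_means, per_patient_mean, per_patient_sem)``.  The
    ratio of cohort means is the headline value.
    """
    a = np.asarray(list(ears_a), dtype=float)
    b = np.asarray(list(ears_b), dtype=float)
    if a.shape != b.shape:
        raise InputError("relative factor needs paired samples of equal length")
    if b.mean() == 0:
        raise InputError("relative factor undefined: comparison cohort mean EAR is 0")
    ratio_of_means = float(a.mean() / b.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_patient = np.where(b != 0, a / np.where(b != 0, b, 1.0), np.nan)
    pp_mean = float(np.nanmean(per_patient))
    n_valid = int(np.sum(~np.isnan(per_patient)))
    pp_sem = (
        float(np.nanstd(per_patient, ddof=1) / np.sqrt(n_valid))
        if n_valid > 1
        else float("nan")
    )
    return ratio_of_means, pp_mean, pp_sem


def compare_cohorts(
    a: Cohort,
    b: Cohort,
    params: RiskModelParams,
    table: BaselineRiskTable,
    age_exposure: int,
    organs: Sequence[str] = ORGANS,
) -> ComparisonResult:
    """Cumulative-EAR comparison of two paired cohorts (A relative to B)."""
    if a.n != b.n:
        raise InputError(
            f"cohorts {a.label!r} and {b.label!r} are not paired ({a.n} vs {b.n} patients)"
        )
    sa = summarize_cohort(a, params, table, age_exposure, organs)
    sb = summarize_cohort(b, params, table, age_exposure, organs)
    rom, ppm, pps = relative_factor(sa.cumulative_per_patient, sb.cumulative_per_patient)
    organ_tests = {
        organ: paired_t_test(
            sa.organ_ear_per_patient[organ], sb.organ_ear_per_patient[organ]
        )
        for organ in organs
    }
    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        model=params.model,
        age_exposure=age_exposure,
        factor_ratio_of_means=rom,
        factor_per_patient_mean=ppm,
        factor_per_patient_sem=pps,
        t_test=paired_t_test(sa.cumulative_per_patient, sb.cumulative_per_patient),
        organ_t_tests=organ_tests,
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("patient_id", "group", "technique", "setup", "organ", "dvh_file")


def load_manifest(path) -> list[Cohort]:
    """Read a cohort manifest CSV and the DVH files it references.

    Columns: ``patient_id, group, technique, setup, organ, dvh_file``; DVH
    paths are resolved relative to the manifest's directory.  Rows are
    grouped into one cohort per (group, technique, setup).
    """
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest {path} lacks columns {missing}")
    base = os.path.dirname(os.path.abspath(path))
    cohorts = []
    for (group, technique, setup), rows in manifest.groupby(
        ["group", "technique", "setup"], sort=False
    ):
        patients = []
        for pid, organ_rows in rows.groupby("patient_id", sort=False):
            dvhs = {}
            for _, row in organ_rows.iterrows():
                fpath = os.path.join(base, row["dvh_file"])
                if not os.path.exists(fpath):
                    raise InputError(f"DVH file not found: {row['dvh_file']}")
                dvh = read_dvh_csv(fpath)
                dvhs[row["organ"]] = dvh.replace(
                    organ_id=row["organ"], patient_id=str(pid)
                )
            patients.append(PatientPlan(patient_id=str(pid), dvhs=dvhs))
        cohorts.append(
            Cohort(
                label=f"Group{group}-{technique}-{setup}",
                group=int(group),
                technique=str(technique),
                setup=str(setup),
                patients=patients,
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RiskReport:
    """Machine- and human-readable report tables for a set of cohorts."""

    mean_dose: pd.DataFrame
    organ_ear: pd.DataFrame
    cumulative: pd.DataFrame
    comparisons: pd.DataFrame
    delta_ear: pd.DataFrame
    n_tests: int
    dispersion: str

    def to_text(self) -> str:
        parts = []

        def fmt(title, df):
            parts.append(title)
            parts.append(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
            parts.append("")

        fmt("Mean organ dose (Gy)", self.mean_dose)
        fmt(
            "Per-organ EAR (cases per 10,000 persons per year); "
            "the linear model is reference only",
            self.organ_ear,
        )
        fmt("Cumulative EAR (cases per 10,000 persons per year)", self.cumulative)
        if len(self.comparisons):
            fmt("Technique comparisons", self.comparisons)
        if len(self.delta_ear):
            fmt("Age dependence: dEAR = EAR(30-70) - EAR(50-70)", self.delta_ear)
        parts.append(
            f"{self.n_tests} paired t tests performed; no multiple-testing "
            "correction applied."
        )
        return "\n".join(parts)

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in ("mean_dose", "organ_ear", "cumulative", "comparisons", "delta_ear"):
            getattr(self, name).to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(self.to_text() + "\n")


def _comparable_pairs(cohorts: list[Cohort]) -> list[tuple[Cohort, Cohort]]:
    """(photon, proton) pairs sharing group and setup, photon first."""
    pairs = []
    by_key = {(c.group, c.technique, c.setup): c for c in cohorts}
    for (group, technique, setup), photon in by_key.items():
        if technique == "PT":
            continue
        proton = by_key.get((group, "PT", setup))
        if proton is not None and proton.n == photon.n:
            pairs.append((photon, proton))
    return pairs


def build_report(
    cohorts: list[Cohort],
    config: RiskConfig | None = None,
    organs: Sequence[str] = ORGANS,
) -> RiskReport:
    """Assemble dose, EAR, comparison and age-dependence tables.

    With a single cohort only the dose/EAR tables are populated.  EARs are
    computed at every configured exposure age; comparisons pair each photon
    cohort with the proton cohort of the same group and setup.
    """
    config = config or RiskConfig()
    table = config.ear0_table

    dose_rows = []
    for cohort in cohorts:
        _require_organs(cohort, organs)
        for organ in organs:
            doses = np.array([mean_dose(p.dvhs[organ]) for p in cohort.patients])
            dose_rows.append(
                {
                    "cohort": cohort.label,
                    "organ": organ,
                    "mean_dose_gy": doses.mean(),
                    "sd": doses.std(ddof=1) if cohort.n > 1 else np.nan,
                    "sem": (
                        doses.std(ddof=1) / np.sqrt(cohort.n) if cohort.n > 1 else np.nan
                    ),
                    "n": cohort.n,
                }
            )

    organ_rows, cum_rows, delta_rows = [], [], []
    summaries: dict[tuple[str, str, int], CohortSummary] = {}
    for cohort in cohorts:
        for params in config.models:
            for age in config.ages_exposure:
                s = summarize_cohort(cohort, params, table, age, organs)
                summaries[(cohort.label, params.model, age)] = s
                for organ in organs:
                    organ_rows.append(
                        {
                            "cohort": cohort.label,
                            "model": params.model,
                            "age_exposure": age,
                            "organ": organ,
                            "mean_ear": s.organ_ear.loc[organ, "mean"],
                            "sd": s.organ_ear.loc[organ, "sd"],
                            "sem": s.organ_ear.loc[organ, "sem"],
                        }
                    )
                cum_rows.append(
                    {
                        "cohort": cohort.label,
                        "model": params.model,
                        "age_exposure": age,
                        "cumulative_ear": s.cumulative_mean,
                        "sd": s.cumulative_sd,
                        "sem": s.cumulative_sem,
                    }
                )
            if set(config.ages_exposure) >= {30, 50}:
                s30 = summaries[(cohort.label, params.model, 30)]
                s50 = summaries[(cohort.label, params.model, 50)]
                for pid in cohort.patient_ids:
                    for organ in organs:
                        e30 = s30.organ_ear_per_patient.loc[pid, organ]
                        e50 = s50.organ_ear_per_patient.loc[pid, organ]
                        delta_rows.append(
                            {
                                "cohort": cohort.label,
                                "patient_id": pid,
                                "organ": organ,
                                "model": params.model,
                                "ear_30_70": e30,
                                "ear_50_70": e50,
                                "delta_ear": e30 - e50,
                            }
                        )

    comp_rows = []
    n_tests = 0
    for photon, proton in _comparable_pairs(cohorts):
        for params in config.models:
            for age in config.ages_exposure:
                result = compare_cohorts(photon, proton, params, table, age, organs)
                n_tests += 1 + len(result.organ_t_tests)
                comp_rows.append(
                    {
                        "cohort_a": result.label_a,
                        "cohort_b": result.label_b,
                        "model": result.model,
                        "age_exposure": age,
                        "factor_ratio_of_means": result.factor_ratio_of_means,
                        "factor_per_patient_mean": result.factor_per_patient_mean,
                        "factor_per_patient_sem": result.factor_per_patient_sem,
                        "p_value": result.p_value,
                        "significant": result.significant,
                        "degenerate_t": result.t_test.degenerate,
                    }
                )

    return RiskReport(
        mean_dose=pd.DataFrame(dose_rows),
        organ_ear=pd.DataFrame(organ_rows),
        cumulative=pd.DataFrame(cum_rows),
        comparisons=pd.DataFrame(
            comp_rows,
            columns=[
                "cohort_a",
                "cohort_b",
                "model",
                "age_exposure",
                "factor_ratio_of_means",
                "factor_per_patient_mean",
                "factor_per_patient_sem",
                "p_value",
                "significant",
                "degenerate_t",
            ],
        ),
        delta_ear=pd.DataFrame(
            delta_rows,
            columns=[
                "cohort",
                "patient_id",
                "organ",
                "model",
                "ear_30_70",
                "ear_50_70",
                "delta_ear",
            ],
        ),
        n_tests=n_tests,
        dispersion=config.dispersion,
    )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_cohort_dvhs(cohorts: list[Cohort], path, organs: Sequence[str] = ORGANS):
    """Patient-averaged cumulative DVHs per organ, one panel per organ."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dvh import differential_to_cumulative

    fig, axes = plt.subplots(len(organs), 1, figsize=(6, 3 * len(organs)), sharex=False)
    axes = np.atleast_1d(axes)
    for ax, organ in zip(axes, organs):
        for cohort in cohorts:
            curves = []
            for patient in cohort.patients:
                c = differential_to_cumulative(patient.dvhs[organ])
                curves.append(np.interp(
                    np.linspace(0, 50, 501), c.bin_edges, c.bin_values
                ))
            ax.plot(np.linspace(0, 50, 501), np.mean(curves, axis=0), label=cohort.label)
        ax.set_title(organ)
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume fraction >= dose")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_delta_ear(report: RiskReport, path, organ: str = "contralateral_breast"):
    """Per-patient dEAR for one organ across cohorts and models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.delta_ear[report.delta_ear["organ"] == organ]
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (label, rows) in enumerate(df.groupby(["cohort", "model"], sort=False)):
        x = np.full(len(rows), i)
        ax.plot(x, rows["delta_ear"], "o", ms=4)
    ax.set_xticks(range(df.groupby(["cohort", "model"]).ngroups))
    ax.set_xticklabels(
        [f"{c}\n{m}" for c, m in df.groupby(["cohort", "model"], sort=False).groups],
        fontsize=6,
        rotation=45,
    )
    ax.set_ylabel("dEAR (cases per 10,000 persons per year)")
    ax.set_title(f"Age dependence of EAR: {organ}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
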