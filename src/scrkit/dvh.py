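"""Dose-volume histogram (DVH) data model, validation and conversions.

A DVH describes how absorbed dose is distributed over an organ's volume.
Two equivalent forms are supported:

* **differential** — ``bin_values[i]`` is the fraction of the organ volume
  receiving a dose inside bin ``[bin_edges[i], bin_edges[i+1])``
  (``n`` values for ``n+1`` edges);
* **cumulative** — ``bin_values[k]`` is the fraction of the organ volume
  receiving at least ``bin_edges[k]`` (``n+1`` values, non-increasing,
  starting at 1 for a fully scored organ).

Volumes are stored as fractions of the organ volume; the absolute organ
volume in cm^3 is optional metadata.  All doses are in Gy (for proton plans
these are RBE-weighted Gy values, flagged but never converted).  The
representative dose of a bin is its centre.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .errors import DVHValidationError, ParameterError

DIFFERENTIAL = "differential"
CUMULATIVE = "cumulative"

#: Tolerance on the differential normalisation (volume fractions sum to 1).
NORMALIZATION_TOL = 1e-9
#: Default dose-bin width in Gy for generated/binned DVHs.
DEFAULT_BIN_WIDTH = 0.05
#: Width of the degenerate bin used to represent a single-dose spike.
SPIKE_WIDTH = 1e-12


@dataclasses.dataclass(frozen=True)
class Violation:
    """One failed DVH invariant: the rule name and the offending index."""

    rule: str
    index: int | None = None
    detail: str = ""

    def __str__(self) -> str:
        loc = f" at index {self.index}" if self.index is not None else ""
        det = f" ({self.detail})" if self.detail else ""
        return f"{self.rule}{loc}{det}"


@dataclasses.dataclass
class DoseVolumeHistogram:
    """Binned dose-to-volume distribution for one organ of one plan."""

    bin_edges: np.ndarray
    bin_values: np.ndarray
    form: str = DIFFERENTIAL
    organ_id: str = ""
    patient_id: str = ""
    total_volume_cm3: float | None = None
    dose_is_rbe_weighted: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)

    # -- basic geometry -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def replace(self, **changes) -> "DoseVolumeHistogram":
        return dataclasses.replace(self, **changes)

    # -- constructors ---------------------------------------------------

    @classmethod
    def uniform(
        cls,
        dose: float,
        *,
        organ_id: str = "",
        patient_id: str = "",
        width: float = SPIKE_WIDTH,
        **kwargs,
    ) -> "DoseVolumeHistogram":
        """DVH of an organ uniformly irradiated at ``dose`` Gy.

        The whole volume sits in one near-degenerate bin centred on
        ``dose`` (clipped at 0 for doses below half the spike width), so
        the mean dose and all dose-response evaluations see the nominal
        dose to within ``width / 2``.
        """
        if dose < 0:
            raise ParameterError(f"uniform dose must be >= 0, got {dose}")
        half = width / 2.0
        lo = max(0.0, dose - half)
        edges = np.array([lo, lo + width])
        return cls(
            bin_edges=edges,
            bin_values=np.array([1.0]),
            form=DIFFERENTIAL,
            organ_id=organ_id,
            patient_id=patient_id,
            **kwargs,
        )

    @classmethod
    def from_voxel_doses(
        cls,
        doses: Iterable[float],
        bin_width: float = DEFAULT_BIN_WIDTH,
        *,
        organ_id: str = "",
        patient_id: str = "",
        **kwargs,
    ) -> "DoseVolumeHistogram":
        """Bin an explicit per-voxel dose list into a differential DVH."""
        doses = np.asarray(list(doses), dtype=float)
        if doses.size == 0:
            raise ParameterError("voxel dose list is empty")
        if bin_width <= 0:
            raise ParameterError("bin_width must be > 0")
        if np.any(doses < 0):
            raise ParameterError("voxel doses must be >= 0")
        n = int(np.floor(doses.max() / bin_width)) + 1
        edges = bin_width * np.arange(n + 1)
        counts, _ = np.histogram(doses, bins=edges)
        return cls(
            bin_edges=edges,
            bin_values=counts / doses.size,
            form=DIFFERENTIAL,
            organ_id=organ_id,
            patient_id=patient_id,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dvh(dvh: DoseVolumeHistogram) -> list[Violation]:
    """Check all DVH invariants; return the (possibly empty) violation list.

    Violations are reported, never silently repaired; callers decide.
    """
    v: list[Violation] = []
    edges = dvh.bin_edges
    values = dvh.bin_values

    if dvh.form not in (DIFFERENTIAL, CUMULATIVE):
        v.append(Violation("form", detail=f"unknown form {dvh.form!r}"))
        return v
    if edges.ndim != 1 or len(edges) < 2:
        v.append(Violation("shape", detail="need at least two dose edges"))
        return v
    if not np.all(np.isfinite(edges)):
        v.append(Violation("dose_edges", detail="non-finite edge"))
        return v
    if edges[0] < 0:
        v.append(Violation("dose_edges", index=0, detail="negative dose"))
    bad = np.nonzero(np.diff(edges) <= 0)[0]
    if bad.size:
        v.append(
            Violation(
                "dose_edges", index=int(bad[0]) + 1, detail="not strictly increasing"
            )
        )
    if not np.all(np.isfinite(values)):
        v.append(Violation("values", detail="non-finite bin value"))
        return v

    if dvh.form == DIFFERENTIAL:
        if len(values) != len(edges) - 1:
            v.append(
                Violation(
                    "shape",
                    detail=f"differential needs {len(edges) - 1} values, got {len(values)}",
                )
            )
            return v
        neg = np.nonzero(values < 0)[0]
        if neg.size:
            v.append(Violation("negative_volume", index=int(neg[0])))
        total = float(values.sum())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            v.append(
                Violation("normalization", detail=f"volume fractions sum to {total:.12g}")
            )
    else:  # cumulative
        if len(values) != len(edges):
            v.append(
                Violation(
                    "shape",
                    detail=f"cumulative needs {len(edges)} values, got {len(values)}",
                )
            )
            return v
        out = np.nonzero((values < -NORMALIZATION_TOL) | (values > 1 + NORMALIZATION_TOL))[0]
        if out.size:
            v.append(Violation("range", index=int(out[0])))
        rising = np.nonzero(np.diff(values) > NORMALIZATION_TOL)[0]
        if rising.size:
            v.append(Violation("monotonicity", index=int(rising[0]) + 1))
        if abs(values[0] - 1.0) > NORMALIZATION_TOL:
            v.append(Violation("first_value", index=0, detail=f"{values[0]:.12g} != 1"))

    if dvh.total_volume_cm3 is not None and dvh.total_volume_cm3 <= 0:
        v.append(Violation("total_volume", detail="must be > 0 when present"))
    return v


def require_valid(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    violations = validate_dvh(dvh)
    if violations:
        raise DVHValidationError(violations)
    return dvh


# ---------------------------------------------------------------------------
# Conversions and summaries
# ---------------------------------------------------------------------------

def cumulative_to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Finite-difference a cumulative DVH into differential form.

    ``differential[i] = cumulative(edge_i) - cumulative(edge_{i+1})``.
    Volume beyond the last edge (``cumulative[-1]`` if nonzero) is dropped;
    for DVHs that score the full organ it is zero.
    """
    require_valid(dvh)
    if dvh.form == DIFFERENTIAL:
        return dvh
    values = -np.diff(dvh.bin_values)
    # floating-point jitter may produce -1e-30-sized negatives
    values = np.where(np.abs(values) < 1e-15, np.abs(values), values)
    return dvh.replace(bin_values=values, form=DIFFERENTIAL)


def differential_to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Accumulate a differential DVH: ``cumulative(edge_k) = sum_{i>=k} v_i``."""
    require_valid(dvh)
    if dvh.form == CUMULATIVE:
        return dvh
    tail = np.concatenate([np.cumsum(dvh.bin_values[::-1])[::-1], [0.0]])
    return dvh.replace(bin_values=tail, form=CUMULATIVE)


def as_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    return cumulative_to_differential(dvh)


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Volume-weighted mean dose in Gy: ``sum_i v_i * D_i`` at bin centres."""
    d = as_differential(dvh)
    return float(np.dot(d.bin_values, d.bin_centres))


def rebin(dvh: DoseVolumeHistogram, new_bin_width: float) -> DoseVolumeHistogram:
    """Rebin onto a uniform grid of width ``new_bin_width``.

    Each bin's volume is treated as concentrated at its representative
    centre dose and reassigned to the new bin containing that centre, so
    total volume is conserved exactly and the mean dose moves by at most
    half the coarser bin width.  The new grid starts at the old first edge.
    """
    if new_bin_width <= 0:
        raise ParameterError("new_bin_width must be > 0")
    d = as_differential(dvh)
    require_valid(d)
    start = d.bin_edges[0]
    span = d.bin_edges[-1] - start
    n_new = max(1, int(np.ceil(span / new_bin_width - 1e-12)))
    new_edges = start + new_bin_width * np.arange(n_new + 1)
    idx = np.clip(
        np.floor((d.bin_centres - start) / new_bin_width).astype(int), 0, n_new - 1
    )
    new_values = np.bincount(idx, weights=d.bin_values, minlength=n_new)
    out = d.replace(bin_edges=new_edges, bin_values=new_values)
    if dvh.form == CUMULATIVE:
        out = differential_to_cumulative(out)
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# One DVH per file.  Header lines:
#   # patient=<id>
#   # organ=<name>
#   # form=differential|cumulative
#   # dose_unit=Gy
# then a `dose_gy,volume_fraction` column header and one row per dose edge.
# Differential files carry n+1 rows: row i gives the lower edge and the
# volume fraction of bin i; the final row is the upper edge with volume 0.
# Floats are written with repr so read/write round-trips bit-exactly.

def write_dvh_csv(dvh: DoseVolumeHistogram, path) -> None:
    require_valid(dvh)
    lines = [
        f"# patient={dvh.patient_id}",
        f"# organ={dvh.organ_id}",
        f"# form={dvh.form}",
        "# dose_unit=Gy",
    ]
    if dvh.total_volume_cm3 is not None:
        lines.append(f"# total_volume_cm3={dvh.total_volume_cm3!r}")
    if dvh.dose_is_rbe_weighted:
        lines.append("# rbe_weighted=true")
    lines.append("dose_gy,volume_fraction")
    if dvh.form == DIFFERENTIAL:
        values = np.concatenate([dvh.bin_values, [0.0]])
    else:
        values = dvh.bin_values
    for dose, vol in zip(dvh.bin_edges, values):
        lines.append(f"{float(dose)!r},{float(vol)!r}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dvh_csv(path) -> DoseVolumeHistogram:
    meta: dict[str, str] = {}
    doses: list[float] = []
    vols: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif line.startswith("dose_gy"):
                continue
            else:
                a, _, b = line.partition(",")
                doses.append(float(a))
                vols.append(float(b))
    form = meta.get("form", DIFFERENTIAL)
    edges = np.array(doses)
    values = np.array(vols)
    if form == DIFFERENTIAL:
        values = values[:-1]
    dvh = DoseVolumeHistogram(
        bin_edges=edges,
        bin_values=values,
        form=form,
        organ_id=meta.get("organ", ""),
        patient_id=meta.get("patient", ""),
        total_volume_cm3=(
            float(meta["total_volume_cm3"]) if "total_volume_cm3" in meta else None
        ),
        dose_is_rbe_weighted=meta.get("rbe_weighted", "false") == "true",
    )
    return require_valid(dvh)
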