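"""Standardization of heterogeneous in vivo kinetic observations.

Literature kinetic studies report amounts in incompatible units
(concentrations, tissue levels, percent of dose, mass-spectrometric peak
area ratios).  For joint likelihood use everything is converted into the
common base unit *amount of substance* (nmol); every record carries the
conversion chain that produced it.  Summary records (mean, sd, n) are
"de-aggregated" into pseudo-individual values whose empirical mean and
standard deviation match the reported summary exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["KineticObservation", "KineticDataset", "standardize_units",
           "deaggregate_summary", "UnsupportedUnitError"]

MATRICES = ("plasma", "liver", "urine", "bile", "dhr_gsh", "dhr_prot", "dhr_dna")
ROUTES = ("iv", "ip", "po")
#: units convertible to nmol; peak-area ratios stay relative
SUPPORTED_UNITS = ("nmol", "ug", "ug_per_ml", "ng_per_g", "percent_dose",
                   "peak_area_ratio")


class UnsupportedUnitError(ValueError):
    pass


@dataclass(frozen=True)
class KineticObservation:
    """One reported kinetic measurement, individual or summary form."""

    study_id: str
    species_id: str
    matrix: str
    route: str
    dose: float                  # mg/kg bodyweight
    time: float                  # h
    value: float
    unit: str
    n: int = 1
    sd: float | None = None
    function: str = "training"   # or "evaluation"
    excluded: bool = False
    relative: bool = False       # peak-area-ratio records stay unconverted
    conversion: tuple = ()

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if (self.sd is not None) != (self.n > 1):
            raise ValueError("sd must be present exactly when n > 1")


def standardize_units(obs: KineticObservation, compound, physiology) -> KineticObservation:
    """Convert one observation to nmol, logging the conversion chain.

    Supported dialects: ``nmol`` (identity), ``ug`` (mass → moles),
    ``ug_per_ml`` (× matrix volume from physiology), ``ng_per_g``
    (× organ mass, tissue density 1 g/mL), ``percent_dose`` (× administered
    dose in nmol) and ``peak_area_ratio`` (passed through, flagged
    relative).  Anything else raises :class:`UnsupportedUnitError`.
    """
    mw = compound.molar_mass
    trace: list[str] = []
    unit = obs.unit
    value, sd = obs.value, obs.sd

    def scale(factor: float, note: str):
        nonlocal value, sd
        value *= factor
        if sd is not None:
            sd *= factor
        trace.append(note)

    if unit == "nmol":
        trace.append("identity")
    elif unit == "ug":
        scale(1000.0 / mw, f"ug -> nmol via molar mass {mw} g/mol")
    elif unit == "ug_per_ml":
        volume = _matrix_volume(obs.matrix, physiology)
        scale(volume * 1000.0 / mw,
              f"ug/mL x {volume:.4g} mL {obs.matrix} -> nmol via molar mass {mw}")
    elif unit == "ng_per_g":
        mass = _matrix_mass_g(obs.matrix, physiology)
        scale(mass / mw, f"ng/g x {mass:.4g} g {obs.matrix} -> nmol via molar mass {mw}")
    elif unit == "percent_dose":
        from .units import dose_mgkg_to_nmol
        dose_nmol = dose_mgkg_to_nmol(obs.dose, physiology.bodyweight, mw)
        scale(dose_nmol / 100.0, f"% of dose x {dose_nmol:.6g} nmol")
    elif unit == "peak_area_ratio":
        return replace(obs, relative=True,
                       conversion=("relative unit: passed through unconverted",))
    else:
        raise UnsupportedUnitError(
            f"unit {unit!r} is not supported (supported: {SUPPORTED_UNITS})")
    return replace(obs, value=value, sd=sd, unit="nmol", conversion=tuple(trace))


def _matrix_volume(matrix: str, physiology) -> float:
    if matrix == "plasma":
        return physiology.tissue_volumes["plasma"]
    if matrix == "liver":
        return physiology.tissue_volumes["liver"]
    raise UnsupportedUnitError(f"no reference volume for matrix {matrix!r}")


def _matrix_mass_g(matrix: str, physiology) -> float:
    if matrix == "liver":
        return physiology.liver_mass
    if matrix in ("dhr_gsh", "dhr_prot", "dhr_dna"):
        return physiology.liver_mass       # hepatic metabolite levels per g liver
    raise UnsupportedUnitError(f"no reference mass for matrix {matrix!r}")


def deaggregate_summary(mean: float, sd: float, n: int, seed: int,
                        max_attempts: int = 100) -> np.ndarray:
    """Expand a (mean, sd, n) summary into n pseudo-individual values.

    Values are drawn from a normal distribution and affinely rescaled so
    the empirical mean and (ddof=1) standard deviation equal the inputs
    exactly; negative values trigger redraws, then a truncated-normal
    fallback whose rescaling is iterated while any value would go
    negative.  Reproducible under ``seed``.
    """
    if n < 2:
        raise ValueError("summaries need n >= 2; use the individual-record path")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        return np.full(n, mean)

    def rescale(x):
        x = x - x.mean()
        s = x.std(ddof=1)
        return mean + (x / s) * sd if s > 0 else None

    for _ in range(max_attempts):
        x = rescale(rng.standard_normal(n))
        if x is not None and np.all(x >= 0.0):
            return x
    # fallback: one-sided draws, shrink dispersion until rescaling stays positive
    for shrink in 2.0 ** np.arange(1, 30):
        x = rescale(np.abs(rng.standard_normal(n)) / shrink)
        if x is not None and np.all(x >= 0.0):
            return x
    raise RuntimeError("could not de-aggregate summary without negative values")


@dataclass
class KineticDataset:
    """Standardized kinetic observations plus their conversion provenance."""

    observations: list = field(default_factory=list)

    def __post_init__(self):
        for obs in self.observations:
            if not obs.relative and obs.unit != "nmol":
                raise ValueError("dataset must contain standardized (nmol) or "
                                 "relative observations; run standardize first")

    @classmethod
    def from_records(cls, records, compound, physiologies) -> "KineticDataset":
        """Standardize raw observations; ``physiologies`` maps species id to
        :class:`~retropbtk.parameters.SpeciesPhysiology`."""
        out = [standardize_units(o, compound, physiologies[o.species_id])
               for o in records]
        return cls(observations=out)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, compound, physiologies) -> "KineticDataset":
        records = []
        for _, row in df.iterrows():
            n = int(row.get("n", 1) or 1)
            sd = row.get("sd")
            sd = None if (sd is None or (isinstance(sd, float) and math.isnan(sd))) else float(sd)
            records.append(KineticObservation(
                study_id=str(row["study_id"]), species_id=str(row["species"]),
                matrix=str(row["matrix"]), route=str(row["route"]),
                dose=float(row["dose_mg_kg"]), time=float(row["time_h"]),
                value=float(row["value"] if row.get("value") is not None
                            else row["value_nmol"]),
                unit=str(row["unit"]), n=n, sd=sd,
                function=str(row.get("function", "training")),
                excluded=bool(row.get("excluded", False))))
        return cls.from_records(records, compound, physiologies)

    def expand_summaries(self, seed: int) -> "KineticDataset":
        """Replace summary records by exact-moment pseudo-individual records."""
        rng = np.random.default_rng(seed)
        out = []
        for obs in self.observations:
            if obs.n == 1:
                out.append(obs)
                continue
            values = deaggregate_summary(obs.value, obs.sd, obs.n,
                                         int(rng.integers(2 ** 31)))
            for v in values:
                out.append(replace(obs, value=float(v), sd=None, n=1,
                                   conversion=obs.conversion + ("de-aggregated",)))
        return KineticDataset(observations=out)

    def training(self) -> "KineticDataset":
        return KineticDataset([o for o in self.observations
                               if o.function == "training" and not o.excluded
                               and not o.relative])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"study_id": o.study_id, "species": o.species_id,
                 "matrix": o.matrix, "route": o.route, "dose_mg_kg": o.dose,
                 "time_h": o.time, "value_nmol": o.value, "unit": o.unit,
                 "n": o.n, "sd": o.sd, "function": o.function,
                 "excluded": o.excluded, "relative": o.relative,
                 "conversion": " | ".join(o.conversion)}
                for o in self.observations]
        return pd.DataFrame(rows)
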