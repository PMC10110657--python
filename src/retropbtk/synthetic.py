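"""Synthetic data generators for all three input families.

The digitized literature dataset behind the original analysis is not
deposited in a public archive, so every pipeline stage is exercised with
generated data that carries the statistical structure the analysis
assumes: monoexponential medium-loss curves with multiplicative replicate
noise, end-product-inhibition microsomal depletion curves, sigmoidal
cytotoxicity curves with biological replicates, and whole-body-model
trajectories sampled at study designs mirroring the literature studies
(doses 5-70 mg/kg; i.v./i.p./p.o.; plasma, liver, urine, bile and hepatic
metabolite matrices; individual and summary records).

Defaults: in vivo noise is lognormal with a log-sd of 0.2; assay noise is
multiplicative normal with a CV of 10%.  All generators are reproducible
under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pbtk
from .dataprep import KineticDataset, KineticObservation
from .dosimetry import CytotoxDataset, _sigmoid
from .ivive import MediumLossDataset, MicrosomalDataset, _simulate_depletion
from .parameters import PBTKParameterSet

__all__ = ["StudyArm", "SyntheticDesign", "generate_invivo_dataset",
           "generate_medium_loss", "generate_microsomal", "generate_cytotox",
           "default_study_arms"]

DEFAULT_INVIVO_SD_LOG = 0.2
DEFAULT_ASSAY_CV = 0.1


@dataclass(frozen=True)
class StudyArm:
    """One simulated study arm: species, route, dose and sampling scheme."""

    study_id: str
    species_id: str
    route: str
    dose: float                    # mg/kg
    matrices: tuple
    times: tuple                   # h
    n_per_time: int = 3
    summary: bool = False          # emit (mean, sd, n) records instead
    function: str = "training"


def default_study_arms() -> list:
    """Study arms mirroring the literature kinetic studies: i.p. plasma and
    hepatic-metabolite time courses, an oral plasma study informing
    absorption, rat bile/urine after i.v. dosing, and an i.p. liver series
    held out for evaluation."""
    return [
        StudyArm("mouse_po_plasma", "mouse", "po", 35.0, ("plasma",),
                 (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0), n_per_time=3, summary=True),
        StudyArm("mouse_ip_plasma", "mouse", "ip", 35.0, ("plasma",),
                 (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0), n_per_time=3, summary=True),
        StudyArm("mouse_ip_conjugates", "mouse", "ip", 35.0,
                 ("dhr_gsh", "dhr_prot"),
                 (1.0, 4.0, 8.0, 24.0, 48.0), n_per_time=4),
        StudyArm("mouse_ip_dna_adducts", "mouse", "ip", 35.0, ("dhr_dna",),
                 (1.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0, 336.0), n_per_time=4),
        StudyArm("mouse_ip_dna_high", "mouse", "ip", 70.0, ("dhr_dna",),
                 (1.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0, 336.0), n_per_time=4),
        StudyArm("rat_iv_excretion", "rat", "iv", 5.0, ("urine", "bile"),
                 (1.0, 2.0, 4.0, 8.0, 24.0), n_per_time=3),
        StudyArm("mouse_ip_liver", "mouse", "ip", 70.0, ("liver",),
                 (0.5, 1.0, 2.0, 4.0, 8.0), n_per_time=3, function="evaluation"),
    ]


@dataclass
class SyntheticDesign:
    """Ground truth and study design for in vivo data generation."""

    truth: dict                                   # species -> PBTKParameterSet
    arms: list = field(default_factory=default_study_arms)
    invivo_sd_log: float = DEFAULT_INVIVO_SD_LOG
    seed: int = 0

    def __post_init__(self):
        if self.invivo_sd_log < 0:
            raise ValueError("noise sd must be nonnegative")
        for arm in self.arms:
            if arm.dose < 0:
                raise ValueError("doses must be nonnegative")


def generate_invivo_dataset(design: SyntheticDesign) -> KineticDataset:
    """Simulate all study arms at the truth and sample noisy observations.

    Observations are emitted directly in the internal amount unit (nmol);
    summary arms report exact empirical mean and sd of the simulated
    animals at each time point.
    """
    rng = np.random.default_rng(design.seed)
    observations = []
    for arm in design.arms:
        params = design.truth[arm.species_id]
        result = pbtk.simulate(params, pbtk.DoseEvent(arm.route, arm.dose, 0.0),
                               t_end=max(arm.times) * 1.0001,
                               t_eval=[0.0, *arm.times], dense=False,
                               rtol=1e-8, atol=1e-10)
        grid = list(result.time_grid)
        for matrix in arm.matrices:
            states = [pbtk.IDX[s] for s in
                      {"plasma": ("plasma",), "liver": ("liver_vi", "liver_c"),
                       "urine": ("urine",), "bile": ("bile",),
                       "dhr_gsh": ("dhr_gsh",), "dhr_prot": ("dhr_prot",),
                       "dhr_dna": ("dhr_dna_fast", "dhr_dna_slow")}[matrix]]
            for t in arm.times:
                true_value = float(result.states[states, grid.index(t)].sum())
                if design.invivo_sd_log > 0:
                    draws = true_value * np.exp(
                        design.invivo_sd_log * rng.standard_normal(arm.n_per_time))
                else:
                    draws = np.full(arm.n_per_time, true_value)
                if arm.summary and arm.n_per_time > 1:
                    observations.append(KineticObservation(
                        study_id=arm.study_id, species_id=arm.species_id,
                        matrix=matrix, route=arm.route, dose=arm.dose, time=t,
                        value=float(draws.mean()), unit="nmol",
                        n=arm.n_per_time, sd=float(draws.std(ddof=1)),
                        function=arm.function))
                else:
                    for v in draws:
                        observations.append(KineticObservation(
                            study_id=arm.study_id, species_id=arm.species_id,
                            matrix=matrix, route=arm.route, dose=arm.dose,
                            time=t, value=float(v), unit="nmol",
                            function=arm.function))
    return KineticDataset(observations=observations)


def generate_medium_loss(lambda_: float, species_id: str = "mouse",
                         temperature: str = "37C", c0: float = 0.7,
                         times: tuple = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0),
                         n_biological: int = 3, n_technical: int = 3,
                         cv: float = DEFAULT_ASSAY_CV,
                         seed: int = 0) -> MediumLossDataset:
    """Monoexponential medium-loss curves with multiplicative noise.

    Replicate structure follows the assay protocol: 0.7 µM start
    concentration, biological replicates each measured in technical
    triplicate."""
    if lambda_ < 0:
        raise ValueError("depletion rate must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    reps = []
    for _ in range(n_biological * n_technical):
        c = c0 * np.exp(-lambda_ * t)
        if cv > 0:
            c = c * np.maximum(1.0 + cv * rng.standard_normal(t.size), 1e-3)
        reps.append((t.copy(), c))
    return MediumLossDataset(species_id=species_id, temperature=temperature,
                             initial_concentration=c0, replicates=reps)


def generate_microsomal(vmax: float, km: float, ic50: float,
                        species_id: str = "mouse",
                        starts: tuple = (1.0, 15.0, 50.0, 200.0),
                        times_min: tuple = (10.0, 20.0, 40.0, 60.0,
                                            120.0, 240.0, 360.0),
                        n_technical: int = 2, cv: float = DEFAULT_ASSAY_CV,
                        seed: int = 0) -> MicrosomalDataset:
    """End-product-inhibition depletion curves at the protocol start
    concentrations (1/15/50/200 µM, technical duplicates)."""
    rng = np.random.default_rng(seed)
    t_h = np.asarray(times_min, float) / 60.0
    inhibition = np.isfinite(ic50)
    reps: dict = {}
    for c0 in starts:
        curve = _simulate_depletion(
            np.array([vmax * 60.0, km, ic50 if inhibition else 1.0]),
            c0, t_h, inhibition)
        series = []
        for _ in range(n_technical):
            c = curve.copy()
            if cv > 0:
                c = c * np.maximum(1.0 + cv * rng.standard_normal(c.size), 1e-3)
            series.append((t_h.copy(), c))
        reps[float(c0)] = series
    return MicrosomalDataset(species_id=species_id, replicates=reps)


def generate_cytotox(ic50: float, slope: float = 2.5, species_id: str = "mouse",
                     concentrations: tuple = (0.0, 10.0, 30.0, 100.0,
                                              300.0, 1000.0),
                     n_biological: int = 3, cv: float = DEFAULT_ASSAY_CV,
                     biological_sd_log_ic50: float = 0.0,
                     seed: int = 0) -> CytotoxDataset:
    """Sigmoidal 48-h cytotoxicity curves with biological replicates.

    ``biological_sd_log_ic50`` shifts each biological replicate's IC50 by
    a lognormal factor, emulating inter-animal sensitivity differences."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_biological):
        rep_ic50 = ic50 * np.exp(biological_sd_log_ic50 * rng.standard_normal()) \
            if biological_sd_log_ic50 > 0 else ic50
        for c in concentrations:
            v = float(_sigmoid(np.array([c]), rep_ic50, slope)[0])
            if cv > 0:
                v *= max(1.0 + cv * rng.standard_normal(), 0.0)
            rows.append({"replicate_id": f"bio{rep + 1}",
                         "concentration_uM": c, "viability": min(v, 1.5)})
    return CytotoxDataset(species_id=species_id, frame=pd.DataFrame(rows))
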