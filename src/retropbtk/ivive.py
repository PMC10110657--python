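"""In vitro-to-in vivo extrapolation of transport and metabolism.

Three assay families inform the liver model:

* medium-loss assays with primary hepatocytes at 4 °C and 37 °C — the
  monoexponential depletion rate at 4 °C reflects passive diffusion only
  (active transport is abolished in the cold), the 37 °C rate reflects
  passive plus active uptake; the difference scales to the in vivo active
  uptake clearance,
* microsomal depletion at several start concentrations — fitted with a
  substrate-depletion model in which accumulated reaction product
  irreversibly attenuates the Michaelis-Menten rate (end-product
  inhibition), giving Vmax and K_M,
* bidirectional Caco-2 permeability — mapped to the fraction absorbed
  through a published-style permeability/F_a correlation.

Scaling from incubation to organ uses hepatocellularity, incubation
geometry and microsomal protein per gram liver.  The extended-clearance
closed form combines uptake, efflux, metabolism and biliary excretion
with hepatic flow and plasma protein binding into the overall hepatic
clearance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import solve_ivp

__all__ = [
    "AssayScalingConstants", "MediumLossDataset", "MicrosomalDataset",
    "Caco2Result", "DepletionFit", "EndProductInhibitionFit",
    "fit_monoexponential_depletion", "medium_loss_to_clearances",
    "fit_end_product_inhibition", "scale_vmax_to_liver", "caco2_to_fa",
    "extended_clearance", "renal_clearance", "gut_metabolic_parameters",
]


@dataclass(frozen=True)
class AssayScalingConstants:
    """Protocol constants used to scale assay rates to the whole organ."""

    incubation_volume: float = 0.5          # mL
    cells_per_incubation: float = 2.5e5     # hepatocytes per incubation
    hepatocellularity: float = 1.422e8      # cells per g liver
    microsomal_protein_conc: float = 0.85   # mg protein / mL incubation
    mppgl: float = 40.0                     # mg microsomal protein / g liver

    def __post_init__(self):
        for name in ("incubation_volume", "cells_per_incubation",
                     "hepatocellularity", "microsomal_protein_conc", "mppgl"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def medium_loss_factor(self) -> float:
        """mL/min/g liver per unit depletion rate (1/h)."""
        return (self.incubation_volume * self.hepatocellularity
                / (self.cells_per_incubation * 60.0))

    @property
    def vmax_factor(self) -> float:
        """nmol/min/g liver per µM/min of in vitro depletion velocity."""
        return self.mppgl / self.microsomal_protein_conc


def _check_series(t: np.ndarray, c: np.ndarray) -> None:
    t, c = np.asarray(t, float), np.asarray(c, float)
    if t.size != c.size:
        raise ValueError("time and concentration series differ in length")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")


@dataclass
class MediumLossDataset:
    """Replicated (time, concentration) depletion series from one condition."""

    species_id: str
    temperature: str                       # "4C" or "37C"
    initial_concentration: float = 0.7     # µM, per protocol
    replicates: list = field(default_factory=list)  # list of (t_h, conc_uM)

    def __post_init__(self):
        if self.temperature not in ("4C", "37C"):
            raise ValueError("temperature must be '4C' or '37C'")
        for t, c in self.replicates:
            _check_series(t, c)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, species_id: str,
                  temperature: str) -> "MediumLossDataset":
        sub = df[(df["species"] == species_id)
                 & (df["assay"] == "medium_loss")
                 & (df["temperature_or_conc"].astype(str) == temperature)]
        reps = [(g["time_h"].to_numpy(float), g["concentration_uM"].to_numpy(float))
                for _, g in sub.groupby("replicate")]
        if not reps:
            raise ValueError(f"no medium-loss rows for {species_id}/{temperature}")
        return cls(species_id=species_id, temperature=temperature, replicates=reps)


@dataclass
class MicrosomalDataset:
    """Depletion series per start concentration from a microsomal assay."""

    species_id: str
    replicates: dict = field(default_factory=dict)  # start µM -> [(t_h, conc_uM)]

    def __post_init__(self):
        for series in self.replicates.values():
            for t, c in series:
                _check_series(t, c)

    @property
    def initial_concentrations(self) -> list:
        return sorted(self.replicates)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, species_id: str) -> "MicrosomalDataset":
        sub = df[(df["species"] == species_id) & (df["assay"] == "microsomal")]
        if sub.empty:
            raise ValueError(f"no microsomal rows for {species_id}")
        reps: dict = {}
        for (c0, _), g in sub.groupby(["temperature_or_conc", "replicate"]):
            reps.setdefault(float(c0), []).append(
                (g["time_h"].to_numpy(float), g["concentration_uM"].to_numpy(float)))
        return cls(species_id=species_id, replicates=reps)


@dataclass(frozen=True)
class Caco2Result:
    """Bidirectional apparent permeabilities (cm/s)."""

    papp_a_to_bl: float
    papp_bl_to_a: float

    def __post_init__(self):
        if not (self.papp_a_to_bl > 0 and self.papp_bl_to_a > 0):
            raise ValueError("permeabilities must be positive")

    @property
    def efflux_ratio(self) -> float:
        # standard definition: secretory over absorptive permeability
        return self.papp_bl_to_a / self.papp_a_to_bl


@dataclass
class DepletionFit:
    lambda_: float                 # 1/h
    ci95: tuple                    # (low, high)
    log_c0: float
    sigma: float                   # residual sd on log scale
    n_obs: int
    warning: str | None = None


def fit_monoexponential_depletion(data: MediumLossDataset) -> DepletionFit:
    """Maximum-likelihood monoexponential depletion rate from pooled replicates.

    The model is ``C(t) = C0 * exp(-λ t)`` with multiplicative
    (log-normal) noise, so the fit is ordinary least squares of log
    concentration on time.  Non-decaying data yield λ = 0 with a warning
    rather than an error.
    """
    t = np.concatenate([r[0] for r in data.replicates])
    c = np.concatenate([r[1] for r in data.replicates])
    if t.size < 3:
        raise ValueError("at least three time points are required")
    if np.any(c <= 0):
        raise ValueError("zero concentrations cannot be log-transformed")
    res = stats.linregress(t, np.log(c))
    lam = -res.slope
    dof = max(t.size - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    half = tcrit * res.stderr
    warning = None
    if lam < 0:
        warning = "no depletion detected; rate floored at 0"
        warnings.warn(warning)
        lam = 0.0
    resid = np.log(c) - (res.intercept + res.slope * t)
    return DepletionFit(lambda_=lam, ci95=(max(lam - half, 0.0), lam + half),
                        log_c0=res.intercept, sigma=float(np.std(resid, ddof=2))
                        if t.size > 2 else 0.0, n_obs=int(t.size), warning=warning)


def medium_loss_to_clearances(lambda_4c: float, lambda_37c: float,
                              k: AssayScalingConstants | None = None) -> dict:
    """Hepatic uptake parameters from the two medium-loss depletion rates.

    Passive diffusion is read from the 4 °C rate without temperature
    correction; active uptake from the 37 °C excess over the cold rate,
    floored at zero.  Both are scaled by one shared factor (incubation
    volume × hepatocellularity / cells), giving mL/min/g liver.
    """
    if lambda_4c < 0 or lambda_37c < 0:
        raise ValueError("depletion rates must be nonnegative")
    k = k or AssayScalingConstants()
    sf = k.medium_loss_factor
    diff = lambda_37c - lambda_4c
    warning = None
    if diff < 0:
        warning = "37C depletion slower than 4C; active uptake set to 0"
        warnings.warn(warning)
        diff = 0.0
    return {"cl_act_in": diff * sf, "ps_diff": lambda_4c * sf, "warning": warning}


def _simulate_depletion(theta: np.ndarray, c0: float, t: np.ndarray,
                        inhibition: bool) -> np.ndarray:
    vmax, km, ic50 = theta

    def rate(_, y):
        c = max(y[0], 0.0)
        r = vmax * c / (km + c)
        if inhibition:
            r /= 1.0 + (c0 - c) / ic50
        return [-r]

    sol = solve_ivp(rate, (0.0, float(t[-1])), [c0], method="LSODA",
                    t_eval=t, rtol=1e-8, atol=1e-10)
    return np.clip(sol.y[0], 1e-12, None)


@dataclass
class EndProductInhibitionFit:
    vmax: float       # µM/min
    km: float         # µM
    ic50: float       # µM (product concentration at half-maximal attenuation)
    ci95: dict
    sigma: float
    n_obs: int
    ic50_identified: bool = True


def fit_end_product_inhibition(data: MicrosomalDataset,
                               inhibition: bool = True) -> EndProductInhibitionFit:
    """Joint fit of the depletion model across all start concentrations.

    The instantaneous Michaelis-Menten rate is attenuated by accumulated
    product ``P = C0 - C`` through a factor ``1/(1 + P/IC50)``
    (irreversible enzyme loss, half-maximal at IC50).  With
    ``inhibition=False`` the plain Michaelis-Menten depletion model is
    fitted instead.  Residuals are on the log-concentration scale;
    parameters are optimized in log space to enforce positivity.
    """
    starts = data.initial_concentrations
    if len(starts) < 2:
        raise ValueError("at least two distinct start concentrations are required")
    times = {c0: np.unique(np.concatenate([r[0] for r in data.replicates[c0]]))
             for c0 in starts}
    n_resid = sum(int(np.sum(c > 0)) for c0 in starts
                  for _, c in data.replicates[c0])

    # internal velocity unit is µM/h (times are hours); reported Vmax is µM/min
    def residuals(log_theta):
        theta = np.exp(log_theta) if inhibition else \
            np.array([math.exp(log_theta[0]), math.exp(log_theta[1]), np.inf])
        if not np.all(np.isfinite(theta[:3 if inhibition else 2])):
            return np.full(n_resid, 1e3)
        out = []
        for c0 in starts:
            grid = times[c0]
            pred = _simulate_depletion(theta, c0, grid, inhibition)
            lookup = dict(zip(grid, np.log(pred)))
            for t, c in data.replicates[c0]:
                mask = c > 0
                out.append(np.log(c[mask]) - np.array([lookup[x] for x in t[mask]]))
        return np.concatenate(out)

    # crude initialisation: initial log-slope of the lowest start concentration
    lo = min(starts)
    t0, c0s = data.replicates[lo][0]
    lam0 = max((np.log(c0s[0] + 1e-12) - np.log(c0s[-1] + 1e-12))
               / max(t0[-1] - t0[0], 1e-6), 1e-3)          # 1/h
    lb = np.log([1e-4, 1e-3, 1e-6])[: 3 if inhibition else 2]
    ub = np.log([1e7, 1e4, 1e9])[: 3 if inhibition else 2]
    # the Vmax/KM ridge has local optima; start from several K_M scales
    fit = None
    for km0 in (0.2 * np.median(starts), 2.0 * np.median(starts), 20.0 * max(starts)):
        x0 = np.log([lam0 * km0, km0, 0.2 * lo]) if inhibition else \
            np.log([lam0 * km0, km0])
        trial = optimize.least_squares(residuals, np.clip(x0, lb, ub),
                                       bounds=(lb, ub), max_nfev=300)
        if fit is None or trial.cost < fit.cost:
            fit = trial
    theta = np.exp(fit.x)
    n = fit.fun.size
    dof = max(n - fit.x.size, 1)
    sigma2 = float(fit.fun @ fit.fun) / dof
    try:
        cov = sigma2 * np.linalg.inv(fit.jac.T @ fit.jac)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(fit.x.size, np.inf)
    tcrit = stats.t.ppf(0.975, dof)
    names = ("vmax", "km", "ic50")[:fit.x.size]
    scale = {"vmax": 1.0 / 60.0}          # µM/h -> µM/min on output
    ci = {name: (float(theta[i] * scale.get(name, 1.0) * np.exp(-min(tcrit * se[i], 700.0))),
                 float(theta[i] * scale.get(name, 1.0) * np.exp(min(tcrit * se[i], 700.0))))
          for i, name in enumerate(names)}
    identified = True
    if inhibition and (not np.isfinite(se[2]) or se[2] > 5.0):
        identified = False
        warnings.warn("IC50 poorly identified (no curvature in the data)")
    return EndProductInhibitionFit(
        vmax=float(theta[0]) / 60.0, km=float(theta[1]),
        ic50=float(theta[2]) if inhibition else math.inf,
        ci95=ci, sigma=math.sqrt(sigma2), n_obs=n, ic50_identified=identified)


def scale_vmax_to_liver(vmax_invitro: float,
                        k: AssayScalingConstants | None = None) -> float:
    """Scale an in vitro maximum depletion velocity (µM/min) to the liver
    (nmol/min/g) via protein content and microsomal protein per gram."""
    if vmax_invitro < 0:
        raise ValueError("Vmax must be nonnegative")
    k = k or AssayScalingConstants()
    return vmax_invitro * k.vmax_factor


# fraction-absorbed correlation constants (logistic in permeability)
FA_P50_CM_S = 2.0e-6
FA_HILL = 1.0


def caco2_to_fa(papp_a_to_bl: float) -> float:
    """Fraction absorbed from the absorptive Caco-2 permeability (cm/s).

    A saturating correlation: F_a rises monotonically from 0 at vanishing
    permeability towards 1, with half-maximal absorption at
    ``FA_P50_CM_S``.
    """
    if not papp_a_to_bl > 0:
        raise ValueError("permeability must be positive")
    return 1.0 / (1.0 + (FA_P50_CM_S / papp_a_to_bl) ** FA_HILL)


def extended_clearance(q_liv: float, fup: float, cl_act_in: float,
                       cl_act_ef: float, cl_bile: float, vmax_liv: float,
                       km_liv: float, liver_mass_per_kg: float) -> dict:
    """Overall hepatic clearance from the extended-clearance closed form.

    All clearance inputs are per gram liver (mL/min/g; Vmax nmol/min/g,
    K_M µM).  Returns the linear metabolic clearance ``CL_met_liv =
    Vmax/K_M`` (mL/min/g) and the overall ``CL_liv`` in mL/min/kg
    bodyweight::

        CL_liv = Q * fuP * CL_in * (CL_met + CL_bile) /
                 [Q * (CL_ef + CL_met + CL_bile) + fuP * CL_in * (CL_met + CL_bile)]

    which is bounded above by hepatic flow.
    """
    if km_liv <= 0:
        raise ValueError("K_M must be positive")
    for v in (q_liv, fup, cl_act_in, cl_act_ef, cl_bile, vmax_liv, liver_mass_per_kg):
        if v < 0:
            raise ValueError("clearance inputs must be nonnegative")
    cl_met = vmax_liv / km_liv
    sink = cl_met + cl_bile
    numer = q_liv * fup * cl_act_in * sink
    denom = q_liv * (cl_act_ef + sink) + fup * cl_act_in * sink
    cl_liv_per_g = numer / denom if denom > 0 else 0.0
    return {"cl_met_liv": cl_met, "cl_liv_per_g": cl_liv_per_g,
            "cl_liv": cl_liv_per_g * liver_mass_per_kg}


def renal_clearance(fup: float, gfr: float) -> float:
    """Renal clearance as unbound glomerular filtration, mL/min/kg."""
    if fup < 0 or gfr < 0:
        raise ValueError("inputs must be nonnegative")
    return fup * gfr


def gut_metabolic_parameters(vmax_liv: float, km_liv: float,
                             liver_mass_per_kg: float) -> dict:
    """Gut metabolism from hepatic metabolism: same K_M, whole-organ Vmax
    one tenth of the whole-liver Vmax.  Returns Vmax_gut in nmol/min per kg
    bodyweight, K_M_gut in µM and the linear gut metabolic clearance
    CL_met_gut in mL/min/kg."""
    if not (vmax_liv >= 0 and km_liv > 0 and liver_mass_per_kg > 0):
        raise ValueError("invalid gut-metabolism inputs")
    vmax_gut = vmax_liv * liver_mass_per_kg / 10.0
    return {"vmax_gut_per_kg": vmax_gut, "km_gut": km_liv,
            "cl_met_gut": vmax_gut / km_liv}
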