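"""Unit conventions and small conversion helpers.

The package works in one internal unit system throughout:

* amount of substance: nmol
* volume: mL  (so concentrations are nmol/mL = µM)
* time: h
* bodyweight: kg

Clearances are stored in the literature units they are reported in
(mL/min/g liver or mL/min/kg bodyweight) and converted to whole-organ
mL/h only when the ODE system is assembled.
"""

from __future__ import annotations

import math

LN2 = math.log(2.0)

#: minutes per hour; clearances reported per minute are scaled by this.
MIN_PER_H = 60.0


def halflife_to_rate(t_half: float) -> float:
    """First-order rate constant from a half-life, ``ln(2)/t_half``.

    Input and output share the same time base (a half-life in hours gives
    a rate in 1/h).  A 15 s peritoneal absorption half-life, expressed in
    hours, gives the 166 1/h default used for intraperitoneal dosing.
    """
    if not t_half > 0.0:
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return LN2 / t_half


def rate_to_halflife(rate: float) -> float:
    """Inverse of :func:`halflife_to_rate`."""
    if not rate > 0.0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    return LN2 / rate


def dose_mgkg_to_nmol(dose_mg_per_kg: float, bodyweight_kg: float,
                      molar_mass_g_mol: float) -> float:
    """Convert a mg/kg bodyweight dose into an absolute amount in nmol."""
    if dose_mg_per_kg < 0.0:
        raise ValueError("dose must be nonnegative")
    mg = dose_mg_per_kg * bodyweight_kg
    return mg / molar_mass_g_mol * 1.0e6


def clearance_per_g_liver_to_ml_h(cl_ml_min_g: float, liver_mass_g: float) -> float:
    """Whole-organ clearance (mL/h) from a per-gram-liver value (mL/min/g)."""
    return cl_ml_min_g * liver_mass_g * MIN_PER_H


def clearance_per_kg_to_ml_h(cl_ml_min_kg: float, bodyweight_kg: float) -> float:
    """Whole-body clearance (mL/h) from a per-kg-bodyweight value (mL/min/kg)."""
    return cl_ml_min_kg * bodyweight_kg * MIN_PER_H
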