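"""Tissue-to-plasma partition coefficients (Rodgers-Rowland model).

Steady-state distribution of a compound into perfusion-limited tissues is
predicted mechanistically from tissue composition: partitioning into tissue
water, neutral lipids and neutral phospholipids, plus — depending on the
ionization class — electrostatic association with acidic phospholipids
(moderate-to-strong bases) or binding to extracellular albumin-type protein
(neutrals, weak bases, acids).

The model needs the compound's octanol-water lipophilicity, its ionization
description and the fraction unbound in plasma.  For adipose the
vegetable-oil:water distribution coefficient replaces the octanol-water
coefficient in the neutral-lipid term.  The association constant to acidic
phospholipids is back-calculated from the blood-to-plasma ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "PartitionSet",
    "fraction_neutral",
    "load_tissue_composition",
    "predict_partition_coefficients",
]

#: pKa above which a base is treated by the acidic-phospholipid branch.
STRONG_BASE_PKA_THRESHOLD = 7.0


def load_tissue_composition() -> dict:
    """Load the packaged tissue-constituent table (fractions of volume)."""
    text = resources.files("retropbtk.data").joinpath("tissue_composition.yaml").read_text()
    return yaml.safe_load(text)


def fraction_neutral(ionization: Mapping, ph: float) -> float:
    """Henderson-Hasselbalch fraction of the neutral (uncharged) species.

    ``ionization`` is a mapping with keys ``type`` (one of ``neutral``,
    ``acid``, ``base``, ``zwitterion``) and ``pka`` (list of pKa values; for
    zwitterions ``pka_acid`` and ``pka_base``).  Multiprotic groups are
    treated as sequential protonations of one centre, which matches the
    microstate enumeration for well-separated pKa values.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {ph!r}")
    kind = ionization.get("type", "neutral")
    if kind == "neutral":
        return 1.0
    if kind == "zwitterion":
        fa = fraction_neutral({"type": "acid", "pka": ionization["pka_acid"]}, ph)
        fb = fraction_neutral({"type": "base", "pka": ionization["pka_base"]}, ph)
        return fa * fb
    pkas = sorted(ionization["pka"], reverse=(kind == "base"))
    total_charged = 0.0
    exponent = 0.0
    for pka in pkas:
        if kind == "base":
            exponent += pka - ph
        elif kind == "acid":
            exponent += ph - pka
        else:
            raise ValueError(f"unknown ionization type {kind!r}")
        total_charged += 10.0 ** exponent
    return 1.0 / (1.0 + total_charged)


@dataclass
class PartitionSet:
    """Tissue-to-plasma partition coefficients plus the liver sub-compartment
    partitions used by the extended-clearance liver model."""

    k_tis: dict = field(default_factory=dict)
    k_liv_vas_vi: float = 1.0
    k_liv_int_u_vi: float = 0.6

    def validate(self) -> None:
        for name, value in self.k_tis.items():
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(f"partition coefficient for {name!r} must be "
                                 f"positive and finite, got {value!r}")
        for name in ("k_liv_vas_vi", "k_liv_int_u_vi"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")


def _logd_vegetable_oil(logp: float) -> float:
    # empirical olive-oil:water correlation used for the adipose neutral-lipid term
    return 1.115 * logp - 1.35


def _lipid_terms(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def _kaap_from_blood(compound, composition: Mapping, y_plasma: float) -> float:
    """Association constant to acidic phospholipids, from the blood:plasma ratio."""
    rbc = composition["red_blood_cell"]
    ph = composition["ph"]
    hct = getattr(compound, "hematocrit", 0.45)
    bp = compound.blood_to_plasma_ratio
    kpu_bc = (bp - (1.0 - hct)) / (hct * compound.fup)
    x_bc = 1.0 / fraction_neutral(compound.ionization, ph["red_blood_cell"])
    p = 10.0 ** compound.logp
    unbound = (x_bc / y_plasma) * rbc["f_iw"] + _lipid_terms(p, rbc["f_nl"], rbc["f_np"]) / y_plasma
    kaap = (kpu_bc - unbound) * y_plasma / (rbc["ap_mg_g"] * (x_bc - 1.0))
    return max(kaap, 0.0)


def _is_strong_base(ionization: Mapping) -> bool:
    if ionization.get("type") == "base":
        return max(ionization["pka"]) >= STRONG_BASE_PKA_THRESHOLD
    if ionization.get("type") == "zwitterion":
        return max(ionization["pka_base"]) >= STRONG_BASE_PKA_THRESHOLD
    return False


def predict_partition_coefficients(compound, tissue_composition: Mapping | None = None,
                                   k_liv_vas_vi: float = 1.0,
                                   k_liv_int_u_vi: float | None = None) -> PartitionSet:
    """Predict tissue-to-plasma partition coefficients ``K_tis``.

    Parameters
    ----------
    compound
        Object with attributes ``logp``, ``ionization``, ``fup`` and
        ``blood_to_plasma_ratio`` (``CompoundProperties`` qualifies).
    tissue_composition
        Constituent-fraction table; the packaged rodent table by default.
    k_liv_vas_vi, k_liv_int_u_vi
        Liver sub-compartment partitions carried through to the returned
        :class:`PartitionSet`; ``k_liv_int_u_vi`` defaults to ``fup``
        (lumped vascular/interstitial space equilibrated with plasma).

    The prediction is deterministic; an unknown tissue in the composition
    table is simply carried along, while requesting a tissue that is absent
    raises a ``KeyError`` listing the supported tissues.
    """
    comp = tissue_composition or load_tissue_composition()
    ph = comp["ph"]
    ion = compound.ionization
    y_plasma = 1.0 / fraction_neutral(ion, ph["plasma"])
    x_cell = 1.0 / fraction_neutral(ion, ph["intracellular"])
    p = 10.0 ** compound.logp
    p_adipose = 10.0 ** _logd_vegetable_oil(compound.logp)
    strong_base = _is_strong_base(ion)
    kaap = _kaap_from_blood(compound, comp, y_plasma) if strong_base else 0.0
    plasma_lipids = _lipid_terms(p, comp["plasma"]["f_nl"], comp["plasma"]["f_np"])

    k_tis: dict[str, float] = {}
    for name, tis in comp["tissues"].items():
        p_eff = p_adipose if name == "adipose" else p
        kpu = (tis["f_ew"]
               + (x_cell / y_plasma) * tis["f_iw"]
               + _lipid_terms(p_eff, tis["f_nl"], tis["f_np"]) / y_plasma)
        if strong_base:
            kpu += kaap * tis["ap_mg_g"] * (x_cell - 1.0) / y_plasma
        else:
            protein_binding = (1.0 / compound.fup - 1.0 - plasma_lipids)
            kpu += max(protein_binding, 0.0) * tis["pr_ratio"]
        k_tis[name] = compound.fup * kpu

    result = PartitionSet(
        k_tis=k_tis,
        k_liv_vas_vi=k_liv_vas_vi,
        k_liv_int_u_vi=compound.fup if k_liv_int_u_vi is None else k_liv_int_u_vi,
    )
    result.validate()
    return result


def cellular_unbound_fraction(compound, tissue_composition: Mapping | None = None,
                              tissue: str = "liver") -> float:
    """Unbound fraction in the cellular space of ``tissue``.

    Approximated as the reciprocal of the unbound tissue-to-plasma partition
    coefficient of the cellular constituents; used as a default for the
    fraction unbound in liver cells when no measured value is configured.
    """
    comp = tissue_composition or load_tissue_composition()
    pset = predict_partition_coefficients(compound, comp)
    kpu = pset.k_tis[tissue] / compound.fup
    return 1.0 / kpu
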