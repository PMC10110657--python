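"""Physiological and compound parameters for the whole-body model.

All constants are read from species configuration documents (packaged YAML
for mouse and rat) and validated into one :class:`PBTKParameterSet`.  The
set stores clearances in the literature units they are reported in
(mL/min/g liver, mL/min/kg bodyweight) and converts them to whole-organ
mL/h only when the ODE system is assembled (see :mod:`retropbtk.pbtk`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from . import distribution, units

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "SpeciesPhysiology",
    "CompoundProperties",
    "PBTKParameterSet",
    "load_parameter_set",
    "packaged_config",
]

#: compartments perfused in parallel from the plasma pool
PERFUSED_TISSUES = ("adipose", "bone", "brain", "heart", "kidneys", "lungs",
                    "muscle", "skin", "spleen", "gut")
#: tissues whose venous outflow drains into the portal inflow of the liver
SPLANCHNIC_TISSUES = ("gut", "spleen")

#: default peritoneal absorption rate constant, ln(2) / 15 s in 1/h
DEFAULT_K_PER_PER_H = units.halflife_to_rate(15.0 / 3600.0)

FLOW_BALANCE_RTOL = 1e-9


class ConfigurationError(ValueError):
    """A required configuration field is missing or malformed."""


class ValidationError(ValueError):
    """A parameter violates a model invariant."""


def _require(mapping: Mapping, key: str, context: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"missing configuration field {context}.{key}") from None


@dataclass
class SpeciesPhysiology:
    """Anatomical volumes, blood flows and liver composition for one species.

    Volumes are absolute mL and flows mL/min for an animal of ``bodyweight``
    kg; per-kg configuration entries are scaled at load time.
    """

    species_id: str
    bodyweight: float                       # kg
    tissue_volumes: dict                    # tissue -> mL
    tissue_blood_flows: dict                # tissue -> mL/min (plasma-equivalent)
    hepatic_artery_flow: float              # mL/min
    v_liv_c: float                          # mL, cellular space
    v_liv_vi: float                         # mL, lumped vascular/interstitial
    gfr: float                              # mL/min/kg bodyweight
    liver_mass_per_kg: float                # g liver per kg bodyweight
    hematocrit: float

    @property
    def q_liv(self) -> float:
        """Total hepatic inflow (portal + arterial), mL/min."""
        return (self.tissue_blood_flows["gut"] + self.tissue_blood_flows["spleen"]
                + self.hepatic_artery_flow)

    @property
    def q_liv_per_g(self) -> float:
        """Hepatic flow per gram liver, mL/min/g."""
        return self.q_liv / self.liver_mass

    @property
    def liver_mass(self) -> float:
        """Liver mass in g."""
        return self.liver_mass_per_kg * self.bodyweight

    @property
    def cardiac_output(self) -> float:
        """Sum of all compartment inflows from the arterial side, mL/min."""
        return sum(self.tissue_blood_flows.values()) + self.hepatic_artery_flow

    def validate(self) -> None:
        if self.species_id not in ("mouse", "rat"):
            raise ValidationError(f"unsupported species {self.species_id!r}")
        if not self.bodyweight > 0:
            raise ValidationError("bodyweight must be positive")
        for name, v in self.tissue_volumes.items():
            if not v > 0:
                raise ValidationError(f"tissue volume {name} must be positive")
        for name, q in self.tissue_blood_flows.items():
            if not q > 0:
                raise ValidationError(f"tissue flow {name} must be positive")
        if not self.hepatic_artery_flow > 0:
            raise ValidationError("hepatic artery flow must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValidationError("hematocrit must lie in (0, 1)")
        if not (self.gfr > 0 and self.liver_mass_per_kg > 0):
            raise ValidationError("GFR and liver mass must be positive")
        v_liv = self.tissue_volumes["liver"]
        if not math.isclose(self.v_liv_c + self.v_liv_vi, v_liv, rel_tol=1e-9):
            raise ValidationError("liver sub-volumes must sum to the total liver volume")
        # venous return equals the arterial outflow by construction; assert the
        # bookkeeping identity at declared tolerance anyway
        venous = (sum(q for t, q in self.tissue_blood_flows.items()
                      if t not in SPLANCHNIC_TISSUES) + self.q_liv)
        if not math.isclose(venous, self.cardiac_output, rel_tol=FLOW_BALANCE_RTOL):
            raise ValidationError("organ outflows do not sum to cardiac output")


@dataclass
class CompoundProperties:
    """Physico-chemical and binding properties of the compound."""

    name: str
    molar_mass: float                # g/mol
    logp: float
    ionization: dict
    fup: float                       # fraction unbound in plasma
    blood_to_plasma_ratio: float
    fu_liv_c: float                  # fraction unbound in liver cellular space
    fn_liv_c: float = field(default=float("nan"))    # fraction neutral, cellular
    fn_liv_int: float = field(default=float("nan"))  # fraction neutral, interstitial
    fu_invitro: float = 1.0
    hematocrit: float = 0.45

    def validate(self) -> None:
        for name in ("fup", "fu_liv_c", "fn_liv_c", "fn_liv_int", "fu_invitro"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1], got {v!r}")
        if not self.molar_mass > 0:
            raise ValidationError("molar mass must be positive")
        if not 0.0 < self.blood_to_plasma_ratio:
            raise ValidationError("blood-to-plasma ratio must be positive")


@dataclass
class AbsorptionParameters:
    k_per: float    # 1/h, peritoneal
    k_a: float      # 1/h, intestinal
    f_a: float      # fraction absorbed

    def validate(self) -> None:
        if not (self.k_per > 0 and self.k_a > 0):
            raise ValidationError("absorption rate constants must be positive")
        if not 0.0 <= self.f_a <= 1.0:
            raise ValidationError("F_a must lie in [0, 1]")


@dataclass
class HepaticParameters:
    """Extended-clearance liver constants, per gram liver."""

    cl_act_in: float     # mL/min/g
    cl_act_ef: float     # mL/min/g
    ps_diff: float       # mL/min/g
    cl_bile: float       # mL/min/g
    vmax_liv: float      # nmol/min/g
    km_liv: float        # µM

    def validate(self) -> None:
        for name in ("cl_act_in", "cl_act_ef", "ps_diff", "cl_bile", "vmax_liv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not self.km_liv > 0:
            raise ValidationError("K_M must be positive")


@dataclass
class ExtrahepaticParameters:
    cl_uri: float      # mL/min/kg bodyweight
    vmax_gut: float    # nmol/min, whole organ
    km_gut: float      # µM

    def validate(self) -> None:
        if self.cl_uri < 0 or self.vmax_gut < 0:
            raise ValidationError("extrahepatic clearances must be nonnegative")
        if not self.km_gut > 0:
            raise ValidationError("K_M,gut must be positive")


#: names of the fractional-formation parameters; they sum to one with f_other
F_FRACTIONS = ("f_dhr_gsh", "f_dhr_prot", "f_dhr_dna", "f_other")


@dataclass
class MetaboliteParameters:
    """Formation fractions and depletion rate constants of the hepatic
    metabolite surrogates (GSH conjugates, protein adducts, DNA adducts)."""

    f_dhr_gsh: float
    f_dhr_prot: float
    f_dhr_dna: float
    f_other: float
    lambda_dhr_gsh: float     # 1/h
    lambda_dhr_prot: float    # 1/h
    lambda1_dhr_dna: float    # 1/h
    lambda2_dhr_dna: float    # 1/h
    k_dhr_dna: float          # 1/h

    def validate(self) -> None:
        for name in F_FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        total = sum(getattr(self, name) for name in F_FRACTIONS)
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-9):
            raise ValidationError(
                f"metabolite formation fractions must sum to 1 exactly, got {total!r}")
        for name in ("lambda_dhr_gsh", "lambda_dhr_prot", "lambda1_dhr_dna",
                     "lambda2_dhr_dna", "k_dhr_dna"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


@dataclass
class PBTKParameterSet:
    """The complete parameter vector consumed by the ODE system."""

    physiology: SpeciesPhysiology
    compound: CompoundProperties
    partition: distribution.PartitionSet
    absorption: AbsorptionParameters
    hepatic: HepaticParameters
    extrahepatic: ExtrahepaticParameters
    metabolites: MetaboliteParameters

    def validate(self) -> "PBTKParameterSet":
        self.physiology.validate()
        self.compound.validate()
        self.partition.validate()
        self.absorption.validate()
        self.hepatic.validate()
        self.extrahepatic.validate()
        self.metabolites.validate()
        missing = [t for t in PERFUSED_TISSUES if t not in self.partition.k_tis]
        if missing:
            raise ValidationError(f"partition coefficients missing for {missing}")
        return self

    def replace(self, **updates) -> "PBTKParameterSet":
        """Return a copy with named leaf parameters replaced.

        Keys address leaves of the nested structure by their field name
        (e.g. ``k_a``, ``cl_bile``, ``f_dhr_gsh``); used by the estimation
        machinery to move through parameter space cheaply.
        """
        import copy

        new = copy.deepcopy(self)
        for key, value in updates.items():
            for section in (new.absorption, new.hepatic, new.extrahepatic,
                            new.metabolites, new.compound):
                if hasattr(section, key):
                    setattr(section, key, value)
                    break
            else:
                raise KeyError(f"unknown parameter {key!r}")
        # keep the simplex closed under changes of the named fractions
        m = new.metabolites
        if any(k in updates for k in ("f_dhr_gsh", "f_dhr_prot", "f_dhr_dna")):
            m.f_other = 1.0 - (m.f_dhr_gsh + m.f_dhr_prot + m.f_dhr_dna)
        return new.validate()


def packaged_config(species: str) -> dict:
    """Load the packaged configuration document for ``species``."""
    if species not in ("mouse", "rat"):
        raise ConfigurationError(f"no packaged configuration for species {species!r}")
    text = resources.files("retropbtk.data").joinpath(f"{species}.yaml").read_text()
    return yaml.safe_load(text)


def load_parameter_set(config: Mapping | str | None = None,
                       species: str | None = None) -> PBTKParameterSet:
    """Assemble and validate a :class:`PBTKParameterSet`.

    ``config`` may be a parsed mapping, a path to a YAML document, or
    ``None`` to use the packaged defaults for ``species``.  Every field is
    required except ``absorption.k_per_per_h``, which defaults to the
    15-second peritoneal absorption half-life (166 1/h).
    """
    if config is None:
        if species is None:
            raise ConfigurationError("either a config document or a species is required")
        config = packaged_config(species)
    elif isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    species_id = _require(config, "species", "config")
    if species is not None and species != species_id:
        raise ConfigurationError(
            f"config is for species {species_id!r}, requested {species!r}")

    bw = float(_require(config, "bodyweight_kg", "config"))
    volumes_per_kg = _require(config, "tissue_volumes_ml_per_kg", "config")
    flows_per_kg = dict(_require(config, "tissue_flows_ml_min_kg", "config"))
    liver_mass_per_kg = float(_require(config, "liver_mass_per_kg", "config"))
    f_cell = float(_require(config, "liver_fraction_cellular", "config"))
    v_liv = float(_require(volumes_per_kg, "liver", "tissue_volumes_ml_per_kg")) * bw
    ha_flow = float(_require(flows_per_kg, "hepatic_artery", "tissue_flows_ml_min_kg")) * bw
    flows_per_kg.pop("hepatic_artery")

    physiology = SpeciesPhysiology(
        species_id=species_id,
        bodyweight=bw,
        tissue_volumes={t: float(v) * bw for t, v in volumes_per_kg.items()},
        tissue_blood_flows={t: float(q) * bw for t, q in flows_per_kg.items()},
        hepatic_artery_flow=ha_flow,
        v_liv_c=f_cell * v_liv,
        v_liv_vi=(1.0 - f_cell) * v_liv,
        gfr=float(_require(config, "gfr_ml_min_kg", "config")),
        liver_mass_per_kg=liver_mass_per_kg,
        hematocrit=float(_require(config, "hematocrit", "config")),
    )

    ph = config.get("ph", {"plasma": 7.4, "interstitial": 7.4, "intracellular": 7.0})
    comp_cfg = _require(config, "compound", "config")
    ionization = dict(_require(comp_cfg, "ionization", "compound"))
    compound = CompoundProperties(
        name=comp_cfg.get("name", "compound"),
        molar_mass=float(_require(comp_cfg, "molar_mass_g_mol", "compound")),
        logp=float(_require(comp_cfg, "logp", "compound")),
        ionization=ionization,
        fup=float(_require(comp_cfg, "fup", "compound")),
        blood_to_plasma_ratio=float(_require(comp_cfg, "blood_to_plasma_ratio", "compound")),
        fu_liv_c=float(_require(comp_cfg, "fu_liv_c", "compound")),
        fu_invitro=float(comp_cfg.get("fu_invitro", 1.0)),
        hematocrit=physiology.hematocrit,
    )
    compound.fn_liv_c = distribution.fraction_neutral(ionization, ph["intracellular"])
    compound.fn_liv_int = distribution.fraction_neutral(ionization, ph["interstitial"])

    hep_cfg = _require(config, "hepatic", "config")
    hepatic = HepaticParameters(
        cl_act_in=float(_require(hep_cfg, "cl_act_in_ml_min_g", "hepatic")),
        cl_act_ef=float(_require(hep_cfg, "cl_act_ef_ml_min_g", "hepatic")),
        ps_diff=float(_require(hep_cfg, "ps_diff_ml_min_g", "hepatic")),
        cl_bile=float(_require(hep_cfg, "cl_bile_ml_min_g", "hepatic")),
        vmax_liv=float(_require(hep_cfg, "vmax_liv_nmol_min_g", "hepatic")),
        km_liv=float(_require(hep_cfg, "km_liv_um", "hepatic")),
    )

    partition = distribution.predict_partition_coefficients(
        compound,
        k_liv_vas_vi=float(_require(hep_cfg, "k_liv_vas_vi", "hepatic")),
        k_liv_int_u_vi=float(_require(hep_cfg, "k_liv_int_u_vi", "hepatic")),
    )

    abs_cfg = _require(config, "absorption", "config")
    absorption = AbsorptionParameters(
        k_per=float(abs_cfg.get("k_per_per_h", DEFAULT_K_PER_PER_H)),
        k_a=float(_require(abs_cfg, "k_a_per_h", "absorption")),
        f_a=float(_require(abs_cfg, "f_a", "absorption")),
    )

    # extrahepatic constants are derived, not configured: renal clearance is
    # fuP*GFR and gut metabolism follows the liver/10 rule
    extrahepatic = ExtrahepaticParameters(
        cl_uri=compound.fup * physiology.gfr,
        vmax_gut=hepatic.vmax_liv * physiology.liver_mass / 10.0,
        km_gut=hepatic.km_liv,
    )

    met_cfg = _require(config, "metabolites", "config")
    metabolites = MetaboliteParameters(
        f_dhr_gsh=float(_require(met_cfg, "f_dhr_gsh", "metabolites")),
        f_dhr_prot=float(_require(met_cfg, "f_dhr_prot", "metabolites")),
        f_dhr_dna=float(_require(met_cfg, "f_dhr_dna", "metabolites")),
        f_other=float(_require(met_cfg, "f_other", "metabolites")),
        lambda_dhr_gsh=float(_require(met_cfg, "lambda_dhr_gsh_per_h", "metabolites")),
        lambda_dhr_prot=float(_require(met_cfg, "lambda_dhr_prot_per_h", "metabolites")),
        lambda1_dhr_dna=float(_require(met_cfg, "lambda1_dhr_dna_per_h", "metabolites")),
        lambda2_dhr_dna=float(_require(met_cfg, "lambda2_dhr_dna_per_h", "metabolites")),
        k_dhr_dna=float(_require(met_cfg, "k_dhr_dna_per_h", "metabolites")),
    )

    return PBTKParameterSet(
        physiology=physiology,
        compound=compound,
        partition=partition,
        absorption=absorption,
        hepatic=hepatic,
        extrahepatic=extrahepatic,
        metabolites=metabolites,
    ).validate()
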