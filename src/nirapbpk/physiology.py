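"""Reference individual physiology for whole-body PBPK simulation.

The model individual is a European adult female described at the organ
level: total volumes, plasma flows, vascular/interstitial/intracellular
volume fractions, tissue composition (water, neutral lipid, phospholipid,
protein), sub-compartment pH values and the CES1 enzyme abundance
distribution.  Organ-level system parameters are configuration data
shipped as YAML, not code constants; everything can be overridden from a
user-supplied physiology file.

Hepatic impairment enters either empirically (see :mod:`nirapbpk.hepatic`)
or mechanistically through :class:`HepaticVariant` multipliers applied by
:func:`apply_hepatic_variant`.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "TissueComposition",
    "OrganSpec",
    "ReferenceIndividual",
    "HepaticVariant",
    "load_reference_individual",
    "apply_hepatic_variant",
    "ces1_amounts",
    "child_pugh_variants",
    "PhysiologyError",
]

ORGAN_NAMES = (
    "lung", "heart", "brain", "muscle", "bone", "gonads", "kidney", "liver",
    "small_intestine", "stomach", "skin", "adipose", "spleen", "pancreas",
    "rest",
)
MANDATORY_ORGANS = ("liver", "kidney", "small_intestine")


class PhysiologyError(ValueError):
    """Configuration or validation failure in a physiology table."""


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions of the major tissue constituents."""

    water: float
    neutral_lipid: float
    phospholipid: float
    protein: float

    def validate(self, organ: str) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise PhysiologyError(
                    f"{organ}: composition fraction {name}={value} outside [0, 1]"
                )


@dataclass(frozen=True)
class OrganSpec:
    """One organ of the reference individual.

    Volumes in L, plasma flow in L/min.  For the lung, ``blood_flow`` is
    the full cardiac (plasma) output; for the liver it is the hepatic
    arterial flow only (portal inflow is the sum of the portal organs'
    outflows).  ``ces1_relative_abundance`` is normalized to liver = 1.
    """

    name: str
    total_volume: float
    plasma_fraction: float
    interstitial_fraction: float
    intracellular_fraction: float
    blood_flow: float
    composition: TissueComposition
    pH_interstitial: float = 7.4
    pH_intracellular: float = 7.0
    ces1_relative_abundance: float = 0.0
    #: per-organ override of the cellular exchange surface density
    #: (dm^2 per L intracellular volume); None falls back to the
    #: individual-level default.  The liver ships a high value: the
    #: sinusoidal hepatocyte membrane is heavily folded and hepatic
    #: uptake of lipophilic bases is not rate-limiting in vivo.
    cell_surface_area_per_volume: float | None = None
    #: per-organ override of the charged:neutral permeability ratio;
    #: None falls back to the drug-level factor.  The intestinal mucosa
    #: ships a markedly higher value: paracellular shunt and carrier
    #: traffic make the gut epithelium much less charge-selective than
    #: a plain lipid bilayer.
    ionic_permeability_factor: float | None = None

    def validate(self) -> None:
        if self.total_volume <= 0:
            raise PhysiologyError(f"{self.name}: total_volume must be > 0")
        if self.blood_flow < 0:
            raise PhysiologyError(f"{self.name}: blood_flow must be >= 0")
        fracs = (
            self.plasma_fraction,
            self.interstitial_fraction,
            self.intracellular_fraction,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise PhysiologyError(
                f"{self.name}: sub-compartment fractions must be >= 0 and sum <= 1"
            )
        for label, ph in (("interstitial", self.pH_interstitial),
                          ("intracellular", self.pH_intracellular)):
            if not 6.0 <= ph <= 8.0:
                raise PhysiologyError(
                    f"{self.name}: pH_{label}={ph} outside [6.0, 8.0]"
                )
        if self.ces1_relative_abundance < 0:
            raise PhysiologyError(f"{self.name}: CES1 abundance must be >= 0")
        self.composition.validate(self.name)

    @property
    def vascular_volume(self) -> float:
        return self.total_volume * self.plasma_fraction

    @property
    def interstitial_volume(self) -> float:
        return self.total_volume * self.interstitial_fraction

    @property
    def intracellular_volume(self) -> float:
        return self.total_volume * self.intracellular_fraction


@dataclass
class ReferenceIndividual:
    """Validated whole-body physiology of one simulated individual."""

    body_weight: float
    organs: dict[str, OrganSpec]
    cardiac_output: float
    plasma_pH: float = 7.4
    arterial_plasma_volume: float = 0.65
    venous_plasma_volume: float = 1.35
    gastric_emptying_halflife: float = 15.0
    small_intestine_transit_time: float = 198.0
    lumen_volume: float = 0.105
    intestinal_surface_area: float = 34.0
    cell_surface_area_per_volume: float = 2000.0
    ces1_reference_concentration: float = 27.0
    portal_organs: tuple[str, ...] = ("stomach", "small_intestine", "spleen", "pancreas")
    fu_scale: float = 1.0
    #: thin absorptive mucosal layer (enterocytes) through which all
    #: absorbed drug transits before reaching the villus capillaries;
    #: carries the gut-wall CES1 first-pass.  Volume in L; surface
    #: density dm^2/L; ionic permeability factor of its basolateral
    #: escape (the gut epithelium is weakly charge-selective).
    mucosa_volume: float = 0.30
    mucosa_surface_area_per_volume: float = 84.0
    mucosa_ionic_permeability_factor: float = 0.2

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise PhysiologyError("body_weight must be > 0")
        for organ in MANDATORY_ORGANS:
            if organ not in self.organs:
                raise PhysiologyError(f"mandatory organ missing: {organ}")
        for spec in self.organs.values():
            spec.validate()
        for organ in self.portal_organs:
            if organ not in self.organs:
                raise PhysiologyError(f"portal organ missing: {organ}")
        systemic = self.systemic_flow()
        residual = abs(systemic - self.cardiac_output) / self.cardiac_output
        if residual > 0.01:
            raise PhysiologyError(
                "flow balance violated: systemic organ plasma flows "
                f"({systemic:.4f} L/min) differ from cardiac output "
                f"({self.cardiac_output:.4f} L/min) by {100 * residual:.2f}%"
            )
        if "lung" in self.organs:
            lung_q = self.organs["lung"].blood_flow
            if abs(lung_q - self.cardiac_output) / self.cardiac_output > 0.01:
                raise PhysiologyError(
                    f"lung plasma flow {lung_q} must equal cardiac output"
                )

    def systemic_flow(self) -> float:
        """Sum of arterial-side organ inflows (liver counted as hepatic artery)."""
        return sum(o.blood_flow for n, o in self.organs.items() if n != "lung")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["portal_organs"] = list(self.portal_organs)
        data["organs"] = {
            name: {k: v for k, v in dataclasses.asdict(spec).items() if k != "name"}
            for name, spec in self.organs.items()
        }
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReferenceIndividual":
        data = dict(data)
        organs = {}
        for name, spec in data.pop("organs", {}).items():
            spec = dict(spec)
            comp = spec.pop("composition")
            organs[name] = OrganSpec(
                name=name, composition=TissueComposition(**comp), **spec
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PhysiologyError(f"unknown physiology fields: {sorted(unknown)}")
        data["portal_organs"] = tuple(data.get("portal_organs", ()))
        ind = cls(organs=organs, **data)
        ind.validate()
        return ind

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceIndividual":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        """Per-organ parameter table for inspection / CSV export."""
        rows = []
        for name, o in self.organs.items():
            row = {"organ": name, **{k: v for k, v in dataclasses.asdict(o).items()
                                     if k not in ("name", "composition")}}
            row.update({f"f_{k}": v for k, v in
                        dataclasses.asdict(o.composition).items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("organ")

    def replace_organ(self, name: str, **changes) -> "ReferenceIndividual":
        """Return a copy with fields of one organ replaced."""
        new = copy.deepcopy(self)
        new.organs[name] = dataclasses.replace(new.organs[name], **changes)
        return new


@dataclass(frozen=True)
class HepaticVariant:
    """Multiplicative physiology modifiers for a Child-Pugh grade."""

    label: str
    liver_volume: float = 1.0
    hepatic_arterial_flow: float = 1.0
    portal_flow: float = 1.0
    renal_flow: float = 1.0
    fu_scale: float = 1.0
    ces1: float = 1.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "label":
                continue
            if getattr(self, f.name) <= 0:
                raise PhysiologyError(f"variant multiplier {f.name} must be > 0")

    def compose(self, other: "HepaticVariant") -> "HepaticVariant":
        """Elementwise product of two variants (label from ``other``)."""
        kwargs = {
            f.name: getattr(self, f.name) * getattr(other, f.name)
            for f in dataclasses.fields(self) if f.name != "label"
        }
        return HepaticVariant(label=other.label, **kwargs)


def _default_path(name: str) -> Path:
    return Path(resources.files("nirapbpk.data").joinpath(name))  # type: ignore[arg-type]


def load_reference_individual(config: str | Path | Mapping | None = None) -> ReferenceIndividual:
    """Load and validate a reference individual.

    ``config`` may be a YAML path, an already-parsed mapping, or ``None``
    for the packaged European adult female defaults.
    """
    if config is None:
        config = _default_path("reference_female.yaml")
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    return ReferenceIndividual.from_dict(config)


def apply_hepatic_variant(ind: ReferenceIndividual, v: HepaticVariant) -> ReferenceIndividual:
    """Apply Child-Pugh style multipliers, re-normalize flows, re-validate.

    Returns a new individual; the input is unchanged.  The cardiac output
    is reset to the sum of the modified systemic organ flows so the flow
    balance holds by construction.
    """
    v.validate()
    new = copy.deepcopy(ind)
    liver = new.organs["liver"]
    new.organs["liver"] = dataclasses.replace(
        liver,
        total_volume=liver.total_volume * v.liver_volume,
        blood_flow=liver.blood_flow * v.hepatic_arterial_flow,
        ces1_relative_abundance=liver.ces1_relative_abundance * v.ces1,
    )
    for name in new.portal_organs:
        organ = new.organs[name]
        new.organs[name] = dataclasses.replace(
            organ, blood_flow=organ.blood_flow * v.portal_flow
        )
    kidney = new.organs["kidney"]
    new.organs["kidney"] = dataclasses.replace(
        kidney, blood_flow=kidney.blood_flow * v.renal_flow
    )
    new.fu_scale = ind.fu_scale * v.fu_scale
    systemic = new.systemic_flow()
    if abs(systemic - ind.cardiac_output) > 1e-12 * ind.cardiac_output:
        new.cardiac_output = systemic
        if "lung" in new.organs:
            lung = new.organs["lung"]
            new.organs["lung"] = dataclasses.replace(lung, blood_flow=systemic)
    new.validate()
    return new


def ces1_amounts(ind: ReferenceIndividual) -> dict[str, float]:
    """Per-organ CES1 concentration (µmol per L intracellular volume).

    The liver carries the absolute reference concentration; every other
    organ is scaled by its relative abundance.  Organs without CES1
    return 0.
    """
    ref = ind.ces1_reference_concentration
    return {name: ref * o.ces1_relative_abundance for name, o in ind.organs.items()}


def child_pugh_variants(path: str | Path | None = None) -> dict[str, HepaticVariant]:
    """Load the Child-Pugh grade multiplier table (grades A, B, C)."""
    if path is None:
        path = _default_path("child_pugh.yaml")
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for grade, mults in raw.items():
        out[grade] = HepaticVariant(label=grade, **mults)
        out[grade].validate()
    return out
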