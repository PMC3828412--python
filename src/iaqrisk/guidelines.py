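"""Guideline concentrations, inhalation unit risks, and hazard-index screening.

Reference values come from three issuing bodies:

* the Chinese National Indoor Air Quality Standard (GB/T 18883-2002),
  which publishes indoor-air limit values in mg/m³;
* the California OEHHA, which publishes acute and chronic reference
  exposure levels (RELs) in µg/m³ and inhalation unit risks (IURs);
* the U.S. EPA IRIS database, which publishes chronic reference
  concentrations (RfCs) and IURs.

All concentrations are held internally in µg/m³ (GB/T values are converted
from mg/m³ at registry load). IURs are lifetime (70-year) excess cancer
risks per (µg/m³) of continuous exposure; per-million scaling happens once,
in :mod:`iaqrisk.risk`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "GuidelineValue",
    "ToxicityFactor",
    "HazardIndex",
    "Registry",
    "RegistryLookupError",
    "load_registry",
    "get_guideline",
    "get_toxicity_factor",
    "hazard_index",
    "risk_equivalent_concentration",
    "mg_to_ug",
    "ug_to_mg",
]

MG_PER_UG = 1e-3
UG_PER_MG = 1e3


def mg_to_ug(value_mg_m3: float) -> float:
    """Convert a concentration from mg/m³ to µg/m³."""
    return value_mg_m3 * UG_PER_MG


def ug_to_mg(value_ug_m3: float) -> float:
    """Convert a concentration from µg/m³ to mg/m³."""
    return value_ug_m3 * MG_PER_UG


class RegistryLookupError(KeyError):
    """Raised when no registry entry matches a (compound, source, class) query."""


@dataclass(frozen=True)
class GuidelineValue:
    """A reference concentration from an issuing body.

    ``effect_class`` distinguishes acute RELs, chronic RfCs/RELs, and
    indoor-air-quality standard limits. ``threshold`` is in µg/m³.
    """

    compound: str
    source: str
    effect_class: str
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"guideline threshold must be positive, got {self.threshold}")


@dataclass(frozen=True)
class ToxicityFactor:
    """An inhalation unit risk: lifetime excess cancer risk per (µg/m³).

    Where an issuing body publishes more than one IUR for a compound
    (EPA IRIS gives two for benzene), the upper value is the ``default``
    variant — giving a maximum risk estimate — and the lower is retained
    as ``alternate``.
    """

    compound: str
    source: str
    iur: float
    variant: str = "default"

    def __post_init__(self) -> None:
        if self.iur <= 0:
            raise ValueError(f"inhalation unit risk must be positive, got {self.iur}")


@dataclass(frozen=True)
class HazardIndex:
    """Ratio of exposure concentration to a guideline threshold.

    Values above 1 flag potential non-carcinogenic risk; at or below 1 the
    exposed population is considered unlikely to be at risk.
    """

    value: float
    compound: str
    guideline: GuidelineValue

    @property
    def flagged(self) -> bool:
        return self.value > 1.0


class Registry:
    """In-memory registry of guideline values and toxicity factors."""

    def __init__(
        self,
        guidelines: list[GuidelineValue],
        toxicity_factors: list[ToxicityFactor],
    ) -> None:
        self._guidelines: dict[tuple[str, str, str], GuidelineValue] = {}
        for g in guidelines:
            key = (g.compound, g.source, g.effect_class)
            if key in self._guidelines:
                raise ValueError(f"duplicate guideline entry {key}")
            self._guidelines[key] = g
        self._factors: dict[tuple[str, str, str], ToxicityFactor] = {}
        defaults_seen: set[tuple[str, str]] = set()
        for f in toxicity_factors:
            key = (f.compound, f.source, f.variant)
            if key in self._factors:
                raise ValueError(f"duplicate toxicity entry {key}")
            if f.variant == "default":
                if (f.compound, f.source) in defaults_seen:
                    raise ValueError(
                        f"multiple default IURs for ({f.compound}, {f.source})"
                    )
                defaults_seen.add((f.compound, f.source))
            self._factors[key] = f

    def guideline(self, compound: str, source: str, effect_class: str) -> GuidelineValue:
        try:
            return self._guidelines[(compound, source, effect_class)]
        except KeyError:
            raise RegistryLookupError(
                f"no guideline for compound={compound!r}, source={source!r}, "
                f"effect_class={effect_class!r}"
            ) from None

    def toxicity_factor(
        self, compound: str, source: str, variant: str = "default"
    ) -> ToxicityFactor:
        try:
            return self._factors[(compound, source, variant)]
        except KeyError:
            raise RegistryLookupError(
                f"no inhalation unit risk for compound={compound!r}, "
                f"source={source!r}, variant={variant!r}"
            ) from None

    def guidelines_for(self, compound: str) -> list[GuidelineValue]:
        return [g for g in self._guidelines.values() if g.compound == compound]


def _packaged_registry_path() -> Path:
    return Path(importlib.resources.files("iaqrisk") / "data" / "registry.csv")


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the guideline/IUR registry from CSV.

    The CSV carries explicit unit tags; mg/m³ guideline values are converted
    to µg/m³ here so every downstream computation sees a single unit.
    """
    df = pd.read_csv(path if path is not None else _packaged_registry_path())
    guidelines: list[GuidelineValue] = []
    factors: list[ToxicityFactor] = []
    for row in df.itertuples(index=False):
        if row.kind == "guideline":
            if row.units == "mg/m3":
                threshold = mg_to_ug(float(row.value))
            elif row.units == "ug/m3":
                threshold = float(row.value)
            else:
                raise ValueError(f"unknown concentration units {row.units!r}")
            guidelines.append(
                GuidelineValue(row.compound, row.source, row.class_or_variant, threshold)
            )
        elif row.kind == "iur":
            if row.units != "per_ug/m3":
                raise ValueError(f"unknown IUR units {row.units!r}")
            factors.append(
                ToxicityFactor(row.compound, row.source, float(row.value), row.class_or_variant)
            )
        else:
            raise ValueError(f"unknown registry row kind {row.kind!r}")
    return Registry(guidelines, factors)


_DEFAULT_REGISTRY: Registry | None = None


def default_registry() -> Registry:
    """The packaged registry, loaded once."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def get_guideline(compound: str, source: str, effect_class: str) -> GuidelineValue:
    """Look up a guideline in the packaged registry, in µg/m³."""
    return default_registry().guideline(compound, source, effect_class)


def get_toxicity_factor(
    compound: str, source: str, variant: str = "default"
) -> ToxicityFactor:
    """Look up an inhalation unit risk in the packaged registry."""
    return default_registry().toxicity_factor(compound, source, variant)


def hazard_index(c_exp: float, guideline: GuidelineValue) -> HazardIndex:
    """Hazard index HI = C_exp / threshold.

    ``c_exp`` is the inhalation exposure concentration in µg/m³. HI > 1
    flags a potential non-carcinogenic hazard.
    """
    if c_exp < 0:
        raise ValueError(f"exposure concentration must be non-negative, got {c_exp}")
    return HazardIndex(value=c_exp / guideline.threshold, compound=guideline.compound, guideline=guideline)


def risk_equivalent_concentration(target_risk_per_million: float, factor: ToxicityFactor) -> float:
    """Concentration (µg/m³) whose lifetime cancer risk equals a per-million target.

    Inverts risk = C × IUR: C = target × 1e-6 / IUR. For example, 100 excess
    cases per million under the EPA IRIS formaldehyde IUR of 1.3e-5 per
    (µg/m³) corresponds to ≈ 7.7 µg/m³.
    """
    if target_risk_per_million <= 0:
        raise ValueError(f"target risk must be positive, got {target_risk_per_million}")
    return target_risk_per_million * 1e-6 / factor.iur
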