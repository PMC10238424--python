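"""Dye/protein constant registry and unit plumbing.

Every downstream calculation pulls its photophysical and protein constants
from here.  Internal unit conventions, used throughout the package:

* concentrations in mol/L
* time in seconds
* mass in Da
* wavelength in nm
* optical path length in cm (default 1 cm)

Public helpers accept the bench-side units (uM, mg/mL, minutes) explicitly
named in the function signature so no silent conversion ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DyeSpec",
    "ProteinSpec",
    "Constants",
    "CONSTANTS",
    "lookup_dye",
    "lookup_protein",
    "load_registry",
    "merge_registry",
    "molar_concentration",
    "uM",
]


def uM(x: float) -> float:
    """Convert micromolar to mol/L (internal unit)."""
    return x * 1e-6


@dataclass(frozen=True)
class DyeSpec:
    """Photophysical constants of a DBCO-functionalized dye.

    Parameters
    ----------
    name : str
        Registry key, e.g. ``"AZ488"``.
    lambda_max : float or None
        Absorption maximum in nm.
    eps_max : float or None
        Extinction coefficient at ``lambda_max``, L/mol/cm.
    cf280 : float or None
        Correction factor: fraction of the dye's peak absorbance that it
        contributes at 280 nm.  Subtracted from A280 before computing the
        protein concentration.  Dye-specific; no default is ever assumed.
    reacts_fully : bool
        False for dyes observed to leave unreacted residuals after a 24 h
        SPAAC incubation (AZ532, AZ647); such dyes break the
        no-purification guarantee and the planner warns on them.
    """

    name: str
    lambda_max: float | None = None
    eps_max: float | None = None
    cf280: float | None = None
    reacts_fully: bool = True

    def __post_init__(self) -> None:
        if self.eps_max is not None and self.eps_max <= 0:
            raise ValueError("eps_max must be positive")
        if self.cf280 is not None and not (0 <= self.cf280 < 1):
            raise ValueError("cf280 must lie in [0, 1)")
        if self.lambda_max is not None and not (300 <= self.lambda_max <= 800):
            raise ValueError("lambda_max must lie in [300, 800] nm")

    def require_optics(self) -> "DyeSpec":
        """Return self, raising if eps_max/cf280/lambda_max are missing."""
        missing = [
            f
            for f in ("lambda_max", "eps_max", "cf280")
            if getattr(self, f) is None
        ]
        if missing:
            raise ValueError(
                f"dye {self.name!r} lacks published constants {missing}; "
                "supply them explicitly (no silent defaults)"
            )
        return self


@dataclass(frozen=True)
class ProteinSpec:
    """Protein identity: molecular weight and 280 nm extinction coefficient."""

    name: str
    mw: float  # Da
    eps280: float  # L/mol/cm
    max_ir_tested: int | None = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.eps280 <= 0:
            raise ValueError("eps280 must be positive")


@dataclass(frozen=True)
class Constants:
    """Fixed protocol constants.

    eps_nhs_260
        Extinction coefficient of hydrolyzed NHS at 260 nm (L/mol/cm),
        used to titrate azidoacetyl-NHS stocks.
    azidoacetyl_mass
        Average mass increment per azidoacetyl attachment,
        azidoacetic acid (101.07 Da) minus water (18.02 Da).  The
        monoisotopic alternative is 83.012 Da.
    min_dbco_conc / min_azide_conc
        Minimum reactant concentrations (mol/L) for which a 24 h SPAAC
        incubation reaches completion.
    """

    eps_nhs_260: float = 9_700.0
    azidoacetyl_mass: float = 83.05
    azidoacetyl_mass_mono: float = 83.012
    min_dbco_conc: float = 10e-6
    min_azide_conc: float = 25e-6


CONSTANTS = Constants()

# Dyes with published constants get the full record; the remaining
# DBCO dyes from the parallel-labeling panel ship with reactivity flags
# only — their eps/CF must be supplied by the caller when needed.
_DYES: dict[str, DyeSpec] = {
    d.name: d
    for d in [
        DyeSpec("AZ488", lambda_max=495.0, eps_max=70_000.0, cf280=0.147),
        DyeSpec("Cy5", lambda_max=663.0, eps_max=255_000.0, cf280=0.05),
        DyeSpec("AZ405"),
        DyeSpec("AZ430"),
        DyeSpec("AZ532", reacts_fully=False),
        DyeSpec("AZ546"),
        DyeSpec("AZ568"),
        DyeSpec("AZ594"),
        DyeSpec("AZ647", reacts_fully=False),
    ]
}

_PROTEINS: dict[str, ProteinSpec] = {
    p.name: p
    for p in [
        ProteinSpec("Ab", mw=150_000.0, eps280=217_500.0, max_ir_tested=24),
        ProteinSpec("apoMb", mw=17_000.0, eps280=15_900.0, max_ir_tested=8),
    ]
}


def lookup_dye(name: str, registry: Mapping[str, DyeSpec] | None = None) -> DyeSpec:
    """Return the immutable spec for a registered dye.

    Raises
    ------
    KeyError
        If ``name`` is not in the registry.
    """
    reg = _DYES if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown dye {name!r}; registered: {sorted(reg)}"
        ) from None


def lookup_protein(
    name: str, registry: Mapping[str, ProteinSpec] | None = None
) -> ProteinSpec:
    """Return the immutable spec for a registered protein."""
    reg = _PROTEINS if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown protein {name!r}; registered: {sorted(reg)}"
        ) from None


def molar_concentration(mass_conc_g_per_L: float, protein: ProteinSpec) -> float:
    """Convert a mass concentration (g/L == mg/mL) to mol/L.

    Linear in ``mass_conc_g_per_L``; e.g. a 2 mg/mL antibody (150 kDa)
    is 13.33 uM.
    """
    if mass_conc_g_per_L < 0:
        raise ValueError("mass concentration must be >= 0")
    return mass_conc_g_per_L / protein.mw


def load_registry(path: str | Path) -> dict[str, dict]:
    """Load a YAML/JSON registry file of dye and protein entries.

    Returns ``{"dyes": {name: DyeSpec}, "proteins": {name: ProteinSpec}}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    dyes = {
        name: DyeSpec(name=name, **entry)
        for name, entry in (raw.get("dyes") or {}).items()
    }
    proteins = {
        name: ProteinSpec(name=name, **entry)
        for name, entry in (raw.get("proteins") or {}).items()
    }
    return {"dyes": dyes, "proteins": proteins}


def merge_registry(extra: dict[str, dict]) -> dict[str, dict]:
    """Merge user entries over the built-ins; user entries win on clashes."""
    dyes = dict(_DYES)
    dyes.update(extra.get("dyes", {}))
    proteins = dict(_PROTEINS)
    proteins.update(extra.get("proteins", {}))
    return {"dyes": dyes, "proteins": proteins}


def with_overrides(dye: DyeSpec, **kwargs) -> DyeSpec:
    """Return a copy of ``dye`` with fields replaced (registry untouched)."""
    return replace(dye, **kwargs)
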