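"""Beer-Lambert degree-of-labeling from absorbance, with 280 nm dye correction.

The average degree of labeling (aDoL) of a dye-protein conjugate follows
from two absorbance readings and three constants:

    [dye]     = A_max / (eps_max * l)
    [protein] = (A280 - CF * A_max) / (eps280 * l)
    aDoL      = [dye] / [protein]

where A_max is the absorbance at the dye's maximum, CF is the dye's
280 nm correction factor (fraction of A_max the dye contributes at
280 nm), and l the path length in cm.  For AZ488 on an antibody this is
[AZ488] = A495/70,000 and [Ab] = (A280 - 0.147*A495)/217,500.

Also provides the hydrolyzed-NHS concentration check at 260 nm
(eps = 9,700 /M/cm), used to titrate azidoacetyl-NHS stocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registry import CONSTANTS, DyeSpec, ProteinSpec

__all__ = [
    "AbsorbancePair",
    "AdolResult",
    "adol_from_absorbance",
    "adol_from_spectrum",
    "nhs_concentration_260",
    "reduce_spectrum",
]


@dataclass(frozen=True)
class AbsorbancePair:
    """A280 and the absorbance at the dye's lambda_max, with path length (cm)."""

    a280: float
    a_dyemax: float
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.a280 < 0 or self.a_dyemax < 0:
            raise ValueError("absorbances must be >= 0")
        if self.path_cm <= 0:
            raise ValueError("path length must be positive")


@dataclass(frozen=True)
class AdolResult:
    dye_conc: float  # mol/L
    protein_conc: float  # mol/L
    adol: float


def adol_from_absorbance(
    ap: AbsorbancePair, dye: DyeSpec, protein: ProteinSpec
) -> AdolResult:
    """Compute dye and protein concentrations and their ratio (aDoL).

    Raises
    ------
    ValueError
        When the dye-corrected A280 is not positive — the correction
        factor and the inputs are then mutually inconsistent (typically a
        wrong CF or a dye-only sample).
    """
    dye = dye.require_optics()
    dye_conc = ap.a_dyemax / (dye.eps_max * ap.path_cm)
    corrected = ap.a280 - dye.cf280 * ap.a_dyemax
    if corrected <= 0:
        raise ValueError(
            f"corrected A280 = {corrected:.4g} <= 0: the dye correction "
            f"(CF={dye.cf280}) exceeds the measured A280; check inputs"
        )
    protein_conc = corrected / (protein.eps280 * ap.path_cm)
    return AdolResult(
        dye_conc=dye_conc,
        protein_conc=protein_conc,
        adol=dye_conc / protein_conc,
    )


def reduce_spectrum(
    wavelength_nm: np.ndarray,
    absorbance: np.ndarray,
    dye: DyeSpec,
    tol_nm: float = 2.0,
    path_cm: float = 1.0,
) -> AbsorbancePair:
    """Reduce a full spectrum to (A280, A at the dye's lambda_max).

    Nearest-sample lookup; raises if no sample lies within ``tol_nm``
    of either wavelength.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    dye = dye.require_optics()

    def nearest(target: float) -> float:
        i = int(np.argmin(np.abs(wl - target)))
        if abs(wl[i] - target) > tol_nm:
            raise ValueError(
                f"no spectrum sample within {tol_nm} nm of {target} nm"
            )
        return float(ab[i])

    return AbsorbancePair(
        a280=nearest(280.0), a_dyemax=nearest(dye.lambda_max), path_cm=path_cm
    )


def adol_from_spectrum(
    wavelength_nm, absorbance, dye: DyeSpec, protein: ProteinSpec, path_cm: float = 1.0
) -> AdolResult:
    """Convenience: reduce a spectrum and compute the aDoL."""
    ap = reduce_spectrum(wavelength_nm, absorbance, dye, path_cm=path_cm)
    return adol_from_absorbance(ap, dye, protein)


def nhs_concentration_260(a260: float, path_cm: float = 1.0) -> float:
    """Hydrolyzed-NHS concentration (mol/L) from A260, eps = 9,700 /M/cm."""
    if a260 < 0:
        raise ValueError("a260 must be >= 0")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return a260 / (CONSTANTS.eps_nhs_260 * path_cm)
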