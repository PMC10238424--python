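"""Synthetic-data generators for every input the analysis pipeline consumes.

Each generator emulates one instrument observable with the statistical
structure the corresponding analysis assumes, so the full pipeline is
testable offline:

* SEC chromatogram time series — two Gaussian peaks (conjugate 8.8 min,
  free dye 16.5 min) whose areas split a constant total dye signal by
  the second-order rate law;
* absorption spectra — Gaussian protein (280 nm) and dye (lambda_max)
  bands obeying Beer-Lambert, with the dye's 280 nm cross-talk enforced
  pointwise to CF x A_max;
* deconvoluted intact-mass peak lists — an 83.05 Da ladder with
  Poisson-distributed intensities at the generating incorporation ratio;
* FCS autocorrelation curves — one/two-component 3D-diffusion model
  with multiplicative noise.

All generators are pure functions of their arguments plus a seed:
identical inputs produce bit-identical outputs.  Peak widths, band
widths, lag grids and noise defaults are realism choices, configurable
per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .chromatogram import CONJUGATE_RT, FREE_DYE_RT, Chromatogram
from .fcs import (
    DEFAULT_STRUCTURE_PARAMETER,
    CorrelationCurve,
    FcsComponent,
    FcsFit,
    g_model,
)
from .kinetics import ReactionConditions, fraction_reacted
from .ms import MassPeakList
from .registry import CONSTANTS, DyeSpec, ProteinSpec, lookup_dye, lookup_protein

__all__ = [
    "NoiseModel",
    "Scenario",
    "fig2_scenario",
    "gen_chromatogram_series",
    "gen_spectrum",
    "gen_ms_peaks",
    "gen_fcs_curve",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-instrument noise levels (all >= 0; zero = noiseless)."""

    chromatogram_rel: float = 0.02
    spectrum_abs: float = 0.002
    fcs_rel: float = 0.01
    ms_rel: float = 0.02

    def __post_init__(self) -> None:
        for f in ("chromatogram_rel", "spectrum_abs", "fcs_rel", "ms_rel"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """One simulated labeling experiment: reaction, reagents, sampling, noise."""

    name: str
    rc: ReactionConditions
    dye: DyeSpec
    protein: ProteinSpec
    ir: float
    timepoints: tuple[float, ...]  # s
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def with_noise(self, **kwargs) -> "Scenario":
        return replace(self, noise=replace(self.noise, **kwargs))

    @property
    def protein_conc(self) -> float:
        """Protein molar concentration implied by a0 = I.R. x protein."""
        return self.rc.a0 / self.ir


def fig2_scenario(seed: int = 0, noise: NoiseModel | None = None) -> Scenario:
    """The reference antibody-labeling monitoring experiment.

    Antibody at 2 mg/mL (13.33 uM, 150 kDa) activated to an I.R. of 5.6,
    reacted with 2x AZ488-DBCO (26.67 uM): azide sites a0 = 74.67 uM,
    dye b0 = 26.67 uM, K = 4.31 /M/s, sampled at 5 min, 55 min, 267 min
    and 24 h.
    """
    protein = lookup_protein("Ab")
    protein_conc = 2.0 / protein.mw  # 2 mg/mL
    ir = 5.6
    rc = ReactionConditions(a0=ir * protein_conc, b0=2.0 * protein_conc, k=4.31)
    return Scenario(
        name="fig2",
        rc=rc,
        dye=lookup_dye("AZ488"),
        protein=protein,
        ir=ir,
        timepoints=(5 * 60.0, 55 * 60.0, 267 * 60.0, 24 * 3600.0),
        noise=noise if noise is not None else NoiseModel(),
        seed=seed,
    )


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_chromatogram_series(
    sc: Scenario,
    total_area: float = 1.0,
    sigma_conjugate: float = 0.15,
    sigma_free: float = 0.10,
    rt_step: float = 0.01,
) -> list[Chromatogram]:
    """Simulate the SEC monitoring series of a click reaction.

    Per timepoint, the constant total dye area (AU*min) is split between
    the conjugate and free-dye Gaussian peaks by the fraction reacted at
    that time; multiplicative Gaussian noise at ``sc.noise.chromatogram_rel``.
    """
    rng = np.random.default_rng(sc.seed)
    rt = np.arange(0.0, 20.0 + rt_step / 2, rt_step)
    out = []
    for t in sc.timepoints:
        f = fraction_reacted(t, sc.rc)
        area_conj = f * total_area
        area_free = (1.0 - f) * total_area
        h_conj = area_conj / (sigma_conjugate * np.sqrt(2 * np.pi))
        h_free = area_free / (sigma_free * np.sqrt(2 * np.pi))
        signal = h_conj * _gaussian(rt, CONJUGATE_RT, sigma_conjugate)
        signal += h_free * _gaussian(rt, FREE_DYE_RT, sigma_free)
        if sc.noise.chromatogram_rel > 0:
            signal *= 1.0 + sc.noise.chromatogram_rel * rng.standard_normal(rt.size)
        out.append(
            Chromatogram(
                rt=rt,
                signal=signal,
                detection_nm=sc.dye.lambda_max or 493.0,
                timestamp=t,
            )
        )
    return out


def gen_spectrum(
    adol: float,
    protein_conc: float,
    dye: DyeSpec,
    protein: ProteinSpec,
    noise_abs: float = 0.0,
    seed: int = 0,
    wl_min: float = 240.0,
    wl_max: float = 750.0,
    wl_step: float = 1.0,
    sigma_protein: float = 12.0,
    sigma_dye: float = 15.0,
    path_cm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the absorption spectrum of a dye-protein conjugate.

    Protein band: Gaussian at 280 nm, peak eps280 x conc x path.
    Dye band: Gaussian at lambda_max, peak eps_max x adol x conc x path.
    The dye's 280 nm cross-talk is enforced exactly: an extra 280 nm
    Gaussian brings the total dye contribution at 280 nm to CF x A_max.
    Returns ``(wavelength_nm, absorbance)``.
    """
    if adol < 0:
        raise ValueError("adol must be >= 0")
    dye = dye.require_optics()
    rng = np.random.default_rng(seed)
    wl = np.arange(wl_min, wl_max + wl_step / 2, wl_step)
    a_protein_peak = protein.eps280 * protein_conc * path_cm
    a_dye_peak = dye.eps_max * adol * protein_conc * path_cm
    spec = a_protein_peak * _gaussian(wl, 280.0, sigma_protein)
    dye_band = a_dye_peak * _gaussian(wl, dye.lambda_max, sigma_dye)
    # 280 nm cross-talk: top up the dye's absorbance at 280 nm to CF*A_max
    crosstalk_peak = dye.cf280 * a_dye_peak - a_dye_peak * _gaussian(
        np.array([280.0]), dye.lambda_max, sigma_dye
    )[0]
    spec += dye_band + max(crosstalk_peak, 0.0) * _gaussian(wl, 280.0, sigma_protein)
    if noise_abs > 0:
        spec = spec + noise_abs * rng.standard_normal(wl.size)
    return wl, spec


def gen_ms_peaks(
    protein: ProteinSpec,
    ir: float,
    n_max: int = 15,
    total_weight: float = 1.0,
    noise_rel: float = 0.0,
    seed: int = 0,
    delta: float = CONSTANTS.azidoacetyl_mass,
) -> MassPeakList:
    """Simulate a deconvoluted intact-mass ladder of an activated protein.

    Masses base + n*delta for n = 0..n_max; intensities proportional to
    the Poisson pmf at mean ``ir``, perturbed by relative Gaussian noise,
    truncated and renormalized to ``total_weight``.
    """
    if ir < 0:
        raise ValueError("ir must be >= 0")
    rng = np.random.default_rng(seed)
    if ir == 0:
        return MassPeakList(
            masses=[protein.mw], intensities=[total_weight], base_mass=protein.mw
        )
    n = np.arange(0, n_max + 1)
    w = poisson.pmf(n, ir)
    if noise_rel > 0:
        w = w * np.clip(1.0 + noise_rel * rng.standard_normal(n.size), 0.0, None)
    w = w / w.sum() * total_weight
    keep = w > 0
    return MassPeakList(
        masses=protein.mw + n[keep] * delta,
        intensities=w[keep],
        base_mass=protein.mw,
    )


def gen_fcs_curve(
    components: Sequence[FcsComponent],
    n: float,
    mean_intensity: float | None = None,
    lag_min: float = 1e-6,
    lag_max: float = 1.0,
    n_lags: int = 64,
    noise_rel: float = 0.0,
    seed: int = 0,
    s: float = DEFAULT_STRUCTURE_PARAMETER,
) -> CorrelationCurve:
    """Simulate an FCS autocorrelation curve on a log-spaced lag grid.

    The 3D-diffusion model is evaluated for the given components and
    occupancy, then multiplied by (1 + noise_rel x N(0,1)) per lag.
    """
    fracs = sum(c.fraction for c in components)
    if abs(fracs - 1.0) > 1e-9:
        raise ValueError("component fractions must sum to 1")
    rng = np.random.default_rng(seed)
    lags = np.logspace(np.log10(lag_min), np.log10(lag_max), n_lags)
    fit = FcsFit(n=n, components=tuple(components), s=s)
    g = g_model(lags, fit)
    if noise_rel > 0:
        g = g * (1.0 + noise_rel * rng.standard_normal(lags.size))
    return CorrelationCurve(lags=lags, g=g, mean_intensity=mean_intensity)
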