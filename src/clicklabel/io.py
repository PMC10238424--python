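"""CSV/JSON readers and writers for every data dialect in the package.

Conventions: comma-separated, dot decimal, UTF-8, one header row with
unit-suffixed column names (``rt_min``, ``absorbance_au``, ``mass_da``,
``lag_s``, ...).  Array-valued instrument files are CSV; scalar metadata
(detection wavelength, timestamp, mean intensity) travel in a JSON
sidecar next to the CSV; analysis results are JSON with a provenance
header (tool version, seed, input hashes).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .chromatogram import Chromatogram
from .fcs import CorrelationCurve
from .kinetics import KineticTrace
from .ms import MassPeakList

__all__ = [
    "read_chromatogram",
    "write_chromatogram",
    "read_kinetic_trace",
    "write_kinetic_trace",
    "read_spectrum",
    "write_spectrum",
    "read_mass_peaks",
    "write_mass_peaks",
    "read_fcs_curve",
    "write_fcs_curve",
    "write_result",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValueError(f"{path}: cannot parse as CSV ({exc})") from exc


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"rt_min": chrom.rt, "absorbance_au": chrom.signal}).to_csv(
        path, index=False
    )
    _sidecar(path).write_text(
        json.dumps(
            {"detection_nm": chrom.detection_nm, "timestamp_s": chrom.timestamp}
        )
    )


def read_chromatogram(path: str | Path) -> Chromatogram:
    path = Path(path)
    df = _read_csv(path)
    _require_columns(df, ["rt_min", "absorbance_au"], path)
    meta: dict[str, Any] = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Chromatogram(
        rt=df["rt_min"].to_numpy(),
        signal=df["absorbance_au"].to_numpy(),
        detection_nm=meta.get("detection_nm", 493.0),
        timestamp=meta.get("timestamp_s", 0.0),
    )


def write_kinetic_trace(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "fraction": trace.fraction_reacted}
    ).to_csv(path, index=False)


def read_kinetic_trace(path: str | Path) -> KineticTrace:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "fraction"], path)
    return KineticTrace(
        times=df["time_s"].to_numpy(), fraction_reacted=df["fraction"].to_numpy()
    )


def write_spectrum(wavelength_nm, absorbance, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": np.asarray(wavelength_nm), "absorbance": np.asarray(absorbance)}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path)
    _require_columns(df, ["wavelength_nm", "absorbance"], path)
    return df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy()


def write_mass_peaks(mpl: MassPeakList, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"mass_da": mpl.masses, "intensity": mpl.intensities}).to_csv(
        path, index=False
    )
    _sidecar(path).write_text(json.dumps({"base_mass_da": mpl.base_mass}))


def read_mass_peaks(path: str | Path, base_mass: float | None = None) -> MassPeakList:
    path = Path(path)
    df = _read_csv(path)
    _require_columns(df, ["mass_da", "intensity"], path)
    if base_mass is None:
        sc = _sidecar(path)
        if not sc.exists():
            raise ValueError(
                f"{path}: base_mass not given and no sidecar {sc.name} found"
            )
        base_mass = json.loads(sc.read_text())["base_mass_da"]
    return MassPeakList(
        masses=df["mass_da"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        base_mass=base_mass,
    )


def write_fcs_curve(curve: CorrelationCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"lag_s": curve.lags, "g": curve.g}).to_csv(path, index=False)
    if curve.mean_intensity is not None:
        _sidecar(path).write_text(
            json.dumps({"mean_intensity_cps": curve.mean_intensity})
        )


def read_fcs_curve(path: str | Path) -> CorrelationCurve:
    path = Path(path)
    df = _read_csv(path)
    _require_columns(df, ["lag_s", "g"], path)
    mean_intensity = None
    sc = _sidecar(path)
    if sc.exists():
        mean_intensity = json.loads(sc.read_text()).get("mean_intensity_cps")
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(), g=df["g"].to_numpy(), mean_intensity=mean_intensity
    )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_result(
    payload: dict,
    path: str | Path,
    seed: int | None = None,
    inputs: list[str | Path] | None = None,
) -> None:
    """Write an analysis result JSON with a provenance header.

    The header records the package version, the run seed and a short
    sha256 of every input file, so a result can always be traced back.
    """
    doc = {
        "provenance": {
            "tool": "clicklabel",
            "version": __version__,
            "seed": seed,
            "inputs": {
                str(p): _hash_file(Path(p)) for p in (inputs or [])
            },
        },
        "result": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")
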