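"""Sensor conditioning: flat-field correction, band trimming, normalization.

A line-scan NIR sensor exhibits fixed-pattern noise -- temporally coherent
column-to-column sensitivity differences that show up as vertical stripes --
plus a dark-current offset, and both drift with sensor temperature and
exposure settings.  Conditioning proceeds in a fixed order:

1. **Flat-field correction** with a dark frame D (shutter closed) and a flat
   frame F (homogeneous bright target): C = (I - D) * m / (F - D), where m is
   the mean of the corrected flat field F - D.  Equivalently C = (I - D) / G
   with the gain G = (F - D) / m.  After correction a homogeneous surface
   appears flat.
2. **Band trimming**: the first and last 20 of the 224 bands are noisy and
   weakly illuminated and are dropped, leaving 184 bands.
3. **Per-pixel spectral normalization** to make the representation invariant
   to residual gain/offset drift and to attenuate shadows.  Default mode
   ``minmax`` maps each pixel spectrum s to (s - min s) / (max s - min s),
   which cancels any per-pixel affine transform with positive gain;
   ``max`` divides by max s instead and cancels pure gain only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cube_io import CalibrationPair, Hypercube, N_BANDS_RAW, N_BANDS_TRIMMED

logger = logging.getLogger(__name__)

#: Band indices kept by trimming: 20 .. 203 inclusive.
TRIM_FIRST = 20
TRIM_LAST = 20

#: Degenerate-spectrum guard for normalization denominators.
NORM_EPS = 1e-8


@dataclass
class GainField:
    """Per-(column, band) multiplicative gain G = (F - D) / m.

    ``m`` is the mean of the corrected flat field over all columns and bands.
    Correction divides by G, so C = (I - D) / G = (I - D) * m / (F - D).
    """

    gain: np.ndarray
    m: float

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        if np.any(self.gain <= 0):
            raise ValueError("gain must be strictly positive everywhere")


@dataclass
class CalibrationLibrary:
    """Dark/flat pairs acquired at distinct sensor temperatures."""

    pairs: list[CalibrationPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        temps = [p.temperature for p in self.pairs]
        if len(set(temps)) != len(temps):
            raise ValueError(f"calibration temperatures must be unique, got {temps}")


def compute_gain(pair: CalibrationPair) -> GainField:
    """Gain field of a dark/flat pair: m = mean(F - D), G = (F - D) / m."""
    diff = pair.flat - pair.dark  # strict positivity enforced by CalibrationPair
    m = float(diff.mean())
    return GainField(gain=diff / m, m=m)


def flat_field_correct(cube: Hypercube, pair: CalibrationPair) -> Hypercube:
    """Apply C = (I - D) * m / (F - D) per line; negative results clamp to 0."""
    if cube.state != "raw224":
        raise ValueError(f"flat-field correction expects a raw224 cube, got state {cube.state!r}")
    lines, samples, bands = cube.shape
    if pair.dark.shape != (samples, bands):
        raise ValueError(
            f"calibration frames of shape {pair.dark.shape} do not match cube (samples, bands) = "
            f"({samples}, {bands})"
        )
    g = compute_gain(pair)
    corrected = (cube.data.astype(np.float64) - pair.dark[None, :, :]) / g.gain[None, :, :]
    np.maximum(corrected, 0.0, out=corrected)
    meta = dict(cube.meta)
    meta.setdefault("temperature", pair.temperature)
    return Hypercube(
        data=corrected.astype(np.float32),
        wavelengths=cube.wavelengths,
        state="corrected224",
        meta=meta,
    )


def trim_bands(cube: Hypercube) -> Hypercube:
    """Drop the 20 noisiest bands at each spectral edge (keep indices 20..203)."""
    if cube.state != "corrected224":
        raise ValueError(f"band trimming expects a corrected224 cube, got state {cube.state!r}")
    if cube.n_bands != N_BANDS_RAW:
        raise ValueError(f"expected {N_BANDS_RAW} bands, got {cube.n_bands}")
    sl = slice(TRIM_FIRST, N_BANDS_RAW - TRIM_LAST)
    data = cube.data[:, :, sl]
    assert data.shape[2] == N_BANDS_TRIMMED
    return Hypercube(
        data=data, wavelengths=cube.wavelengths[sl], state="trimmed184", meta=dict(cube.meta)
    )


def normalize_pixelwise(cube: Hypercube, mode: str = "minmax") -> Hypercube:
    """Per-pixel spectral normalization onto [0, 1].

    ``minmax``: (s - min s) / (max s - min s); each pixel attains 0 and 1 and
    any per-pixel affine map a*s + b with a > 0 gives identical output.
    ``max``: (s - min s) / (max s); invariant to gain only.
    Degenerate pixels (denominator below ``NORM_EPS``) normalize to the zero
    spectrum; a counter is logged because dead pixels occur in real sensors.
    """
    if cube.state != "trimmed184":
        raise ValueError(f"normalization expects a trimmed184 cube, got state {cube.state!r}")
    if mode not in ("minmax", "max"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    data = cube.data.astype(np.float64)
    lo = data.min(axis=2, keepdims=True)
    hi = data.max(axis=2, keepdims=True)
    denom = (hi - lo) if mode == "minmax" else hi
    degenerate = denom < NORM_EPS
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("normalize_pixelwise: %d degenerate pixel(s) set to zero spectrum", n_degenerate)
    safe = np.where(degenerate, 1.0, denom)
    out = (data - lo) / safe
    out[np.broadcast_to(degenerate, out.shape)] = 0.0
    meta = dict(cube.meta)
    meta["normalization"] = mode
    return Hypercube(
        data=out.astype(np.float32), wavelengths=cube.wavelengths, state="normalized184", meta=meta
    )


def nearest_band(cube: Hypercube, wavelength_nm: float) -> int:
    """Index of the grid wavelength closest to ``wavelength_nm`` (ties -> lower).

    The query must lie inside the cube's grid extended by half the local band
    spacing; the spectral rules are phrased in nanometres and resolved here.
    """
    wl = cube.wavelengths
    spacing = float(np.median(np.diff(wl)))
    if not (wl[0] - spacing / 2 <= wavelength_nm <= wl[-1] + spacing / 2):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid [{wl[0]:.1f}, {wl[-1]:.1f}] nm (± half spacing)"
        )
    dist = np.abs(wl - wavelength_nm)
    return int(np.argmin(dist))  # argmin takes the lower index on ties


def select_calibration(library: CalibrationLibrary, temperature: float) -> CalibrationPair:
    """Pair with temperature closest to the query; ties go to the lower one."""
    if not library.pairs:
        raise ValueError("calibration library is empty")
    return min(library.pairs, key=lambda p: (abs(p.temperature - temperature), p.temperature))


def preprocess(
    cube: Hypercube, pair: CalibrationPair, mode: str = "minmax"
) -> Hypercube:
    """Full conditioning chain: correct -> trim -> normalize."""
    return normalize_pixelwise(trim_bands(flat_field_correct(cube, pair)), mode=mode)
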