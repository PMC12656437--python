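"""Hypercube containers and on-disk I/O (ENVI cubes, PNG masks, calibration pairs).

A line-scan NIR camera emits one spatial line of 640 pixels x 224 spectral
bands per frame; conveyor motion supplies the second spatial axis.  In memory
a cube is always ordered ``(line, sample, band)`` -- rows index scan lines,
columns index sensor pixels, and the band axis is innermost.  On disk cubes
use the ENVI convention of a plain-text ``.hdr`` next to a raw binary file;
all three interleaves (BIL, BIP, BSQ) and data types 4 (float32) and 12
(uint16) are supported and round-trip losslessly.

Processing state is tracked explicitly so that stages cannot be skipped or
repeated: ``raw224 -> corrected224 -> trimmed184 -> normalized184``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .taxonomy import UNANNOTATED, ClassTaxonomy, default_taxonomy

#: Spectral range of the sensor in nanometres.
WAVELENGTH_MIN_NM = 942.0
WAVELENGTH_MAX_NM = 1723.0
#: Native number of bands, and the count left after trimming 20 per edge.
N_BANDS_RAW = 224
N_BANDS_TRIMMED = 184

VALID_STATES = ("raw224", "corrected224", "trimmed184", "normalized184")

_STATE_BANDS = {
    "raw224": N_BANDS_RAW,
    "corrected224": N_BANDS_RAW,
    "trimmed184": N_BANDS_TRIMMED,
    "normalized184": N_BANDS_TRIMMED,
}


class EnviParseError(ValueError):
    """Malformed ENVI header; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (header line {line})" if line is not None else ""
        super().__init__(message + suffix)


def default_wavelength_grid(n_bands: int = N_BANDS_RAW) -> np.ndarray:
    """Nominal linear wavelength grid of the sensor.

    lambda(i) = 942 + i * (1723 - 942) / 223 nm for i = 0..223, i.e. a
    spacing of about 3.50 nm per band.  Only the native 224-band grid can be
    synthesised; trimmed grids are obtained by slicing it.
    """
    if n_bands != N_BANDS_RAW:
        raise ValueError(f"default grid is only defined for {N_BANDS_RAW} bands, got {n_bands}")
    i = np.arange(N_BANDS_RAW, dtype=np.float64)
    return WAVELENGTH_MIN_NM + i * (WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM) / (N_BANDS_RAW - 1)


@dataclass
class Hypercube:
    """A (lines, samples, bands) stack of intensities with its wavelength grid.

    ``data`` holds non-negative intensities: arbitrary sensor counts while
    raw/corrected, unitless reflectance-like values after normalization.
    ``meta`` carries acquisition context (sensor ``temperature`` in Celsius,
    free-text ``exposure`` tag).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    state: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (lines, samples, bands), got {self.data.shape}")
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {VALID_STATES}")
        if self.wavelengths.shape != (self.n_bands,):
            raise ValueError(
                f"wavelengths length {self.wavelengths.shape} does not match band axis {self.n_bands}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        expected = _STATE_BANDS[self.state]
        if self.n_bands != expected:
            raise ValueError(f"state {self.state} requires {expected} bands, cube has {self.n_bands}")


@dataclass
class CalibrationPair:
    """Dark and flat reference frames of a line-scan sensor.

    Both frames are (samples, bands) -- one value per sensor column and band,
    broadcast over scan lines.  ``flat - dark`` must be strictly positive
    everywhere, otherwise the per-element gain is undefined.
    """

    dark: np.ndarray
    flat: np.ndarray
    temperature: float = 25.0

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.flat = np.asarray(self.flat, dtype=np.float64)
        if self.dark.shape != self.flat.shape or self.dark.ndim != 2:
            raise ValueError(
                f"dark/flat must be matching 2-D (samples, bands) arrays, got {self.dark.shape} vs {self.flat.shape}"
            )
        diff = self.flat - self.dark
        if np.any(diff <= 0):
            col, band = np.unravel_index(int(np.argmin(diff)), diff.shape)
            raise ValueError(
                f"flat - dark must be strictly positive; violated at column {col}, band {band} "
                f"(value {diff[col, band]:g})"
            )


# ---------------------------------------------------------------------------
# ENVI header + raw binary
# ---------------------------------------------------------------------------

_DTYPE_CODES = {4: np.float32, 12: np.uint16}
_DTYPE_OF = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


def _parse_envi_header(text: str) -> dict:
    """Parse `key = value` pairs; `{...}` values may span lines."""
    lines = text.splitlines()
    if not lines or lines[0].strip().upper() != "ENVI":
        raise EnviParseError("header must start with the magic word 'ENVI'", line=1)
    fields: dict[str, str] = {}
    i = 1
    while i < len(lines):
        raw = lines[i].strip()
        i += 1
        if not raw or raw.startswith(";"):
            continue
        if "=" not in raw:
            raise EnviParseError(f"expected 'key = value', got {raw!r}", line=i)
        key, _, value = raw.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            start_line = i
            while "}" not in value:
                if i >= len(lines):
                    raise EnviParseError(f"unterminated '{{' in field {key!r}", line=start_line)
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ")
        fields[key] = value
    return fields


def _interleave_axes(interleave: str) -> tuple[int, ...]:
    # Stored axis order for each interleave, expressed as a transpose of the
    # in-memory (line, sample, band) order.
    return {"bil": (0, 2, 1), "bip": (0, 1, 2), "bsq": (2, 0, 1)}[interleave]


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI cube into canonical (line, sample, band) order.

    The stored interleave only affects the file layout; the returned array is
    identical for BIL/BIP/BSQ copies of the same cube.  A cube must have
    either 224 bands (raw/corrected) or 184 (trimmed/normalized); the
    processing state is restored from the custom ``processing state`` header
    key when present, else inferred from the band count.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in fields:
            raise EnviParseError(f"missing required field {required!r}")
    samples, lines, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviParseError(f"unsupported interleave {fields['interleave']!r}")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise EnviParseError(f"unsupported data type code {code} (supported: 4=float32, 12=uint16)")
    if bands not in (N_BANDS_RAW, N_BANDS_TRIMMED):
        raise EnviParseError(f"unsupported band count {bands} (expected {N_BANDS_RAW} or {N_BANDS_TRIMMED})")
    if "wavelength" not in fields:
        raise EnviParseError("missing 'wavelength' field")
    wavelengths = np.array([float(v) for v in fields["wavelength"].split(",")], dtype=np.float64)
    if wavelengths.size != bands:
        raise EnviParseError(f"wavelength list has {wavelengths.size} entries for {bands} bands")

    data_path = header_path.with_suffix(".raw")
    if not data_path.exists():
        # ENVI readers conventionally also accept the header name minus .hdr
        alt = header_path.with_suffix("")
        if alt.exists():
            data_path = alt
        else:
            raise FileNotFoundError(f"cube data file not found next to {header_path}")
    offset = int(fields.get("header offset", 0))
    flat = np.fromfile(data_path, dtype=_DTYPE_CODES[code], offset=offset)
    if flat.size != lines * samples * bands:
        raise EnviParseError(
            f"data file holds {flat.size} values, header declares {lines * samples * bands}"
        )
    axes = _interleave_axes(interleave)
    stored_shape = tuple((lines, samples, bands)[a] for a in axes)
    data = flat.reshape(stored_shape).transpose(np.argsort(axes))

    state = fields.get("processing state")
    if state is None:
        state = "raw224" if bands == N_BANDS_RAW else "trimmed184"
    elif state not in VALID_STATES:
        raise EnviParseError(f"unknown processing state {state!r}")

    meta: dict = {}
    if "sensor temperature" in fields:
        meta["temperature"] = float(fields["sensor temperature"])
    if "exposure tag" in fields:
        meta["exposure"] = fields["exposure tag"]
    return Hypercube(data=data, wavelengths=wavelengths, state=state, meta=meta)


def write_envi(cube: Hypercube, header_path: str | Path, interleave: str = "bil") -> None:
    """Write ``cube`` as ENVI header + raw binary; ``read_envi`` inverts it exactly.

    Wavelengths are written with full ``repr`` precision.  The processing
    state and acquisition metadata go into custom header keys.
    """
    cube.validate()
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_OF:
        raise ValueError(f"cube dtype {dtype} not storable; use float32 or uint16")
    header_path = Path(header_path)
    lines, samples, bands = cube.shape
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    parts = [
        "ENVI",
        "description = {hyperfod hypercube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_OF[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
        f"processing state = {cube.state}",
    ]
    if "temperature" in cube.meta:
        parts.append(f"sensor temperature = {float(cube.meta['temperature'])!r}")
    if "exposure" in cube.meta:
        parts.append(f"exposure tag = {cube.meta['exposure']}")
    header_path.write_text("\n".join(parts) + "\n")
    stored = cube.data.transpose(_interleave_axes(interleave))
    np.ascontiguousarray(stored).tofile(header_path.with_suffix(".raw"))


# ---------------------------------------------------------------------------
# Label masks (indexed PNG) and calibration archives
# ---------------------------------------------------------------------------


def write_mask(mask: np.ndarray, path: str | Path, taxonomy: ClassTaxonomy | None = None) -> None:
    """Save a label mask as a palettised single-channel PNG.

    Pixel values are class indices 0..12; 255 marks unannotated pixels.
    """
    taxonomy = taxonomy or default_taxonomy()
    mask = np.asarray(mask)
    valid = (mask == UNANNOTATED) | (mask < taxonomy.n_classes)
    if mask.ndim != 2 or not valid.all():
        raise ValueError("mask must be 2-D with values in 0..12 or 255")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(taxonomy.palette_array().ravel().tolist())
    img.save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Load an indexed-PNG label mask as a (H, W) uint8 array."""
    img = Image.open(Path(path))
    if img.mode not in ("P", "L"):
        raise ValueError(f"expected an indexed or gray PNG, got mode {img.mode}")
    return np.asarray(img, dtype=np.uint8)


def save_calibration(pair: CalibrationPair, path: str | Path) -> None:
    """Store a dark/flat pair plus temperature in a single ``.npz`` archive."""
    np.savez(
        Path(path),
        dark=pair.dark.astype(np.float32),
        flat=pair.flat.astype(np.float32),
        temperature=np.float64(pair.temperature),
    )


def load_calibration(path: str | Path) -> CalibrationPair:
    with np.load(Path(path)) as archive:
        return CalibrationPair(
            dark=archive["dark"], flat=archive["flat"], temperature=float(archive["temperature"])
        )
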