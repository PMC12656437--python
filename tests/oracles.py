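"""Independent oracles shared by the unit and acceptance tests.

These deliberately re-derive results from first principles (literal rule
transcription, shift-and-AND erosion, per-pixel loops) and never call the
implementation paths they check.
"""

import numpy as np

from hyperfod.cube_io import default_wavelength_grid
from hyperfod.taxonomy import default_taxonomy

_TAX = default_taxonomy()
_WL_TRIMMED = default_wavelength_grid()[20:204]

MEAT, FAT, BELT = (_TAX.index_of(n) for n in ("meat", "fat", "conveyor_belt"))
PEHD, PA_PP = _TAX.index_of("pehd"), _TAX.index_of("pa_pp")


def band_of(wavelength_nm: float) -> int:
    """Nearest trimmed-grid band, lower index on ties."""
    return int(np.argmin(np.abs(_WL_TRIMMED - wavelength_nm)))


def literal_rule_interpreter(spectrum: np.ndarray, predicted: int) -> int:
    """Plain transcription of the three published spectral conditions."""

    def I(w):
        return spectrum[band_of(w)]

    if predicted == PEHD:
        cond1 = I(1225.5) - I(1211.5) > I(1026) - I(1012)
        cond1 = cond1 and (I(1407.5) > 1e-8 and I(1411) / I(1407.5) < 1.04)
        if cond1:
            return FAT
        if I(1117) > I(1099.5):
            return BELT
    if predicted == PA_PP:
        if I(1225.5) - I(1215) < I(1232.5) - I(1012):
            return MEAT
    return predicted


def erosion_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force full-3x3 erosion: a pixel survives iff its whole
    8-neighbourhood is set, with the image border treated as background."""
    padded = np.pad(mask, 1, constant_values=False)
    out = np.ones_like(mask, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= padded[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
    return out


def flat_field_oracle(data: np.ndarray, dark: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Per-pixel re-computation of the correction formula, looped explicitly."""
    diff = flat - dark
    m = diff.mean()
    out = np.empty(data.shape, dtype=np.float64)
    for c in range(data.shape[1]):
        for b in range(data.shape[2]):
            out[:, c, b] = (data[:, c, b] - dark[c, b]) * m / diff[c, b]
    return np.maximum(out, 0.0)
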