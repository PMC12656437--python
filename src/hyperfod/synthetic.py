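"""Synthetic pork-belly hypercubes with the statistical structure the
pipeline assumes.

The generator renders scenes of a pork belly on a conveyor belt as seen by a
NIR line-scan camera, so that every stage -- calibration, normalization,
tiling, the ViT, the spectral rules and erosion, and the evaluation counts --
can be exercised without any external data.  It emulates, by construction:

* 13 distinguishable material reflectance curves over the 224-band grid,
  each a baseline plus a few Gaussian/sigmoid features, with per-pixel
  amplitude jitter (intra-class variability) and additive read noise;
* a deliberately hard fat mode (``pehd_hard``): fat pixels whose spectra
  carry the PEHD-like rise around the 1222 nm inflection but *lack* the
  sharp PEHD reflectance step above 1407 nm.  A spectrum-only classifier
  mislabels a controllable fraction of them as PEHD -- the fixture for the
  first spectral rule;
* fixed-pattern stripe noise as per-column multiplicative gains, a dark
  offset, and affine temperature/exposure gain drift, all consistent with a
  matching dark/flat calibration pair so that flat-field correction inverts
  the forward model exactly (up to read noise);
* smooth multiplicative shadow fields, which per-pixel minmax normalization
  cancels;
* contaminant shapes down to ribbons 1-2 px wide (every scan line a ribbon
  crosses holds at least 2 of its pixels, mirroring the sensor's minimum
  object size).

Curve shapes are parametric inventions -- only their *structure* (class
distinguishability, the fat/PEHD confusion geometry near 1222 nm) is
modelled, not any measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube_io import (
    CalibrationPair,
    Hypercube,
    default_wavelength_grid,
    save_calibration,
    write_envi,
    write_mask,
)
from .taxonomy import ClassTaxonomy, default_taxonomy

# ---------------------------------------------------------------------------
# material spectra
# ---------------------------------------------------------------------------


def _gauss(wl, center, sigma, amp):
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _sigmoid(wl, center, width, amp):
    return amp / (1.0 + np.exp(-(wl - center) / width))


#: (baseline, [feature, ...]) per class; features are ("g", center, sigma, amp)
#: or ("s", center, width, amp).  Wavelengths in nm on the native 224-band grid.
_CURVE_SPEC: dict[str, tuple[float, list[tuple]]] = {
    "meat": (0.45, [("g", 975, 25, -0.08), ("g", 1450, 45, -0.22), ("g", 1190, 60, 0.05)]),
    "fat": (0.62, [("g", 1160, 35, -0.15), ("g", 1310, 50, 0.06), ("g", 1680, 45, -0.10)]),
    "conveyor_belt": (0.25, [("s", 1105, 12, 0.15), ("g", 1550, 60, 0.08)]),
    "pa_pp": (0.50, [("g", 1225.5, 4, 0.30), ("g", 1390, 30, -0.10), ("g", 1050, 30, 0.08)]),
    "pu": (0.55, [("g", 1060, 25, 0.18), ("g", 1360, 40, -0.12), ("g", 1600, 50, 0.10)]),
    "metal": (0.15, [("s", 1300, 150, 0.06)]),
    # PEHD = the fat curve plus the 1222 nm rise and a sharp step just above
    # 1407 nm -- the two handles the first spectral rule relies on.
    "pehd": (
        0.62,
        [
            ("g", 1160, 35, -0.15),
            ("g", 1310, 50, 0.06),
            ("g", 1680, 45, -0.10),
            ("g", 1222, 8, 0.18),
            ("g", 1413, 3, 0.38),
        ],
    ),
    "teflon": (0.88, [("g", 1180, 70, -0.05), ("g", 1500, 80, -0.04)]),
    "nitrile": (0.40, [("g", 1300, 25, 0.20), ("g", 1520, 35, -0.08)]),
    "wood": (0.50, [("g", 1470, 60, -0.25), ("g", 1650, 30, 0.15), ("g", 1200, 45, -0.06)]),
    "paper": (0.75, [("g", 1450, 40, -0.15), ("g", 990, 20, 0.06)]),
    "cardboard": (0.55, [("g", 1450, 45, -0.18), ("g", 1190, 25, -0.10), ("s", 1600, 80, -0.08)]),
    "white_belt": (0.80, [("s", 1105, 12, 0.10), ("g", 1550, 40, -0.15)]),
}

#: The hard fat mode: mean amplitude of its 1222 nm bump relative to PEHD's,
#: and the per-pixel spread.  At 1.1 +/- 0.25 a majority of hard pixels land
#: on the PEHD side of a spectrum-only decision boundary while the mean hard
#: curve remains closer to fat than any other class pair.
HARD_BUMP = ("g", 1222, 8, 0.18)
HARD_AMP_MEAN = 1.1
HARD_AMP_SD = 0.25


@dataclass
class MaterialSpectrumModel:
    """Mean reflectance curves plus the noise model of the generator."""

    wavelengths: np.ndarray
    baselines: dict[str, float]
    features: dict[str, np.ndarray]  # summed feature curves, one per class
    sigma_class: float = 0.08  # relative amplitude jitter of the features
    sigma_gain: float = 0.02  # per-pixel brightness jitter (cancels in normalization)
    sigma_read: float = 6.0  # additive sensor noise, counts
    seed: int = 0

    def curve(self, name: str) -> np.ndarray:
        return np.clip(self.baselines[name] + self.features[name], 0.02, 0.98)

    @property
    def class_names(self) -> list[str]:
        return [n for n in self.features if n != "pehd_hard"]

    def hard_bump_unit(self) -> np.ndarray:
        _, center, sigma, amp = HARD_BUMP
        return _gauss(self.wavelengths, center, sigma, amp)


def make_spectrum_library(seed: int = 0) -> MaterialSpectrumModel:
    """Build the 13 canonical curves plus the ``pehd_hard`` variant.

    The curve parameters are fixed constants, so equal seeds trivially give
    identical libraries; the seed feeds the *sampling* of pixels later on.
    """
    wl = default_wavelength_grid()
    baselines: dict[str, float] = {}
    features: dict[str, np.ndarray] = {}
    for name, (base, feats) in _CURVE_SPEC.items():
        acc = np.zeros_like(wl)
        for kind, center, width, amp in feats:
            acc += _gauss(wl, center, width, amp) if kind == "g" else _sigmoid(wl, center, width, amp)
        baselines[name] = base
        features[name] = acc
    base_f, feats_f = _CURVE_SPEC["fat"]
    baselines["pehd_hard"] = base_f
    features["pehd_hard"] = features["fat"] + HARD_AMP_MEAN * _gauss(wl, *HARD_BUMP[1:])
    return MaterialSpectrumModel(wavelengths=wl, baselines=baselines, features=features, seed=seed)


def spectral_angles(model: MaterialSpectrumModel) -> dict[tuple[str, str], float]:
    """Pairwise spectral angles (radians) between all mean curves."""
    names = list(model.features)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ca, cb = model.curve(a), model.curve(b)
            cos = np.dot(ca, cb) / (np.linalg.norm(ca) * np.linalg.norm(cb))
            out[(a, b)] = float(np.arccos(np.clip(cos, -1, 1)))
    return out


# ---------------------------------------------------------------------------
# scene recipes
# ---------------------------------------------------------------------------


@dataclass
class Contaminant:
    """One foreign object: class, shape and placement (row, col of centre)."""

    class_name: str
    shape: str  # "rectangle" | "ellipse" | "ribbon"
    size: tuple[int, int]  # (height, width) for rectangle/ellipse; (length, width<=2) for ribbon
    center: tuple[int, int]


@dataclass
class SceneRecipe:
    """Everything needed to render one scene deterministically."""

    height: int = 128
    width: int = 160
    side: str = "fat_up"  # which belly surface faces the camera
    contaminants: list[Contaminant] = field(default_factory=list)
    hard_speckles: int = 0  # small patches of the hard fat mode (labelled fat)
    shadow_amplitude: float = 0.2
    stripe_sigma: float = 0.05  # log-sd of per-column gains
    dark_level: float = 90.0
    temperature: float = 25.0  # sensor temperature, degC (10..55 typical)
    exposure_gain: float = 1.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("fat_up", "meat_up"):
            raise ValueError(f"side must be fat_up or meat_up, got {self.side!r}")


@dataclass
class SynthSample:
    """A rendered scene: raw sensor cube, ground-truth reflectance and mask,
    the matching calibration pair, and where the hard fat pixels sit."""

    raw: Hypercube
    reflectance: np.ndarray  # (H, W, 224), noiseless, before shadow
    mask: np.ndarray  # (H, W) class indices
    pair: CalibrationPair
    hard_map: np.ndarray  # (H, W) bool
    recipe: SceneRecipe


def _draw_contaminant(mask: np.ndarray, item: Contaminant, class_id: int, rng: np.random.Generator) -> None:
    h, w = mask.shape
    r0, c0 = item.center
    if item.shape == "rectangle":
        sh, sw = item.size
        r, c = r0 - sh // 2, c0 - sw // 2
        if r < 0 or c < 0 or r + sh > h or c + sw > w:
            raise ValueError(f"contaminant {item} outside the image")
        mask[r : r + sh, c : c + sw] = class_id
    elif item.shape == "ellipse":
        sh, sw = item.size
        rr, cc = np.mgrid[0:h, 0:w]
        sel = ((rr - r0) / max(sh / 2, 1)) ** 2 + ((cc - c0) / max(sw / 2, 1)) ** 2 <= 1.0
        if r0 - sh // 2 < 0 or c0 - sw // 2 < 0 or r0 + sh // 2 > h or c0 + sw // 2 > w:
            raise ValueError(f"contaminant {item} outside the image")
        mask[sel] = class_id
    elif item.shape == "ribbon":
        length, width = item.size
        if width not in (1, 2):
            raise ValueError("ribbon width must be 1 or 2 pixels")
        r, c = float(r0), float(c0)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(length):
            angle += rng.normal(0, 0.35)  # meandering, spiral-ish path
            r += np.sin(angle)
            c += np.cos(angle)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 1 <= ci < w - 1):
                raise ValueError(f"contaminant {item} outside the image")
            # each crossed scan line receives >= 2 pixels (minimum object size)
            mask[ri, ci : ci + 2] = class_id
            if width == 2 and 0 <= ri + 1 < h:
                mask[ri + 1, ci : ci + 2] = class_id
    else:
        raise ValueError(f"unknown shape {item.shape!r}")


def _belly_layout(recipe: SceneRecipe, taxonomy: ClassTaxonomy, rng: np.random.Generator) -> np.ndarray:
    """Belt everywhere, an elliptical belly, and a wavy meat/fat split."""
    h, w = recipe.height, recipe.width
    mask = np.full((h, w), taxonomy.index_of("conveyor_belt"), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = h / 2 + rng.uniform(-h * 0.04, h * 0.04), w / 2 + rng.uniform(-w * 0.04, w * 0.04)
    ay, ax = h * rng.uniform(0.38, 0.44), w * rng.uniform(0.40, 0.46)
    belly = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    # the facing surface dominates; the other tissue shows along a wavy band
    phase = rng.uniform(0, 2 * np.pi)
    boundary = cy + ay * 0.45 + h * 0.04 * np.sin(2 * np.pi * cc[0] / w * 2 + phase)
    lower = rr > boundary[None, :].repeat(h, axis=0)
    top_cls = "fat" if recipe.side == "fat_up" else "meat"
    bottom_cls = "meat" if recipe.side == "fat_up" else "fat"
    mask[belly] = taxonomy.index_of(top_cls)
    mask[belly & lower] = taxonomy.index_of(bottom_cls)
    return mask


def render_scene(
    recipe: SceneRecipe,
    lib: MaterialSpectrumModel | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> SynthSample:
    """Render the recipe through the sensor forward model.

    raw = D + stripe[col] * g(T) * S[band] * reflectance * shadow + noise,
    with the flat frame F = D + stripe * g(T) * S (a unit-reflectance
    target), so that flat-field correction returns m * reflectance * shadow
    exactly up to read noise.
    """
    lib = lib or make_spectrum_library()
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.height, recipe.width
    n_bands = lib.wavelengths.size

    mask = _belly_layout(recipe, taxonomy, rng)
    for item in recipe.contaminants:
        _draw_contaminant(mask, item, taxonomy.index_of(item.class_name), rng)

    # hard fat speckles: ground truth fat, spectra carrying the 1222 nm bump
    hard_map = np.zeros((h, w), dtype=bool)
    if recipe.hard_speckles:
        fat_rows, fat_cols = np.nonzero(mask == taxonomy.index_of("fat"))
        if fat_rows.size:
            for _ in range(recipe.hard_speckles):
                j = rng.integers(fat_rows.size)
                r, c = int(fat_rows[j]), int(fat_cols[j])
                sh, sw = int(rng.integers(1, 3)), int(rng.integers(1, 3))
                patch = (slice(r, min(r + sh, h)), slice(c, min(c + sw, w)))
                hard_map[patch] |= mask[patch] == taxonomy.index_of("fat")

    # per-pixel reflectance spectra
    reflectance = np.empty((h, w, n_bands), dtype=np.float32)
    for class_id in np.unique(mask):
        name = taxonomy.name_of(int(class_id))
        sel = (mask == class_id) & ~hard_map
        n = int(sel.sum())
        if n == 0:
            continue
        jit = 1.0 + rng.normal(0.0, lib.sigma_class, n)
        gain = 1.0 + rng.normal(0.0, lib.sigma_gain, n)
        spectra = lib.baselines[name] + jit[:, None] * lib.features[name][None, :]
        reflectance[sel] = (gain[:, None] * spectra).astype(np.float32)
    if hard_map.any():
        n = int(hard_map.sum())
        jit = 1.0 + rng.normal(0.0, lib.sigma_class, n)
        amp = np.clip(rng.normal(HARD_AMP_MEAN, HARD_AMP_SD, n), 0.0, None)
        spectra = (
            lib.baselines["fat"]
            + jit[:, None] * lib.features["fat"][None, :]
            + amp[:, None] * lib.hard_bump_unit()[None, :]
        )
        reflectance[hard_map] = spectra.astype(np.float32)
    np.clip(reflectance, 0.02, 0.98, out=reflectance)

    # sensor forward model
    temp_gain = (1.0 + 0.004 * (recipe.temperature - 25.0)) * recipe.exposure_gain
    sensitivity = 2500.0 * (0.55 + 0.45 * np.exp(-(((lib.wavelengths - 1300.0) / 300.0) ** 2)))
    dark = (
        recipe.dark_level
        + 0.25 * (recipe.temperature - 25.0)
        + 4.0 * rng.standard_normal((w, n_bands))
    )
    stripes = np.exp(rng.normal(0.0, recipe.stripe_sigma, w))
    flat = dark + stripes[:, None] * temp_gain * sensitivity[None, :]
    pair = CalibrationPair(dark=dark, flat=flat, temperature=recipe.temperature)

    if recipe.shadow_amplitude > 0:
        rough = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(rough, sigma=min(h, w) / 8)
        smooth = (smooth - smooth.min()) / max(float(np.ptp(smooth)), 1e-12)
        shadow = 1.0 - recipe.shadow_amplitude * smooth
    else:
        shadow = np.ones((h, w))

    signal = stripes[None, :, None] * temp_gain * sensitivity[None, None, :]
    raw = dark[None, :, :] + signal * reflectance * shadow[:, :, None].astype(np.float32)
    if recipe.noise:
        raw = raw + rng.normal(0.0, lib.sigma_read, raw.shape)
    raw = np.maximum(raw, 0.0).astype(np.float32)

    cube = Hypercube(
        data=raw,
        wavelengths=lib.wavelengths,
        state="raw224",
        meta={"temperature": recipe.temperature, "exposure": f"gain={recipe.exposure_gain:g}"},
    )
    return SynthSample(
        raw=cube, reflectance=reflectance, mask=mask, pair=pair, hard_map=hard_map, recipe=recipe
    )


# ---------------------------------------------------------------------------
# random recipes and datasets
# ---------------------------------------------------------------------------

#: Contaminant classes drawn for random scenes.
_CONTAMINANT_POOL = (
    "pa_pp", "pu", "metal", "pehd", "teflon", "nitrile", "wood", "paper", "cardboard", "white_belt",
)


def random_recipe(
    seed: int,
    height: int = 128,
    width: int = 160,
    clean: bool = False,
    n_contaminants: tuple[int, int] = (3, 6),
    hard_speckles: int = 0,
    temperature_range: tuple[float, float] = (10.0, 55.0),
    **overrides,
) -> SceneRecipe:
    """Draw a plausible scene: random side, temperature and contaminant mix.

    Contaminants are kept away from image borders; clean scenes carry none.
    """
    rng = np.random.default_rng(seed)
    contaminants: list[Contaminant] = []
    if not clean:
        n = int(rng.integers(n_contaminants[0], n_contaminants[1] + 1))
        for _ in range(n):
            cls = str(rng.choice(_CONTAMINANT_POOL))
            shape = str(rng.choice(["rectangle", "ellipse", "ribbon"], p=[0.45, 0.35, 0.2]))
            margin = max(10, min(24, height // 5, width // 5))
            center = (
                int(rng.integers(margin, height - margin)),
                int(rng.integers(margin, width - margin)),
            )
            if shape == "ribbon":
                size = (int(rng.integers(8, 16)), int(rng.integers(1, 3)))
            else:
                size = (int(rng.integers(4, 13)), int(rng.integers(4, 13)))
            contaminants.append(Contaminant(cls, shape, size, center))
    return SceneRecipe(
        height=height,
        width=width,
        side=str(rng.choice(["fat_up", "meat_up"])),
        contaminants=contaminants,
        hard_speckles=hard_speckles,
        temperature=float(rng.uniform(*temperature_range)),
        seed=int(rng.integers(0, 2**31 - 1)),
        **overrides,
    )


def make_dataset(
    out_dir: str | Path,
    n_train_scenes: int,
    n_clean_scenes: int,
    n_contaminated_scenes: int,
    seed: int = 0,
    height: int = 128,
    width: int = 160,
    hard_speckles_clean: int = 6,
) -> pd.DataFrame:
    """Write train/test splits of ENVI cubes + PNG masks + calibration pairs.

    Mirrors the study design -- annotated training scenes, a contaminated
    test split and a larger clean split for false-positive counting -- at a
    configurable scale.  Returns (and writes) the manifest.
    """
    out_dir = Path(out_dir)
    lib = make_spectrum_library(seed)
    rows = []
    specs = (
        [("train", i, False, 0) for i in range(n_train_scenes)]
        + [("test_contaminated", i, False, 0) for i in range(n_contaminated_scenes)]
        + [("test_clean", i, True, hard_speckles_clean) for i in range(n_clean_scenes)]
    )
    for split, i, clean, hard in specs:
        scene_id = f"{split}_{i:04d}"
        recipe = random_recipe(
            seed=seed * 100003 + len(rows) * 101 + 7,
            height=height,
            width=width,
            clean=clean,
            hard_speckles=hard,
        )
        sample = render_scene(recipe, lib)
        split_dir = out_dir / split
        split_dir.mkdir(parents=True, exist_ok=True)
        write_envi(sample.raw, split_dir / f"{scene_id}.hdr")
        write_mask(sample.mask, split_dir / f"{scene_id}_mask.png")
        save_calibration(sample.pair, split_dir / f"{scene_id}_calib.npz")
        rows.append(
            {
                "scene_id": scene_id,
                "split": split,
                "side": recipe.side,
                "temperature": round(recipe.temperature, 2),
                "n_contaminants": len(recipe.contaminants),
                "contaminants": json.dumps(
                    [[c.class_name, c.shape, list(c.size)] for c in recipe.contaminants]
                ),
                "hard_speckles": recipe.hard_speckles,
            }
        )
    manifest = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
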