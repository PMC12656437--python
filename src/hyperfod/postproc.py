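"""False-positive suppression: spectral rules, then morphological erosion.

Two contaminant classes -- PEHD and the merged PA-PP class -- have NIR
signatures close to fat and meat respectively, and account for most false
positives.  Three pixel-wise rules re-examine the *spectrum* of every pixel
the model flagged as one of these classes, with I(w) the normalized
intensity at the band nearest to wavelength w (nm):

1. predicted PEHD, and I(1225.5) - I(1211.5) > I(1026) - I(1012), and
   I(1411) / I(1407.5) < 1.04                      -> relabel **fat**
2. predicted PEHD, and I(1117) > I(1099.5)          -> relabel **conveyor belt**
3. predicted PA-PP, and I(1225.5) - I(1215) < I(1232.5) - I(1012)
                                                    -> relabel **meat**

Rule 1's first clause detects the fat-like rise around the 1222 nm
inflection; its ratio clause asks whether the sharp PEHD reflectance step
just above 1407 nm is *absent* (ratio below 1.04).  Rule 3's comparison of
the 1232.5 nm band against 1012 nm is asymmetric but deliberate, and is
implemented exactly as stated.  All rules evaluate on the original model
prediction (no chaining); when rules 1 and 2 both fire, rule 1 wins.

Erosion then shrinks every per-class contaminant mask with the full 3x3
structuring element: 8-connected blobs lacking a 3x3 core vanish entirely
and are relabelled with the fallback class (fat); eroded-away border pixels
of surviving blobs are relabelled the same way, so only confident blob
interiors remain contaminant.  Background predictions are never modified,
and no stage can create contaminant pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calib import NORM_EPS, nearest_band
from .cube_io import Hypercube
from .taxonomy import ClassTaxonomy, default_taxonomy

STAGES = ("raw_model", "rules_applied", "eroded")

#: 8-connected structuring element used for blob labelling.
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class PredictionMap:
    """Per-pixel class indices plus the post-processing stage reached."""

    labels: np.ndarray
    stage: str = "raw_model"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("prediction map must be 2-D")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.labels.max(initial=0) > 12:
            raise ValueError("class indices must lie in 0..12")


@dataclass(frozen=True)
class SpectralRuleSet:
    """Wavelengths (nm) and the rule-1 ratio threshold; overridable, defaults
    are the published values."""

    rule1_diff: tuple[float, float, float, float] = (1225.5, 1211.5, 1026.0, 1012.0)
    rule1_ratio: tuple[float, float] = (1411.0, 1407.5)
    rule1_threshold: float = 1.04
    rule2_pair: tuple[float, float] = (1117.0, 1099.5)
    rule3_quad: tuple[float, float, float, float] = (1225.5, 1215.0, 1232.5, 1012.0)


def apply_spectral_rules(
    pred: PredictionMap,
    cube: Hypercube,
    rules: SpectralRuleSet | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> PredictionMap:
    """Re-label PEHD / PA-PP pixels whose spectra contradict those classes.

    Expects the cube the model saw (normalized; a corrected-unnormalized cube
    is accepted for ablation).  Rules evaluate on the original prediction and
    rule 1 takes precedence over rule 2.  If the rule-1 denominator band is
    below ``NORM_EPS`` the ratio clause counts as false.
    """
    rules = rules or SpectralRuleSet()
    taxonomy = taxonomy or default_taxonomy()
    labels = pred.labels
    if labels.shape != cube.shape[:2]:
        raise ValueError(f"prediction shape {labels.shape} does not match cube {cube.shape[:2]}")

    def band(w: float) -> np.ndarray:
        return cube.data[:, :, nearest_band(cube, w)].astype(np.float64)

    pehd = labels == taxonomy.index_of("pehd")
    pa_pp = labels == taxonomy.index_of("pa_pp")
    out = labels.copy()

    # rule 3: PA-PP lacking its sharp 1225 nm peak relative to the long tail
    a, b, c, d = rules.rule3_quad
    fire3 = pa_pp & ((band(a) - band(b)) < (band(c) - band(d)))
    out[fire3] = taxonomy.index_of("meat")

    # rule 2: PEHD with a belt-like rise from 1099.5 to 1117 nm
    hi, lo = rules.rule2_pair
    fire2 = pehd & (band(hi) > band(lo))
    out[fire2] = taxonomy.index_of("conveyor_belt")

    # rule 1 (highest precedence): fat-like 1222 nm rise and no 1409 nm step
    a, b, c, d = rules.rule1_diff
    num_w, den_w = rules.rule1_ratio
    den = band(den_w)
    ratio_ok = np.zeros_like(den, dtype=bool)
    nz = den >= NORM_EPS
    ratio_ok[nz] = band(num_w)[nz] / den[nz] < rules.rule1_threshold
    fire1 = pehd & ((band(a) - band(b)) > (band(c) - band(d))) & ratio_ok
    out[fire1] = taxonomy.index_of("fat")

    return PredictionMap(labels=out, stage="rules_applied")


def erode_and_reclassify(
    pred: PredictionMap,
    fallback: str = "fat",
    taxonomy: ClassTaxonomy | None = None,
) -> PredictionMap:
    """Erode each contaminant class with a full 3x3 kernel.

    Equivalent per class: contaminant pixels that survive are exactly the
    erosion of that class's binary mask; everything else in the mask --
    whole blobs without a 3x3 core as well as border pixels of surviving
    blobs -- is relabelled to ``fallback``.  Works from either the
    rules_applied stage (default pipeline) or raw_model (erosion-only arm).
    """
    taxonomy = taxonomy or default_taxonomy()
    labels = pred.labels
    out = labels.copy()
    fb = taxonomy.index_of(fallback)
    for class_id in taxonomy.contaminant_indices:
        mask = labels == class_id
        if not mask.any():
            continue
        core = ndimage.binary_erosion(mask, structure=_CONN8, border_value=0)
        out[mask & ~core] = fb
    return PredictionMap(labels=out, stage="eroded")


def run_postprocessing(
    pred: PredictionMap,
    cube: Hypercube | None = None,
    pipeline: tuple[str, ...] = ("rules", "erosion"),
    rules: SpectralRuleSet | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> PredictionMap:
    """Apply the selected stages in order; default is the best-performing
    arm: spectral rules followed by erosion.  An empty pipeline is identity."""
    out = pred
    for stage in pipeline:
        if stage == "rules":
            if cube is None:
                raise ValueError("spectral rules require the hypercube")
            out = apply_spectral_rules(out, cube, rules=rules, taxonomy=taxonomy)
        elif stage == "erosion":
            out = erode_and_reclassify(out, taxonomy=taxonomy)
        else:
            raise ValueError(f"unknown post-processing stage {stage!r}")
    return out
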