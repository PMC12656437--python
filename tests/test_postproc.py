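"""Spectral rules and erosion: crafted triggers, oracles, invariants."""

import numpy as np
import pytest

from hyperfod.calib import nearest_band
from hyperfod.cube_io import Hypercube, default_wavelength_grid
from hyperfod.postproc import (
    PredictionMap,
    apply_spectral_rules,
    erode_and_reclassify,
    run_postprocessing,
)
from hyperfod.taxonomy import default_taxonomy

TAX = default_taxonomy()
MEAT, FAT, BELT = (TAX.index_of(n) for n in ("meat", "fat", "conveyor_belt"))
PEHD, PA_PP = TAX.index_of("pehd"), TAX.index_of("pa_pp")
WL = default_wavelength_grid()[20:204]


def cube_from_spectra(spectra: np.ndarray) -> Hypercube:
    """(H, W, 184) array of normalized intensities as a hypercube."""
    return Hypercube(data=spectra.astype(np.float32), wavelengths=WL, state="normalized184")


def band_of(w):
    return int(np.argmin(np.abs(WL - w)))


def set_bands(spec, **values):
    for w, v in values.items():
        spec[band_of(float(w.lstrip("w").replace("_", ".")))] = v
    return spec


def literal_rule_interpreter(spectrum, predicted):
    """Independent per-pixel re-statement of the three published conditions."""

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


class TestSpectralRules:
    def _apply_single(self, spectrum, predicted):
        cube = cube_from_spectra(spectrum.reshape(1, 1, 184))
        pred = PredictionMap(labels=np.array([[predicted]], dtype=np.uint8))
        return int(apply_spectral_rules(pred, cube).labels[0, 0])

    def test_rule1_crafted_trigger(self):
        # a fat-like 1222 nm rise (0.20 vs 0.10) and a flat 1407-1411 region
        spec = np.full(184, 0.5)
        set_bands(spec, w1225_5=0.70, w1211_5=0.50, w1026=0.60, w1012=0.50, w1411=0.50, w1407_5=0.50)
        assert self._apply_single(spec, PEHD) == FAT

    def test_rule1_ratio_clause_blocks_true_pehd(self):
        # same rise, but the sharp step above 1407 nm is present -> keep PEHD
        spec = np.full(184, 0.5)
        set_bands(spec, w1225_5=0.70, w1211_5=0.50, w1026=0.60, w1012=0.50, w1411=0.80, w1407_5=0.50)
        # rule 2 must not fire either: make 1117 < 1099.5 explicit
        set_bands(spec, w1117=0.45, w1099_5=0.55)
        assert self._apply_single(spec, PEHD) == PEHD

    def test_rule2_belt_like_rise(self):
        spec = np.full(184, 0.5)
        set_bands(spec, w1117=0.65, w1099_5=0.45)  # rising toward 1117
        set_bands(spec, w1225_5=0.40, w1211_5=0.50)  # rule 1 diff clause false
        assert self._apply_single(spec, PEHD) == BELT

    def test_rule1_takes_precedence_over_rule2(self):
        spec = np.full(184, 0.5)
        set_bands(spec, w1225_5=0.70, w1211_5=0.50, w1026=0.55, w1012=0.50, w1411=0.50, w1407_5=0.50)
        set_bands(spec, w1117=0.65, w1099_5=0.45)  # rule 2 would also fire
        assert self._apply_single(spec, PEHD) == FAT

    def test_rule3_meat_like_pa_pp(self):
        spec = np.full(184, 0.5)
        set_bands(spec, w1225_5=0.52, w1215=0.50, w1232_5=0.70, w1012=0.40)
        assert self._apply_single(spec, PA_PP) == MEAT

    def test_rule3_true_pa_pp_peak_survives(self):
        spec = np.full(184, 0.5)
        set_bands(spec, w1225_5=0.85, w1215=0.50, w1232_5=0.55, w1012=0.50)
        assert self._apply_single(spec, PA_PP) == PA_PP

    def test_non_trigger_classes_unchanged(self, rng):
        spectra = rng.random((4, 5, 184))
        cube = cube_from_spectra(spectra)
        labels = rng.choice([MEAT, FAT, BELT, TAX.index_of("wood")], size=(4, 5)).astype(np.uint8)
        out = apply_spectral_rules(PredictionMap(labels=labels), cube)
        np.testing.assert_array_equal(out.labels, labels)
        assert out.stage == "rules_applied"

    def test_zero_denominator_ratio_clause_is_false(self):
        spec = np.zeros(184)
        set_bands(spec, w1225_5=0.30, w1211_5=0.10)
        # I(1407.5) == 0: rule 1 must not fire; rule 2 must not either (equal bands)
        assert self._apply_single(spec, PEHD) == PEHD

    def test_agrees_with_literal_interpreter_on_random_pairs(self, rng):
        n = 10_000
        spectra = rng.random((n, 184))
        predicted = rng.choice([PEHD, PA_PP, MEAT, FAT], size=n)
        cube = cube_from_spectra(spectra.reshape(1, n, 184))
        pred = PredictionMap(labels=predicted.reshape(1, n).astype(np.uint8))
        out = apply_spectral_rules(pred, cube).labels.reshape(-1)
        expected = np.array(
            [literal_rule_interpreter(spectra[i], int(predicted[i])) for i in range(n)]
        )
        np.testing.assert_array_equal(out, expected)

    def test_idempotent(self, rng):
        spectra = rng.random((8, 8, 184))
        cube = cube_from_spectra(spectra)
        labels = rng.choice([PEHD, PA_PP, MEAT], size=(8, 8)).astype(np.uint8)
        once = apply_spectral_rules(PredictionMap(labels=labels), cube)
        twice = apply_spectral_rules(once, cube)
        np.testing.assert_array_equal(once.labels, twice.labels)


def erosion_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force 3x3 erosion by shifting: a pixel survives iff its full
    8-neighbourhood (with the border treated as background) is set."""
    padded = np.pad(mask, 1, constant_values=False)
    out = np.ones_like(mask, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= padded[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
    return out


def pred_with_blob(blob_rows, blob_cols, cls=PEHD, shape=(12, 12)):
    labels = np.full(shape, FAT, dtype=np.uint8)
    labels[np.ix_(blob_rows, blob_cols)] = cls
    return PredictionMap(labels=labels)


class TestErosion:
    def test_2x2_blob_vanishes_to_fallback(self):
        pred = pred_with_blob(range(4, 6), range(4, 6))
        out = erode_and_reclassify(pred)
        assert (out.labels == FAT).all()
        assert out.stage == "eroded"

    def test_3x3_blob_keeps_only_its_center(self):
        pred = pred_with_blob(range(4, 7), range(4, 7))
        out = erode_and_reclassify(pred)
        assert out.labels[5, 5] == PEHD
        assert (out.labels == PEHD).sum() == 1

    def test_4x6_blob_keeps_2x4_core(self):
        pred = pred_with_blob(range(2, 6), range(3, 9))
        out = erode_and_reclassify(pred)
        core = out.labels == PEHD
        assert core.sum() == 8
        assert core[3:5, 4:8].all()

    def test_matches_bruteforce_oracle_on_random_masks(self, rng):
        for _ in range(100):
            labels = np.where(rng.random((64, 64)) < 0.35, PEHD, MEAT).astype(np.uint8)
            out = erode_and_reclassify(PredictionMap(labels=labels))
            expected = erosion_oracle(labels == PEHD)
            np.testing.assert_array_equal(out.labels == PEHD, expected)
            # everything eroded away became the fallback class
            np.testing.assert_array_equal(out.labels == FAT, (labels == PEHD) & ~expected)

    def test_classes_eroded_independently(self):
        # two touching blobs of different contaminant classes must not prop
        # each other up: neither 3x2 half of the 3x4 union has a 3x3 core
        labels = np.full((9, 9), MEAT, dtype=np.uint8)
        labels[3:6, 2:4] = PEHD
        labels[3:6, 4:6] = TAX.index_of("wood")
        out = erode_and_reclassify(PredictionMap(labels=labels))
        assert not np.any(out.labels == PEHD)
        assert not np.any(out.labels == TAX.index_of("wood"))

    def test_background_never_modified(self, rng):
        labels = rng.choice([MEAT, FAT, BELT], size=(20, 20)).astype(np.uint8)
        out = erode_and_reclassify(PredictionMap(labels=labels))
        np.testing.assert_array_equal(out.labels, labels)


class TestPipeline:
    def _random_case(self, rng):
        spectra = rng.random((16, 16, 184))
        labels = rng.choice([MEAT, FAT, BELT, PEHD, PA_PP], size=(16, 16)).astype(np.uint8)
        return cube_from_spectra(spectra), PredictionMap(labels=labels)

    def test_empty_pipeline_is_identity(self, rng):
        cube, pred = self._random_case(rng)
        out = run_postprocessing(pred, cube, pipeline=())
        np.testing.assert_array_equal(out.labels, pred.labels)

    def test_erosion_only_arm_matches_function(self, rng):
        cube, pred = self._random_case(rng)
        a = run_postprocessing(pred, cube, pipeline=("erosion",))
        b = erode_and_reclassify(pred)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_unknown_stage_rejected(self, rng):
        cube, pred = self._random_case(rng)
        with pytest.raises(ValueError, match="unknown"):
            run_postprocessing(pred, cube, pipeline=("dilate",))

    def test_contaminant_pixels_monotone_nonincreasing(self, rng):
        lut = np.zeros(256, dtype=bool)
        for i in TAX.contaminant_indices:
            lut[i] = True
        for _ in range(5):
            cube, pred = self._random_case(rng)
            counts = [lut[pred.labels].sum()]
            staged = apply_spectral_rules(pred, cube)
            counts.append(lut[staged.labels].sum())
            eroded = erode_and_reclassify(staged)
            counts.append(lut[eroded.labels].sum())
            assert counts[0] >= counts[1] >= counts[2]

    def test_background_pixels_are_fixed_points(self, rng):
        cube, pred = self._random_case(rng)
        bg = np.isin(pred.labels, (MEAT, FAT, BELT))
        out = run_postprocessing(pred, cube, pipeline=("rules", "erosion"))
        np.testing.assert_array_equal(out.labels[bg], pred.labels[bg])
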