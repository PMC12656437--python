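"""Material class universe shared by every stage of the pipeline.

The detector distinguishes 13 materials.  Three of them -- meat, fat and the
conveyor belt -- are *background* (negative) classes: predicting them never
raises an alarm.  The remaining ten are *contaminant* (positive) classes:
plastics (PA/PP merged into one class for spectral similarity, PU, PEHD),
metal, teflon, nitrile glove rubber, wood, paper, cardboard, and fragments of
white conveyor belt.  Note that ``white_belt`` (a contaminant fragment lying
on the product) is deliberately distinct from the ``conveyor_belt``
background class.

The canonical class order, index assignment and display palette are shipped
as a YAML resource so that label masks, checkpoints and reports produced by
different tools agree on indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

UNANNOTATED = 255
"""Reserved mask value for pixels without a ground-truth label."""


@dataclass(frozen=True)
class ClassTaxonomy:
    """Ordered class universe with a background/contaminant partition.

    Attributes
    ----------
    classes:
        Class names in canonical index order (index 0 .. 12).
    background_set:
        Names of the negative classes ``{meat, fat, conveyor_belt}``.
    contaminant_set:
        Names of the ten positive classes.
    palette:
        ``name -> (r, g, b)`` display colour, 0-255 per channel.
    """

    classes: tuple[str, ...]
    background_set: frozenset[str]
    contaminant_set: frozenset[str]
    palette: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) != 13:
            raise ValueError(f"expected 13 classes, got {len(self.classes)}")
        if self.background_set & self.contaminant_set:
            raise ValueError("background and contaminant sets overlap")
        if self.background_set | self.contaminant_set != set(self.classes):
            raise ValueError("background ∪ contaminant must equal the class set")

    # -- index/name mapping -------------------------------------------------
    def index_of(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"unknown class name {name!r}") from None

    def name_of(self, class_id: int) -> str:
        self._check_index(class_id)
        return self.classes[class_id]

    def _check_index(self, class_id: int) -> None:
        if not 0 <= int(class_id) < len(self.classes):
            raise IndexError(f"class index {class_id} outside 0..{len(self.classes) - 1}")

    # -- partition queries --------------------------------------------------
    def is_contaminant(self, class_id: int) -> bool:
        """True iff ``class_id`` is one of the ten positive classes."""
        self._check_index(class_id)
        return self.classes[class_id] in self.contaminant_set

    @property
    def background_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.classes) if c in self.background_set)

    @property
    def contaminant_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.classes) if c in self.contaminant_set)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def palette_array(self):
        """Palette as a (256, 3) uint8 array suitable for indexed PNGs."""
        import numpy as np

        pal = np.zeros((256, 3), dtype=np.uint8)
        for i, name in enumerate(self.classes):
            pal[i] = self.palette.get(name, (0, 0, 0))
        pal[UNANNOTATED] = (255, 255, 255)
        return pal


def _hex_to_rgb(code: str) -> tuple[int, int, int]:
    code = code.lstrip("#")
    return tuple(int(code[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def load_taxonomy(path: str | Path | None = None) -> ClassTaxonomy:
    """Load a taxonomy from YAML; default is the resource shipped in-package."""
    if path is None:
        text = resources.files("hyperfod.data").joinpath("taxonomy.yaml").read_text()
    else:
        text = Path(path).read_text()
    spec = yaml.safe_load(text)
    entries = sorted(spec["classes"], key=lambda e: e["index"])
    for pos, entry in enumerate(entries):
        if entry["index"] != pos:
            raise ValueError(f"class indices must be 0..N-1 without gaps, got {entry['index']} at {pos}")
    names = tuple(e["name"] for e in entries)
    background = frozenset(e["name"] for e in entries if e["role"] == "background")
    contaminant = frozenset(e["name"] for e in entries if e["role"] == "contaminant")
    palette = {e["name"]: _hex_to_rgb(e["color"]) for e in entries}
    return ClassTaxonomy(names, background, contaminant, palette)


_DEFAULT: ClassTaxonomy | None = None


def default_taxonomy() -> ClassTaxonomy:
    """The packaged 13-class taxonomy (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_taxonomy()
    return _DEFAULT
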