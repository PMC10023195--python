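"""Seeded shape/color assignment for frequent features and value-to-color maps.

The one-click styling rule: rank features by total occurrence (ties broken
alphabetically), give the top ``max_features`` each a unique (shape, fill)
combination drawn from a seeded stream, and bucket the rest under a single
muted "other" style.  The assignment is a pure function of
(occurrence table, seed, max_features), so runs are reproducible and a new
seed reshuffles the look without touching the data.

Colors come first from a fixed 20-color qualitative palette (seeded order),
then from seeded HSV sampling that keeps new hues at least 18 degrees away
from the hues already in use, so late colors stay distinguishable.
"""

from __future__ import annotations

import colorsys
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .model import OccurrenceTable

logger = logging.getLogger(__name__)

SHAPES = ("rounded-rect", "rect", "ellipse", "hexagon", "diamond", "chevron")

RGB = tuple[int, int, int]

#: Qualitative base palette, exhausted before HSV sampling kicks in.
PALETTE20: tuple[RGB, ...] = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
)

_MIN_HUE_DISTANCE = 18.0 / 360.0


@dataclass(frozen=True)
class FeatureStyle:
    shape: str
    fill: RGB
    outline: RGB

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        for c in (*self.fill, *self.outline):
            if not 0 <= c <= 255:
                raise ValueError(f"color channel out of range: {c}")


OTHER_STYLE = FeatureStyle("rect", (210, 210, 210), (120, 120, 120))


@dataclass
class StyleMap:
    """Feature name -> style, in occurrence-rank order, plus the overflow bucket."""

    styles: dict[str, FeatureStyle] = field(default_factory=dict)
    other: FeatureStyle = OTHER_STYLE
    overflow: list[str] = field(default_factory=list)

    def style_for(self, name: str) -> FeatureStyle:
        return self.styles.get(name, self.other)

    # -- hand-editable structured-text round trip ---------------------------

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tshape\tfill\toutline\n")
            for name, s in self.styles.items():
                fh.write(f"{name}\t{s.shape}\t{_hex(s.fill)}\t{_hex(s.outline)}\n")
            fh.write(f"*\t{self.other.shape}\t{_hex(self.other.fill)}\t{_hex(self.other.outline)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "StyleMap":
        styles: dict[str, FeatureStyle] = {}
        other = OTHER_STYLE
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("name\t"):
                raise ValueError("style file must start with a name/shape/fill/outline header")
            for line in fh:
                if not line.strip():
                    continue
                name, shape, fill, outline = line.rstrip("\n").split("\t")
                style = FeatureStyle(shape, _unhex(fill), _unhex(outline))
                if name == "*":
                    other = style
                else:
                    styles[name] = style
        return cls(styles=styles, other=other)


def _hex(rgb: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _unhex(s: str) -> RGB:
    s = s.lstrip("#")
    return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


def _darken(rgb: RGB, factor: float = 0.55) -> RGB:
    return tuple(int(c * factor) for c in rgb)  # type: ignore[return-value]


def _hue(rgb: RGB) -> float:
    return colorsys.rgb_to_hsv(*(c / 255.0 for c in rgb))[0]


def _color_stream(rng: random.Random):
    """Yield distinguishable colors forever: shuffled palette, then HSV draws."""
    palette = list(PALETTE20)
    rng.shuffle(palette)
    used_hues = []
    for color in palette:
        used_hues.append(_hue(color))
        yield color
    while True:
        best, best_dist = None, -1.0
        for _ in range(200):
            h = rng.random()
            dist = min(
                (min(abs(h - u), 1 - abs(h - u)) for u in used_hues), default=1.0
            )
            if dist >= _MIN_HUE_DISTANCE:
                best = h
                break
            if dist > best_dist:
                best, best_dist = h, dist
        s = rng.uniform(0.55, 0.95)
        v = rng.uniform(0.65, 0.95)
        used_hues.append(best)
        r, g, b = colorsys.hsv_to_rgb(best, s, v)
        yield (int(r * 255), int(g * 255), int(b * 255))


def assign_styles(
    occurrences: OccurrenceTable, seed: int = 42, max_features: int = 30
) -> StyleMap:
    """Give the ``max_features`` most frequent features unique (shape, fill) pairs.

    Deterministic for a fixed seed; the remainder of the ranking is recorded
    in ``overflow`` and drawn with the shared "other" style.
    """
    ranked = occurrences.ranked()
    rng = random.Random(seed)
    colors = _color_stream(rng)
    styles: dict[str, FeatureStyle] = {}
    used_pairs: set[tuple[str, RGB]] = set()
    for name in ranked[:max_features]:
        while True:
            shape = rng.choice(SHAPES)
            fill = next(colors)
            if (shape, fill) not in used_pairs:
                break
        used_pairs.add((shape, fill))
        styles[name] = FeatureStyle(shape, fill, _darken(fill))
    return StyleMap(styles=styles, overflow=ranked[max_features:])


# ---------------------------------------------------------------------------
# Value coloring


@dataclass(frozen=True)
class ColorScale:
    """Linear two-point color scale; out-of-range values clamp to the endpoints."""

    vmin: float
    vmax: float
    low: RGB = (255, 245, 240)
    high: RGB = (165, 15, 21)

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError(f"need vmin < vmax, got {self.vmin} >= {self.vmax}")


def value_to_color(
    value: float, scale: ColorScale, fallback: RGB | None = None
) -> RGB:
    """Per-channel linear interpolation with round-half-up; clamps outside range.

    A non-finite value falls back to *fallback* (the feature's default fill)
    with a warning, or to the low endpoint when no fallback is given.
    """
    if not math.isfinite(value):
        logger.warning("non-finite value %r, using default color", value)
        return fallback if fallback is not None else scale.low
    t = (value - scale.vmin) / (scale.vmax - scale.vmin)
    t = min(1.0, max(0.0, t))
    return tuple(
        int(math.floor(lo + t * (hi - lo) + 0.5))
        for lo, hi in zip(scale.low, scale.high)
    )  # type: ignore[return-value]
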