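"""Map and legend drawing.

Rows are proteins, the x axis is residue position:

    x(s) = left_gutter + (s - 1) * pixels_per_residue

and a feature spanning residues ``start..end`` (1-based, inclusive) occupies
the half-open pixel interval ``[x(start), x(end + 1))``.

Drawing goes through a small display list of primitives that is serialized
two ways: to SVG text (the source of truth — coordinates are rounded
half-up to 0.1 px so the bytes are stable across platforms) and to a PNG
rasterized from the very same geometry with Pillow.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape, quoteattr

from .annotation import Feature, ProteinRecord
from .io_tables import ValueTable
from .model import PROFILE_CATEGORIES, feature_ordinals
from .styling import RGB, ColorScale, FeatureStyle, StyleMap, value_to_color

GLYPH_CATEGORIES = PROFILE_CATEGORIES  # DOMAIN/REPEAT/REGION/MOTIF get shaped glyphs


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class TrackToggles:
    """Optional annotation tracks around each backbone."""

    disorder: bool = False
    pdb: bool = False
    secondary: bool = False
    compbias: bool = False
    modres: bool = False

    @classmethod
    def all_on(cls) -> "TrackToggles":
        return cls(True, True, True, True, True)


@dataclass(frozen=True)
class MapLayout:
    """Pixel geometry of the map grid."""

    n_rows: int
    max_length: int
    pixels_per_residue: float = 2.0
    row_height: float = 36.0
    row_gap: float = 16.0
    left_gutter: float = 150.0
    top_margin: float = 20.0
    right_margin: float = 20.0
    bottom_margin: float = 20.0

    def __post_init__(self) -> None:
        if self.pixels_per_residue <= 0:
            raise LayoutError("pixels_per_residue must be > 0")

    def x(self, residue: int) -> float:
        """Pixel x of the left edge of 1-based residue position *residue*."""
        return self.left_gutter + (residue - 1) * self.pixels_per_residue

    def glyph_span(self, start: int, end: int) -> tuple[float, float]:
        """Pixel extent [x(start), x(end+1)) of an inclusive residue interval."""
        return self.x(start), self.x(end + 1)

    def row_top(self, i: int) -> float:
        return self.top_margin + i * (self.row_height + self.row_gap)

    def backbone_y(self, i: int) -> float:
        return self.row_top(i) + self.row_height / 2.0

    @property
    def width(self) -> float:
        return self.left_gutter + self.max_length * self.pixels_per_residue + self.right_margin

    @property
    def height(self) -> float:
        return (
            self.top_margin
            + self.n_rows * self.row_height
            + max(0, self.n_rows - 1) * self.row_gap
            + self.bottom_margin
        )


def layout_map(records: Sequence[ProteinRecord], **options) -> MapLayout:
    if not records:
        raise LayoutError("no records to lay out")
    return MapLayout(
        n_rows=len(records), max_length=max(r.length for r in records), **options
    )


# ---------------------------------------------------------------------------
# Display list


@dataclass(frozen=True)
class Item:
    kind: str  # rect | ellipse | polygon | line | circle | text
    coords: tuple[float, ...]
    fill: RGB | None = None
    outline: RGB | None = None
    opacity: float = 1.0
    cls: str = ""
    data: tuple[tuple[str, str], ...] = ()
    text: str = ""
    font_size: float = 12.0
    anchor: str = "start"
    stroke_width: float = 1.0


def _fmt(v: float) -> str:
    return str(Decimal(repr(float(v))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _rgb(c: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*c)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merged and sorted."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _glyph_items(
    feature: Feature,
    accession: str,
    x0: float,
    x1: float,
    yc: float,
    h: float,
    style: FeatureStyle,
    fill: RGB,
) -> Item:
    w = x1 - x0
    top, bot = yc - h / 2, yc + h / 2
    data = (
        ("data-acc", accession),
        ("data-cat", feature.category),
        ("data-name", feature.name),
        ("data-start", str(feature.start)),
        ("data-end", str(feature.end)),
    )
    common = dict(fill=fill, outline=style.outline, cls="feature", data=data)
    if style.shape == "rect":
        return Item("rect", (x0, top, w, h, 0.0), **common)
    if style.shape == "rounded-rect":
        return Item("rect", (x0, top, w, h, min(5.0, w / 2)), **common)
    if style.shape == "ellipse":
        return Item("ellipse", ((x0 + x1) / 2, yc, w / 2, h / 2), **common)
    if style.shape == "hexagon":
        d = min(h / 2, w / 4)
        pts = (x0, yc, x0 + d, top, x1 - d, top, x1, yc, x1 - d, bot, x0 + d, bot)
        return Item("polygon", pts, **common)
    if style.shape == "diamond":
        xc = (x0 + x1) / 2
        return Item("polygon", (x0, yc, xc, top, x1, yc, xc, bot), **common)
    # chevron: forward-pointing arrow band
    d = min(h / 2, w / 3)
    pts = (x0, top, x1 - d, top, x1, yc, x1 - d, bot, x0, bot, x0 + d, yc)
    return Item("polygon", pts, **common)


def _ellipsize(name: str, gutter: float, char_w: float = 7.0) -> str:
    max_chars = max(1, int((gutter - 12) / char_w))
    if len(name) <= max_chars:
        return name
    return name[: max_chars - 1] + "…"


def build_map_items(
    records: Sequence[ProteinRecord],
    style_map: StyleMap,
    layout: MapLayout,
    tracks: TrackToggles | None = None,
    value_table: ValueTable | None = None,
    color_scale: ColorScale | None = None,
    display_names: dict[str, str] | None = None,
) -> list[Item]:
    """Assemble the display list for the full map (z-order = list order)."""
    tracks = tracks or TrackToggles()
    display_names = display_names or {}
    if value_table is not None and value_table.rows and color_scale is None:
        vmin, vmax = value_table.vmin, value_table.vmax
        if vmin == vmax:
            vmin, vmax = vmin - 0.5, vmax + 0.5
        color_scale = ColorScale(vmin, vmax)

    items: list[Item] = [
        Item("rect", (0.0, 0.0, layout.width, layout.height, 0.0),
             fill=(255, 255, 255), cls="background")
    ]
    h_glyph = layout.row_height * 0.5

    for i, rec in enumerate(records):
        yc = layout.backbone_y(i)
        label = _ellipsize(
            display_names.get(rec.accession, rec.accession), layout.left_gutter
        )

        if tracks.disorder:
            for f in rec.features_in({"DISORDER"}):
                x0, x1 = layout.glyph_span(f.start, f.end)
                items.append(
                    Item("rect",
                         (x0, yc - layout.row_height * 0.31, x1 - x0,
                          layout.row_height * 0.62, 0.0),
                         fill=(150, 150, 150), opacity=0.35, cls="disorder")
                )

        items.append(
            Item("line", (layout.x(1), yc, layout.x(rec.length + 1), yc),
                 outline=(60, 60, 60), cls="backbone", stroke_width=2.0)
        )

        # main glyphs: longer drawn first (behind), ties by start then name
        ordinals = {id(f): k for k, f in feature_ordinals(rec).items()}
        glyphs = sorted(
            rec.features_in(GLYPH_CATEGORIES),
            key=lambda f: (-f.length, f.start, f.name),
        )
        for f in glyphs:
            style = style_map.style_for(f.canonical_name)
            fill = style.fill
            if value_table is not None and color_scale is not None:
                key = ordinals.get(id(f))
                if key is not None:
                    value = value_table.lookup(rec.accession, key[0], key[1])
                    if value is not None:
                        fill = value_to_color(value, color_scale, fallback=style.fill)
            x0, x1 = layout.glyph_span(f.start, f.end)
            items.append(
                _glyph_items(f, rec.accession, x0, x1, yc, h_glyph, style, fill)
            )

        if tracks.compbias:
            yb = yc - layout.row_height * 0.33
            for f in rec.features_in({"COMPBIAS"}):
                x0, x1 = layout.glyph_span(f.start, f.end)
                items.append(Item("line", (x0, yb, x1, yb),
                                  outline=(80, 40, 120), cls="compbias",
                                  stroke_width=1.5))
                for xe in (x0, x1):
                    items.append(Item("line", (xe, yb, xe, yb + 3.0),
                                      outline=(80, 40, 120), cls="compbias",
                                      stroke_width=1.5))
        if tracks.secondary:
            ys = yc + layout.row_height * 0.32
            colors = {"HELIX": (202, 0, 32), "STRAND": (244, 165, 130),
                      "TURN": (146, 197, 222)}
            for f in rec.features_in({"HELIX", "STRAND", "TURN"}):
                x0, x1 = layout.glyph_span(f.start, f.end)
                items.append(
                    Item("rect", (x0, ys, x1 - x0, 4.0, 0.0),
                         fill=colors[f.category],
                         cls=f"secondary {f.category.lower()}")
                )
        if tracks.pdb:
            yp = yc + layout.row_height * 0.42
            spans = [
                (start, end)
                for ref in rec.pdb_refs
                for (_, start, end) in ref.chain_ranges
            ]
            for s, e in merge_intervals(spans):
                x0, x1 = layout.glyph_span(s, e)
                items.append(
                    Item("rect", (x0, yp, x1 - x0, 5.0, 0.0),
                         fill=(40, 90, 160), cls="pdb",
                         data=(("data-start", str(s)), ("data-end", str(e))))
                )
        if tracks.modres:
            ym = yc - layout.row_height * 0.42
            for f in rec.features_in({"MOD_RES"}):
                xm = (layout.x(f.start) + layout.x(f.end + 1)) / 2
                items.append(Item("line", (xm, yc - h_glyph / 2, xm, ym),
                                  outline=(30, 30, 30), cls="modres",
                                  stroke_width=1.0))
                items.append(
                    Item("circle", (xm, ym, 3.0), fill=(230, 60, 60),
                         outline=(30, 30, 30), cls="modres",
                         data=(("data-start", str(f.start)),
                               ("data-name", f.name)))
                )

        items.append(
            Item("text", (layout.left_gutter - 8.0, yc + 4.0), text=label,
                 fill=(0, 0, 0), cls="label", anchor="end")
        )
    return items


# ---------------------------------------------------------------------------
# Serialization


def _svg_element(item: Item) -> str:
    style_bits = []
    if item.fill is not None:
        style_bits.append(f'fill="{_rgb(item.fill)}"')
    elif item.kind not in ("line", "text"):
        style_bits.append('fill="none"')
    if item.outline is not None:
        if item.kind == "line":
            style_bits.append(f'stroke="{_rgb(item.outline)}"')
        else:
            style_bits.append(f'stroke="{_rgb(item.outline)}"')
    if item.kind == "line" or item.outline is not None:
        style_bits.append(f'stroke-width="{_fmt(item.stroke_width)}"')
    if item.opacity != 1.0:
        style_bits.append(f'opacity="{_fmt(item.opacity)}"')
    attrs = ""
    if item.cls:
        attrs += f' class={quoteattr(item.cls)}'
    for k, v in item.data:
        attrs += f" {k}={quoteattr(v)}"
    style = (" " + " ".join(style_bits)) if style_bits else ""

    c = item.coords
    if item.kind == "rect":
        x, y, w, h, rx = c
        rx_attr = f' rx="{_fmt(rx)}"' if rx else ""
        return (f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
                f'height="{_fmt(h)}"{rx_attr}{style}{attrs}/>')
    if item.kind == "ellipse":
        cx, cy, rx, ry = c
        return (f'<ellipse cx="{_fmt(cx)}" cy="{_fmt(cy)}" rx="{_fmt(rx)}" '
                f'ry="{_fmt(ry)}"{style}{attrs}/>')
    if item.kind == "polygon":
        pts = " ".join(
            f"{_fmt(c[i])},{_fmt(c[i + 1])}" for i in range(0, len(c), 2)
        )
        return f'<polygon points="{pts}"{style}{attrs}/>'
    if item.kind == "line":
        x1, y1, x2, y2 = c
        return (f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
                f'y2="{_fmt(y2)}"{style}{attrs}/>')
    if item.kind == "circle":
        cx, cy, r = c
        return f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}"{style}{attrs}/>'
    if item.kind == "text":
        x, y = c
        anchor = f' text-anchor="{item.anchor}"' if item.anchor != "start" else ""
        fill = f' fill="{_rgb(item.fill)}"' if item.fill else ""
        return (f'<text x="{_fmt(x)}" y="{_fmt(y)}" '
                f'font-family="Helvetica,Arial,sans-serif" '
                f'font-size="{_fmt(item.font_size)}"{anchor}{fill}{attrs}>'
                f"{escape(item.text)}</text>")
    raise ValueError(f"unknown item kind {item.kind!r}")


def _items_to_svg(items: Sequence[Item], width: float, height: float) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
    )
    body = "\n".join(_svg_element(i) for i in items)
    return head + body + "\n</svg>\n"


def _blend_white(color: RGB, opacity: float) -> RGB:
    return tuple(round(255 * (1 - opacity) + ch * opacity) for ch in color)  # type: ignore[return-value]


_PIL_ANCHORS = {"start": "lm", "middle": "mm", "end": "rm"}


def _items_to_png(items: Sequence[Item], width: float, height: float, path: Path) -> None:
    from PIL import Image, ImageDraw

    img = Image.new("RGB", (max(1, round(width)), max(1, round(height))), "white")
    draw = ImageDraw.Draw(img)
    for it in items:
        fill = _blend_white(it.fill, it.opacity) if it.fill is not None else None
        outline = it.outline
        c = it.coords
        if it.kind == "rect":
            x, y, w, h, rx = c
            box = (x, y, x + w, y + h)
            if rx:
                draw.rounded_rectangle(box, radius=rx, fill=fill, outline=outline)
            else:
                draw.rectangle(box, fill=fill, outline=outline)
        elif it.kind == "ellipse":
            cx, cy, rx, ry = c
            draw.ellipse((cx - rx, cy - ry, cx + rx, cy + ry), fill=fill, outline=outline)
        elif it.kind == "polygon":
            pts = [(c[i], c[i + 1]) for i in range(0, len(c), 2)]
            draw.polygon(pts, fill=fill, outline=outline)
        elif it.kind == "line":
            draw.line(c, fill=outline, width=max(1, round(it.stroke_width)))
        elif it.kind == "circle":
            cx, cy, r = c
            draw.ellipse((cx - r, cy - r, cx + r, cy + r), fill=fill, outline=outline)
        elif it.kind == "text":
            x, y = c
            draw.text((x, y - 2), it.text, fill=it.fill or (0, 0, 0),
                      anchor=_PIL_ANCHORS.get(it.anchor, "lm"))
    img.save(path, format="PNG")


@dataclass
class RenderedMap:
    """An assembled drawing: SVG text plus the display list it came from."""

    svg: str
    items: list[Item]
    width: float
    height: float

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.svg.encode()).hexdigest()

    def save_svg(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.svg)
        return path

    def save_png(self, path: str | Path) -> Path:
        path = Path(path)
        _items_to_png(self.items, self.width, self.height, path)
        return path


def render_map(
    records: Sequence[ProteinRecord],
    style_map: StyleMap,
    layout: MapLayout,
    tracks: TrackToggles | None = None,
    value_table: ValueTable | None = None,
    color_scale: ColorScale | None = None,
    display_names: dict[str, str] | None = None,
) -> RenderedMap:
    """Draw the 2D map for *records*, in the given row order."""
    items = build_map_items(
        records, style_map, layout, tracks, value_table, color_scale, display_names
    )
    svg = _items_to_svg(items, layout.width, layout.height)
    return RenderedMap(svg=svg, items=items, width=layout.width, height=layout.height)


# ---------------------------------------------------------------------------
# Legend


def render_legend(
    style_map: StyleMap,
    tracks: TrackToggles | None = None,
    color_scale: ColorScale | None = None,
) -> RenderedMap:
    """One swatch + label per styled feature, in occurrence-rank order.

    The "other" bucket appears only when features overflowed the styled set;
    track markers and the value color bar are keyed when active.
    """
    if not style_map.styles:
        raise ValueError("style map is empty")
    tracks = tracks or TrackToggles()
    row_h, swatch_w, swatch_h, pad = 22.0, 26.0, 13.0, 10.0
    entries: list[tuple[str, FeatureStyle]] = list(style_map.styles.items())
    if style_map.overflow:
        entries.append(("other", style_map.other))
    track_labels = {
        "disorder": "Disordered region", "pdb": "PDB coverage",
        "secondary": "Helix / Strand", "compbias": "Compositional bias",
        "modres": "Modified residue",
    }
    active_tracks = [k for k in track_labels if getattr(tracks, k)]

    n_rows = len(entries) + len(active_tracks)
    width = 240.0
    height = pad * 2 + n_rows * row_h + (70.0 if color_scale else 0.0)
    items: list[Item] = [
        Item("rect", (0.0, 0.0, width, height, 0.0), fill=(255, 255, 255),
             cls="background")
    ]
    y = pad
    for name, style in entries:
        x0, x1 = pad, pad + swatch_w
        yc = y + row_h / 2
        fake = Feature("DOMAIN", name, 1, 1)
        items.append(_glyph_items(fake, "", x0, x1, yc, swatch_h, style, style.fill))
        items.append(Item("text", (x1 + 8.0, yc + 4.0), text=name,
                          fill=(0, 0, 0), cls="legend-label"))
        y += row_h
    for key in active_tracks:
        yc = y + row_h / 2
        if key == "modres":
            items.append(Item("circle", (pad + swatch_w / 2, yc, 3.0),
                              fill=(230, 60, 60), outline=(30, 30, 30),
                              cls="modres"))
        elif key == "disorder":
            items.append(Item("rect", (pad, yc - 5.0, swatch_w, 10.0, 0.0),
                              fill=(150, 150, 150), opacity=0.35, cls="disorder"))
        elif key == "pdb":
            items.append(Item("rect", (pad, yc - 2.5, swatch_w, 5.0, 0.0),
                              fill=(40, 90, 160), cls="pdb"))
        elif key == "secondary":
            items.append(Item("rect", (pad, yc - 2.0, swatch_w / 2 - 1, 4.0, 0.0),
                              fill=(202, 0, 32), cls="secondary helix"))
            items.append(Item("rect", (pad + swatch_w / 2 + 1, yc - 2.0,
                                       swatch_w / 2 - 1, 4.0, 0.0),
                              fill=(244, 165, 130), cls="secondary strand"))
        elif key == "compbias":
            items.append(Item("line", (pad, yc, pad + swatch_w, yc),
                              outline=(80, 40, 120), cls="compbias",
                              stroke_width=1.5))
        items.append(Item("text", (pad + swatch_w + 8.0, yc + 4.0),
                          text=track_labels[key], fill=(0, 0, 0),
                          cls="legend-label"))
        y += row_h
    if color_scale is not None:
        bar_w, bar_h, n_steps = 160.0, 12.0, 32
        y += 10
        for k in range(n_steps):
            t = k / (n_steps - 1)
            v = color_scale.vmin + t * (color_scale.vmax - color_scale.vmin)
            items.append(
                Item("rect", (pad + k * bar_w / n_steps, y,
                              bar_w / n_steps + 0.5, bar_h, 0.0),
                     fill=value_to_color(v, color_scale), cls="scale")
            )
        items.append(Item("text", (pad, y + bar_h + 14.0),
                          text=f"{color_scale.vmin:g}", fill=(0, 0, 0),
                          cls="scale-min"))
        items.append(Item("text", (pad + bar_w, y + bar_h + 14.0),
                          text=f"{color_scale.vmax:g}", fill=(0, 0, 0),
                          anchor="end", cls="scale-max"))
    svg = _items_to_svg(items, width, height)
    return RenderedMap(svg=svg, items=items, width=width, height=height)
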