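"""Layout geometry, SVG determinism, tracks and legend content."""

import xml.etree.ElementTree as ET

import pytest

from featmap.annotation import Feature, PdbRef
from featmap.io_tables import ValueRow, ValueTable
from featmap.model import compute_occurrences
from featmap.rendering import (
    LayoutError,
    MapLayout,
    TrackToggles,
    layout_map,
    merge_intervals,
    render_legend,
    render_map,
)
from featmap.rendering import _fmt  # rounding rule shared with the serializer
from featmap.styling import ColorScale, assign_styles

from conftest import make_record


def style_for(records, **kw):
    return assign_styles(compute_occurrences(records), **kw)


def svg_feature_extents(svg: str):
    """Parse glyph x-extents back out of the SVG, keyed by data attributes."""
    root = ET.fromstring(svg)
    out = []
    for el in root.iter():
        if el.get("class") != "feature":
            continue
        tag = el.tag.split("}")[-1]
        if tag == "rect":
            x0 = float(el.get("x"))
            x1 = x0 + float(el.get("width"))
        elif tag == "ellipse":
            cx, rx = float(el.get("cx")), float(el.get("rx"))
            x0, x1 = cx - rx, cx + rx
        else:  # polygon
            xs = [float(p.split(",")[0]) for p in el.get("points").split()]
            x0, x1 = min(xs), max(xs)
        out.append(
            {
                "acc": el.get("data-acc"),
                "name": el.get("data-name"),
                "start": int(el.get("data-start")),
                "end": int(el.get("data-end")),
                "x0": x0,
                "x1": x1,
            }
        )
    return out


class TestLayout:
    def test_backbone_extent_formula(self):
        layout = MapLayout(n_rows=1, max_length=100, pixels_per_residue=2.0,
                           left_gutter=150.0)
        assert layout.x(1) == 150.0
        assert layout.x(101) == 350.0

    def test_second_row_offset(self):
        layout = MapLayout(n_rows=2, max_length=100, row_height=36.0, row_gap=16.0)
        assert layout.row_top(1) - layout.row_top(0) == 52.0

    def test_nonpositive_ppr_rejected(self):
        with pytest.raises(LayoutError, match="pixels_per_residue"):
            MapLayout(n_rows=1, max_length=10, pixels_per_residue=0.0)

    def test_layout_map_requires_records(self):
        with pytest.raises(LayoutError):
            layout_map([])


class TestMapGeometry:
    def test_hand_computed_glyph_extent(self):
        rec = make_record("P00001", length=800,
                          features=[Feature("DOMAIN", "SH3", 500, 605)])
        layout = layout_map([rec], pixels_per_residue=1.0, left_gutter=150.0)
        rendered = render_map([rec], style_for([rec]), layout)
        (glyph,) = svg_feature_extents(rendered.svg)
        assert (glyph["x0"], glyph["x1"]) == (649.0, 755.0)

    def test_all_glyph_extents_match_formula(self, small_records):
        layout = layout_map(small_records, pixels_per_residue=1.7)
        rendered = render_map(small_records, style_for(small_records), layout)
        glyphs = svg_feature_extents(rendered.svg)
        assert glyphs
        for g in glyphs:
            # left edge is serialized directly; the right edge of a rect is
            # x + width, two independently-rounded 0.1-px values
            assert g["x0"] == float(_fmt(layout.x(g["start"])))
            assert abs(g["x1"] - layout.x(g["end"] + 1)) <= 0.1 + 1e-9

    def test_minimal_map_element_counts(self):
        rec = make_record("P00001", length=300,
                          features=[Feature("DOMAIN", "SH3", 10, 66)])
        rendered = render_map([rec], style_for([rec]), layout_map([rec]))
        kinds = [(i.kind, i.cls) for i in rendered.items]
        assert kinds.count(("line", "backbone")) == 1
        assert sum(1 for _, c in kinds if c == "feature") == 1
        assert kinds.count(("text", "label")) == 1

    def test_z_order_longer_features_drawn_first(self):
        rec = make_record(
            "P00001", length=500,
            features=[Feature("DOMAIN", "Short", 100, 120),
                      Feature("DOMAIN", "Long", 50, 400)],
        )
        rendered = render_map([rec], style_for([rec]), layout_map([rec]))
        names = [dict(i.data).get("data-name") for i in rendered.items
                 if i.cls == "feature"]
        assert names == ["Long", "Short"]

    def test_byte_determinism(self, small_records):
        layout = layout_map(small_records)
        style = style_for(small_records)
        a = render_map(small_records, style, layout, tracks=TrackToggles.all_on())
        b = render_map(small_records, style, layout, tracks=TrackToggles.all_on())
        assert a.svg == b.svg
        assert a.sha256 == b.sha256

    def test_label_truncated_to_gutter(self):
        rec = make_record("P00001", length=100)
        layout = layout_map([rec], left_gutter=60.0)
        rendered = render_map(
            [rec], style_for([rec]), layout,
            display_names={"P00001": "an extremely long protein display name"},
        )
        (label,) = [i for i in rendered.items if i.cls == "label"]
        assert label.text.endswith("…")
        assert len(label.text) <= (60 - 12) // 7


class TestTracks:
    def build(self, tracks):
        rec = make_record(
            "P00001", length=400,
            features=[
                Feature("DOMAIN", "SH3", 10, 66),
                Feature("REGION", "Disordered", 100, 160),
                Feature("DISORDER", "Disordered", 100, 160),
                Feature("HELIX", "Helix", 200, 215),
                Feature("STRAND", "Strand", 220, 228),
                Feature("COMPBIAS", "Polar residues", 300, 330),
                Feature("MOD_RES", "Phosphoserine", 350, 350),
            ],
            pdb_refs=[PdbRef("1ABC", (("A", 1, 120), ("B", 100, 200))),
                      PdbRef("2DEF", (("A", 300, 380),))],
        )
        return render_map([rec], style_for([rec]), layout_map([rec]), tracks=tracks)

    def test_all_tracks_emit_elements(self):
        rendered = self.build(TrackToggles.all_on())
        classes = {i.cls for i in rendered.items}
        assert {"disorder", "pdb", "modres", "compbias"} <= classes
        assert {"secondary helix", "secondary strand"} <= classes

    def test_tracks_off_emit_nothing(self):
        rendered = self.build(TrackToggles())
        classes = {i.cls for i in rendered.items}
        assert not classes & {"disorder", "pdb", "modres", "compbias",
                              "secondary helix", "secondary strand"}

    def test_pdb_bar_is_interval_union(self):
        rendered = self.build(TrackToggles(pdb=True))
        bars = sorted(
            (int(dict(i.data)["data-start"]), int(dict(i.data)["data-end"]))
            for i in rendered.items if i.cls == "pdb"
        )
        assert bars == [(1, 200), (300, 380)]


class TestIntervalUnion:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([], []),
            ([(5, 9), (1, 3)], [(1, 3), (5, 9)]),
            ([(1, 5), (4, 9), (11, 12)], [(1, 9), (11, 12)]),
            ([(1, 5), (6, 9)], [(1, 9)]),  # directly adjacent intervals merge
            ([(1, 10), (2, 3)], [(1, 10)]),
        ],
    )
    def test_merge_examples(self, intervals, expected):
        assert merge_intervals(intervals) == expected

    def test_against_brute_force_membership(self):
        import random

        rng = random.Random(1)
        for _ in range(50):
            ivs = [
                (s, s + rng.randint(0, 30))
                for s in (rng.randint(1, 150) for _ in range(rng.randint(1, 8)))
            ]
            merged = merge_intervals(ivs)
            covered = set()
            for s, e in ivs:
                covered.update(range(s, e + 1))
            merged_cover = set()
            for s, e in merged:
                merged_cover.update(range(s, e + 1))
            assert merged_cover >= covered
            # merged intervals may only bridge directly adjacent residues
            for s, e in merged:
                for pos in range(s, e + 1):
                    assert pos in covered or (
                        pos - 1 in covered and pos + 1 in covered
                    )


class TestValueColoring:
    def test_value_overrides_fill(self):
        rec = make_record("P00001", length=300,
                          features=[Feature("DOMAIN", "SH3", 10, 66)])
        style = style_for([rec])
        layout = layout_map([rec])
        scale = ColorScale(0.0, 1.0, low=(0, 0, 0), high=(255, 255, 255))
        table = ValueTable([ValueRow("P00001", "SH3", 1, 1.0)])
        plain = render_map([rec], style, layout)
        colored = render_map([rec], style, layout, value_table=table,
                             color_scale=scale)
        (g0,) = [i for i in plain.items if i.cls == "feature"]
        (g1,) = [i for i in colored.items if i.cls == "feature"]
        assert g0.fill != g1.fill
        assert g1.fill == (255, 255, 255)


class TestLegend:
    def test_one_swatch_per_styled_feature(self, small_records):
        style = style_for(small_records, max_features=3)
        legend = render_legend(style)
        labels = [i.text for i in legend.items if i.cls == "legend-label"]
        assert labels[:3] == list(style.styles)

    def test_other_entry_iff_overflow(self, small_records):
        occ = compute_occurrences(small_records)
        full = assign_styles(occ, max_features=len(occ.total_count))
        cut = assign_styles(occ, max_features=1)
        full_labels = [i.text for i in render_legend(full).items
                       if i.cls == "legend-label"]
        cut_labels = [i.text for i in render_legend(cut).items
                      if i.cls == "legend-label"]
        assert "other" not in full_labels
        assert "other" in cut_labels

    def test_color_scale_ticks_show_bounds(self, small_records):
        style = style_for(small_records)
        legend = render_legend(style, color_scale=ColorScale(-2.5, 7.0))
        texts = {i.text for i in legend.items}
        assert {"-2.5", "7"} <= texts

    def test_empty_style_map_rejected(self):
        from featmap.styling import StyleMap

        with pytest.raises(ValueError, match="empty"):
            render_legend(StyleMap())
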