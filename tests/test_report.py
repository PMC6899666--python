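"""Result tables (sort/filter/export) and rendering."""

import csv
import json
import math

import numpy as np
import pytest
from PIL import Image

import splicecov as sc
from splicecov.report import table_to_dataframe


def make_rows(values, variant="v1"):
    """Rows with given r_pb values (None = undefined); rpkm = index."""
    rows = []
    for i, val in enumerate(values):
        rec = sc.SampleRecord(
            name=f"s{i}", bam_locator=f"s{i}.bam", title=f"title {i}",
            total_reads_mapped=1_000_000,
        )
        summary = sc.ExpressionSummary(
            sample_id=f"s{i}", gene_id="g", reads_in_region=i,
            rpkm_absolute=float(i),
            rpb_by_variant={variant: float("nan") if val is None else val},
        )
        rows.append(sc.ResultRow(rec, summary, variant))
    return sc.ResultTable("g", variant, rows)


class TestSortTable:
    def test_stable_desc_with_undefined_last(self):
        t = sc.sort_table(make_rows([0.2, 0.9, None, 0.9]), "rpb", "desc")
        assert [r.sample.name for r in t.rows] == ["s1", "s3", "s0", "s2"]

    def test_asc_reverses_defined_block_only(self):
        vals = [0.5, 0.1, None, 0.8]
        desc = sc.sort_table(make_rows(vals), "rpb", "desc")
        asc = sc.sort_table(make_rows(vals), "rpb", "asc")
        assert [r.sample.name for r in asc.rows[:3]] == [
            r.sample.name for r in reversed(desc.rows[:3])
        ]
        assert asc.rows[-1].sample.name == "s2"

    def test_matches_independent_sort_on_random_rows(self):
        """100 random rows: agree with a hand-coded selection sort."""
        rng = np.random.default_rng(9)
        vals = [None if rng.random() < 0.1 else float(rng.random()) for _ in range(100)]
        t = sc.sort_table(make_rows(vals), "rpb", "desc")
        # oracle: decorate with (-value, original index), selection-sorted
        items = [
            (i, v) for i, v in enumerate(vals) if v is not None
        ]
        order = []
        pool = list(items)
        while pool:
            best = 0
            for j in range(1, len(pool)):
                if pool[j][1] > pool[best][1] or (
                    pool[j][1] == pool[best][1] and pool[j][0] < pool[best][0]
                ):
                    best = j
            order.append(pool.pop(best)[0])
        order += [i for i, v in enumerate(vals) if v is None]
        assert [r.sample.name for r in t.rows] == [f"s{i}" for i in order]

    def test_sort_is_permutation(self):
        rng = np.random.default_rng(1)
        vals = list(rng.random(50))
        t = make_rows(vals)
        sorted_t = sc.sort_table(t, "rpkm", "asc")
        assert sorted({r.sample.name for r in sorted_t.rows}) == sorted(
            {r.sample.name for r in t.rows}
        )
        assert len(sorted_t.rows) == len(t.rows)

    def test_rpkm_sort_uses_relative_in_relative_mode(self):
        t = make_rows([0.1, 0.2, 0.3])
        t.mode = "relative"
        t.rows[0].summary.rpkm_relative = 5.0
        t.rows[1].summary.rpkm_relative = float("nan")
        t.rows[2].summary.rpkm_relative = -1.0
        out = sc.sort_table(t, "rpkm", "desc")
        assert [r.sample.name for r in out.rows] == ["s0", "s2", "s1"]


class TestFilterTable:
    def _table(self):
        t = make_rows([0.1] * 6)
        for i, r in enumerate(t.rows):
            r.sample.title = "Heat shock" if i in (1, 4) else "Control"
            r.sample.description = f"desc {i}"
        return t

    def test_keyword_matches_case_insensitive(self):
        out = sc.filter_table(self._table(), "heat")
        assert [r.sample.name for r in out.rows] == ["s1", "s4"]

    def test_empty_keyword_is_identity(self):
        t = self._table()
        assert [r.sample.name for r in sc.filter_table(t, "").rows] == [
            r.sample.name for r in t.rows
        ]

    def test_filter_sort_commute(self):
        rng = np.random.default_rng(4)
        t = make_rows(list(rng.random(40)))
        for i, r in enumerate(t.rows):
            r.sample.title = "keep" if i % 3 else "drop"
        a = sc.sort_table(sc.filter_table(t, "keep"), "rpb", "desc")
        b = sc.filter_table(sc.sort_table(t, "rpb", "desc"), "keep")
        assert [r.sample.name for r in a.rows] == [r.sample.name for r in b.rows]

    def test_filters_commute_with_each_other(self):
        t = self._table()
        ab = sc.filter_table(sc.filter_table(t, "heat"), "desc")
        ba = sc.filter_table(sc.filter_table(t, "desc"), "heat")
        assert [r.sample.name for r in ab.rows] == [r.sample.name for r in ba.rows]


class TestExportTable:
    def test_csv_header_and_rows(self, tmp_path):
        t = make_rows([0.5, None])
        path = sc.export_table(t, "csv", tmp_path / "out.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert lines[0].startswith("sample,")

    def test_csv_roundtrip_six_sig_digits(self, tmp_path):
        t = make_rows([0.123456789, 0.987654321, None])
        t.rows[0].summary.rpkm_relative = -1.23456789
        path = sc.export_table(t, "csv", tmp_path / "out.csv")
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert float(rows[0]["rpb_v1"]) == pytest.approx(0.123456789, rel=1e-5)
        assert float(rows[0]["rpkm_relative"]) == pytest.approx(-1.23456789, rel=1e-5)
        assert rows[2]["rpb_v1"] == ""  # undefined -> empty field

    def test_json_schema_and_nulls(self, tmp_path):
        t = make_rows([0.5, None])
        path = sc.export_table(t, "json", tmp_path / "out.json")
        payload = json.loads(path.read_text())
        assert set(payload) == {"gene_id", "selected_variant", "mode", "rows"}
        assert payload["rows"][1]["rpb_v1"] is None
        for row in payload["rows"]:
            assert {"sample", "title", "sra_id", "reads_in_region",
                    "rpkm_absolute", "rpkm_relative", "failed"} <= set(row)

    def test_failed_rows_exported_not_dropped(self, tmp_path):
        t = make_rows([0.5])
        t.rows[0].failed = True
        t.rows[0].failure_reason = "no such BAM"
        df = table_to_dataframe(t)
        assert bool(df.iloc[0]["failed"])


class TestBuildTable:
    def test_three_sample_compendium(self, skip_compendium, skip_gene):
        comp = sc.read_config(skip_compendium["config"])
        t = sc.build_table(
            skip_gene, comp, "SIMG01.1", bam_dir=skip_compendium["dir"]
        )
        assert len(t.rows) == 3
        for r in t.rows:
            assert set(r.summary.rpb_by_variant) == {"SIMG01.1", "SIMG01.2"}

    def test_self_control_relative_zero(self, skip_compendium, skip_gene):
        comp = sc.read_config(skip_compendium["config"])
        t = sc.build_table(
            skip_gene, comp, "SIMG01.1", mode="relative", bam_dir=skip_compendium["dir"]
        )
        pure1 = next(r for r in t.rows if r.sample.name == "pure1")
        assert pure1.summary.rpkm_relative == 0.0  # its own control

    def test_rebuild_is_deterministic(self, skip_compendium, skip_gene):
        comp = sc.read_config(skip_compendium["config"])
        kw = dict(bam_dir=skip_compendium["dir"], mode="relative")
        t1 = sc.build_table(skip_gene, comp, "SIMG01.1", **kw)
        t2 = sc.build_table(skip_gene, comp, "SIMG01.1", **kw)
        for a, b in zip(t1.rows, t2.rows):
            assert a.summary == b.summary

    def test_unreadable_bam_flags_row(self, skip_compendium, skip_gene, tmp_path):
        comp = sc.read_config(skip_compendium["config"])
        comp.samples[0].bam_locator = str(tmp_path / "missing.bam")
        t = sc.build_table(skip_gene, comp, "SIMG01.1", bam_dir=skip_compendium["dir"])
        assert t.rows[0].failed and t.rows[0].failure_reason
        assert not t.rows[1].failed


class TestEfpColor:
    ABS = sc.ColorScale("absolute", 10.0)
    REL = sc.ColorScale("relative", 4.0)

    def test_absolute_endpoints(self):
        assert sc.efp_color(0.0, self.ABS) == "#FFFF00"
        assert sc.efp_color(10.0, self.ABS) == "#FF0000"
        assert sc.efp_color(99.0, self.ABS) == "#FF0000"  # clamped

    def test_relative_midpoint_and_extremes(self):
        assert sc.efp_color(0.0, self.REL) == "#FFFF00"
        assert sc.efp_color(4.0, self.REL) == "#FF0000"
        assert sc.efp_color(-4.0, self.REL) == "#0000FF"

    def test_undefined_is_grey(self):
        assert sc.efp_color(float("nan"), self.ABS) == "#D3D3D3"

    def test_half_scale_is_channelwise_midpoint(self):
        # independent oracle: channel-wise linear interpolation at t = 0.5
        def lerp_hex(a, b, t):
            return "#" + "".join(
                f"{round(a[i] + (b[i] - a[i]) * t):02X}" for i in range(3)
            )
        assert sc.efp_color(5.0, self.ABS) == lerp_hex((255, 255, 0), (255, 0, 0), 0.5)
        assert sc.efp_color(-2.0, self.REL) == lerp_hex((255, 255, 0), (0, 0, 255), 0.5)

    def test_monotone_redness_absolute(self):
        greens = []
        for v in np.linspace(0, 10, 21):
            c = sc.efp_color(float(v), self.ABS)
            greens.append(int(c[3:5], 16))
        assert all(a >= b for a, b in zip(greens, greens[1:]))

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            sc.ColorScale("absolute", 0.0)


class TestRendering:
    def test_single_read_track_renders(self, tmp_path):
        track = sc.CoverageTrack(
            "s", sc.GenomicInterval("c", 0, 100),
            np.concatenate([np.ones(10, int), np.zeros(90, int)]), 1,
        )
        path = sc.render_coverage(track, "#AA0000", tmp_path / "cov.png")
        assert path.exists() and path.stat().st_size > 0

    def test_zero_depth_track_renders_baseline(self, tmp_path):
        track = sc.CoverageTrack("s", sc.GenomicInterval("c", 0, 50), np.zeros(50, int), 0)
        path = sc.render_coverage(track, "#AA0000", tmp_path / "flat.png")
        assert path.exists()

    def test_per_track_normalization(self, tmp_path):
        """Same shape at 10x vs 100x gives (near-)identical images apart
        from the depth label."""
        shape = np.concatenate([np.ones(30), np.zeros(40), np.ones(30)])
        region = sc.GenomicInterval("c", 0, 100)
        t10 = sc.CoverageTrack("a", region, (10 * shape).astype(int), 10)
        t100 = sc.CoverageTrack("b", region, (100 * shape).astype(int), 100)
        p10 = sc.render_coverage(t10, "#336699", tmp_path / "d10.png")
        p100 = sc.render_coverage(t100, "#336699", tmp_path / "d100.png")
        a = np.asarray(Image.open(p10).convert("L"), dtype=float)
        b = np.asarray(Image.open(p100).convert("L"), dtype=float)
        # identical except the label area: >99% of pixels equal
        assert (a == b).mean() > 0.99

    def test_render_fidelity_profile_tracks_depth(self, tmp_path):
        """Column-wise ink height correlates with the depth vector."""
        rng = np.random.default_rng(8)
        depth = rng.poisson(20, 400)
        region = sc.GenomicInterval("c", 0, 400)
        track = sc.CoverageTrack("s", region, depth, int(depth.sum()))
        path = sc.render_coverage(track, "#FF0000", tmp_path / "fid.png")
        img = np.asarray(Image.open(path).convert("RGB"), dtype=int)
        # count only fill-colored pixels so axis ink and labels don't intrude
        red = (img[:, :, 0] > 180) & (img[:, :, 1] < 120) & (img[:, :, 2] < 120)
        ink = red.sum(axis=0).astype(float)
        cols = np.nonzero(ink)[0]
        lo, hi = cols.min(), cols.max() + 1  # fill spans the full region
        # average the pixel columns belonging to each genomic base
        bounds = np.linspace(lo, hi, len(depth) + 1)
        heights = np.array([
            ink[int(a) : max(int(a) + 1, int(b))].mean()
            for a, b in zip(bounds[:-1], bounds[1:])
        ])
        r = np.corrcoef(heights, depth)[0, 1]
        assert r > 0.95

    def test_gene_structure_two_rows(self, toy_gene, tmp_path):
        path = sc.render_gene_structure(toy_gene, tmp_path / "gene.png", also_svg=True)
        assert path.exists()
        assert path.with_suffix(".svg").exists()

    def test_structure_pixels_contain_feature_colors(self, toy_gene, tmp_path):
        """The exon/CDS dark green actually appears in the rendered figure."""
        path = sc.render_gene_structure(toy_gene, tmp_path / "geo.png")
        img = np.asarray(Image.open(path).convert("RGB"))
        # dark-green pixels exist, and the image is wider than tall
        dark = (np.abs(img - np.array([0x1B, 0x78, 0x37])) < 30).all(axis=2)
        assert dark.any()
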