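"""Result tables, exports and plots.

Assembles per-sample expression summaries into a sortable/filterable
table, exports it as TSV/CSV/JSON, and renders the browser's graphical
outputs headlessly: per-sample coverage profiles (scaled to each track's
own maximum depth), gene-structure diagrams (CDS dark green, UTR light
green, introns as thin connectors), and the eFP value-to-color mapping
(yellow-to-red absolute scale, blue-yellow-red relative scale).
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import coverage as cov
from .config import Compendium, SampleRecord, resolve_controls
from .genemodel import GeneModel, GenomicInterval
from .stats import ExpressionSummary, relative_expression, summarize

logger = logging.getLogger(__name__)

__all__ = [
    "ResultRow",
    "ResultTable",
    "ColorScale",
    "build_table",
    "sort_table",
    "filter_table",
    "export_table",
    "render_coverage",
    "render_gene_structure",
    "efp_color",
]

# eFP scale endpoints
_YELLOW = (0xFF, 0xFF, 0x00)
_RED = (0xFF, 0x00, 0x00)
_BLUE = (0x00, 0x00, 0xFF)
_UNDEFINED_GREY = "#D3D3D3"

_CDS_GREEN = "#1B7837"   # dark green: exon/CDS
_UTR_GREEN = "#A6DBA0"   # light green: UTRs


@dataclass
class ResultRow:
    """One sample's scores for the queried gene."""

    sample: SampleRecord
    summary: ExpressionSummary
    selected_variant: str
    failed: bool = False
    failure_reason: str = ""

    def __post_init__(self) -> None:
        if not self.failed and self.summary.sample_id != self.sample.name:
            raise ValueError(
                f"summary sample {self.summary.sample_id!r} != record {self.sample.name!r}"
            )


@dataclass
class ResultTable:
    """Ordered result rows plus the sort/filter state applied to them."""

    gene_id: str
    selected_variant: str
    rows: list[ResultRow]
    mode: Literal["absolute", "relative"] = "absolute"
    sort_key: str = "config_order"
    sort_direction: str = "asc"


@dataclass
class ColorScale:
    """Value-to-color mapping bounds for the expression pictographs."""

    mode: Literal["absolute", "relative"]
    max_value: float

    def __post_init__(self) -> None:
        if not self.max_value > 0:
            raise ValueError(f"scale maximum must be positive, got {self.max_value}")


def build_table(
    gene: GeneModel,
    compendium: Compendium,
    selected_variant: str,
    mode: Literal["absolute", "relative"] = "absolute",
    bam_dir: str | Path | None = None,
) -> ResultTable:
    """Score every compendium sample against a gene.

    Each sample's BAM is piled up over the gene span, summarized, and —
    in relative mode — referenced against its resolved controls.  A
    sample whose BAM cannot be read yields a row flagged ``failed`` with
    the reason; the table is still returned.  ``bam_dir`` resolves
    relative BAM locators.
    """
    gene.variant(selected_variant)  # validate early
    rows: list[ResultRow] = []
    for record in compendium.samples:
        t0 = time.perf_counter()
        bam_path = Path(record.bam_locator)
        if bam_dir is not None and not bam_path.is_absolute():
            bam_path = Path(bam_dir) / bam_path
        try:
            track = cov.pileup(bam_path, gene.span, sample_id=record.name)
            summary = summarize(
                track, gene, record.total_reads_mapped, selected_variant
            )
            rows.append(ResultRow(record, summary, selected_variant))
        except (OSError, ValueError) as exc:
            logger.warning("sample %s failed: %s", record.name, exc)
            rows.append(
                ResultRow(
                    record,
                    ExpressionSummary(record.name, gene.gene_id, 0, 0.0),
                    selected_variant,
                    failed=True,
                    failure_reason=str(exc),
                )
            )
        logger.info(
            "sample %s scored in %.3f s", record.name, time.perf_counter() - t0
        )

    if mode == "relative":
        rpkms = {r.sample.name: r.summary.rpkm_absolute for r in rows if not r.failed}
        for row in rows:
            if row.failed:
                continue
            controls = resolve_controls(compendium, row.sample, rpkms)
            if controls:
                row.summary.rpkm_relative = relative_expression(
                    row.summary.rpkm_absolute, controls, atlas_mode=compendium.atlas_mode
                )
    return ResultTable(gene.gene_id, selected_variant, rows, mode=mode)


def sort_table(
    table: ResultTable,
    key: Literal["rpkm", "rpb"],
    direction: Literal["asc", "desc"] = "desc",
) -> ResultTable:
    """Stable sort by RPKM or by the selected variant's r_pb.

    Ties keep config order (the input order); undefined (NaN) values sink
    to the bottom regardless of direction.  Sorting on ``rpkm`` uses the
    absolute value in absolute mode and the log2 ratio in relative mode.
    """
    if key == "rpkm" and table.mode == "relative":
        def value(row: ResultRow) -> float:
            return float("nan") if row.failed else row.summary.rpkm_relative
    elif key == "rpkm":
        def value(row: ResultRow) -> float:
            return float("nan") if row.failed else row.summary.rpkm_absolute
    elif key == "rpb":
        def value(row: ResultRow) -> float:
            if row.failed:
                return float("nan")
            return row.summary.rpb_by_variant.get(row.selected_variant, float("nan"))
    else:
        raise ValueError(f"unknown sort key {key!r}; use 'rpkm' or 'rpb'")

    defined = [r for r in table.rows if not math.isnan(value(r))]
    undefined = [r for r in table.rows if math.isnan(value(r))]
    reverse = direction == "desc"
    defined.sort(key=value, reverse=reverse)  # list.sort is stable
    return replace(
        table, rows=defined + undefined, sort_key=key, sort_direction=direction
    )


def filter_table(table: ResultTable, keyword: str) -> ResultTable:
    """Keep rows whose title or description contains ``keyword``.

    Case-insensitive substring match; relative row order is preserved.
    An empty keyword is the identity.
    """
    if not keyword:
        return replace(table, rows=list(table.rows))
    kw = keyword.lower()
    kept = [
        r
        for r in table.rows
        if kw in r.sample.title.lower() or kw in r.sample.description.lower()
    ]
    return replace(table, rows=kept)


def _sig6(x: float) -> str:
    if math.isnan(x):
        return ""
    return f"{x:.6g}"


def table_to_dataframe(table: ResultTable) -> pd.DataFrame:
    """Flatten a ResultTable into a pandas DataFrame (one r_pb column per variant)."""
    variant_ids = sorted(
        {vid for r in table.rows for vid in r.summary.rpb_by_variant}
    )
    records = []
    for r in table.rows:
        rec: dict[str, object] = {
            "sample": r.sample.name,
            "title": r.sample.title,
            "sra_id": r.sample.sra_id,
            "reads_in_region": r.summary.reads_in_region,
            "rpkm_absolute": r.summary.rpkm_absolute,
            "rpkm_relative": r.summary.rpkm_relative,
        }
        for vid in variant_ids:
            rec[f"rpb_{vid}"] = r.summary.rpb_by_variant.get(vid, float("nan"))
        rec["failed"] = r.failed
        records.append(rec)
    return pd.DataFrame.from_records(records)


def export_table(
    table: ResultTable,
    fmt: Literal["tsv", "csv", "json"],
    path: str | Path,
) -> Path:
    """Write the table to disk.

    Numeric values are formatted at 6 significant digits; undefined values
    become empty fields (tsv/csv) or ``null`` (json).  Failed samples are
    exported with their failure flag set, never silently dropped.
    """
    path = Path(path)
    df = table_to_dataframe(table)
    float_cols = [
        c for c in df.columns
        if c.startswith("rpb_") or c in ("rpkm_absolute", "rpkm_relative")
    ]
    if fmt in ("tsv", "csv"):
        out = df.copy()
        for c in float_cols:
            out[c] = out[c].map(_sig6)
        out.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)
    elif fmt == "json":
        records = []
        for rec in df.to_dict(orient="records"):
            clean: dict[str, object] = {}
            for k, v in rec.items():
                if isinstance(v, float) and k in float_cols:
                    clean[k] = None if math.isnan(v) else float(f"{v:.6g}")
                elif isinstance(v, (np.integer,)):
                    clean[k] = int(v)
                elif isinstance(v, (np.bool_,)):
                    clean[k] = bool(v)
                else:
                    clean[k] = v
            records.append(clean)
        payload = {
            "gene_id": table.gene_id,
            "selected_variant": table.selected_variant,
            "mode": table.mode,
            "rows": records,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def render_coverage(
    track: cov.CoverageTrack,
    color: str = "#1f77b4",
    path: str | Path = "coverage.png",
    also_svg: bool = False,
) -> Path:
    """Render a filled coverage profile for one sample.

    The y-axis is normalized to the track's own maximum depth (annotated
    as text), so every sample's profile fills the same vertical extent —
    shape, not scale, is what the image conveys.  A zero-depth track
    renders as a flat baseline.
    """
    path = Path(path)
    edges = np.arange(track.region.start, track.region.end + 1)
    peak = track.max_depth
    y = track.depth / peak if peak > 0 else np.zeros_like(track.depth, dtype=float)

    fig, ax = plt.subplots(figsize=(8, 1.6), dpi=100)
    ax.stairs(y, edges, fill=True, color=color, linewidth=0)
    ax.set_xlim(track.region.start, track.region.end)
    ax.set_ylim(0, 1.05)
    ax.set_yticks([])
    ax.set_xlabel(f"{track.region.chromosome} position")
    ax.text(
        0.995, 0.95, f"max depth = {peak}",
        transform=ax.transAxes, ha="right", va="top", fontsize=8,
    )
    fig.tight_layout()
    fig.savefig(path)
    if also_svg:
        fig.savefig(path.with_suffix(".svg"))
    plt.close(fig)
    return path


def render_gene_structure(
    gene: GeneModel,
    path: str | Path = "gene.png",
    also_svg: bool = False,
) -> Path:
    """Draw the gene's splice variants, one row per variant.

    Introns are thin connector lines; CDS (and exon portions without UTR
    annotation) are dark green boxes, UTRs light green.  The x-axis spans
    the gene span so the figure aligns with coverage renderings.
    """
    path = Path(path)
    n = len(gene.variants)
    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.5 * n), dpi=100)
    for i, variant in enumerate(gene.variants):
        ymid = n - i
        first = variant.exons[0].start
        last = variant.exons[-1].end
        ax.plot([first, last], [ymid, ymid], color="grey", linewidth=0.8, zorder=1)
        utr = variant.utr5 + variant.utr3
        for ex in variant.exons:
            ax.add_patch(
                plt.Rectangle(
                    (ex.start, ymid - 0.18), len(ex), 0.36,
                    facecolor=_CDS_GREEN, edgecolor="none", zorder=2,
                )
            )
        for iv in utr:
            ax.add_patch(
                plt.Rectangle(
                    (iv.start, ymid - 0.18), len(iv), 0.36,
                    facecolor=_UTR_GREEN, edgecolor="none", zorder=3,
                )
            )
        ax.text(
            gene.span.start, ymid + 0.26, variant.variant_id,
            fontsize=8, va="bottom",
        )
    ax.set_xlim(gene.span.start, gene.span.end)
    ax.set_ylim(0.3, n + 0.9)
    ax.set_yticks([])
    ax.set_xlabel(f"{gene.span.chromosome} position")
    fig.tight_layout()
    fig.savefig(path)
    if also_svg:
        fig.savefig(path.with_suffix(".svg"))
    plt.close(fig)
    return path


def _lerp(a: tuple[int, int, int], b: tuple[int, int, int], t: float) -> str:
    t = min(1.0, max(0.0, t))
    rgb = tuple(round(a[i] + (b[i] - a[i]) * t) for i in range(3))
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def efp_color(value: float, scale: ColorScale) -> str:
    """Map an expression value to its eFP pictograph color.

    Absolute mode interpolates yellow (0) to red (scale maximum), clamped.
    Relative mode is a symmetric diverging scale: blue at the negative
    bound, yellow at 0, red at the positive bound.  NaN maps to grey.
    """
    if math.isnan(value):
        return _UNDEFINED_GREY
    if scale.mode == "absolute":
        return _lerp(_YELLOW, _RED, value / scale.max_value)
    if value >= 0:
        return _lerp(_YELLOW, _RED, value / scale.max_value)
    return _lerp(_YELLOW, _BLUE, -value / scale.max_value)
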