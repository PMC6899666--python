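"""Compendium configuration: an extended annots.xml-style sample listing.

A compendium is an ordered set of RNA-seq samples, each described by a
``<file>`` element carrying the BAM locator and the browser metadata:
title, description, SRA record, total reads mapped, read-map method,
tissue image key (+ optional subpart), display color, publication link,
and control/replicate-control sample names.  The dialect:

.. code-block:: xml

    <files dataset_id="..." atlas_mode="false">
      <file name="..." bam_url="..." title="..." description="..."
            sra_id="..." total_reads_mapped="..." read_map_method="..."
            svg_part="..." svg_subpart="..." color="#RRGGBB" url="..."
            controls="s1,s2" replicate_controls=""/>
    </files>

``atlas_mode`` marks datasets without designated controls, where relative
expression is computed against the median RPKM across all samples.
Unknown attributes are preserved so that read/write round-trips are
lossless.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)

__all__ = ["SampleRecord", "Compendium", "read_config", "write_config", "resolve_controls"]

# canonical attribute order for deterministic output
_FILE_ATTRS = [
    "name", "bam_url", "title", "description", "sra_id", "total_reads_mapped",
    "read_map_method", "svg_part", "svg_subpart", "color", "url",
    "controls", "replicate_controls",
]


@dataclass
class SampleRecord:
    """One compendium entry: a BAM locator plus display/control metadata."""

    name: str
    bam_locator: str
    title: str = ""
    description: str = ""
    sra_id: str = ""
    total_reads_mapped: int = 1
    read_map_method: str = ""
    tissue_image_key: str = ""
    tissue_subpart: str = ""
    color: str = "#000000"
    publication_link: str = ""
    controls: list[str] = field(default_factory=list)
    replicate_controls: list[str] = field(default_factory=list)
    extra_attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sample name must be non-empty")
        if self.total_reads_mapped <= 0:
            raise ValueError(
                f"sample {self.name}: total_reads_mapped must be positive, "
                f"got {self.total_reads_mapped}"
            )


@dataclass
class Compendium:
    """An ordered, named collection of samples.

    Order is meaningful: it defines default display order and sort
    tie-breaking downstream.
    """

    dataset_id: str
    samples: list[SampleRecord]
    atlas_mode: bool = False

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"compendium {self.dataset_id} has no samples")
        names = [s.name for s in self.samples]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate sample names in {self.dataset_id}: {sorted(dupes)}")

    def sample(self, name: str) -> SampleRecord:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(f"no sample {name!r} in compendium {self.dataset_id}")

    def names(self) -> list[str]:
        return [s.name for s in self.samples]


def _split_names(text: str) -> list[str]:
    return [t.strip() for t in text.split(",") if t.strip()]


def read_config(path: str | Path) -> Compendium:
    """Parse a compendium XML file.

    Dangling control references are dropped with a warning (the sample is
    kept); duplicate sample names are an error.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "files":
        raise ValueError(f"{path}: expected root element <files>, found <{root.tag}>")
    dataset_id = root.get("dataset_id", path.stem)
    atlas_mode = root.get("atlas_mode", "false").lower() in ("true", "1", "yes")

    samples: list[SampleRecord] = []
    for el in root.findall("file"):
        attrs = dict(el.attrib)
        extra = {k: v for k, v in attrs.items() if k not in _FILE_ATTRS}
        samples.append(
            SampleRecord(
                name=attrs.get("name", ""),
                bam_locator=attrs.get("bam_url", ""),
                title=attrs.get("title", ""),
                description=attrs.get("description", ""),
                sra_id=attrs.get("sra_id", ""),
                total_reads_mapped=int(attrs.get("total_reads_mapped", "1")),
                read_map_method=attrs.get("read_map_method", ""),
                tissue_image_key=attrs.get("svg_part", ""),
                tissue_subpart=attrs.get("svg_subpart", ""),
                color=attrs.get("color", "#000000"),
                publication_link=attrs.get("url", ""),
                controls=_split_names(attrs.get("controls", "")),
                replicate_controls=_split_names(attrs.get("replicate_controls", "")),
                extra_attrs=extra,
            )
        )
    comp = Compendium(dataset_id=dataset_id, samples=samples, atlas_mode=atlas_mode)

    # validate control references; drop dangling ones with a warning
    known = set(comp.names())
    for s in comp.samples:
        for attr in ("controls", "replicate_controls"):
            refs = getattr(s, attr)
            dangling = [c for c in refs if c not in known]
            if dangling:
                logger.warning(
                    "sample %s: dropping dangling %s reference(s) %s", s.name, attr, dangling
                )
                setattr(s, attr, [c for c in refs if c in known])
    return comp


def write_config(compendium: Compendium, path: str | Path) -> Path:
    """Write a compendium back to XML with deterministic attribute order.

    Empty-string attributes are emitted explicitly (never omitted) so a
    read/write cycle is attribute-identical.
    """
    root = ET.Element("files")
    root.set("dataset_id", compendium.dataset_id)
    root.set("atlas_mode", "true" if compendium.atlas_mode else "false")
    for s in compendium.samples:
        el = ET.SubElement(root, "file")
        values = {
            "name": s.name,
            "bam_url": s.bam_locator,
            "title": s.title,
            "description": s.description,
            "sra_id": s.sra_id,
            "total_reads_mapped": str(s.total_reads_mapped),
            "read_map_method": s.read_map_method,
            "svg_part": s.tissue_image_key,
            "svg_subpart": s.tissue_subpart,
            "color": s.color,
            "url": s.publication_link,
            "controls": ",".join(s.controls),
            "replicate_controls": ",".join(s.replicate_controls),
        }
        for key in _FILE_ATTRS:
            el.set(key, values[key])
        for key in sorted(s.extra_attrs):
            el.set(key, s.extra_attrs[key])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(str(path), encoding="utf-8", xml_declaration=True)
    return path


def resolve_controls(
    compendium: Compendium,
    sample: SampleRecord,
    rpkms: Mapping[str, float],
) -> list[float]:
    """Collect the RPKM values the relative mode should reference.

    Atlas mode: every sample's RPKM (the stats layer takes the median).
    Otherwise: the RPKM values of the union of the sample's controls and
    replicate controls, in compendium order.  A non-atlas sample with no
    resolvable control yields an empty list (relative value undefined),
    logged.
    """
    if compendium.atlas_mode:
        return [rpkms[name] for name in compendium.names() if name in rpkms]
    wanted = set(sample.controls) | set(sample.replicate_controls)
    vals = [rpkms[name] for name in compendium.names() if name in wanted and name in rpkms]
    if not vals:
        logger.warning(
            "sample %s has no resolvable controls; relative expression undefined",
            sample.name,
        )
    return vals
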