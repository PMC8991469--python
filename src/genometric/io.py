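"""On-disk layout of GDM datasets, peak-format import, and flat table export.

A dataset directory holds one ``schema.xml`` at its root and a ``files/``
subdirectory with, per sample, a tab-delimited region file
``<sample_id>.gdm`` and a metadata file ``<sample_id>.gdm.meta``.  Region
files carry no header and the fixed column order
``chr left right strand <schema attributes...>``; a missing value is encoded
as ``"."``.  Metadata files are ``key<TAB>value`` lines.  Writing is
deterministic: samples, regions and metadata pairs are emitted sorted, so the
same dataset always produces byte-identical output.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .expressions import Predicate, evaluate_meta_predicate
from .model import (
    FormatError,
    GDMDataset,
    GDMError,
    MetadataSet,
    Region,
    Sample,
    Schema,
    format_value,
    parse_value,
)

__all__ = [
    "read_gdm_dataset",
    "write_gdm_dataset",
    "import_bed",
    "metadata_table",
    "filter_and_extract",
    "io_counters",
    "reset_io_counters",
    "BED_DIALECTS",
]

REGION_SUFFIX = ".gdm"
META_SUFFIX = ".gdm.meta"
SCHEMA_FILENAME = "schema.xml"


@dataclass
class IOCounters:
    """Observable I/O effort, used to verify the engine's laziness contract."""

    region_rows_parsed: int = 0
    region_files_opened: int = 0


_COUNTERS = IOCounters()


def io_counters() -> IOCounters:
    return _COUNTERS


def reset_io_counters() -> None:
    _COUNTERS.region_rows_parsed = 0
    _COUNTERS.region_files_opened = 0


# ---------------------------------------------------------------------------
# schema.xml


def _schema_to_xml(schema: Schema) -> str:
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append(f'<schema coordinates="{schema.coordinate_system}">')
    for name, dtype in schema.attributes:
        lines.append(f'  <attribute name="{name}" type="{dtype}"/>')
    lines.append("</schema>")
    return "\n".join(lines) + "\n"


def _schema_from_xml(path: Path) -> Schema:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse schema file {path}: {exc}") from exc
    if root.tag != "schema":
        raise FormatError(f"schema file {path} has root element {root.tag!r}")
    attributes = []
    for child in root:
        if child.tag != "attribute":
            raise FormatError(f"unexpected element {child.tag!r} in {path}")
        name = child.get("name")
        dtype = child.get("type")
        if name is None or dtype is None:
            raise FormatError(f"attribute element without name/type in {path}")
        attributes.append((name, dtype))
    coords = root.get("coordinates", "0-based half-open")
    return Schema(tuple(attributes), coordinate_system=coords)


# ---------------------------------------------------------------------------
# dataset read / write


def read_gdm_dataset(path: Union[str, Path]) -> GDMDataset:
    """Load a dataset directory; regions are typed per schema and sorted.

    Raises :class:`FormatError` on a missing schema, an unpaired region or
    metadata file, or a region row with the wrong column count (naming file
    and line), and :class:`ValidationError` when ``right <= left``.
    """
    root = Path(path)
    schema_path = root / SCHEMA_FILENAME
    if not schema_path.is_file():
        raise FormatError(f"missing {SCHEMA_FILENAME} in {root}")
    schema = _schema_from_xml(schema_path)
    files_dir = root / "files"
    if not files_dir.is_dir():
        raise FormatError(f"missing files/ directory in {root}")

    region_files = {
        p.name[: -len(REGION_SUFFIX)]: p
        for p in files_dir.iterdir()
        if p.name.endswith(REGION_SUFFIX) and not p.name.endswith(META_SUFFIX)
    }
    meta_files = {
        p.name[: -len(META_SUFFIX)]: p
        for p in files_dir.iterdir()
        if p.name.endswith(META_SUFFIX)
    }
    if set(region_files) != set(meta_files):
        orphans = sorted(set(region_files) ^ set(meta_files))
        raise FormatError(f"unpaired region/metadata files for samples {orphans}")

    samples = []
    for sample_id in sorted(region_files):
        regions = _read_region_file(region_files[sample_id], schema)
        metadata = _read_meta_file(meta_files[sample_id])
        samples.append(Sample(sample_id, regions, metadata))
    return GDMDataset(schema, samples, name=root.name)


def _read_region_file(path: Path, schema: Schema) -> list:
    _COUNTERS.region_files_opened += 1
    n_columns = 4 + len(schema)
    regions = []
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_columns} columns, got {len(fields)}"
                )
            _COUNTERS.region_rows_parsed += 1
            chrom, left, right, strand = fields[:4]
            try:
                left_i, right_i = int(left), int(right)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            values = tuple(
                parse_value(text, dtype)
                for text, (_, dtype) in zip(fields[4:], schema.attributes)
            )
            regions.append(Region(chrom, left_i, right_i, strand, values))
    return regions


def _read_meta_file(path: Path) -> MetadataSet:
    metadata = MetadataSet()
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise FormatError(f"{path}:{lineno}: expected key<TAB>value")
            key, value = line.split("\t", 1)
            metadata.add(key, value)
    return metadata


def write_gdm_dataset(
    dataset: GDMDataset, path: Union[str, Path], overwrite: bool = False
) -> Path:
    """Persist a dataset; output bytes are deterministic for a given dataset.

    Refuses to write into an existing non-empty directory unless ``overwrite``
    is set.
    """
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"refusing to overwrite non-empty directory {root}")
    files_dir = root / "files"
    files_dir.mkdir(parents=True, exist_ok=True)
    if overwrite:
        for old in files_dir.iterdir():
            old.unlink()
    (root / SCHEMA_FILENAME).write_text(_schema_to_xml(dataset.schema), encoding="utf-8")
    for sample in sorted(dataset.samples, key=lambda s: s.id):
        region_lines = []
        for region in sorted(sample.regions, key=lambda r: r.sort_key):
            fields = [region.chrom, str(region.left), str(region.right), region.strand]
            fields.extend(format_value(v) for v in region.values)
            region_lines.append("\t".join(fields))
        (files_dir / f"{sample.id}{REGION_SUFFIX}").write_text(
            "".join(line + "\n" for line in region_lines), encoding="utf-8"
        )
        meta_lines = [f"{k}\t{v}" for k, v in sample.metadata.pairs()]
        (files_dir / f"{sample.id}{META_SUFFIX}").write_text(
            "".join(line + "\n" for line in meta_lines), encoding="utf-8"
        )
    return root


# ---------------------------------------------------------------------------
# BED / ENCODE peak import

BED_DIALECTS = {
    "bed": Schema((("name", "string"), ("score", "float"))),
    "narrowPeak": Schema(
        (
            ("name", "string"),
            ("score", "integer"),
            ("signalValue", "float"),
            ("pValue", "float"),
            ("qValue", "float"),
            ("peak", "integer"),
        )
    ),
    "broadPeak": Schema(
        (
            ("name", "string"),
            ("score", "integer"),
            ("signalValue", "float"),
            ("pValue", "float"),
            ("qValue", "float"),
        )
    ),
}

_DIALECT_COLUMNS = {"narrowPeak": 10, "broadPeak": 9}


def import_bed(
    paths: Sequence[Union[str, Path]],
    dialect: str = "bed",
    meta_sidecar: bool = True,
) -> GDMDataset:
    """Import BED3/6 or ENCODE narrowPeak/broadPeak files, one sample each.

    The BED ``.`` strand maps to ``*``; a BED3 line gets strand ``*`` and
    missing attribute values.  When ``meta_sidecar`` is true, a ``<file>.meta``
    sidecar (``key<TAB>value`` lines) next to each input becomes that sample's
    metadata.
    """
    if dialect not in BED_DIALECTS:
        raise GDMError(f"unknown BED dialect {dialect!r}")
    schema = BED_DIALECTS[dialect]
    samples = []
    seen_ids = set()
    for path in paths:
        path = Path(path)
        sample_id = path.stem
        if sample_id in seen_ids:
            sample_id = f"{sample_id}_{len(seen_ids)}"
        seen_ids.add(sample_id)
        regions = []
        with path.open("r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                regions.append(_parse_bed_line(line, dialect, path, lineno))
        metadata = MetadataSet()
        sidecar = path.with_name(path.name + ".meta")
        if meta_sidecar and sidecar.is_file():
            metadata = _read_meta_file(sidecar)
        samples.append(Sample(sample_id, regions, metadata))
    return GDMDataset(schema, samples, name=dialect)


def _parse_bed_line(line: str, dialect: str, path: Path, lineno: int) -> Region:
    fields = line.split("\t") if "\t" in line else line.split()
    expected = _DIALECT_COLUMNS.get(dialect)
    if expected is not None and len(fields) != expected:
        raise FormatError(
            f"{path}:{lineno}: {dialect} requires {expected} columns, got {len(fields)}"
        )
    if dialect == "bed" and not 3 <= len(fields) <= 6:
        raise FormatError(f"{path}:{lineno}: BED requires 3-6 columns, got {len(fields)}")
    try:
        chrom, left, right = fields[0], int(fields[1]), int(fields[2])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:{lineno}: bad coordinates") from exc

    def get(i: int) -> Optional[str]:
        return fields[i] if i < len(fields) else None

    strand = get(5) or "."
    strand = "*" if strand == "." else strand
    if strand not in ("+", "-", "*"):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")

    def typed(i: int, dtype: str):
        raw = get(i)
        if raw is None or raw == ".":
            return None
        try:
            return parse_value(raw, dtype)
        except GDMError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc

    if dialect == "bed":
        values = (typed(3, "string"), typed(4, "float"))
    elif dialect == "narrowPeak":
        values = (
            typed(3, "string"),
            typed(4, "integer"),
            typed(6, "float"),
            typed(7, "float"),
            typed(8, "float"),
            typed(9, "integer"),
        )
    else:  # broadPeak
        values = (
            typed(3, "string"),
            typed(4, "integer"),
            typed(6, "float"),
            typed(7, "float"),
            typed(8, "float"),
        )
    return Region(chrom, left, right, strand, values)


# ---------------------------------------------------------------------------
# flat tables


def metadata_table(dataset: GDMDataset) -> pd.DataFrame:
    """One row per (sample, key, value) metadata triple."""
    rows = [
        (sample.id, key, value)
        for sample in dataset.samples
        for key, value in sample.metadata.pairs()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "key", "value"])


def filter_and_extract(
    dataset: GDMDataset,
    meta_predicate: Optional[Predicate] = None,
    region_attrs: Iterable[str] = (),
    label_key: Optional[str] = None,
) -> pd.DataFrame:
    """Flatten the regions of metadata-selected samples into one table.

    Columns are ``sample_label, chrom, left, right, strand`` followed by the
    requested region attributes in the given order.  ``sample_label`` is the
    sample's value of ``label_key`` when given (ambiguous multi-valued keys
    raise :class:`GDMError`), otherwise the sample id.
    """
    region_attrs = list(region_attrs)
    indices = [dataset.schema.index(a) for a in region_attrs]
    rows = []
    for sample in dataset.samples:
        if meta_predicate is not None and not evaluate_meta_predicate(
            meta_predicate, sample.metadata
        ):
            continue
        if label_key is None:
            label = sample.id
        else:
            values = sample.metadata.values(label_key)
            if len(values) > 1:
                raise GDMError(
                    f"label key {label_key!r} has {len(values)} values in sample "
                    f"{sample.id!r}"
                )
            label = values[0] if values else sample.id
        for region in sample.regions:
            rows.append(
                (label, region.chrom, region.left, region.right, region.strand)
                + tuple(region.values[i] for i in indices)
            )
    columns = ["sample_label", "chrom", "left", "right", "strand"] + region_attrs
    return pd.DataFrame(rows, columns=columns)
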