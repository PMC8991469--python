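"""Core containers of the Genomic Data Model (GDM).

The GDM organizes genomic data as *datasets of samples*: every sample pairs an
ordered collection of genomic regions with a free-form set of key/value
metadata describing the experiment or patient the sample came from.  Regions
carry four fixed coordinate attributes (``chr``, ``left``, ``right``,
``strand``) plus further typed attributes declared by the dataset schema;
metadata are schemaless string pairs in which one key may hold several values.

Coordinates are 0-based, half-open ``[left, right)`` — the BED convention.
The strand alphabet is ``{+, -, *}``, where ``*`` means "either strand".
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "GDMError",
    "SchemaError",
    "FormatError",
    "ValidationError",
    "EvaluationError",
    "ArgumentError",
    "Schema",
    "Region",
    "MetadataSet",
    "Sample",
    "GDMDataset",
    "AggregateSpec",
    "apply_aggregate",
    "parse_value",
    "format_value",
    "MISSING",
    "DTYPES",
    "RESERVED_NAMES",
    "STRANDS",
]

MISSING = "."
DTYPES = ("string", "integer", "float", "boolean")
RESERVED_NAMES = ("chr", "left", "right", "strand")
STRANDS = ("+", "-", "*")

Value = Union[str, int, float, bool, None]


class GDMError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(GDMError):
    """An attribute reference or declaration violates the dataset schema."""


class FormatError(GDMError):
    """A file on disk does not conform to the expected layout or dialect."""


class ValidationError(GDMError):
    """In-memory data violate a GDM invariant (e.g. right <= left)."""


class EvaluationError(GDMError):
    """A predicate or expression cannot be evaluated on the given data."""


class ArgumentError(GDMError):
    """An operator received an invalid parameter."""


# ---------------------------------------------------------------------------
# value (de)serialization


def parse_value(text: str, dtype: str) -> Value:
    """Parse one on-disk token into a typed value; ``"."`` means missing."""
    if text == MISSING:
        return None
    if dtype == "string":
        return text
    if dtype == "integer":
        try:
            return int(text)
        except ValueError as exc:
            raise FormatError(f"cannot parse {text!r} as integer") from exc
    if dtype == "float":
        try:
            return float(text)
        except ValueError as exc:
            raise FormatError(f"cannot parse {text!r} as float") from exc
    if dtype == "boolean":
        lowered = text.lower()
        if lowered in ("true", "1"):
            return True
        if lowered in ("false", "0"):
            return False
        raise FormatError(f"cannot parse {text!r} as boolean")
    raise SchemaError(f"unknown dtype {dtype!r}")


def format_value(value: Value) -> str:
    """Serialize one typed value to its on-disk token."""
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "true" if value else "false"
    # str(float) is the shortest round-tripping representation in Python 3.
    return str(value)


# ---------------------------------------------------------------------------
# schema


@dataclass(frozen=True)
class Schema:
    """Ordered declaration of the non-coordinate region attributes.

    Coordinate attributes are implicit and fixed; only the additional typed
    attributes are declared, as ``(name, dtype)`` pairs with dtype in
    ``{string, integer, float, boolean}``.  Order is significant and preserved
    through read/write round trips.
    """

    attributes: tuple = ()
    coordinate_system: str = "0-based half-open"

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(tuple(a) for a in self.attributes))
        seen = set()
        for name, dtype in self.attributes:
            if not name:
                raise SchemaError("attribute names must be non-empty")
            if name in RESERVED_NAMES:
                raise SchemaError(f"attribute name {name!r} is reserved")
            if name in seen:
                raise SchemaError(f"duplicate attribute name {name!r}")
            if dtype not in DTYPES:
                raise SchemaError(f"unknown dtype {dtype!r} for attribute {name!r}")
            seen.add(name)

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as exc:
            raise SchemaError(f"attribute {name!r} not in schema") from exc

    def dtype(self, name: str) -> str:
        return self.attributes[self.index(name)][1]


# ---------------------------------------------------------------------------
# region


@dataclass
class Region:
    """One genomic interval plus its schema-aligned attribute values.

    ``values`` is positionally aligned to ``Schema.attributes``; ``None``
    encodes a missing value.
    """

    chrom: str
    left: int
    right: int
    strand: str = "*"
    values: tuple = ()

    def __post_init__(self) -> None:
        self.values = tuple(self.values)
        if self.left < 0:
            raise ValidationError(f"negative left coordinate {self.left}")
        if self.right <= self.left:
            raise ValidationError(
                f"empty or inverted region [{self.left}, {self.right}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.right - self.left

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.left, self.right, self.strand, self.values)

    def value(self, name: str, schema: Schema) -> Value:
        return self.values[schema.index(name)]

    def validate(self, schema: Schema) -> None:
        if len(self.values) != len(schema):
            raise ValidationError(
                f"region on {self.chrom} carries {len(self.values)} values, "
                f"schema declares {len(schema)}"
            )


# ---------------------------------------------------------------------------
# metadata


class MetadataSet:
    """Free attribute-value pairs of one sample.

    A key may appear several times with distinct values; exact duplicate
    ``(key, value)`` pairs are collapsed.  Keys and values are stored verbatim
    (no case folding), always as strings.
    """

    __slots__ = ("_pairs",)

    def __init__(self, pairs: Iterable = ()) -> None:
        self._pairs = {(str(k), str(v)) for k, v in pairs}

    def add(self, key: str, value: str) -> None:
        self._pairs.add((str(key), str(value)))

    def discard_key(self, key: str) -> None:
        self._pairs = {(k, v) for k, v in self._pairs if k != key}

    def values(self, key: str) -> list:
        return sorted(v for k, v in self._pairs if k == key)

    def keys(self) -> list:
        return sorted({k for k, _ in self._pairs})

    def pairs(self) -> list:
        return sorted(self._pairs)

    def copy(self) -> "MetadataSet":
        return MetadataSet(self._pairs)

    def union(self, *others: "MetadataSet") -> "MetadataSet":
        merged = set(self._pairs)
        for other in others:
            merged |= other._pairs
        return MetadataSet(merged)

    def prefixed(self, prefix: str) -> "MetadataSet":
        return MetadataSet((prefix + k, v) for k, v in self._pairs)

    def __contains__(self, key: str) -> bool:
        return any(k == key for k, _ in self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator:
        return iter(self.pairs())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetadataSet):
            return NotImplemented
        return self._pairs == other._pairs

    def __repr__(self) -> str:
        return f"MetadataSet({self.pairs()!r})"


# ---------------------------------------------------------------------------
# sample / dataset


@dataclass
class Sample:
    """An identified collection of regions plus its metadata."""

    id: str
    regions: list = field(default_factory=list)
    metadata: MetadataSet = field(default_factory=MetadataSet)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sample id must be non-empty")
        self.sort_regions()

    def sort_regions(self) -> None:
        self.regions.sort(key=lambda r: r.sort_key)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sample):
            return NotImplemented
        return (
            self.id == other.id
            and self.regions == other.regions
            and self.metadata == other.metadata
        )


@dataclass
class GDMDataset:
    """A schema plus a list of samples: the unit every operator consumes."""

    schema: Schema = field(default_factory=Schema)
    samples: list = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids {dup}")
        for sample in self.samples:
            for region in sample.regions:
                region.validate(self.schema)

    @property
    def n_regions(self) -> int:
        return sum(s.n_regions for s in self.samples)

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        """Structural equality: schema, samples, regions and metadata.

        The dataset ``name`` is a label, not content, and is ignored.
        """
        if not isinstance(other, GDMDataset):
            return NotImplemented
        return self.schema == other.schema and self.samples == other.samples


# ---------------------------------------------------------------------------
# aggregates


AGGREGATE_FUNCTIONS = ("COUNT", "SUM", "AVG", "MIN", "MAX", "MEDIAN", "STD", "BAG")


@dataclass(frozen=True)
class AggregateSpec:
    """One aggregation over the regions of a sample.

    ``COUNT`` takes no input attribute; ``BAG`` concatenates the sorted
    distinct string forms of the values, joined by ``;``; every other function
    requires a numeric input attribute.  Over an empty region set COUNT yields
    0 and every other function yields a missing value.
    """

    fn: str
    output_name: str
    input_attr: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fn not in AGGREGATE_FUNCTIONS:
            raise ArgumentError(f"unknown aggregate function {self.fn!r}")
        if self.fn == "COUNT":
            if self.input_attr is not None:
                raise ArgumentError("COUNT takes no input attribute")
        elif self.input_attr is None:
            raise ArgumentError(f"{self.fn} requires an input attribute")
        if not self.output_name:
            raise ArgumentError("aggregate output name must be non-empty")


def apply_aggregate(spec: AggregateSpec, regions: Sequence[Region], schema: Schema) -> Value:
    """Compute one aggregate over a region list; missing values are skipped.

    Returns ``None`` (missing) when no non-missing input value exists, except
    for COUNT which always returns the region count.  The sample standard
    deviation (n-1 divisor) is used for STD and is missing for fewer than two
    values; the median of an even count is the mean of the two central values.
    """
    if spec.fn == "COUNT":
        return len(regions)
    idx = schema.index(spec.input_attr)
    values = [r.values[idx] for r in regions if r.values[idx] is not None]
    if spec.fn == "BAG":
        if not values:
            return None
        return ";".join(sorted({format_value(v) for v in values}))
    if schema.dtype(spec.input_attr) == "string":
        raise EvaluationError(
            f"numeric aggregate {spec.fn} on string attribute {spec.input_attr!r}"
        )
    if not values:
        return None
    numbers = [float(v) for v in values]
    if spec.fn == "SUM":
        total = sum(values)
        return total
    if spec.fn == "AVG":
        return statistics.fmean(numbers)
    if spec.fn == "MIN":
        return min(values)
    if spec.fn == "MAX":
        return max(values)
    if spec.fn == "MEDIAN":
        return float(statistics.median(numbers))
    if spec.fn == "STD":
        if len(numbers) < 2:
            return None
        return statistics.stdev(numbers)
    raise ArgumentError(f"unknown aggregate function {spec.fn!r}")  # pragma: no cover
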