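"""Lesion-anchored mutation catalogs: data model, coordinates and TSV I/O.

The canonical coordinate throughout the package is the *signed distance* ``d``
from the lesion site, in nucleotides, oriented along the direction of
translesion synthesis (TLS): ``d > 0`` is downstream (synthesized after the
bypass), ``d < 0`` is upstream, and ``d = 0`` is reserved for the lesion site
itself.  External coordinate systems (gene ORF positions, chromosomal
positions, insert-relative positions) are derived views obtained through
invertible piecewise-affine maps attached to each assay geometry.

Windows over signed distance are half-open ``(lo, hi]``, so ``d = +1`` is the
first nucleotide of the downstream window ``(0, L]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

__all__ = [
    "AffineBranch",
    "CoordMap",
    "ExternalPosition",
    "AssayGeometry",
    "MutationRecord",
    "TLSEvent",
    "Catalog",
    "CatalogParseError",
    "signed_distance_to_ura3",
    "signed_distance_to_chrom",
    "load_catalog",
    "write_catalog",
    "count_in_window",
]


class CatalogParseError(ValueError):
    """Malformed catalog file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ExternalPosition(NamedTuple):
    """A position in an external coordinate system, e.g. ``229i`` (LEU2 insert)."""

    value: int
    system: str
    suffix: str = ""

    def __str__(self) -> str:  # "116946" or "229i"
        return f"{self.value}{self.suffix}"


@dataclass(frozen=True)
class AffineBranch:
    """One affine piece of a coordinate map: ``pos = slope * d + offset``.

    Valid on the closed signed-distance interval [d_min, d_max]; slope is
    +1 or -1 so every branch is trivially invertible.
    """

    d_min: int
    d_max: int
    slope: int
    offset: int
    system: str
    suffix: str = ""

    def __post_init__(self):
        if self.slope not in (-1, 1):
            raise ValueError("branch slope must be +1 or -1")
        if self.d_min > self.d_max:
            raise ValueError("empty branch domain")

    def contains(self, d: int) -> bool:
        return self.d_min <= d <= self.d_max

    def forward(self, d: int) -> ExternalPosition:
        return ExternalPosition(self.slope * d + self.offset, self.system, self.suffix)

    def inverse(self, pos: ExternalPosition) -> int:
        return self.slope * (pos.value - self.offset)


@dataclass(frozen=True)
class CoordMap:
    """Invertible piecewise-affine map from signed distance to an external system."""

    name: str
    branches: tuple[AffineBranch, ...]

    def __post_init__(self):
        # branches must not overlap in d, or the map would be ambiguous
        spans = sorted((b.d_min, b.d_max) for b in self.branches)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi:
                raise ValueError(f"coord map {self.name!r}: overlapping branches")

    def to_external(self, d: int) -> ExternalPosition:
        for b in self.branches:
            if b.contains(d):
                return b.forward(d)
        raise ValueError(f"d={d} outside the domain of coord map {self.name!r}")

    def to_distance(self, pos: ExternalPosition | str) -> int:
        if isinstance(pos, str):
            pos = self.parse(pos)
        for b in self.branches:
            if b.system == pos.system and b.suffix == pos.suffix:
                d = b.inverse(pos)
                if b.contains(d):
                    return d
        raise ValueError(f"{pos} not reachable in coord map {self.name!r}")

    def parse(self, text: str) -> ExternalPosition:
        """Parse a printed position such as ``"116946"`` or ``"229i"``."""
        text = text.strip()
        for b in self.branches:
            if b.suffix and text.endswith(b.suffix):
                return ExternalPosition(int(text[: -len(b.suffix)]), b.system, b.suffix)
        for b in self.branches:
            if not b.suffix:
                return ExternalPosition(int(text), b.system, "")
        raise ValueError(f"cannot parse position {text!r} for map {self.name!r}")


@dataclass(frozen=True)
class AssayGeometry:
    """Lesion site, TLS direction, sequenced extents and exclusions for one assay.

    ``upstream_extent``/``downstream_extent`` are the lengths (nt) of the
    sequenced regions before/after the lesion along the direction of TLS.
    ``excluded_intervals`` are closed signed-distance intervals removed from
    the analysis (e.g. the footprint of the oligonucleotide used to build a
    lesion-bearing plasmid, where errors could predate replication).
    """

    assay_id: str
    lesion_label: str
    upstream_extent: int
    downstream_extent: int
    excluded_intervals: tuple[tuple[int, int], ...] = ()
    coord_maps: Mapping[str, CoordMap] = field(default_factory=dict)

    def __post_init__(self):
        if self.upstream_extent < 0 or self.downstream_extent <= 0:
            raise ValueError("extents must be nonnegative (downstream positive)")
        for lo, hi in self.excluded_intervals:
            if lo > hi:
                raise ValueError(f"empty excluded interval ({lo}, {hi})")
            if lo < -self.upstream_extent or hi > self.downstream_extent:
                raise ValueError(
                    f"excluded interval [{lo}, {hi}] outside sequenced extents "
                    f"[-{self.upstream_extent}, +{self.downstream_extent}]"
                )

    def contains(self, d: int) -> bool:
        return -self.upstream_extent <= d <= self.downstream_extent

    def is_excluded(self, d: int) -> bool:
        return any(lo <= d <= hi for lo, hi in self.excluded_intervals)

    def check_window(self, window: tuple[int, int]) -> None:
        lo, hi = window
        if lo >= hi:
            raise ValueError(f"empty window ({lo}, {hi}]")
        if lo < -self.upstream_extent - 1 or hi > self.downstream_extent:
            raise ValueError(
                f"window ({lo}, {hi}] outside sequenced extents "
                f"[-{self.upstream_extent}, +{self.downstream_extent}]"
            )


@dataclass(frozen=True)
class MutationRecord:
    """One observed mutation, positioned by signed distance from the lesion.

    ``change`` is the printed descriptor, e.g. ``"A → C"``, ``"G del"``,
    ``"C ins"``, ``"TC → AA"``.  ``strand_convention`` names the strand the
    change is reported on (assay tables conventionally report the strand
    complementary to the lesion-containing strand).
    """

    product_id: str
    d: int
    change: str
    strand_convention: str = "complementary"
    note: str = ""

    def __post_init__(self):
        if self.d == 0:
            raise ValueError(
                "d=0 is reserved for the lesion site; lesion-site outcomes "
                "belong on TLSEvent, not MutationRecord"
            )


@dataclass(frozen=True)
class TLSEvent:
    """The lesion-site outcome of one TLS product.

    For an abasic-site (THF) bypass assay the outcome is the base inserted
    opposite the lesion (``"A"``/``"C"``/``"T"``/``"G"``); for a reversion
    assay it is a codon-change descriptor such as ``"GAC→AAC"``.
    """

    product_id: str
    outcome: str
    note: str = ""


@dataclass
class Catalog:
    """A set of TLS products: lesion-site events plus flanking mutations.

    ``n_products`` is the number of products sequenced — the denominator for
    every rate computed from this catalog.  It may exceed the number of
    listed events (controls often list none).
    """

    geometry: AssayGeometry
    n_products: int
    events: list[TLSEvent] = field(default_factory=list)
    mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.n_products < 0:
            raise ValueError("n_products must be nonnegative")
        ids = {e.product_id for e in self.events} | {m.product_id for m in self.mutations}
        if self.n_products < len(ids):
            raise ValueError(
                f"n_products={self.n_products} < {len(ids)} distinct product ids"
            )
        for m in self.mutations:
            if not self.geometry.contains(m.d):
                raise ValueError(
                    f"mutation {m.product_id} at d={m.d} outside sequenced extents "
                    f"of assay {self.geometry.assay_id!r}"
                )

    # -- convenience views -------------------------------------------------

    @property
    def assay_id(self) -> str:
        return self.geometry.assay_id

    def downstream(self) -> list[MutationRecord]:
        return [m for m in self.mutations if m.d > 0]

    def upstream(self) -> list[MutationRecord]:
        return [m for m in self.mutations if m.d < 0]

    def count_in_window(self, window: tuple[int, int], respect_exclusions: bool = True) -> int:
        return count_in_window(self, window, respect_exclusions)

    def products_in_window(self, window: tuple[int, int], respect_exclusions: bool = True) -> set[str]:
        """Distinct product ids with at least one mutation in the window."""
        self.geometry.check_window(window)
        lo, hi = window
        out = set()
        for m in self.mutations:
            if lo < m.d <= hi and not (respect_exclusions and self.geometry.is_excluded(m.d)):
                out.add(m.product_id)
        return out


def count_in_window(catalog: Catalog, window: tuple[int, int], respect_exclusions: bool = True) -> int:
    """Count mutation events with signed distance in half-open ``(lo, hi]``.

    Each record counts once — a tandem or complex change is a single event.
    With ``respect_exclusions`` records inside the geometry's excluded
    intervals are never counted.
    """
    catalog.geometry.check_window(window)
    lo, hi = window
    n = 0
    for m in catalog.mutations:
        if lo < m.d <= hi and not (respect_exclusions and catalog.geometry.is_excluded(m.d)):
            n += 1
    return n


# -- assay-specific coordinate helpers ------------------------------------


def signed_distance_to_ura3(d: int, geometry: AssayGeometry) -> int:
    """Map signed distance to a URA3-ORF position (``pos = 605 - d``).

    The lesion sits at ORF position 605 and TLS proceeds toward the 5' end
    of the ORF coordinate, so the map is monotone decreasing in ``d``.
    """
    return geometry.coord_maps["URA3-ORF"].to_external(d).value


def signed_distance_to_chrom(d: int, geometry: AssayGeometry) -> ExternalPosition:
    """Map signed distance to a chromosome-V or LEU2-insert position.

    The lesion dinucleotide occupies chromosomal positions 116929–116930, so
    d=0 has no single external coordinate and is rejected.  Downstream
    positions switch to insert-relative ``i`` numbering once inside the
    inserted LEU2 fragment.
    """
    if d == 0:
        raise ValueError("d=0: the lesion site spans two chromosomal positions")
    return geometry.coord_maps["chromosome-V"].to_external(d)


# -- TSV I/O ----------------------------------------------------------------

_COLUMNS = ("assay_id", "product_id", "record_type", "d", "change", "note")


def load_catalog(path: str | Path, registry: Mapping[str, AssayGeometry] | None = None) -> Catalog:
    """Load a catalog TSV and validate it against its assay geometry.

    Format: '#' comment lines (a ``# n_products: N`` directive is required),
    then a header row ``assay_id product_id record_type d change note`` and
    one row per event/mutation.  The geometry is resolved from the file's
    assay_id through ``registry`` (defaults to the packaged registry).
    """
    if registry is None:
        from .datasets import geometry_registry

        registry = geometry_registry()
    path = Path(path)
    n_products: int | None = None
    header: list[str] | None = None
    events: list[TLSEvent] = []
    mutations: list[MutationRecord] = []
    assay_id: str | None = None
    strand = "complementary"

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("n_products:"):
                    n_products = int(body.split(":", 1)[1])
                elif body.lower().startswith("strand_convention:"):
                    strand = body.split(":", 1)[1].strip()
                elif body.lower().startswith("assay_id:"):
                    assay_id = body.split(":", 1)[1].strip()
                    if assay_id not in registry:
                        raise CatalogParseError(f"unknown assay_id {assay_id!r}", lineno)
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if tuple(header) != _COLUMNS:
                    raise CatalogParseError(
                        f"expected header {_COLUMNS}, got {tuple(header)}", lineno
                    )
                continue
            if len(fields) != len(_COLUMNS):
                raise CatalogParseError(
                    f"expected {len(_COLUMNS)} fields, got {len(fields)}", lineno
                )
            row = dict(zip(_COLUMNS, (f.strip() for f in fields)))
            if assay_id is None:
                assay_id = row["assay_id"]
                if assay_id not in registry:
                    raise CatalogParseError(f"unknown assay_id {assay_id!r}", lineno)
            elif row["assay_id"] != assay_id:
                raise CatalogParseError(
                    f"mixed assay_ids {assay_id!r} and {row['assay_id']!r}", lineno
                )
            if row["record_type"] == "event":
                events.append(TLSEvent(row["product_id"], row["change"], row["note"]))
            elif row["record_type"] == "mutation":
                try:
                    d = int(row["d"])
                except ValueError:
                    raise CatalogParseError(f"non-integer distance {row['d']!r}", lineno) from None
                mutations.append(
                    MutationRecord(row["product_id"], d, row["change"], strand, row["note"])
                )
            else:
                raise CatalogParseError(
                    f"record_type must be 'event' or 'mutation', got {row['record_type']!r}",
                    lineno,
                )

    if n_products is None:
        raise CatalogParseError(f"{path}: missing '# n_products:' directive")
    if assay_id is None:
        raise CatalogParseError(f"{path}: no data rows and no assay_id")
    return Catalog(registry[assay_id], n_products, events, mutations)


def catalog_to_tsv(catalog: Catalog) -> str:
    """Serialize a catalog to the canonical TSV text (byte-stable)."""
    buf = io.StringIO()
    buf.write("# tlstracts catalog\n")
    buf.write(f"# assay_id: {catalog.assay_id}\n")
    buf.write(f"# n_products: {catalog.n_products}\n")
    strands = {m.strand_convention for m in catalog.mutations}
    if len(strands) == 1:
        buf.write(f"# strand_convention: {strands.pop()}\n")
    buf.write("\t".join(_COLUMNS) + "\n")
    aid = catalog.assay_id
    for e in catalog.events:
        buf.write(f"{aid}\t{e.product_id}\tevent\t\t{e.outcome}\t{e.note}\n")
    for m in catalog.mutations:
        buf.write(f"{aid}\t{m.product_id}\tmutation\t{m.d}\t{m.change}\t{m.note}\n")
    return buf.getvalue()


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    Path(path).write_text(catalog_to_tsv(catalog), encoding="utf-8")
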