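"""Classification of lesion-site outcomes and flanking-mutation types.

Two assay designs are supported.  In the abasic-site (THF) bypass assay the
lesion replaces a template C, so an A, C or T inserted opposite it changes
the sequence and marks a TLS product, while a G restores the wild type and
cannot be told apart from lesion-free copying.  In the UV reversion assay a
TC dipyrimidine at codon positions 763-764 is the presumed lesion site;
reversion requires a substitution at one of those two positions, and a
co-mutation at the adjacent position 765 (the next templated G) is recorded
but set aside when flanking mutation rates are computed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum

from .catalog import Catalog, MutationRecord

__all__ = [
    "TLSClass",
    "MutationType",
    "MutationTypeTally",
    "classify_thf_outcome",
    "classify_uv_reversion",
    "parse_change",
    "mutation_type",
    "to_reported_strand",
    "spectrum_tally",
]


class TLSClass(Enum):
    # THF assay outcomes
    TLS_A = "TLS_A"
    TLS_C = "TLS_C"
    TLS_T = "TLS_T"
    INDISTINGUISHABLE = "INDISTINGUISHABLE"
    # UV reversion outcomes
    TARGETED = "TARGETED"
    TARGETED_PLUS_ADJACENT = "TARGETED_PLUS_ADJACENT"
    INVALID = "INVALID"


class MutationType(Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"
    COMPLEX = "tandem/complex"


_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PURINES = frozenset("AG")


def classify_thf_outcome(base: str) -> TLSClass:
    """Classify the base inserted opposite the abasic-site analog.

    A, C and T insertions change the sequence and are scored as TLS; a G
    restores the wild-type sequence and is indistinguishable from bypass
    mechanisms that never touched the lesion.
    """
    if base not in _BASES:
        raise ValueError(f"not a DNA base: {base!r}")
    return {
        "A": TLSClass.TLS_A,
        "C": TLSClass.TLS_C,
        "T": TLSClass.TLS_T,
        "G": TLSClass.INDISTINGUISHABLE,
    }[base]


def classify_uv_reversion(codon_change: str) -> TLSClass:
    """Classify a codon 763-765 change descriptor such as ``"GAC→AAC"``.

    Changes confined to positions 763-764 (the lesion dipyrimidine, read on
    the coding strand) are TARGETED; any additional change at 765 makes the
    product TARGETED_PLUS_ADJACENT; a descriptor with no change at 763-764
    is not a reversion-by-TLS product at all (INVALID).
    """
    ref, alt = _split_arrow(codon_change)
    if ref != "GAC":
        raise ValueError(f"reference codon must be GAC, got {ref!r}")
    if len(alt) != 3 or not _BASES.issuperset(alt):
        raise ValueError(f"malformed codon change {codon_change!r}")
    changed = {i for i in range(3) if ref[i] != alt[i]}
    if not changed & {0, 1}:
        return TLSClass.INVALID
    if 2 in changed:
        return TLSClass.TARGETED_PLUS_ADJACENT
    return TLSClass.TARGETED


def _split_arrow(text: str) -> tuple[str, str]:
    t = text.replace("->", "→")
    if "→" not in t:
        raise ValueError(f"no '→' in change descriptor {text!r}")
    ref, alt = (part.strip() for part in t.split("→", 1))
    return ref, alt


def parse_change(change: str) -> tuple[str, str, str]:
    """Parse a change descriptor into ``(kind, ref, alt)``.

    kind is one of 'sub' (``"A → C"``, ``"TC → AA"``), 'ins' (``"C ins"``)
    or 'del' (``"GAT del"``); for indels alt is empty and ref holds the
    inserted/deleted bases.
    """
    text = change.strip()
    lowered = text.lower()
    for kind in ("ins", "del"):
        if lowered.endswith(" " + kind):
            bases = text[: -len(kind)].strip().upper()
            if not bases or not _BASES.issuperset(bases):
                raise ValueError(f"malformed {kind} descriptor {change!r}")
            return kind, bases, ""
    ref, alt = _split_arrow(text)
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt or not _BASES.issuperset(ref) or not _BASES.issuperset(alt):
        raise ValueError(f"malformed substitution descriptor {change!r}")
    if len(ref) != len(alt):
        raise ValueError(f"substitution with unequal lengths {change!r}")
    return "sub", ref, alt


def mutation_type(record: MutationRecord | str) -> MutationType:
    """Assign one mutation-type class to a record; one record = one event."""
    change = record.change if isinstance(record, MutationRecord) else record
    kind, ref, alt = parse_change(change)
    if kind == "ins":
        return MutationType.INSERTION
    if kind == "del":
        return MutationType.DELETION
    if len(ref) > 1:
        return MutationType.COMPLEX
    if (ref in _PURINES) == (alt in _PURINES):
        return MutationType.TRANSITION
    return MutationType.TRANSVERSION


def _complement_change(change: str) -> str:
    kind, ref, alt = parse_change(change)
    assert kind == "sub"
    ref_c = ref.translate(_COMPLEMENT)[::-1]
    alt_c = alt.translate(_COMPLEMENT)[::-1]
    return f"{ref_c} → {alt_c}"


def to_reported_strand(record: MutationRecord, target_strand: str) -> MutationRecord:
    """Re-express a substitution on the requested strand.

    A ``G → A`` reported on one strand is a ``C → T`` on the other;
    applying the conversion twice is the identity.  Indels have no
    strand-specific base identity here and pass through unchanged (with a
    warning so the caller knows the label did not flip).
    """
    if record.strand_convention == target_strand:
        return record
    kind, _, _ = parse_change(record.change)
    if kind != "sub":
        warnings.warn(
            f"indel record {record.change!r} passed through unchanged "
            f"(no strand normalization for indels)",
            stacklevel=2,
        )
        return record
    return replace(
        record,
        change=_complement_change(record.change),
        strand_convention=target_strand,
    )


@dataclass
class MutationTypeTally:
    """Counts of mutation records by type class and by base change.

    ``by_change`` keys substitutions by their descriptor on the tally's
    strand convention; indels are keyed by length class (``"-1 del"``,
    ``"+1 ins"``, ``"-3 del"`` ...).
    """

    strand: str
    counts: Counter = field(default_factory=Counter)
    by_change: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, key: MutationType) -> int:
        return self.counts[key]


def spectrum_tally(
    catalog: Catalog,
    window: tuple[int, int] | None = None,
    strand: str | None = None,
    respect_exclusions: bool = True,
) -> MutationTypeTally:
    """Tally mutation types (and base changes) in a window, on one strand.

    ``window=None`` covers the full sequenced extents.  Substitutions are
    complemented onto ``strand`` when it differs from the record's own
    convention; the tally is invariant under record order.
    """
    geom = catalog.geometry
    if window is None:
        window = (-geom.upstream_extent - 1, geom.downstream_extent)
    else:
        geom.check_window(window)
    lo, hi = window
    tally = MutationTypeTally(strand=strand or "as-reported")
    for m in catalog.mutations:
        if not (lo < m.d <= hi):
            continue
        if respect_exclusions and geom.is_excluded(m.d):
            continue
        mtype = mutation_type(m)
        tally.counts[mtype] += 1
        kind, ref, alt = parse_change(m.change)
        if kind == "sub":
            rec = m if strand is None else to_reported_strand(m, strand)
            _, r, a = parse_change(rec.change)
            tally.by_change[f"{r} → {a}"] += 1
        elif kind == "ins":
            tally.by_change[f"+{len(ref)} ins"] += 1
        else:
            tally.by_change[f"-{len(ref)} del"] += 1
    return tally
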