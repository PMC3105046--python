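"""In-silico assembly of luciferase reporter promoter constructs.

A construct is a promoter insert (the vector backbone is not modelled)
defined by a parent sequence plus an ordered list of edits in *parent*
coordinates: element deletions, length-conserving replacements, and 3-bp
site-directed substitutions (e.g. mutating the GAG core of a Zeste site to
AGA).  Edits must not overlap; the construct sequence is always obtained by
replaying the edit list on the parent, so the edit manifest is a complete,
verifiable provenance record.

The wild-type amplicon convention follows reporter-cloning practice for
heat-shock promoters: the insert starts 65 bp upstream of the most distal
heat-shock element (HSE4) and ends 135 bp downstream of the transcription
start site, thereby covering the promoter, the 5'UTR, and the first 55 bp
of coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .promoter_align import ATRichElement
from .seqio import Interval, SequenceRecord

__all__ = [
    "Edit",
    "ReporterConstruct",
    "ValidationReport",
    "DEFAULT_ENZYMES",
    "build_wt_amplicon",
    "apply_deletion",
    "apply_replacement",
    "apply_site_mutation",
    "replay_edits",
    "validate_construct",
]

#: Recognition sites of the cloning enzymes used for reporter assembly.
DEFAULT_ENZYMES: dict[str, str] = {
    "KpnI": "GGTACC",
    "BglII": "AGATCT",
    "PacI": "TTAATTAA",
}


@dataclass(frozen=True)
class Edit:
    """One edit in parent coordinates (0-based half-open)."""

    kind: str  # delete | replace | substitute
    start: int
    end: int
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "replace", "substitute"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid edit interval")
        if self.kind in ("replace", "substitute") and len(self.payload) != (
            self.end - self.start
        ):
            raise ValueError(f"{self.kind} edits must conserve length")


def replay_edits(parent_sequence: str, edits: Sequence[Edit]) -> str:
    """Apply non-overlapping edits (parent coordinates) left to right."""
    ordered = sorted(edits, key=lambda e: e.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping edits [{prev.start},{prev.end}) and "
                f"[{nxt.start},{nxt.end})"
            )
    if ordered and ordered[-1].end > len(parent_sequence):
        raise ValueError("edit extends past parent sequence")
    pieces: list[str] = []
    cursor = 0
    for e in ordered:
        pieces.append(parent_sequence[cursor : e.start])
        if e.kind != "delete":
            pieces.append(e.payload)
        cursor = e.end
    pieces.append(parent_sequence[cursor:])
    return "".join(pieces)


@dataclass(frozen=True)
class ReporterConstruct:
    """An edited promoter insert with full edit provenance."""

    name: str
    sequence: str
    parent: str
    parent_sequence: str
    edits: tuple[Edit, ...] = ()
    origin: int = 0  # start of the parent amplicon in its source sequence

    def __post_init__(self) -> None:
        if replay_edits(self.parent_sequence, self.edits) != self.sequence:
            raise ValueError(
                f"construct {self.name!r}: edits do not replay to sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_local(self, interval: Interval) -> Interval:
        """Map an interval from source-sequence to parent-amplicon coordinates."""
        start = interval.start - self.origin
        end = interval.end - self.origin
        if start < 0 or end > len(self.parent_sequence):
            raise ValueError(
                f"interval [{interval.start},{interval.end}) outside amplicon"
            )
        return Interval(self.parent, start, end, interval.strand)

    def manifest(self) -> dict:
        """JSON-ready edit manifest."""
        return {
            "name": self.name,
            "parent": self.parent,
            "length": len(self.sequence),
            "edits": [
                {
                    "kind": e.kind,
                    "start": e.start,
                    "end": e.end,
                    "payload": e.payload,
                }
                for e in self.edits
            ],
        }


def build_wt_amplicon(
    genomic: SequenceRecord,
    hse4_start: int,
    tss: int,
    name: str = "WT",
    upstream_of_hse4: int = 65,
    downstream_of_tss: int = 135,
) -> ReporterConstruct:
    """Wild-type reporter amplicon: [HSE4 start - 65, TSS + 135)."""
    start = hse4_start - upstream_of_hse4
    end = tss + downstream_of_tss
    if start < 0:
        raise ValueError(
            f"amplicon start {start} before sequence start "
            f"(HSE4 at {hse4_start} leaves < {upstream_of_hse4} bp upstream)"
        )
    if end > len(genomic.sequence):
        raise ValueError(f"amplicon end {end} past sequence end")
    seq = genomic.sequence[start:end]
    return ReporterConstruct(
        name=name,
        sequence=seq,
        parent=genomic.id,
        parent_sequence=seq,
        edits=(),
        origin=start,
    )


def _derived(c: ReporterConstruct, name: str, new_edits: Sequence[Edit]) -> ReporterConstruct:
    edits = tuple(c.edits) + tuple(new_edits)
    return ReporterConstruct(
        name=name,
        sequence=replay_edits(c.parent_sequence, edits),
        parent=c.parent,
        parent_sequence=c.parent_sequence,
        edits=edits,
        origin=c.origin,
    )


def apply_deletion(
    c: ReporterConstruct, element: ATRichElement, name: str | None = None
) -> ReporterConstruct:
    """Excise an element (interval in parent-amplicon coordinates)."""
    iv = element.interval
    if iv.end > len(c.parent_sequence):
        raise ValueError(f"element {element.label} outside construct")
    edit = Edit("delete", iv.start, iv.end)
    return _derived(c, name or f"{c.name}_d{element.label}", [edit])


def apply_replacement(
    c: ReporterConstruct,
    element: ATRichElement,
    replacement: str,
    name: str | None = None,
) -> ReporterConstruct:
    """Swap an element for a same-length sequence (spacing is conserved)."""
    iv = element.interval
    if len(replacement) != element.length:
        raise ValueError(
            f"replacement length {len(replacement)} != element length "
            f"{element.length}; replacements must conserve length"
        )
    if iv.end > len(c.parent_sequence):
        raise ValueError(f"element {element.label} outside construct")
    edit = Edit("replace", iv.start, iv.end, replacement.upper())
    return _derived(c, name or f"{c.name}_r{element.label}", [edit])


def apply_site_mutation(
    c: ReporterConstruct,
    sites: Sequence[Interval],
    from_motif: str = "GAG",
    to_motif: str = "AGA",
    name: str | None = None,
) -> ReporterConstruct:
    """Substitute ``from_motif`` with ``to_motif`` at each annotated site.

    Each site interval must be exactly the motif footprint and must contain
    ``from_motif`` in the parent sequence; anything else is refused rather
    than silently edited.
    """
    if len(from_motif) != len(to_motif):
        raise ValueError("site mutations must conserve length")
    new_edits: list[Edit] = []
    for iv in sites:
        if iv.length() != len(from_motif):
            raise ValueError(
                f"site [{iv.start},{iv.end}) is not a {len(from_motif)}-bp footprint"
            )
        found = c.parent_sequence[iv.start : iv.end]
        if found != from_motif:
            raise ValueError(
                f"site [{iv.start},{iv.end}) contains {found!r}, "
                f"expected {from_motif!r}"
            )
        new_edits.append(Edit("substitute", iv.start, iv.end, to_motif))
    if not new_edits:
        return c
    return _derived(c, name or f"{c.name}_mut", new_edits)


@dataclass(frozen=True)
class ValidationReport:
    """Restriction-site census of a construct."""

    construct: str
    positions: Mapping[str, tuple[int, ...]]
    warnings: tuple[str, ...]

    def count(self, enzyme: str) -> int:
        return len(self.positions.get(enzyme, ()))


def _find_all(seq: str, site: str) -> tuple[int, ...]:
    out = []
    i = seq.find(site)
    while i != -1:
        out.append(i)
        i = seq.find(site, i + 1)
    return tuple(out)


def validate_construct(
    c: ReporterConstruct, enzymes: Mapping[str, str] | None = None
) -> ValidationReport:
    """Count recognition sites of each enzyme; warn on internal cutters.

    An internal occurrence of a cloning-relevant site means the enzyme used
    for vector assembly would also cut inside the insert.
    """
    enzymes = dict(enzymes) if enzymes is not None else dict(DEFAULT_ENZYMES)
    positions = {
        name: _find_all(c.sequence, site.upper()) for name, site in enzymes.items()
    }
    warnings = tuple(
        f"{name} site ({enzymes[name]}) occurs {len(pos)}x inside {c.name}"
        for name, pos in positions.items()
        if pos
    )
    return ValidationReport(construct=c.name, positions=positions, warnings=warnings)
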