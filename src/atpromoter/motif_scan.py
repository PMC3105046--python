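"""Degenerate-consensus motif scanning: HSE dimers, TATA, and motif libraries.

Matching uses IUPAC semantics: a consensus symbol accepts exactly the bases
in its degeneracy set.  An ``N`` in the scanned *text* (a masked base) is
conservative: it matches only a fully degenerate ``N`` in the consensus, so
masked regions never produce phantom hits.

The heat-shock element (HSE) is modelled as an adjacent head-to-tail dimer
of the 10-bp unit ``NTTCNNGAAN`` characteristic of dipteran hsp promoters.
That unit is its own reverse complement, so HSE scanning is inherently
strand-symmetric and only the forward strand needs to be searched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SequenceRecord, reverse_complement, tss_absolute, tss_relative

__all__ = [
    "IUPAC_SETS",
    "HSE_UNIT",
    "Motif",
    "MotifHit",
    "HSEHit",
    "iupac_match",
    "find_hse_dimers",
    "find_tata",
    "scan_library",
    "load_motif_library",
    "write_motif_library",
    "default_exclusion_library",
]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: The 10-bp HSE unit; an HSE is an adjacent dimer of two such units.
HSE_UNIT = "NTTCNNGAAN"


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus, optionally scanned on both strands."""

    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: illegal IUPAC symbols {sorted(bad)!r}"
            )
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")


@dataclass(frozen=True)
class MotifHit:
    """One consensus match: position is 0-based in the scanned sequence."""

    motif_name: str
    start: int
    strand: str
    matched: str
    tss_relative: int | None = None


@dataclass(frozen=True)
class HSEHit:
    """One HSE dimer: two adjacent 10-bp units, labelled by TSS proximity."""

    start: int
    tss_relative: int | None
    unit1: str
    unit2: str
    label: str

    def __post_init__(self) -> None:
        for unit in (self.unit1, self.unit2):
            if not iupac_match(unit, HSE_UNIT):
                raise ValueError(f"unit {unit!r} does not satisfy {HSE_UNIT}")


def iupac_match(text: str, consensus: str) -> bool:
    """True iff ``text`` satisfies the IUPAC ``consensus`` position-wise."""
    if len(text) != len(consensus):
        raise ValueError(
            f"length mismatch: text {len(text)} vs consensus {len(consensus)}"
        )
    for t, c in zip(text, consensus):
        allowed = IUPAC_SETS.get(c)
        if allowed is None:
            raise ValueError(f"illegal consensus symbol {c!r}")
        if t == "N":
            if c != "N":
                return False
        elif t not in allowed:
            if t not in IUPAC_SETS:
                raise ValueError(f"illegal text character {t!r}")
            return False
    return True


@lru_cache(maxsize=256)
def _consensus_regex(consensus: str) -> re.Pattern:
    """Compiled lookahead regex yielding all (overlapping) match starts."""
    parts = []
    for c in consensus:
        allowed = IUPAC_SETS[c]
        cls = allowed + ("N" if c == "N" else "")
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _match_starts(text: str, consensus: str) -> list[int]:
    return [m.start() for m in _consensus_regex(consensus).finditer(text)]


def find_hse_dimers(
    record: SequenceRecord, tss: int | None = None
) -> list[HSEHit]:
    """All HSE dimers (two adjacent ``NTTCNNGAAN`` units) in a sequence.

    Overlapping 20-bp dimer windows are resolved by greedy left-to-right
    non-overlapping selection.  With a TSS, hits are labelled HSE1..HSEn from
    the TSS outward and returned in that order; without one they are labelled
    and returned left to right.
    """
    seq = record.sequence
    if len(seq) < 2 * len(HSE_UNIT):
        raise ValueError("sequence shorter than an HSE dimer")
    unit_ok = set(_match_starts(seq, HSE_UNIT))
    u = len(HSE_UNIT)
    dimer_starts = sorted(p for p in unit_ok if p + u in unit_ok)
    chosen: list[int] = []
    for p in dimer_starts:
        if not chosen or p >= chosen[-1] + 2 * u:
            chosen.append(p)
    if tss is not None:
        chosen.sort(key=lambda p: abs(tss_relative(p, tss)))
    return [
        HSEHit(
            start=p,
            tss_relative=tss_relative(p, tss) if tss is not None else None,
            unit1=seq[p : p + u],
            unit2=seq[p + u : p + 2 * u],
            label=f"HSE{i + 1}",
        )
        for i, p in enumerate(chosen)
    ]


def find_tata(
    record: SequenceRecord,
    tss: int,
    search_window: tuple[int, int] = (-45, -20),
    consensus: str = "TATAWAW",
) -> MotifHit | None:
    """Most TSS-proximal TATA-consensus match with start in the window.

    ``search_window`` bounds the signed TSS-relative *start* position of the
    match (inclusive).  Returns ``None`` when the window holds no match.
    """
    lo, hi = search_window
    abs_lo = max(0, tss_absolute(lo, tss))
    abs_hi = min(len(record.sequence), tss_absolute(hi, tss) + len(consensus))
    if abs_hi <= abs_lo:
        return None
    window_seq = record.sequence[abs_lo:abs_hi]
    starts = [abs_lo + s for s in _match_starts(window_seq, consensus)]
    starts = [s for s in starts if lo <= tss_relative(s, tss) <= hi]
    if not starts:
        return None
    best = min(starts, key=lambda s: abs(tss_relative(s, tss)))
    return MotifHit(
        motif_name="TATA",
        start=best,
        strand="+",
        matched=record.sequence[best : best + len(consensus)],
        tss_relative=tss_relative(best, tss),
    )


def scan_library(
    record: SequenceRecord,
    library: Sequence[Motif],
    tss: int | None = None,
) -> list[MotifHit]:
    """All matches of all library motifs, both strands where flagged.

    Minus-strand hits are reported at their forward-strand footprint start,
    with ``matched`` being the minus-strand (reverse-complemented) text so
    that it satisfies the consensus as stated.  Hits are sorted by position.
    """
    if not library:
        raise ValueError("motif library is empty")
    seq = record.sequence
    hits: list[MotifHit] = []
    for motif in library:
        for s in _match_starts(seq, motif.consensus):
            hits.append(
                MotifHit(
                    motif_name=motif.name,
                    start=s,
                    strand="+",
                    matched=seq[s : s + len(motif.consensus)],
                    tss_relative=tss_relative(s, tss) if tss is not None else None,
                )
            )
        if motif.both_strands:
            rc_consensus = reverse_complement(motif.consensus)
            for s in _match_starts(seq, rc_consensus):
                hits.append(
                    MotifHit(
                        motif_name=motif.name,
                        start=s,
                        strand="-",
                        matched=reverse_complement(
                            seq[s : s + len(motif.consensus)]
                        ),
                        tss_relative=tss_relative(s, tss)
                        if tss is not None
                        else None,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def load_motif_library(path: str | Path) -> list[Motif]:
    """Read a motif library TSV: ``name  consensus  both_strands``."""
    motifs: list[Motif] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            name, consensus, both = fields
            if both.lower() not in ("true", "false", "1", "0"):
                raise ValueError(
                    f"{path}: line {lineno}: both_strands must be true/false"
                )
            motifs.append(
                Motif(name, consensus.upper(), both.lower() in ("true", "1"))
            )
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_motif_library(motifs: Iterable[Motif], path: str | Path) -> None:
    with open(path, "w") as handle:
        for m in motifs:
            handle.write(f"{m.name}\t{m.consensus}\t{str(m.both_strands).lower()}\n")


def default_exclusion_library() -> list[Motif]:
    """Motifs excluded from matched-control sequences.

    HSE dimers, GAG-core Zeste sites, and GAGA-factor elements: the
    regulatory elements this analysis manipulates.  A TATA consensus is
    deliberately not part of the exclusion set - in AT-rich DNA short
    TATA-like words occur every few hundred bases and excluding them would
    leave no viable AT-matched control windows.
    """
    return [
        Motif("HSE_dimer", HSE_UNIT + HSE_UNIT, both_strands=False),
        Motif("Zeste", "YGAGYG", both_strands=True),
        Motif("GAGA", "GAGAG", both_strands=True),
    ]
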