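"""Matched-control sequence selection from an annotated genome.

The screening procedure mirrors how replacement ("random") sequences are
chosen for promoter-element swap experiments: draw a long chromosome
fragment at random, enumerate every window of the exact target length whose
A+T content lies within a tolerance of the target (in percentage points),
discard windows overlapping annotated genes extended by strand-aware
flanks (upstream of the 5' end, downstream of the 3' end), discard windows
containing any hit from a transcription-factor motif library, and pick one
survivor uniformly at random.  Every stage's attrition is recorded so an
empty result can be diagnosed and the tolerance relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motif_scan import Motif, scan_library
from .seqio import GeneAnnotation, Interval, SequenceRecord

__all__ = [
    "SelectorConfig",
    "ControlCandidate",
    "EmptyCandidateSetError",
    "pick_fragment",
    "enumerate_candidates",
    "filter_intergenic",
    "filter_tfbs_free",
    "select_control",
    "select_control_sequence",
]


@dataclass(frozen=True)
class SelectorConfig:
    """Parameters of the matched-control screen.

    ``target_at`` and ``at_tolerance`` are in percent; the tolerance is in
    percentage points (``|AT% - target%| <= at_tolerance``), reading the
    conventional "+-0.3%" literally.
    """

    target_length: int
    target_at: float
    at_tolerance: float = 0.3
    fragment_length: int = 5_000_000
    flank_upstream: int = 300
    flank_downstream: int = 200

    def __post_init__(self) -> None:
        if self.target_length < 1:
            raise ValueError("target_length must be positive")
        if not 0.0 <= self.target_at <= 100.0:
            raise ValueError("target_at must be a percentage")
        if self.at_tolerance <= 0:
            raise ValueError("at_tolerance must be > 0")
        if self.fragment_length < self.target_length:
            raise ValueError("fragment_length must be >= target_length")


@dataclass(frozen=True)
class ControlCandidate:
    """A candidate window: interval, realised A+T fraction, sequence."""

    interval: Interval
    at_fraction: float
    sequence: str


class EmptyCandidateSetError(RuntimeError):
    """No candidate survived; carries per-stage attrition counts."""

    def __init__(self, stage_counts: Mapping[str, int]):
        self.stage_counts = dict(stage_counts)
        super().__init__(
            "no candidate sequence survived screening; stage counts: "
            + ", ".join(f"{k}={v}" for k, v in stage_counts.items())
            + " (consider relaxing at_tolerance or the motif library)"
        )


def _as_genome(genome) -> list[SequenceRecord]:
    if isinstance(genome, SequenceRecord):
        return [genome]
    return list(genome)


def pick_fragment(
    genome: Sequence[SequenceRecord] | SequenceRecord,
    cfg: SelectorConfig,
    rng: np.random.Generator,
) -> Interval:
    """Uniformly random fragment of ``cfg.fragment_length`` from the genome.

    The draw is uniform over all eligible (chromosome, start) pairs, so
    longer chromosomes are proportionally more likely to contribute.
    """
    records = _as_genome(genome)
    eligible = [r for r in records if len(r) >= cfg.fragment_length]
    if not eligible:
        raise ValueError(
            f"no chromosome is at least {cfg.fragment_length} bp long"
        )
    n_starts = np.array(
        [len(r) - cfg.fragment_length + 1 for r in eligible], dtype=np.int64
    )
    flat = int(rng.integers(0, int(n_starts.sum())))
    cum = np.cumsum(n_starts)
    idx = int(np.searchsorted(cum, flat, side="right"))
    start = flat - (int(cum[idx - 1]) if idx > 0 else 0)
    return Interval(eligible[idx].id, start, start + cfg.fragment_length)


def enumerate_candidates(
    fragment_seq: str,
    cfg: SelectorConfig,
    chrom: str = "fragment",
    offset: int = 0,
) -> list[ControlCandidate]:
    """Every step-1 window of exact target length within the AT tolerance.

    A+T fractions are computed with a rolling count (cumulative sums), so the
    scan is O(fragment length); windows containing only N bases are skipped.
    ``offset`` places the reported intervals in chromosome coordinates when
    the fragment was cut from a larger sequence.
    """
    L = cfg.target_length
    if len(fragment_seq) < L:
        raise ValueError("fragment shorter than target length")
    arr = np.frombuffer(fragment_seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_ok = is_at | (arr == ord("G")) | (arr == ord("C"))
    cum_at = np.concatenate(([0], np.cumsum(is_at)))
    cum_ok = np.concatenate(([0], np.cumsum(is_ok)))
    starts = np.arange(0, len(fragment_seq) - L + 1)
    at = cum_at[starts + L] - cum_at[starts]
    ok = cum_ok[starts + L] - cum_ok[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ok > 0, at / np.maximum(ok, 1), np.nan)
    keep = (ok > 0) & (
        np.abs(100.0 * frac - cfg.target_at) <= cfg.at_tolerance
    )
    return [
        ControlCandidate(
            interval=Interval(chrom, offset + int(s), offset + int(s) + L),
            at_fraction=float(frac[s]),
            sequence=fragment_seq[int(s) : int(s) + L],
        )
        for s in starts[keep]
    ]


def _exclusion_zones(
    genes: Sequence[GeneAnnotation], cfg: SelectorConfig
) -> dict[str, np.ndarray]:
    """Merged per-chromosome exclusion intervals around flanked genes."""
    zones: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            lo, hi = iv.start - cfg.flank_upstream, iv.end + cfg.flank_downstream
        elif iv.strand == "-":
            lo, hi = iv.start - cfg.flank_downstream, iv.end + cfg.flank_upstream
        else:  # unstranded fallback: union of both orientations
            ext = max(cfg.flank_upstream, cfg.flank_downstream)
            lo, hi = iv.start - ext, iv.end + ext
        zones.setdefault(iv.chrom, []).append((max(0, lo), hi))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in zones.items():
        ivs.sort()
        out = [list(ivs[0])]
        for lo, hi in ivs[1:]:
            if lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def filter_intergenic(
    cands: Sequence[ControlCandidate],
    genes: Sequence[GeneAnnotation],
    cfg: SelectorConfig,
) -> list[ControlCandidate]:
    """Drop candidates sharing >= 1 base with any flank-extended gene."""
    zones = _exclusion_zones(genes, cfg)
    kept: list[ControlCandidate] = []
    for cand in cands:
        z = zones.get(cand.interval.chrom)
        if z is None:
            kept.append(cand)
            continue
        # Overlap iff some zone has lo < cand.end and hi > cand.start.
        i = int(np.searchsorted(z[:, 0], cand.interval.end, side="left"))
        if i == 0 or z[i - 1, 1] <= cand.interval.start:
            kept.append(cand)
    return kept


def filter_tfbs_free(
    cands: Sequence[ControlCandidate], library: Sequence[Motif]
) -> list[ControlCandidate]:
    """Drop candidates with at least one motif-library hit."""
    if not library:
        return list(cands)
    kept = []
    for cand in cands:
        rec = SequenceRecord("cand", cand.sequence)
        if not scan_library(rec, library):
            kept.append(cand)
    return kept


def select_control(
    cands: Sequence[ControlCandidate],
    rng: np.random.Generator,
    stage_counts: Mapping[str, int] | None = None,
) -> ControlCandidate:
    """Uniform random choice among surviving candidates."""
    if not cands:
        raise EmptyCandidateSetError(stage_counts or {"survivors": 0})
    return cands[int(rng.integers(0, len(cands)))]


def select_control_sequence(
    genome: Sequence[SequenceRecord] | SequenceRecord,
    genes: Sequence[GeneAnnotation],
    cfg: SelectorConfig,
    library: Sequence[Motif],
    seed: int | np.random.Generator,
) -> tuple[ControlCandidate, dict]:
    """The full screen: fragment -> AT windows -> intergenic -> motif-free -> pick.

    Returns the selected candidate and a provenance report with the fragment
    interval and the candidate count after each stage.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    records = _as_genome(genome)
    frag = pick_fragment(records, cfg, rng)
    by_id = {r.id: r for r in records}
    frag_seq = by_id[frag.chrom].sequence[frag.start : frag.end]
    cands = enumerate_candidates(frag_seq, cfg, chrom=frag.chrom, offset=frag.start)
    n_at = len(cands)
    cands = filter_intergenic(cands, genes, cfg)
    n_intergenic = len(cands)
    cands = filter_tfbs_free(cands, library)
    n_free = len(cands)
    counts = {
        "at_matched": n_at,
        "intergenic": n_intergenic,
        "tfbs_free": n_free,
    }
    chosen = select_control(cands, rng, stage_counts=counts)
    provenance = {
        "fragment": {
            "chrom": frag.chrom,
            "start": frag.start,
            "end": frag.end,
        },
        "stage_counts": counts,
        "selected": {
            "chrom": chosen.interval.chrom,
            "start": chosen.interval.start,
            "end": chosen.interval.end,
            "at_percent": 100.0 * chosen.at_fraction,
        },
        "config": {
            "target_length": cfg.target_length,
            "target_at": cfg.target_at,
            "at_tolerance": cfg.at_tolerance,
            "fragment_length": cfg.fragment_length,
            "flank_upstream": cfg.flank_upstream,
            "flank_downstream": cfg.flank_downstream,
        },
    }
    return chosen, provenance
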