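"""A+T content statistics: point values, sliding-window profiles, region means.

The base statistic is the A+T fraction ``(#A + #T) / (#A + #T + #G + #C)``;
``N`` bases are excluded from both numerator and denominator, so masked
positions do not dilute the estimate.  Profiles are computed over fully
contained windows only (trailing partial windows are dropped rather than
padded, which would bias the edge estimates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import Interval, SequenceRecord, reverse_complement

__all__ = ["ATProfile", "at_fraction", "sliding_profile", "region_mean_at"]


@dataclass(frozen=True)
class ATProfile:
    """Windowed A+T fractions over a sequence.

    ``centers`` are 0-based window midpoints (``start + window // 2``),
    strictly increasing; one fraction per window.
    """

    window: int
    step: int
    centers: tuple[int, ...]
    at_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.at_fraction):
            raise ValueError("centers and at_fraction must have equal length")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("centers must be strictly increasing")
        for f in self.at_fraction:
            if not (np.isnan(f) or 0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.centers)

    def to_tsv(self, path: str | Path) -> None:
        """Write the profile as TSV with 1-based window centers."""
        with open(path, "w") as handle:
            handle.write("center_1based\tat_fraction\n")
            for c, f in zip(self.centers, self.at_fraction):
                handle.write(f"{c + 1}\t{f:.6f}\n")


def at_fraction(seq: str) -> float:
    """A+T fraction of a DNA string, with N bases excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    if at + gc == 0:
        raise ValueError("A+T fraction undefined: no unambiguous bases")
    return at / (at + gc)


def sliding_profile(seq: str, window: int, step: int = 1) -> ATProfile:
    """A+T fraction in a sliding window over ``seq``.

    One value per fully contained window starting at 0, step, 2*step, ...
    Windows made entirely of N are reported as NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > len(seq):
        raise ValueError(
            f"window {window} exceeds sequence length {len(seq)}"
        )
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_acgt = is_at | (arr == ord("G")) | (arr == ord("C"))
    cum_at = np.concatenate(([0], np.cumsum(is_at)))
    cum_ok = np.concatenate(([0], np.cumsum(is_acgt)))
    starts = np.arange(0, len(seq) - window + 1, step)
    at = cum_at[starts + window] - cum_at[starts]
    ok = cum_ok[starts + window] - cum_ok[starts]
    with np.errstate(invalid="ignore"):
        frac = np.where(ok > 0, at / np.maximum(ok, 1), np.nan)
    return ATProfile(
        window=window,
        step=step,
        centers=tuple(int(s) + window // 2 for s in starts),
        at_fraction=tuple(float(f) for f in frac),
    )


def region_mean_at(record: SequenceRecord, interval: Interval) -> float:
    """A+T fraction of the subsequence under ``interval``.

    The subsequence is reverse-complemented first on the minus strand; the
    statistic is strand-invariant (A<->T, G<->C), so this only matters for
    documentation of what was measured.
    """
    sub = record.subsequence(interval.start, interval.end)
    if interval.strand == "-":
        sub = reverse_complement(sub)
    return at_fraction(sub)
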