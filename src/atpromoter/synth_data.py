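"""Synthetic fixtures with exact ground truth for every analysis stage.

Three generators, each a pure function of its spec plus a seed:

* an annotated genome with a position-dependent A+T landscape and
  non-overlapping stranded genes (a stand-in for a real chromosome in the
  matched-control screen);
* a pair of orthologous promoters sharing a TATA box at -30 and four HSE
  dimers, where the second species additionally carries two planted AT-rich
  insertion elements (495 bp at ~75% A+T between HSE2 and HSE3; 98 bp at
  ~65% A+T, holding two GAG-core Zeste sites, between HSE3 and HSE4) and
  optional per-base divergence outside planted footprints;
* log-normal dual-luciferase replicate tables with configurable construct
  and heat-shock effect multipliers.

Planted element A+T contents are achieved by exact base-count shuffling, so
the realised fraction equals the target up to 1/length quantisation.
Promoter backgrounds are rejection-sampled so the planted HSE dimers and
TATA box are the only ones present, and insertion ends are arranged to
differ from their flanking bases, keeping gap placement unambiguous for
boundary-exact element recovery.  Every claim in the emitted manifests is
independently re-measurable by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_scan import HSE_UNIT, _match_starts
from .seqio import GeneAnnotation, Interval, SequenceRecord

__all__ = [
    "PromoterPairSpec",
    "LuminSpec",
    "make_genome",
    "make_promoter_pair",
    "make_luminescence",
    "default_at_landscape",
]

_BASES = np.array(list("ACGT"))


def default_at_landscape(pos: np.ndarray) -> np.ndarray:
    """Sinusoidal A+T probability between 0.55 and 0.80 (period 50 kb).

    Sweeps through the compositions that matter for AT-matched control
    screens (65% and 75% A+T) while keeping genome-wide heterogeneity.
    """
    return 0.675 + 0.125 * np.sin(2.0 * np.pi * np.asarray(pos) / 50_000.0)


def _random_dna(rng: np.random.Generator, p_at: np.ndarray | float, n: int) -> str:
    """i.i.d. bases with position-wise P(A or T) = p_at; A/T and G/C equiprobable."""
    p = np.broadcast_to(np.asarray(p_at, dtype=float), (n,))
    is_at = rng.random(n) < p
    second = rng.random(n) < 0.5
    codes = np.where(is_at, np.where(second, 0, 3), np.where(second, 1, 2))
    return "".join(_BASES[codes])


def make_genome(
    n_chroms: int = 1,
    chrom_length: int = 1_000_000,
    n_genes: int = 20,
    at_landscape: float | Callable[[np.ndarray], np.ndarray] = default_at_landscape,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 3000),
) -> tuple[list[SequenceRecord], list[GeneAnnotation], dict]:
    """An annotated genome: i.i.d. bases under an A+T landscape plus genes.

    Genes are non-overlapping stranded intervals placed uniformly (rejection
    sampled; raises if the requested genes cannot be packed).  Returns
    (records, annotations, manifest).
    """
    if n_chroms < 1 or chrom_length < 1 or n_genes < 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    genes: list[GeneAnnotation] = []
    per_chrom = [
        n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
        for i in range(n_chroms)
    ]
    manifest: dict = {"chroms": {}, "seed": seed}
    for ci in range(n_chroms):
        name = f"chr{ci + 1}"
        pos = np.arange(chrom_length)
        p_at = (
            at_landscape(pos)
            if callable(at_landscape)
            else float(at_landscape)
        )
        seq = _random_dna(rng, p_at, chrom_length)
        records.append(SequenceRecord(name, seq, description="synthetic"))
        placed: list[tuple[int, int]] = []
        for gi in range(per_chrom[ci]):
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            if glen >= chrom_length:
                raise ValueError("gene longer than chromosome")
            ok = False
            for _ in range(1000):
                start = int(rng.integers(0, chrom_length - glen + 1))
                if all(
                    start + glen <= s or start >= e for s, e in placed
                ):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"could not place {per_chrom[ci]} genes on {name}"
                )
            placed.append((start, start + glen))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(
                    f"{name}_g{gi + 1}",
                    Interval(name, start, start + glen, strand=strand),
                )
            )
        manifest["chroms"][name] = {
            "length": chrom_length,
            "n_genes": per_chrom[ci],
        }
    manifest["genes"] = [
        {
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
        }
        for g in genes
    ]
    return records, genes, manifest


# ---------------------------------------------------------------------------
# Orthologous promoter pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterPairSpec:
    """Layout of the synthetic ortholog pair (all positions TSS-relative).

    Species A is the insertion-free promoter (~900 bp with the default
    150 bp of transcribed sequence retained downstream of the TSS); species
    B carries both AT-rich insertions (at ~75% and ~65% A+T, the planted
    compositions of the two elements) and, optionally, per-base divergence
    substitutions outside planted footprints.
    """

    base_length: int = 900
    downstream_length: int = 150  # transcribed bases kept past the TSS
    # (>= 135 so the reporter amplicon, which ends 135 bp past the TSS, fits)
    tata_offset: int = -30
    hse_offsets: tuple[int, int, int, int] = (-75, -140, -310, -550)
    atrs1_length: int = 495
    atrs1_at: float = 0.75
    atrs1_insert_at: int = -200  # between HSE2 and HSE3
    atrs2_length: int = 98
    atrs2_at: float = 0.65
    atrs2_insert_at: int = -400  # between HSE3 and HSE4
    zeste_offsets: tuple[int, int] = (20, 46)  # within the 98-bp element
    background_at: float = 0.73
    divergence: float = 0.0
    boundary_guard: int = 10  # divergence-free margin around insertions
    seed: int = 0

    def __post_init__(self) -> None:
        offs = self.hse_offsets
        if not all(b < a for a, b in zip(offs, offs[1:])):
            raise ValueError("hse_offsets must run proximal to distal")
        h2_end = offs[1] + 2 * len(HSE_UNIT)
        if not (offs[2] + 2 * len(HSE_UNIT) <= self.atrs1_insert_at <= offs[1]):
            raise ValueError("atrs1_insert_at must lie between HSE2 and HSE3")
        if not (offs[3] + 2 * len(HSE_UNIT) <= self.atrs2_insert_at <= offs[2]):
            raise ValueError("atrs2_insert_at must lie between HSE3 and HSE4")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        z1, z2 = self.zeste_offsets
        if not (0 <= z1 and z1 + 6 <= z2 and z2 + 6 <= self.atrs2_length):
            raise ValueError("zeste sites must be ordered and inside the element")


def _rel_to_abs(rel: int, tss: int) -> int:
    return tss + (rel - 1 if rel > 0 else rel)


def _exact_at_fill(
    rng: np.random.Generator, length: int, at_target: float
) -> str:
    """A sequence of exact length with round(at_target * length) A/T bases."""
    n_at = int(round(at_target * length))
    at_part = rng.integers(0, 2, n_at)  # A or T
    gc_part = rng.integers(0, 2, length - n_at)  # C or G
    chars = np.concatenate(
        [np.where(at_part == 0, 0, 3), np.where(gc_part == 0, 1, 2)]
    )
    rng.shuffle(chars)
    return "".join(_BASES[chars])


def _hse_dimer(rng: np.random.Generator) -> str:
    """A concrete 20-mer satisfying two adjacent NTTCNNGAAN units."""
    def unit() -> str:
        ns = "".join(_BASES[rng.integers(0, 4, 4)])
        return ns[0] + "TTC" + ns[1:3] + "GAA" + ns[3]
    return unit() + unit()


def _count_hse_dimers(seq: str) -> int:
    unit_ok = set(_match_starts(seq, HSE_UNIT))
    return sum(1 for p in unit_ok if p + len(HSE_UNIT) in unit_ok)


def _count_tata(seq: str, lo: int, hi: int) -> int:
    window = seq[lo:hi]
    return len(_match_starts(window, "TATAWAW"))


def make_promoter_pair(
    spec: PromoterPairSpec = PromoterPairSpec(),
) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """Generate the ortholog promoter pair plus an exact truth manifest.

    Manifest keys: per-species TSS, HSE/TATA positions (absolute), and for
    species B the two element intervals, their realised A+T fractions, and
    the Zeste-site intervals.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.base_length
    tss_a = L - spec.downstream_length
    u = len(HSE_UNIT)

    hse_abs_a = [_rel_to_abs(r, tss_a) for r in spec.hse_offsets]
    tata_abs_a = _rel_to_abs(spec.tata_offset, tss_a)
    tata_seq = "TATAAA" + ("A" if rng.random() < 0.5 else "T")
    hse_seqs = [_hse_dimer(rng) for _ in range(4)]

    # Background rejection-sampled so the planted motifs are the only ones.
    for _attempt in range(200):
        base = list(_random_dna(rng, spec.background_at, L))
        for p, d in zip(hse_abs_a, hse_seqs):
            base[p : p + 2 * u] = d
        base[tata_abs_a : tata_abs_a + 7] = tata_seq
        seq_a = "".join(base)
        tata_lo = _rel_to_abs(-45, tss_a)
        tata_hi = _rel_to_abs(-20, tss_a) + 7
        if (
            _count_hse_dimers(seq_a) == 4
            and _count_tata(seq_a, tata_lo, tata_hi) == 1
        ):
            break
    else:
        raise RuntimeError("could not sample a clean promoter background")

    # Planted insertion elements (exact-count composition).
    ins1_abs = _rel_to_abs(spec.atrs1_insert_at, tss_a)
    ins2_abs = _rel_to_abs(spec.atrs2_insert_at, tss_a)

    def make_insert(length: int, at: float, zeste: bool, left: str, right: str) -> str:
        """Element whose ends differ from flanks and that plants no HSE."""
        for _ in range(200):
            if zeste:
                site = "TGAGTG"  # satisfies the YGAGYG Zeste consensus
                fixed_at = 2 * sum(1 for c in site if c in "AT")
                n_free = length - 2 * len(site)
                n_at = int(round(at * length)) - fixed_at
                free_at = rng.integers(0, 2, n_at)
                free_gc = rng.integers(0, 2, n_free - n_at)
                chars = np.concatenate(
                    [np.where(free_at == 0, 0, 3), np.where(free_gc == 0, 1, 2)]
                )
                rng.shuffle(chars)
                free = "".join(_BASES[chars])
                z1, z2 = spec.zeste_offsets
                s = (
                    free[:z1]
                    + site
                    + free[z1 : z2 - len(site)]
                    + site
                    + free[z2 - len(site) :]
                )
            else:
                s = _exact_at_fill(rng, length, at)
            if s[0] != right and s[-1] != left and _count_hse_dimers(s) == 0:
                return s
        raise RuntimeError("could not sample a clean insertion element")

    shift1 = spec.atrs2_length  # shift for positions in [ins2, ins1)
    shift_full = spec.atrs2_length + spec.atrs1_length
    tss_b = tss_a + shift_full
    tata_lo_b = _rel_to_abs(-45, tss_b)
    tata_hi_b = _rel_to_abs(-20, tss_b) + 7

    # Retry until the assembled pair carries exactly the planted motifs
    # (junctions between background and inserts could mint spurious ones).
    for _attempt in range(200):
        atrs1_seq = make_insert(
            spec.atrs1_length, spec.atrs1_at, False,
            seq_a[ins1_abs - 1], seq_a[ins1_abs],
        )
        atrs2_seq = make_insert(
            spec.atrs2_length, spec.atrs2_at, True,
            seq_a[ins2_abs - 1], seq_a[ins2_abs],
        )
        seq_b = (
            seq_a[:ins2_abs]
            + atrs2_seq
            + seq_a[ins2_abs:ins1_abs]
            + atrs1_seq
            + seq_a[ins1_abs:]
        )
        if (
            _count_hse_dimers(seq_b) == 4
            and _count_tata(seq_b, tata_lo_b, tata_hi_b) == 1
        ):
            break
    else:
        raise RuntimeError("could not assemble a clean insertion-bearing ortholog")

    def b_coord(a_pos: int) -> int:
        if a_pos < ins2_abs:
            return a_pos
        if a_pos < ins1_abs:
            return a_pos + shift1
        return a_pos + shift_full

    atrs2_iv = (ins2_abs, ins2_abs + spec.atrs2_length)
    atrs1_iv = (
        ins1_abs + spec.atrs2_length,
        ins1_abs + spec.atrs2_length + spec.atrs1_length,
    )
    hse_abs_b = [b_coord(p) for p in hse_abs_a]
    tata_abs_b = b_coord(tata_abs_a)
    zeste_ivs = [
        (atrs2_iv[0] + off, atrs2_iv[0] + off + 6) for off in spec.zeste_offsets
    ]
    gag_ivs = [(s + 1, s + 4) for s, _e in zeste_ivs]  # the GAG cores

    # Divergence substitutions outside planted footprints and guard zones.
    n_subs = 0
    if spec.divergence > 0:
        protected = np.zeros(len(seq_b), dtype=bool)
        for p in hse_abs_b:
            protected[p : p + 2 * u] = True
        protected[tata_abs_b : tata_abs_b + 7] = True
        for s, e in zeste_ivs:
            protected[s:e] = True
        g = spec.boundary_guard
        for s, e in (atrs1_iv, atrs2_iv):
            protected[max(0, s - g) : s + g] = True
            protected[e - g : e + g] = True
        for _attempt in range(50):
            arr = list(seq_b)
            hit = np.flatnonzero(
                (rng.random(len(seq_b)) < spec.divergence) & ~protected
            )
            for p in hit:
                choices = [b for b in "ACGT" if b != arr[p]]
                arr[p] = choices[int(rng.integers(0, 3))]
            cand = "".join(arr)
            if (
                _count_hse_dimers(cand) == 4
                and _count_tata(cand, tata_lo_b, tata_hi_b) == 1
            ):
                seq_b = cand
                n_subs = int(hit.size)
                break
        else:
            raise RuntimeError("could not apply divergence without motif damage")

    rec_a = SequenceRecord("promoterA", seq_a, description="synthetic ortholog A")
    rec_b = SequenceRecord("promoterB", seq_b, description="synthetic ortholog B")

    # Re-measure element composition from the emitted sequence (divergence
    # substitutions inside an element count against its realised A+T).
    atrs1_final = seq_b[atrs1_iv[0] : atrs1_iv[1]]
    atrs2_final = seq_b[atrs2_iv[0] : atrs2_iv[1]]
    at1 = (atrs1_final.count("A") + atrs1_final.count("T")) / spec.atrs1_length
    at2 = (atrs2_final.count("A") + atrs2_final.count("T")) / spec.atrs2_length
    manifest = {
        "seed": spec.seed,
        "tss_a": tss_a,
        "tss_b": tss_b,
        "tata_a": tata_abs_a,
        "tata_b": tata_abs_b,
        "hse_a": hse_abs_a,
        "hse_b": hse_abs_b,
        "atrs1": {
            "start": atrs1_iv[0],
            "end": atrs1_iv[1],
            "length": spec.atrs1_length,
            "at_fraction": at1,
            "sequence": atrs1_final,
        },
        "atrs2": {
            "start": atrs2_iv[0],
            "end": atrs2_iv[1],
            "length": spec.atrs2_length,
            "at_fraction": at2,
            "sequence": atrs2_final,
        },
        "zeste_sites": [{"start": s, "end": e} for s, e in zeste_ivs],
        "gag_cores": [{"start": s, "end": e} for s, e in gag_ivs],
        "n_divergence_substitutions": n_subs,
    }
    return rec_a, rec_b, manifest


# ---------------------------------------------------------------------------
# Luminescence tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LuminSpec:
    """Planted effect structure of a synthetic dual-luciferase assay.

    Defaults plant the headline reporter effects: a sevenfold drop of the
    element-2 deletion construct, tenfold heat-shock induction, and an
    elevated element-1 deletion, over log-normal replicate noise with five
    replicates per cell.
    """

    construct_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "WT": 1.0,
            "dATRS1": 3.0,
            "dATRS2": 1.0 / 7.0,
            "dATRS1_2": 1.1,
        }
    )
    induction: float = 10.0
    n_replicates: int = 5
    sigma: float = 0.1  # log-scale SD of the firefly channel
    sigma_renilla: float = 0.1
    baseline_firefly: float = 1000.0
    baseline_renilla: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.construct_multipliers.values()):
            raise ValueError("construct multipliers must be positive")
        if self.induction <= 0:
            raise ValueError("induction multiplier must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def make_luminescence(
    spec: LuminSpec = LuminSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Log-normal replicate table plus the planted-truth manifest.

    firefly = baseline * construct multiplier * (induction if heat shock)
    * exp(N(0, sigma^2)); renilla = its baseline * exp(N(0, sigma_r^2)).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for construct, mult in spec.construct_multipliers.items():
        for treatment in ("control", "heat_shock"):
            eff = mult * (spec.induction if treatment == "heat_shock" else 1.0)
            for rep in range(1, spec.n_replicates + 1):
                firefly = (
                    spec.baseline_firefly
                    * eff
                    * float(np.exp(rng.normal(0.0, spec.sigma)))
                )
                renilla = spec.baseline_renilla * float(
                    np.exp(rng.normal(0.0, spec.sigma_renilla))
                )
                rows.append(
                    {
                        "construct": construct,
                        "treatment": treatment,
                        "replicate": rep,
                        "firefly": firefly,
                        "renilla": renilla,
                    }
                )
    df = pd.DataFrame(rows)
    manifest = {
        "seed": spec.seed,
        "construct_multipliers": dict(spec.construct_multipliers),
        "induction": spec.induction,
        "n_replicates": spec.n_replicates,
        "sigma": spec.sigma,
        "sigma_renilla": spec.sigma_renilla,
    }
    return df, manifest
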