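"""Dual-luciferase assay statistics.

Raw firefly luminescence is normalised by the co-transfected Renilla signal
(ratio per replicate).  Fold induction is the ratio of mean normalised
luminescence under heat shock to that under control conditions.  Construct
groups are compared with one-way ANOVA followed by Tukey's HSD
(Tukey-Kramer for unbalanced groups, studentized-range distribution) and
summarised as a compact letter display: groups sharing a letter are not
significantly different at the chosen alpha.

Pairwise significance decisions come from the studentized-range critical
value (one cached ``scipy.stats.studentized_range.ppf`` evaluation per
(alpha, k, df)); the matrix of Tukey-adjusted p-values is computed from the
same scipy distribution on first access.  Heat-shock versus control
contrasts use Welch's unequal-variance t test by default (a pooled-variance
test is available via ``equal_var=True``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LuminescenceRecord",
    "GroupComparison",
    "normalize",
    "fold_induction",
    "compare_groups",
    "two_sample_test",
    "analyze_assay",
    "load_luminescence_tsv",
]


@dataclass(frozen=True)
class LuminescenceRecord:
    """One well: construct, treatment, replicate, raw firefly and Renilla."""

    construct: str
    treatment: str  # heat_shock | control
    replicate: int
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.treatment not in ("heat_shock", "control"):
            raise ValueError(
                f"treatment must be 'heat_shock' or 'control', got "
                f"{self.treatment!r}"
            )
        if self.firefly <= 0 or self.renilla <= 0:
            raise ValueError(
                f"non-positive luminescence for {self.construct}/"
                f"{self.treatment}/rep{self.replicate}"
            )


def normalize(
    records: Sequence[LuminescenceRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-replicate firefly/Renilla ratios.

    Accepts a list of :class:`LuminescenceRecord` or a DataFrame with columns
    ``construct, treatment, replicate, firefly, renilla``; returns the same
    keys plus ``ratio``.  Replicate ids must be unique within
    (construct, treatment).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"construct", "treatment", "replicate", "firefly", "renilla"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (df["firefly"] <= 0).any() or (df["renilla"] <= 0).any():
            raise ValueError("luminescence signals must be positive")
    else:
        df = pd.DataFrame(
            {
                "construct": [r.construct for r in records],
                "treatment": [r.treatment for r in records],
                "replicate": [r.replicate for r in records],
                "firefly": [r.firefly for r in records],
                "renilla": [r.renilla for r in records],
            }
        )
    if df.duplicated(["construct", "treatment", "replicate"]).any():
        raise ValueError("replicate ids must be unique within construct/treatment")
    df["ratio"] = df["firefly"] / df["renilla"]
    return df


def fold_induction(
    hs: Sequence[float], ctrl: Sequence[float]
) -> float:
    """Mean heat-shock ratio over mean control ratio."""
    hs = np.asarray(hs, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if hs.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control mean is zero")
    return float(hs.mean()) / ctrl_mean


@lru_cache(maxsize=64)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


class GroupComparison:
    """One-way ANOVA + Tukey HSD + compact letter display for k groups.

    ``letters`` maps each group to its letter string; groups sharing any
    letter are not significantly different at ``alpha`` and vice versa
    (asserted at construction).  ``p_matrix`` (Tukey-adjusted pairwise
    p-values as a DataFrame) is computed lazily on first access.
    """

    def __init__(self, groups: Mapping[str, Sequence[float]], alpha: float = 0.05):
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        self.alpha = float(alpha)
        self.group_names: tuple[str, ...] = tuple(groups)
        self._data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        for g, v in self._data.items():
            if v.size < 2:
                raise ValueError(f"group {g!r} has n < 2")
        self.n = {g: int(v.size) for g, v in self._data.items()}
        self.means = {g: float(v.mean()) for g, v in self._data.items()}
        self.sds = {g: float(v.std(ddof=1)) for g, v in self._data.items()}
        k = len(self.group_names)
        N = sum(self.n.values())
        self.df_within = N - k
        # Pooled within-group variance (Tukey's MSE).
        sse = sum(((v - v.mean()) ** 2).sum() for v in self._data.values())
        self.mse = float(sse) / self.df_within

        # One-way ANOVA; the all-identical boundary (MSE = 0, equal means)
        # is reported as F = 0, p = 1 rather than scipy's NaN.
        grand = sum(v.sum() for v in self._data.values()) / N
        ssb = sum(
            self.n[g] * (self.means[g] - grand) ** 2 for g in self.group_names
        )
        if self.mse > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*self._data.values())
            self.F, self.p_anova = float(f), float(p)
        elif ssb == 0:
            self.F, self.p_anova = 0.0, 1.0
        else:
            self.F, self.p_anova = float("inf"), 0.0

        # Tukey-Kramer q statistics and significance decisions.
        self._q = {}
        for g1, g2 in itertools.combinations(self.group_names, 2):
            se = np.sqrt(self.mse / 2.0 * (1.0 / self.n[g1] + 1.0 / self.n[g2]))
            diff = abs(self.means[g1] - self.means[g2])
            if se > 0:
                q = diff / se
            else:
                q = 0.0 if diff == 0 else float("inf")
            self._q[(g1, g2)] = q
        qc = _q_crit(self.alpha, k, self.df_within)
        self.significant = {
            pair: q > qc for pair, q in self._q.items()
        }
        self._p_matrix: pd.DataFrame | None = None
        self.letters = self._letter_display()
        self._assert_letter_consistency()

    # -- Tukey-adjusted p-values (lazy: the studentized-range survival
    # function is expensive and not needed for decisions or letters) --
    @property
    def p_matrix(self) -> pd.DataFrame:
        if self._p_matrix is None:
            names = self.group_names
            k = len(names)
            mat = pd.DataFrame(
                np.ones((k, k)), index=names, columns=names, dtype=float
            )
            finite = {
                pair: q for pair, q in self._q.items() if np.isfinite(q)
            }
            if finite:
                qs = np.array(list(finite.values()))
                ps = stats.studentized_range.sf(qs, k, self.df_within)
                ps = np.clip(ps, 0.0, 1.0)
                for (g1, g2), p in zip(finite.keys(), ps):
                    mat.loc[g1, g2] = mat.loc[g2, g1] = float(p)
            for (g1, g2), q in self._q.items():
                if not np.isfinite(q):
                    mat.loc[g1, g2] = mat.loc[g2, g1] = 0.0
            self._p_matrix = mat
        return self._p_matrix

    def _letter_display(self) -> dict[str, str]:
        """Insert-and-absorb compact letter display.

        Start with one column holding all groups; for each significant pair,
        split every column containing both into two (one without each group)
        and absorb columns that became subsets of others.  Columns are then
        lettered in order of the best (highest-mean) group they contain.
        """
        names = list(self.group_names)
        columns: list[frozenset[str]] = [frozenset(names)]
        for (g1, g2), sig in self.significant.items():
            if not sig:
                continue
            new_cols: list[frozenset[str]] = []
            for col in columns:
                if g1 in col and g2 in col:
                    new_cols.append(col - {g1})
                    new_cols.append(col - {g2})
                else:
                    new_cols.append(col)
            # absorb: drop duplicates and proper subsets
            uniq = set(new_cols)
            columns = [
                c
                for c in uniq
                if c and not any(c < other for other in uniq)
            ]
        rank = {
            g: i
            for i, g in enumerate(
                sorted(names, key=lambda g: -self.means[g])
            )
        }
        columns.sort(key=lambda col: min(rank[g] for g in col))
        letters: dict[str, list[str]] = {g: [] for g in names}
        for i, col in enumerate(columns):
            ch = chr(ord("a") + i)
            for g in col:
                letters[g].append(ch)
        return {g: "".join(sorted(v)) for g, v in letters.items()}

    def _assert_letter_consistency(self) -> None:
        for (g1, g2), sig in self.significant.items():
            share = bool(set(self.letters[g1]) & set(self.letters[g2]))
            if share == sig:
                raise AssertionError(
                    f"letter display inconsistent for pair ({g1}, {g2})"
                )

    def any_difference(self) -> bool:
        """True iff any pair of groups carries no shared letter."""
        return any(self.significant.values())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_names,
                "n": [self.n[g] for g in self.group_names],
                "mean": [self.means[g] for g in self.group_names],
                "sd": [self.sds[g] for g in self.group_names],
                "letters": [self.letters[g] for g in self.group_names],
            }
        )


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc and compact letter display."""
    return GroupComparison(groups, alpha=alpha)


def two_sample_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Independent-samples t test (Welch by default): (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def analyze_assay(
    df: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Full assay workup from a normalised ratio table.

    Within each treatment, constructs are compared by ANOVA + Tukey with
    letters; per construct, fold induction (heat shock over control) and the
    Welch t test between treatments are reported.
    """
    if "ratio" not in df.columns:
        df = normalize(df)
    out: dict = {"treatments": {}, "constructs": {}}
    for treatment, sub in df.groupby("treatment"):
        groups = {
            c: g["ratio"].to_numpy() for c, g in sub.groupby("construct")
        }
        if len(groups) >= 2:
            out["treatments"][treatment] = compare_groups(groups, alpha=alpha)
    for construct, sub in df.groupby("construct"):
        hs = sub.loc[sub["treatment"] == "heat_shock", "ratio"].to_numpy()
        ctrl = sub.loc[sub["treatment"] == "control", "ratio"].to_numpy()
        entry: dict = {}
        if hs.size and ctrl.size:
            entry["fold_induction"] = fold_induction(hs, ctrl)
        if hs.size >= 2 and ctrl.size >= 2:
            t, p = two_sample_test(hs, ctrl)
            entry["t"] = t
            entry["p"] = p
        out["constructs"][construct] = entry
    return out


def load_luminescence_tsv(path) -> pd.DataFrame:
    """Read a replicate table: construct, treatment, replicate, firefly, renilla."""
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "treatment", "replicate", "firefly", "renilla"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
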