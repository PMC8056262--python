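"""Top-N clonotype extraction, multi-sample overlap, and frequency tracking.

Frequency changes of a clonotype between two samples are tested with a
Pearson chi-squared comparison of proportions on the 2x2 table

                    sample 1    sample 2
    clonotype          x1          x2
    all others       n1-x1       n2-x2

with 1 df and no continuity correction by default. A clonotype is called
``up`` (``down``) when p < alpha and its proportion increased (decreased)
from sample 1 to sample 2, else ``no_change``. No multiple-testing
correction is applied by default; a Benjamini-Hochberg option exists.

When a clonotype is absent from one sample the test is still computed but
flagged; ``strict_absence`` withholds the p-value instead (reported as
``not_tested``), mirroring reports that mark such entries "n.d.".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire_io import ClonotypeTable, SampleMeta

DIRECTIONS = ("up", "down", "no_change", "not_tested")


@dataclass
class TopNList:
    """The n highest-template clonotypes of one sample.

    ``repertoire_fraction`` is the share of all sampled templates carried
    by the returned entries (the "percent of the total sampled repertoire").
    """

    meta: SampleMeta
    n_requested: int
    entries: pd.DataFrame  # columns rank, cdr3_aa, templates, frequency
    repertoire_fraction: float

    def cdr3_set(self) -> set[str]:
        return set(self.entries["cdr3_aa"])


@dataclass
class FrequencyComparison:
    """Two-proportion chi-squared result for one clonotype across two samples."""

    cdr3_aa: str
    x1: int
    n1: int
    x2: int
    n2: int
    chi2: float
    p: float
    direction: str
    alpha: float
    absent_in: int | None = None  # 1 or 2 when the clonotype has zero templates there
    in_top_a: bool | None = None
    in_top_b: bool | None = None
    p_adjusted: float | None = None


def top_n(table: ClonotypeTable, n: int = 50) -> TopNList:
    """Extract the top-n clonotypes by template count.

    Ties at the boundary are broken by lexicographic CDR3 (deterministic);
    tables with fewer than n clonotypes return everything.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    df = table.df.sort_values(
        ["templates", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    ).head(n)
    entries = df[["cdr3_aa", "templates", "frequency"]].reset_index(drop=True)
    entries.insert(0, "rank", np.arange(1, len(entries) + 1))
    return TopNList(
        meta=table.meta,
        n_requested=n,
        entries=entries,
        repertoire_fraction=float(entries["frequency"].sum()),
    )


def overlap(
    sets: Sequence[Iterable[str]], labels: Sequence[str] | None = None
) -> dict[frozenset, int]:
    """Exclusive Venn-region counts for 2-4 clonotype sets.

    Returns a mapping from each non-empty combination of set labels to the
    number of elements belonging to exactly those sets; region counts sum
    to the size of the union.
    """
    sets = [set(s) for s in sets]
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"overlap supports 2-4 sets, got {len(sets)}")
    if any(len(s) == 0 for s in sets):
        raise ValueError("overlap requires non-empty sets")
    if labels is None:
        labels = [str(i + 1) for i in range(len(sets))]
    if len(labels) != len(sets):
        raise ValueError("labels must match sets in length")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = set.intersection(*(sets[i] for i in combo))
            outside = set.union(
                set(), *(sets[i] for i in range(len(sets)) if i not in combo)
            )
            regions[frozenset(labels[i] for i in combo)] = len(inside - outside)
    return regions


def _pearson_chi2(x1: int, n1: int, x2: int, n2: int, yates: bool) -> tuple[float, float]:
    """Closed-form Pearson chi-squared (1 df) for the 2x2 proportions table.

    Equals the square of the pooled two-proportion z statistic. Degenerate
    margins (pooled proportion 0 or 1) carry no signal: chi2 = 0, p = 1.
    """
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    total = n1 + n2
    row1, row2 = a + c, b + d
    if row1 == 0 or row2 == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - total / 2.0)
    chi2 = total * diff * diff / (row1 * row2 * n1 * n2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compare_frequency(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alpha: float = 0.05,
    yates: bool = False,
    cdr3_aa: str = "",
    strict_absence: bool = False,
) -> FrequencyComparison:
    """Test whether a clonotype's frequency differs between two samples."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample totals must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("clonotype counts must satisfy 0 <= x <= n")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    absent_in = 1 if x1 == 0 else (2 if x2 == 0 else None)
    if x1 == 0 and x2 == 0:
        return FrequencyComparison(
            cdr3_aa, x1, n1, x2, n2,
            chi2=float("nan"), p=float("nan"),
            direction="not_tested", alpha=alpha, absent_in=absent_in,
        )
    if strict_absence and absent_in is not None:
        return FrequencyComparison(
            cdr3_aa, x1, n1, x2, n2,
            chi2=float("nan"), p=float("nan"),
            direction="not_tested", alpha=alpha, absent_in=absent_in,
        )
    chi2, p = _pearson_chi2(x1, n1, x2, n2, yates)
    p1, p2 = x1 / n1, x2 / n2
    if p < alpha and p2 > p1:
        direction = "up"
    elif p < alpha and p2 < p1:
        direction = "down"
    else:
        direction = "no_change"
    return FrequencyComparison(
        cdr3_aa, x1, n1, x2, n2, chi2=chi2, p=p,
        direction=direction, alpha=alpha, absent_in=absent_in,
    )


def track(
    table_a: ClonotypeTable,
    table_b: ClonotypeTable,
    universe: Iterable[str],
    alpha: float = 0.05,
    yates: bool = False,
    strict_absence: bool = False,
    bh_correct: bool = False,
    top_n_size: int = 50,
) -> list[FrequencyComparison]:
    """Test every universe clonotype present in at least one table.

    The universe is typically a top-N list or a multi-sample intersection.
    Each comparison carries membership flags against the two samples'
    top-``top_n_size`` lists. With ``bh_correct`` the direction calls use
    Benjamini-Hochberg adjusted p-values (off by default).
    """
    counts_a = dict(zip(table_a.df["cdr3_aa"], table_a.df["templates"]))
    counts_b = dict(zip(table_b.df["cdr3_aa"], table_b.df["templates"]))
    n1, n2 = table_a.total_templates, table_b.total_templates
    top_a = top_n(table_a, top_n_size).cdr3_set()
    top_b = top_n(table_b, top_n_size).cdr3_set()
    results: list[FrequencyComparison] = []
    for cdr3 in sorted(set(universe)):
        x1 = int(counts_a.get(cdr3, 0))
        x2 = int(counts_b.get(cdr3, 0))
        if x1 == 0 and x2 == 0:
            continue  # absent from both tables: nothing to test
        comp = compare_frequency(
            x1, n1, x2, n2, alpha=alpha, yates=yates,
            cdr3_aa=cdr3, strict_absence=strict_absence,
        )
        comp.in_top_a = cdr3 in top_a
        comp.in_top_b = cdr3 in top_b
        results.append(comp)
    if bh_correct:
        _apply_bh(results, alpha)
    return results


def _apply_bh(results: list[FrequencyComparison], alpha: float) -> None:
    tested = [r for r in results if r.direction != "not_tested"]
    if not tested:
        return
    ps = np.array([r.p for r in tested])
    order = np.argsort(ps)
    m = len(ps)
    adjusted = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        idx = order[pos]
        running_min = min(running_min, ps[idx] * m / (pos + 1))
        adjusted[idx] = running_min
    for r, p_adj in zip(tested, adjusted):
        r.p_adjusted = float(p_adj)
        if p_adj >= alpha:
            r.direction = "no_change"
        else:
            r.direction = "up" if (r.x2 / r.n2) > (r.x1 / r.n1) else "down"


def comparisons_to_frame(results: Sequence[FrequencyComparison]) -> pd.DataFrame:
    """Tabulate comparisons in a report-table layout (direction as ASCII token)."""
    rows = [
        {
            "cdr3_aa": r.cdr3_aa,
            "x1": r.x1, "n1": r.n1, "x2": r.x2, "n2": r.n2,
            "freq1": r.x1 / r.n1, "freq2": r.x2 / r.n2,
            "chi2": r.chi2, "p": r.p,
            "direction": {"up": "up", "down": "down",
                          "no_change": "nc", "not_tested": "nd"}[r.direction],
            "in_top_a": r.in_top_a, "in_top_b": r.in_top_b,
            "absent_in": r.absent_in,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
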