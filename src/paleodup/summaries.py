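"""Aggregate duplication calls into summary tables and downstream statistics.

Covers: per-method/threshold orthogroup summary tables, retention-pattern
distributions, the human-vs-plant copy-number Spearman correlation, a
permutation test for the difference between two groups' correlations, and
one-sided hypergeometric term enrichment with Bonferroni correction.

All printed percentages use round-half-away-from-zero to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .duplications import PATTERNS, DuplicationCall
from .errors import AnalysisInputError
from .orthogroups import Orthogroup

__all__ = [
    "SummaryTable",
    "round_half_away",
    "build_summary",
    "summary_from_counts",
    "pattern_distribution",
    "copy_number_spearman",
    "correlation_difference_permutation_test",
    "term_for_term_enrichment",
]


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round with halves going away from zero (1 decimal by default)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _pct(dup: int, total: int) -> float:
    if total == 0:
        return 0.0
    q = (Decimal(dup) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class SummaryTable:
    """Orthogroup tally for one (method, threshold, criterion) combination."""

    method: str
    threshold: float
    criterion: str  # "relaxed" or "stringent"
    type1_with_duplication: int
    type1_total: int
    type2_with_duplication: int
    type2_total: int

    def __post_init__(self):
        if not (0 <= self.type1_with_duplication <= self.type1_total):
            raise AnalysisInputError("type I duplication count exceeds total")
        if not (0 <= self.type2_with_duplication <= self.type2_total):
            raise AnalysisInputError("type II duplication count exceeds total")

    @property
    def total_with_duplication(self) -> int:
        return self.type1_with_duplication + self.type2_with_duplication

    @property
    def total(self) -> int:
        return self.type1_total + self.type2_total

    @property
    def percentage(self) -> float:
        """100 × with-duplication / total, one decimal, halves away from 0."""
        return _pct(self.total_with_duplication, self.total)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "criterion": self.criterion,
            "type1_dup": self.type1_with_duplication,
            "type1_total": self.type1_total,
            "type2_dup": self.type2_with_duplication,
            "type2_total": self.type2_total,
            "total_dup": self.total_with_duplication,
            "total": self.total,
            "percentage": self.percentage,
        }


def summary_from_counts(
    type1_dup: int,
    type1_total: int,
    type2_dup: int,
    type2_total: int,
    method: str = "",
    threshold: float = 50.0,
    criterion: str = "relaxed",
) -> SummaryTable:
    """Summary arithmetic from externally supplied orthogroup counts."""
    return SummaryTable(
        method, threshold, criterion, type1_dup, type1_total, type2_dup, type2_total
    )


def build_summary(
    orthogroups: Sequence[Orthogroup],
    calls: Sequence[DuplicationCall],
    method: str = "",
    threshold: float = 50.0,
    criterion: str = "relaxed",
) -> SummaryTable:
    """Count orthogroups (not events) with at least one accepted call.

    Every call must reference an orthogroup in the inventory.
    """
    by_id = {og.orthogroup_id: og for og in orthogroups}
    with_dup: set[str] = set()
    for call in calls:
        if call.orthogroup_id not in by_id:
            raise AnalysisInputError(
                f"call references unknown orthogroup {call.orthogroup_id!r}"
            )
        with_dup.add(call.orthogroup_id)
    t1_total = sum(1 for og in orthogroups if og.og_type == "I")
    t2_total = sum(1 for og in orthogroups if og.og_type == "II")
    t1_dup = sum(1 for oid in with_dup if by_id[oid].og_type == "I")
    t2_dup = sum(1 for oid in with_dup if by_id[oid].og_type == "II")
    return SummaryTable(method, threshold, criterion, t1_dup, t1_total, t2_dup, t2_total)


def pattern_distribution(patterns: Iterable[str]) -> pd.DataFrame:
    """Counts and one-decimal percentage shares per retention pattern.

    Input: one pattern label per duplicated orthogroup.
    """
    patterns = list(patterns)
    unknown = set(patterns) - set(PATTERNS)
    if unknown:
        raise AnalysisInputError(f"unknown pattern labels: {sorted(unknown)}")
    total = len(patterns)
    rows = []
    for label in PATTERNS:
        count = patterns.count(label)
        rows.append(
            {"pattern": label, "count": count, "share": _pct(count, total)}
        )
    frame = pd.DataFrame(rows)
    frame.attrs["total"] = total
    return frame


# ---------------------------------------------------------------------------
# copy-number statistics
# ---------------------------------------------------------------------------

def _group_counts(table: pd.DataFrame, group: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table[table["group"] == group]
    if len(sub) < 3:
        raise AnalysisInputError(
            f"group {group!r} has {len(sub)} families; need at least 3"
        )
    return sub["count_a"].to_numpy(float), sub["count_b"].to_numpy(float)


def copy_number_spearman(table: pd.DataFrame, group: str) -> float:
    """Spearman rank correlation of per-family copy counts (columns
    ``count_a``, ``count_b``; rows selected by ``group``), with average-rank
    tie handling."""
    a, b = _group_counts(table, group)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise AnalysisInputError("constant copy-number vector: correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _rho(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(ra, rb)[0, 1]
    return float(r)


def correlation_difference_permutation_test(
    table: pd.DataFrame,
    n_perm: Optional[int] = 999,
    seed: int = 0,
) -> dict:
    """Permutation test for a difference between two groups' Spearman
    correlations.

    Statistic: |rho_A − rho_B| over the table's two group labels.  The null
    is generated by reassigning group labels at random while preserving group
    sizes.  With ``n_perm=None`` all label assignments are enumerated exactly
    and p = #{assignment statistic ≥ observed} / #assignments; otherwise the
    add-one Monte-Carlo estimator p = (1 + #{perm ≥ observed}) / (1 + n_perm)
    is used.  Invariant to input row order; reproducible given (seed,
    n_perm).
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise AnalysisInputError(f"need exactly 2 groups, got {groups}")
    ordered = table.sort_values(["group", "count_a", "count_b"], kind="mergesort")
    a1, b1 = _group_counts(ordered, groups[0])
    a2, b2 = _group_counts(ordered, groups[1])
    for a, b in ((a1, b1), (a2, b2)):
        if np.all(a == a[0]) or np.all(b == b[0]):
            raise AnalysisInputError("degenerate group: constant copy numbers")
    observed = abs(_rho(a1, b1) - _rho(a2, b2))
    all_a = np.concatenate([a1, a2])
    all_b = np.concatenate([b1, b2])
    n1 = len(a1)
    n = len(all_a)
    eps = 1e-12

    def stat(idx1: np.ndarray) -> float:
        mask = np.zeros(n, bool)
        mask[idx1] = True
        return abs(
            _rho(all_a[mask], all_b[mask]) - _rho(all_a[~mask], all_b[~mask])
        )

    if n_perm is None:
        stats_null = [
            stat(np.fromiter(idx, int)) for idx in combinations(range(n), n1)
        ]
        hits = sum(1 for s in stats_null if s >= observed - eps)
        p = hits / len(stats_null)
        n_used = len(stats_null)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            idx1 = rng.choice(n, size=n1, replace=False)
            if stat(idx1) >= observed - eps:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        n_used = n_perm
    return {"statistic": observed, "p_value": p, "n_permutations": n_used}


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

def term_for_term_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric (upper tail) enrichment of annotation terms
    in a study set against a population, Bonferroni-corrected over the terms
    with at least one study annotation."""
    study = set(study)
    population = set(population)
    if not study <= population:
        raise AnalysisInputError("study set must be a subset of the population")
    term_items: dict[str, set[str]] = {}
    for item, terms in annotations.items():
        if item not in population:
            continue
        for term in terms:
            term_items.setdefault(term, set()).add(item)
    tested = {t: items for t, items in term_items.items() if items & study}
    m = len(tested)
    rows = []
    N = len(population)
    n = len(study)
    for term in sorted(tested):
        items = tested[term]
        K = len(items)
        k = len(items & study)
        raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        adj = min(1.0, raw * m)
        rows.append(
            {
                "term": term,
                "study_count": k,
                "pop_count": K,
                "raw_p": raw,
                "adj_p": adj,
                "significant": adj <= alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "study_count", "pop_count", "raw_p", "adj_p", "significant"]
    )
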