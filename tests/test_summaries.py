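"""Summary arithmetic, correlation statistics and term enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleodup.duplications import detect_duplications
from paleodup.errors import AnalysisInputError
from paleodup.orthogroups import delineate_orthogroups
from paleodup.summaries import (
    build_summary,
    copy_number_spearman,
    correlation_difference_permutation_test,
    pattern_distribution,
    round_half_away,
    summary_from_counts,
    term_for_term_enrichment,
)
from paleodup.trees import parse_newick

# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def test_summary_arithmetic_printed_counts():
    table = summary_from_counts(205, 522, 100, 235)
    assert table.total_with_duplication == 305
    assert table.total == 757
    assert table.percentage == 40.3


def test_summary_arithmetic_stringent_counts():
    assert summary_from_counts(136, 522, 63, 235).percentage == 26.3


def test_zero_calls_zero_percentage():
    assert summary_from_counts(0, 10, 0, 5).percentage == 0.0


def test_dup_count_cannot_exceed_total():
    with pytest.raises(AnalysisInputError):
        summary_from_counts(11, 10, 0, 5)


@pytest.mark.parametrize("seed", range(20))
def test_summary_identities_random_counts(seed):
    rng = np.random.default_rng(seed)
    t1, t2 = int(rng.integers(1, 500)), int(rng.integers(1, 500))
    d1, d2 = int(rng.integers(0, t1 + 1)), int(rng.integers(0, t2 + 1))
    table = summary_from_counts(d1, t1, d2, t2)
    assert table.total == t1 + t2
    assert table.total_with_duplication == d1 + d2
    assert table.percentage == round_half_away(100 * (d1 + d2) / (t1 + t2))


def test_round_half_away_from_zero():
    assert round_half_away(0.05) == 0.1
    assert round_half_away(2.25) == 2.3
    assert round_half_away(-0.05) == -0.1
    assert round_half_away(36.65) == 36.7


def test_build_summary_from_screen(taxa):
    trees = [
        parse_newick("((Eco_1,Bsu_1)99,((Ath_1,Hsa_1)90,(Ath_2,Sce_1)85)80);", name="t1"),
        parse_newick("((Eco_2,Bsu_2)99,(Ath_3,(Hsa_3,Sce_3)80)75);", name="t2"),
    ]
    ogs, calls = [], []
    for tree in trees:
        for og in delineate_orthogroups(tree, taxa):
            ogs.append(og)
            calls.extend(detect_duplications(og, taxa, 50))
    table = build_summary(ogs, calls, "NJ-BS", 50, "relaxed")
    assert table.type1_total == 2
    assert table.type1_with_duplication == 1
    assert table.percentage == 50.0


def test_build_summary_unknown_orthogroup(taxa):
    tree = parse_newick("((Eco_1,Bsu_1)99,((Ath_1,Hsa_1)90,(Ath_2,Sce_1)85)80);", name="t1")
    (og,) = delineate_orthogroups(tree, taxa)
    calls = detect_duplications(og, taxa, 50)
    with pytest.raises(AnalysisInputError, match="unknown orthogroup"):
        build_summary([], calls)


def test_pattern_distribution_printed_row():
    patterns = ["RO_RO"] * 73 + ["RO_R"] * 56 + ["RO_O"] * 59 + ["OTHER"] * 11
    frame = pattern_distribution(patterns)
    assert frame.attrs["total"] == 199
    shares = dict(zip(frame["pattern"], frame["share"]))
    assert shares == {"RO_RO": 36.7, "RO_R": 28.1, "RO_O": 29.6, "OTHER": 5.5}


def test_pattern_distribution_single():
    frame = pattern_distribution(["RO_RO"])
    assert frame.set_index("pattern").loc["RO_RO", "share"] == 100.0


@pytest.mark.parametrize("seed", range(5))
def test_pattern_distribution_matches_tally(seed):
    rng = np.random.default_rng(seed)
    labels = list(rng.choice(["RO_RO", "RO_R", "RO_O", "OTHER"], size=50))
    frame = pattern_distribution(labels)
    counts = dict(zip(frame["pattern"], frame["count"]))
    for label in counts:
        assert counts[label] == sum(1 for x in labels if x == label)
    assert frame["count"].sum() == 50


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def _table(a, b, group="g"):
    return pd.DataFrame({"count_a": a, "count_b": b, "group": group})


def test_spearman_perfect_monotone():
    assert copy_number_spearman(_table([1, 2, 3], [2, 4, 6]), "g") == 1.0
    assert copy_number_spearman(_table([1, 2, 3], [3, 2, 1]), "g") == -1.0


def test_spearman_with_ties_matches_hand_ranks():
    a = [1, 2, 2, 3, 4, 4]
    b = [2, 1, 3, 3, 3, 5]
    # hand-assigned average ranks
    ra = [1, 2.5, 2.5, 4, 5.5, 5.5]
    rb = [2, 1, 4, 4, 4, 6]
    expected = np.corrcoef(ra, rb)[0, 1]
    assert copy_number_spearman(_table(a, b), "g") == pytest.approx(expected)


def test_spearman_degenerate_vector():
    with pytest.raises(AnalysisInputError, match="constant"):
        copy_number_spearman(_table([2, 2, 2], [1, 2, 3]), "g")


def test_spearman_too_few_families():
    with pytest.raises(AnalysisInputError, match="at least 3"):
        copy_number_spearman(_table([1, 2], [1, 2]), "g")


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def test_identical_groups_p_is_one():
    a = _table([1, 2, 3, 5], [2, 3, 4, 1], "A")
    b = _table([1, 2, 3, 5], [2, 3, 4, 1], "B")
    result = correlation_difference_permutation_test(pd.concat([a, b]), 99, seed=0)
    assert result["statistic"] == pytest.approx(0.0)
    assert result["p_value"] == 1.0


def test_exhaustive_matches_independent_enumeration():
    a = _table([1, 2, 5], [2, 3, 9], "A")
    b = _table([3, 1, 4], [9, 2, 1], "B")
    table = pd.concat([a, b])
    result = correlation_difference_permutation_test(table, None)
    # independent oracle: enumerate all C(6,3)=20 assignments with scipy
    xs = [1, 2, 5, 3, 1, 4]
    ys = [2, 3, 9, 9, 2, 1]

    def rho(idx):
        sel = [i in idx for i in range(6)]
        g1 = ([x for x, s in zip(xs, sel) if s], [y for y, s in zip(ys, sel) if s])
        g2 = ([x for x, s in zip(xs, sel) if not s], [y for y, s in zip(ys, sel) if not s])
        return abs(
            stats.spearmanr(*g1).statistic - stats.spearmanr(*g2).statistic
        )

    observed = rho({0, 1, 2})
    null = [rho(set(c)) for c in itertools.combinations(range(6), 3)]
    expected_p = sum(1 for s in null if s >= observed - 1e-12) / 20
    assert result["n_permutations"] == 20
    assert result["p_value"] == pytest.approx(expected_p)
    assert result["statistic"] == pytest.approx(observed)


def test_permutation_invariant_to_row_order():
    rng = np.random.default_rng(4)
    a = _table(rng.integers(1, 30, 12), rng.integers(1, 30, 12), "A")
    b = _table(rng.integers(1, 30, 12), rng.integers(1, 30, 12), "B")
    table = pd.concat([a, b]).reset_index(drop=True)
    shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
    r1 = correlation_difference_permutation_test(table, 199, seed=3)
    r2 = correlation_difference_permutation_test(shuffled, 199, seed=3)
    assert r1 == r2


def test_permutation_null_calibration():
    """Groups drawn from the same distribution: p-values are not inflated
    (roughly uniform; few small p-values)."""
    rng = np.random.default_rng(12)
    pvals = []
    for _ in range(200):
        a = _table(rng.integers(1, 50, 10), rng.integers(1, 50, 10), "A")
        b = _table(rng.integers(1, 50, 10), rng.integers(1, 50, 10), "B")
        result = correlation_difference_permutation_test(
            pd.concat([a, b]), 49, seed=int(rng.integers(2**31))
        )
        pvals.append(result["p_value"])
    assert all(p > 0.0 for p in pvals)  # add-one estimator never hits 0
    assert np.mean(pvals) == pytest.approx(0.5, abs=0.1)
    assert np.mean(np.array(pvals) <= 0.05) <= 0.12


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def test_hypergeometric_closed_form():
    population = [f"i{k}" for k in range(10)]
    study = population[:5]
    annotations = {item: {"T"} for item in population[:4]}
    frame = term_for_term_enrichment(study, population, annotations)
    # P(X >= 4), X ~ Hypergeom(N=10, K=4, n=5) = C(4,4) C(6,1) / C(10,5)
    assert frame.loc[0, "raw_p"] == pytest.approx(6 / 252)


def test_term_covering_population_p_one():
    population = [f"i{k}" for k in range(8)]
    frame = term_for_term_enrichment(
        population[:3], population, {item: {"T"} for item in population}
    )
    assert frame.loc[0, "raw_p"] == pytest.approx(1.0)


def test_bonferroni_multiplies_by_tested_terms():
    population = [f"i{k}" for k in range(10)]
    study = population[:5]
    annotations = {item: {"T1"} for item in population[:4]}
    for k, item in enumerate(population):
        annotations.setdefault(item, set()).add(f"X{k % 4 + 2}")
    frame = term_for_term_enrichment(study, population, annotations).set_index("term")
    assert len(frame) == 5  # T1 plus 4 X-terms with study members
    assert frame.loc["T1", "adj_p"] == pytest.approx(min(1.0, 5 * 6 / 252))


def test_enrichment_matches_exact_combinatorics():
    rng = np.random.default_rng(3)
    population = [f"i{k}" for k in range(15)]
    study = list(rng.choice(population, size=6, replace=False))
    annotations = {
        item: {t for t in ("A", "B", "C") if rng.random() < 0.4}
        for item in population
    }
    frame = term_for_term_enrichment(study, population, annotations).set_index("term")
    N, n = 15, 6
    for term in frame.index:
        items = {i for i, ts in annotations.items() if term in ts}
        K = len(items)
        k_obs = len(items & set(study))
        exact = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(k_obs, min(K, n) + 1)
        )
        assert frame.loc[term, "raw_p"] == pytest.approx(exact)


def test_study_must_be_subset():
    with pytest.raises(AnalysisInputError, match="subset"):
        term_for_term_enrichment(["x"], ["a", "b"], {})
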