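"""Synthetic gene-family generator: truth logs, replay, supports, LBA,
copy-number tables."""

import numpy as np
import pytest

from paleodup.duplications import detect_duplications
from paleodup.errors import AnalysisInputError
from paleodup.orthogroups import delineate_orthogroups
from paleodup.simulate import (
    SPECIES_LINEAGES,
    SimulationConfig,
    SupportModel,
    assign_supports,
    corrupt_with_lba,
    default_taxon_map,
    simulate_batch,
    simulate_copy_numbers,
    simulate_family,
)
from paleodup.summaries import copy_number_spearman
from paleodup.trees import GeneTree, Node, root_by_prokaryotes, write_newick

EUK = ["Ath", "Ppa", "Cre", "Hsa", "Tru", "Spu", "Sce", "Spo"]
PROK = ["Eco", "Rpr", "Bsu", "Mac", "Sso", "Pae"]


# ---------------------------------------------------------------------------
# basic generative contracts
# ---------------------------------------------------------------------------


def test_zero_rates_single_copy_families():
    config = SimulationConfig(p_early=0.0, dup_rate=0.0, loss_rate=0.0, seed=5)
    for fam in range(10):
        record = simulate_family(config, fam)
        assert record.events == ()
        assert all(record.copy_counts[sp] == 1 for sp in EUK + PROK)
        assert len(record.tree.leaves()) == 14


def test_forced_early_duplication_doubles_eukaryotes():
    config = SimulationConfig(p_early=1.0, dup_rate=0.0, loss_rate=0.0, seed=5)
    for fam in range(10):
        record = simulate_family(config, fam)
        kinds = [e["kind"] for e in record.events]
        assert kinds == ["early_duplication"]
        assert all(record.copy_counts[sp] == 2 for sp in EUK)
        assert all(record.copy_counts[sp] == 1 for sp in PROK)


def test_copy_counts_equal_leaf_tallies():
    taxa = default_taxon_map()
    config = SimulationConfig(p_early=0.5, dup_rate=0.2, loss_rate=0.15, seed=9)
    for record in simulate_batch(config, 25):
        tally = {sp: 0 for sp in SPECIES_LINEAGES}
        for leaf in record.tree.leaves():
            tally[taxa.species_of(leaf.label)] += 1
        assert tally == record.copy_counts


def test_deterministic_given_seed_and_family():
    config = SimulationConfig(p_early=0.4, dup_rate=0.3, loss_rate=0.2, seed=21)
    a = simulate_family(config, 7)
    b = simulate_family(config, 7)
    assert a.events == b.events
    assert write_newick(a.tree) == write_newick(b.tree)
    c = simulate_family(config, 8)
    assert write_newick(c.tree) != write_newick(a.tree)


def test_poisson_event_rate_on_single_branch():
    """Duplication events on the branch into the Archaeplastida ancestor are
    Poisson(dup_rate) per entering lineage; with p_early = 0 exactly one
    lineage enters, so the batch mean must sit within 3 standard errors."""
    lam = 0.4
    n = 2000
    config = SimulationConfig(p_early=0.0, dup_rate=lam, loss_rate=0.0, seed=17)
    counts = []
    for record in simulate_batch(config, n):
        counts.append(
            sum(
                1
                for e in record.events
                if e["kind"] == "lineage_duplication"
                and e["branch"] == "R"
                and e["lineage"] == "L"
            )
        )
    se = np.sqrt(lam / n)
    assert abs(np.mean(counts) - lam) < 3 * se


def test_discarded_families_are_resimulated():
    config = SimulationConfig(p_early=0.0, dup_rate=0.0, loss_rate=3.0, seed=13)
    record = simulate_family(config, 0)
    # heavy loss forces discards, yet the returned family has eukaryotes
    taxa = default_taxon_map()
    assert any(taxa.is_eukaryote(l.label) for l in record.tree.leaves())


# ---------------------------------------------------------------------------
# event-log replay cross-check
# ---------------------------------------------------------------------------

_TOPOLOGY = (
    "euk",
    [
        ("R", [("AthPpa", ["Ath", "Ppa"]), "Cre"]),
        (
            "O",
            [
                ("animals", [("HsaTru", ["Hsa", "Tru"]), "Spu"]),
                ("fungi", ["Sce", "Spo"]),
            ],
        ),
    ],
)


def _independent_replay(events, family_id):
    """A second, independently written replayer: reconstruct the eukaryotic
    subtree purely from the event log."""
    dups = {}
    lost = set()
    early = False
    for e in events:
        if e["kind"] == "early_duplication":
            early = True
        elif e["kind"] == "lineage_duplication":
            dups[(e["branch"], e["lineage"])] = dups.get((e["branch"], e["lineage"]), 0) + 1
        elif e["kind"] == "loss":
            lost.add((e["branch"], e["lineage"]))
    leaf_counter = {}

    def descend(spec, lineage):
        name = spec if isinstance(spec, str) else spec[0]
        n_copies = dups.get((name, lineage), 0) + 1
        ids = [f"{lineage}/{name}.{i}" for i in range(n_copies)]
        ids = [i for i in ids if (name, i) not in lost]
        built = []
        for cid in ids:
            if isinstance(spec, str):
                idx = leaf_counter.get(name, 0)
                leaf_counter[name] = idx + 1
                built.append(Node(label=f"{name}_{family_id}_{idx}"))
            else:
                subs = [descend(child, cid) for child in spec[1]]
                subs = [s for s in subs if s is not None]
                if not subs:
                    continue
                if len(subs) == 1:
                    built.append(subs[0])
                else:
                    node = Node()
                    for s in subs:
                        node.add_child(s)
                    built.append(node)
        if not built:
            return None
        acc = built[0]
        for extra in built[1:]:
            j = Node()
            j.add_child(acc)
            j.add_child(extra)
            acc = j
        return acc

    lineages = ["L/stem.0", "L/stem.1"] if early else ["L"]
    tops = []
    for lin in lineages:
        subs = [descend(child, lin) for child in _TOPOLOGY[1]]
        subs = [s for s in subs if s is not None]
        if not subs:
            continue
        tops.append(subs[0] if len(subs) == 1 else _join(subs))
    if not tops:
        return None
    return tops[0] if len(tops) == 1 else _join(tops)


def _join(subs):
    node = Node()
    for s in subs:
        node.add_child(s)
    return node


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_replaying_event_log_reproduces_emitted_tree(seed):
    config = SimulationConfig(p_early=0.5, dup_rate=0.25, loss_rate=0.2, seed=seed)
    taxa = default_taxon_map()
    for record in simulate_batch(config, 40):
        euk_replayed = _independent_replay(list(record.events), record.family_id)
        assert euk_replayed is not None
        # compare against the eukaryotic half of the emitted tree
        euk_emitted = [
            child
            for child in record.tree.root.children
            if all(taxa.is_eukaryote(l.label) for l in child.leaves())
        ]
        assert len(euk_emitted) == 1
        assert write_newick(GeneTree(euk_replayed)) == write_newick(
            GeneTree(euk_emitted[0].copy())
        )


# ---------------------------------------------------------------------------
# supports
# ---------------------------------------------------------------------------


def test_noise_free_supports_are_base():
    config = SimulationConfig(p_early=1.0, dup_rate=0.0, loss_rate=0.0, seed=2)
    record = assign_supports(
        simulate_family(config, 0), SupportModel(100.0, 100.0, 0.0), seed=2
    )
    for node in record.tree.internal_nodes():
        if node is not record.tree.root:
            assert node.support == 100.0


def test_supports_reproducible_and_bounded():
    config = SimulationConfig(p_early=0.5, dup_rate=0.2, loss_rate=0.1, seed=6)
    model = SupportModel(95.0, 55.0, 60.0)
    for record in simulate_batch(config, 30):
        once = assign_supports(record, model, seed=8)
        twice = assign_supports(record, model, seed=8)
        assert write_newick(once.tree) == write_newick(twice.tree)
        for node in once.tree.internal_nodes():
            if node is not once.tree.root:
                assert 0.0 <= node.support <= 100.0


def test_discordant_clades_get_lower_base():
    config = SimulationConfig(p_early=1.0, dup_rate=0.0, loss_rate=0.0, seed=3)
    record = assign_supports(
        simulate_family(config, 1), SupportModel(90.0, 40.0, 0.0), seed=3
    )
    supports = {n.support for n in record.tree.internal_nodes() if n is not record.tree.root}
    # species-tree clades get 90; the duplication joint (all eight species on
    # both sides) is concordant with the eukaryote clade, so 40 never occurs
    # in this loss-free family
    assert supports == {90.0}


# ---------------------------------------------------------------------------
# long-branch corruption
# ---------------------------------------------------------------------------


def test_lba_moves_target_basal_and_keeps_leaves():
    config = SimulationConfig(p_early=0.0, dup_rate=0.0, loss_rate=0.0, seed=4)
    record = assign_supports(simulate_family(config, 0), SupportModel(100, 100, 0), 4)
    corrupted = corrupt_with_lba(record, "Spo", seed=4)
    assert corrupted.lba_corrupted
    assert corrupted.tree.leaf_labels() == record.tree.leaf_labels()
    assert corrupted.events[-1]["kind"] == "lba_corrupted"
    taxa = default_taxon_map()
    rooted = root_by_prokaryotes(corrupted.tree, taxa)
    (og,) = delineate_orthogroups(rooted, taxa)
    spo_child = [
        c for c in og.root.children if c.leaf_labels() == frozenset({f"Spo_0_0"})
    ]
    assert spo_child, "Spo leaf should sit basally in the eukaryotic clade"


def test_lba_creates_relaxed_but_not_stringent_false_positive():
    config = SimulationConfig(p_early=0.0, dup_rate=0.0, loss_rate=0.0, seed=4)
    taxa = default_taxon_map()
    for fam in range(10):
        record = assign_supports(simulate_family(config, fam), SupportModel(100, 100, 0), 4)
        corrupted = corrupt_with_lba(record, "Spo", seed=4)
        rooted = root_by_prokaryotes(corrupted.tree, taxa)
        (og,) = delineate_orthogroups(rooted, taxa)
        assert detect_duplications(og, taxa, 50, stringent=False)
        assert not detect_duplications(og, taxa, 50, stringent=True)


def test_lba_absent_species_error():
    config = SimulationConfig(p_early=0.0, dup_rate=0.0, loss_rate=0.0, seed=4)
    record = simulate_family(config, 0)
    with pytest.raises(AnalysisInputError, match="absent"):
        corrupt_with_lba(record, "Xen", seed=1)


# ---------------------------------------------------------------------------
# copy-number tables
# ---------------------------------------------------------------------------


def test_comonotone_target_exact():
    table = simulate_copy_numbers(200, 1.0, "dup", seed=1)
    assert copy_number_spearman(table, "dup") == 1.0


@pytest.mark.parametrize("target", [0.0, 0.6])
def test_copy_number_convergence(target):
    table = simulate_copy_numbers(5000, target, "g", seed=2)
    assert copy_number_spearman(table, "g") == pytest.approx(target, abs=0.05)


def test_copy_numbers_deterministic_and_validated():
    a = simulate_copy_numbers(50, 0.4, "g", seed=9)
    b = simulate_copy_numbers(50, 0.4, "g", seed=9)
    assert a.equals(b)
    assert (a[["count_a", "count_b"]] >= 0).all().all()
    with pytest.raises(AnalysisInputError):
        simulate_copy_numbers(50, 1.5, "g", seed=1)
    with pytest.raises(AnalysisInputError):
        simulate_copy_numbers(5, 0.5, "g", seed=1)
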