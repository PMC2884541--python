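"""Gene-family simulator with known duplication/loss histories.

Families evolve along a fixed 14-species phylogeny: three Archaeplastida
(Ath = *Arabidopsis*, Ppa = *Physcomitrella*, Cre = *Chlamydomonas*), three
animals (Hsa = human, Tru = pufferfish, Spu = sea urchin), two fungi (Sce =
budding yeast, Spo = fission yeast), three bacteria (Eco, Rpr, Bsu) and
three archaea (Mac, Sso, Pae).  The prokaryotes contribute one gene each and
form the basal outgroup; eukaryotic gene lineages descend from a single stem
gene that duplicates on the eukaryote stem (before the R/O split) with
probability ``p_early``, then accumulate per-branch Poisson duplications and
losses below the split.

Generation is two-phase: a sampling pass draws an explicit event log, and a
deterministic replay pass builds the gene tree from the log alone, so any
independent replayer reproduces the emitted tree exactly.  All randomness
flows from explicit seeds; a family is fully determined by (seed,
family_id).  Families losing every eukaryotic gene are discarded and
resimulated (counted), since empty families are unobservable in real
cluster data.

Leaves are named ``species_familyid_copyindex``, the convention resolved by
:class:`paleodup.taxa.TaxonMap`'s species-prefix fallback.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AnalysisInputError
from .taxa import Lineage, TaxonMap
from .trees import GeneTree, Node

__all__ = [
    "SPECIES_LINEAGES",
    "SupportModel",
    "SimulationConfig",
    "SimulationRecord",
    "default_taxon_map",
    "species_tree",
    "simulate_family",
    "simulate_batch",
    "assign_supports",
    "corrupt_with_lba",
    "simulate_copy_numbers",
]

SPECIES_LINEAGES: dict[str, Lineage] = {
    "Ath": Lineage.ARCHAEPLASTIDA,
    "Ppa": Lineage.ARCHAEPLASTIDA,
    "Cre": Lineage.ARCHAEPLASTIDA,
    "Hsa": Lineage.ANIMAL,
    "Tru": Lineage.ANIMAL,
    "Spu": Lineage.ANIMAL,
    "Sce": Lineage.FUNGUS,
    "Spo": Lineage.FUNGUS,
    "Eco": Lineage.BACTERIA,
    "Rpr": Lineage.BACTERIA,
    "Bsu": Lineage.BACTERIA,
    "Mac": Lineage.ARCHAEA,
    "Sso": Lineage.ARCHAEA,
    "Pae": Lineage.ARCHAEA,
}

# (name, children) nested species-tree description; leaf = species code.
_EUK_TOPOLOGY = (
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
_PROK_TOPOLOGY = (
    "prok",
    [
        ("bacteria", [("EcoRpr", ["Eco", "Rpr"]), "Bsu"]),
        ("archaea", [("MacSso", ["Mac", "Sso"]), "Pae"]),
    ],
)


def _build(spec) -> Node:
    if isinstance(spec, str):
        return Node(label=spec)
    name, children = spec
    node = Node(label=name)
    for child in children:
        node.add_child(_build(child))
    return node


def species_tree() -> Node:
    """The fixed 14-species tree: (prokaryote outgroup, eukaryotes)."""
    root = Node(label="root")
    root.add_child(_build(_PROK_TOPOLOGY))
    root.add_child(_build(_EUK_TOPOLOGY))
    return root


def default_taxon_map() -> TaxonMap:
    return TaxonMap({}, SPECIES_LINEAGES, species_prefix_fallback=True)


def _species_clade_sets() -> list[frozenset[str]]:
    sets = []
    for node in species_tree().preorder():
        if not node.is_leaf:
            sets.append(frozenset(l.label for l in node.leaves()))
    return sets


@dataclass(frozen=True)
class SupportModel:
    """Support values: clamp(base − Uniform(0, noise_width), 0, 100), with
    separate bases for species-tree-concordant clades and all other clades."""

    base_true: float = 95.0
    base_other: float = 55.0
    noise_width: float = 25.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated family batch.

    ``p_early`` is the probability of a duplication on the eukaryote stem
    (before the R/O split); ``dup_rate`` / ``loss_rate`` are expected
    per-branch Poisson event counts for each gene lineage below the split.
    """

    p_early: float = 0.3
    dup_rate: float = 0.05
    loss_rate: float = 0.05
    support: SupportModel = field(default_factory=SupportModel)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_early <= 1.0):
            raise AnalysisInputError("p_early must lie in [0, 1]")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise AnalysisInputError("rates must be non-negative")


@dataclass(frozen=True)
class SimulationRecord:
    family_id: int
    events: tuple[dict, ...]
    tree: GeneTree
    copy_counts: dict[str, int]
    n_discarded: int = 0
    lba_corrupted: bool = False

    @property
    def has_early_duplication(self) -> bool:
        return any(e["kind"] == "early_duplication" for e in self.events)


# ---------------------------------------------------------------------------
# phase 1: event sampling
# ---------------------------------------------------------------------------

def _sample_events(config: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    events: list[dict] = []
    euk_root = _build(_EUK_TOPOLOGY)

    def walk(species_node: Node, entering: str) -> list[str]:
        """Sample events on the branch above species_node for one entering
        lineage; return surviving copy ids at the bottom of the branch."""
        branch = species_node.label
        k = int(rng.poisson(config.dup_rate))
        copies = [f"{entering}/{branch}.{i}" for i in range(k + 1)]
        for _ in range(k):
            events.append(
                {"kind": "lineage_duplication", "branch": branch, "lineage": entering}
            )
        m = int(rng.poisson(config.loss_rate))
        m = min(m, len(copies))
        if m:
            victims = sorted(rng.choice(copies, size=m, replace=False).tolist())
            for victim in victims:
                events.append({"kind": "loss", "branch": branch, "lineage": victim})
            copies = [c for c in copies if c not in victims]
        survivors = []
        for copy_id in copies:
            if species_node.is_leaf:
                survivors.append(copy_id)
            else:
                alive = False
                for child in species_node.children:
                    if walk(child, copy_id):
                        alive = True
                if alive:
                    survivors.append(copy_id)
        return survivors

    stem_lineages = ["L"]
    if rng.random() < config.p_early:
        events.append({"kind": "early_duplication", "branch": "euk_stem", "lineage": "L"})
        stem_lineages = ["L/stem.0", "L/stem.1"]
    for lineage in stem_lineages:
        for child in euk_root.children:
            walk(child, lineage)
    return events


# ---------------------------------------------------------------------------
# phase 2: deterministic replay
# ---------------------------------------------------------------------------

def replay_events(
    events: list[dict], family_id: int
) -> tuple[Optional[Node], dict[str, int]]:
    """Rebuild the eukaryotic gene subtree from an event log alone.

    Returns (subtree or None if extinct, per-species eukaryotic copy
    counts).  Purely deterministic: duplications on a branch build a
    left-deep caterpillar in copy-index order; leaf copy indices follow
    replay traversal order per species.
    """
    dup_count: dict[tuple[str, str], int] = {}
    losses: set[tuple[str, str]] = set()
    early = False
    for event in events:
        if event["kind"] == "early_duplication":
            early = True
        elif event["kind"] == "lineage_duplication":
            key = (event["branch"], event["lineage"])
            dup_count[key] = dup_count.get(key, 0) + 1
        elif event["kind"] == "loss":
            losses.add((event["branch"], event["lineage"]))
        else:
            raise AnalysisInputError(f"unknown event kind {event['kind']!r}")

    counters: dict[str, int] = {}
    euk_root = _build(_EUK_TOPOLOGY)

    def walk(species_node: Node, entering: str) -> Optional[Node]:
        branch = species_node.label
        k = dup_count.get((branch, entering), 0)
        copies = [f"{entering}/{branch}.{i}" for i in range(k + 1)]
        copies = [c for c in copies if (branch, c) not in losses]
        subtrees: list[Node] = []
        for copy_id in copies:
            if species_node.is_leaf:
                idx = counters.get(branch, 0)
                counters[branch] = idx + 1
                subtrees.append(Node(label=f"{branch}_{family_id}_{idx}"))
            else:
                kids = [walk(child, copy_id) for child in species_node.children]
                kids = [kid for kid in kids if kid is not None]
                if not kids:
                    continue
                if len(kids) == 1:
                    subtrees.append(kids[0])
                else:
                    spec_node = Node()
                    for kid in kids:
                        spec_node.add_child(kid)
                    subtrees.append(spec_node)
        if not subtrees:
            return None
        tree = subtrees[0]
        for extra in subtrees[1:]:
            joint = Node()
            joint.add_child(tree)
            joint.add_child(extra)
            tree = joint
        return tree

    stem_lineages = ["L/stem.0", "L/stem.1"] if early else ["L"]
    stem_subtrees = []
    for lineage in stem_lineages:
        kids = [walk(child, lineage) for child in euk_root.children]
        kids = [kid for kid in kids if kid is not None]
        if not kids:
            continue
        if len(kids) == 1:
            stem_subtrees.append(kids[0])
        else:
            node = Node()
            for kid in kids:
                node.add_child(kid)
            stem_subtrees.append(node)
    if not stem_subtrees:
        return None, dict(counters)
    if len(stem_subtrees) == 1:
        euk = stem_subtrees[0]
    else:
        euk = Node()
        for sub in stem_subtrees:
            euk.add_child(sub)
    return euk, dict(counters)


def _prok_subtree(family_id: int) -> Node:
    node = _build(_PROK_TOPOLOGY)
    for leaf in node.leaves():
        leaf.label = f"{leaf.label}_{family_id}_0"
    for internal in node.preorder():
        if not internal.is_leaf:
            internal.label = None
    return node


def simulate_family(config: SimulationConfig, family_id: int) -> SimulationRecord:
    """Simulate one gene family; deterministic given (config.seed, family_id)."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, family_id])
    n_discarded = 0
    while True:
        events = _sample_events(config, rng)
        euk, euk_counts = replay_events(events, family_id)
        if euk is not None:
            break
        n_discarded += 1
        if n_discarded > 10_000:
            raise AnalysisInputError(
                "loss rate so high that no family retains eukaryotic genes"
            )
    root = Node()
    root.add_child(_prok_subtree(family_id))
    root.add_child(euk)
    counts = {sp: 0 for sp in SPECIES_LINEAGES}
    counts.update(euk_counts)
    for sp in ("Eco", "Rpr", "Bsu", "Mac", "Sso", "Pae"):
        counts[sp] = 1
    tree = GeneTree(root, rooted=True, name=f"fam{family_id}")
    return SimulationRecord(
        family_id=family_id,
        events=tuple(events),
        tree=tree,
        copy_counts=counts,
        n_discarded=n_discarded,
    )


def simulate_batch(config: SimulationConfig, n_families: int) -> list[SimulationRecord]:
    return [simulate_family(config, i) for i in range(n_families)]


# ---------------------------------------------------------------------------
# support assignment and long-branch corruption
# ---------------------------------------------------------------------------

def assign_supports(
    record: SimulationRecord,
    model: Optional[SupportModel] = None,
    seed: Optional[int] = None,
) -> SimulationRecord:
    """Assign supports to every non-root internal node.

    A clade whose species set matches a species-tree clade's species set is
    'concordant' and draws from ``base_true``; all other clades from
    ``base_other``.  support = clamp(base − Uniform(0, noise_width), 0, 100).
    """
    model = model or SupportModel()
    if seed is None:
        seed = 1
    rng = np.random.default_rng([seed & 0x7FFFFFFF, record.family_id, 1])
    concordant = set(_species_clade_sets())
    tree = record.tree.copy()
    taxa = default_taxon_map()
    for node in tree.root.preorder():
        if node.is_leaf or node is tree.root:
            continue
        species = frozenset(taxa.species_of(l.label) for l in node.leaves())
        base = model.base_true if species in concordant else model.base_other
        noise = rng.uniform(0.0, model.noise_width) if model.noise_width > 0 else 0.0
        node.support = min(100.0, max(0.0, base - noise))
    return replace(record, tree=tree)


def corrupt_with_lba(
    record: SimulationRecord, target_species: str, seed: int = 0
) -> SimulationRecord:
    """Emulate long-branch attraction: pull one gene of ``target_species``
    to the base of the eukaryotic clade.

    The chosen leaf is detached and re-attached as sister to the remaining
    eukaryotic subtree, producing the artifactual basal topology that the
    stringent criterion is designed to reject.  The leaf set is unchanged.
    """
    tree = record.tree.copy()
    taxa = default_taxon_map()
    candidates = sorted(
        l.label for l in tree.leaves() if taxa.species_of(l.label) == target_species
    )
    if not candidates:
        raise AnalysisInputError(f"species {target_species!r} absent from family")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, record.family_id, 2])
    victim_label = candidates[int(rng.integers(len(candidates)))]
    by_label = {l.label: l for l in tree.leaves()}
    victim = by_label[victim_label]

    parent = victim.parent
    if parent is None:
        raise AnalysisInputError("cannot corrupt a single-leaf tree")
    parent.children = [c for c in parent.children if c is not victim]
    victim.parent = None
    # splice out a now-degree-2 node
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        grand = parent.parent
        only.length = (
            None
            if only.length is None and parent.length is None
            else (only.length or 0.0) + (parent.length or 0.0)
        )
        grand.children = [only if c is parent else c for c in grand.children]
        only.parent = grand

    euk_leaves = [l for l in tree.root.leaves() if taxa.is_eukaryote(l.label)]
    # MRCA of remaining eukaryotic leaves
    from .duplications import _mrca  # local import to avoid a cycle

    euk_mrca = _mrca(tree, frozenset(l.label for l in euk_leaves))
    anchor_parent = euk_mrca.parent
    joint = Node(support=euk_mrca.support)
    if anchor_parent is None:
        raise AnalysisInputError("eukaryotic clade spans the whole tree")
    anchor_parent.children = [joint if c is euk_mrca else c for c in anchor_parent.children]
    joint.parent = anchor_parent
    joint.add_child(euk_mrca)
    joint.add_child(victim)

    events = record.events + ({"kind": "lba_corrupted", "branch": target_species, "lineage": victim_label},)
    return replace(record, tree=GeneTree(tree.root, rooted=True, name=tree.name), events=events, lba_corrupted=True)


# ---------------------------------------------------------------------------
# copy-number tables
# ---------------------------------------------------------------------------

def simulate_copy_numbers(
    n_families: int,
    target_rho: float,
    group_label: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired per-family copy counts whose Spearman correlation converges to
    ``target_rho``.

    A latent bivariate normal with Pearson correlation r = 2·sin(π·ρ/6)
    (the inverse of the normal rank-correlation identity) is mapped through
    a monotone exponential transform to non-negative integer counts; at
    ``target_rho = 1`` the two latent variables are identical, so the
    realized rank correlation is exactly 1.
    """
    if not (-1.0 <= target_rho <= 1.0):
        raise AnalysisInputError("target correlation must lie in [-1, 1]")
    if n_families < 10:
        raise AnalysisInputError("need at least 10 families")
    label_key = zlib.crc32(group_label.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([seed & 0x7FFFFFFF, label_key])
    if target_rho >= 1.0:
        z1 = rng.standard_normal(n_families)
        z2 = z1
    elif target_rho <= -1.0:
        z1 = rng.standard_normal(n_families)
        z2 = -z1
    else:
        r = 2.0 * math.sin(math.pi * target_rho / 6.0)
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n_families)
        z1, z2 = z[:, 0], z[:, 1]

    def to_counts(z: np.ndarray) -> np.ndarray:
        return np.maximum(0, np.round(np.exp(1.2 + 1.1 * z))).astype(int)

    return pd.DataFrame(
        {
            "count_a": to_counts(z1),
            "count_b": to_counts(z2),
            "group": group_label,
        }
    )
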