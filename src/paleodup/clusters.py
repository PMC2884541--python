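"""Pre-phylogenetic cluster eligibility and cleaning.

Gene clusters (the output of similarity clustering, supplied as membership
tables) are screened before any tree is looked at:

1. ``redundancy_filter`` — within each species, members connected by
   pairwise identity strictly above a threshold (default 80%) are collapsed
   to a single representative (longest sequence, ties by smallest gene id).
2. ``domain_filter`` — members lacking every one of the most prevalent
   domain accession(s) are dropped; clusters with no domain information pass
   through unchanged.
3. ``check_eligibility`` — lineage-composition requirements per analysis:
   I/III need ≥1 prokaryotic member, ≥3 eukaryotic members, ≥1 R and ≥1 O;
   II needs no prokaryotic members, ≥2 R and ≥2 O.

The default pipeline order is redundancy → domain → eligibility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import AnalysisInputError
from .taxa import Group, TaxonMap

__all__ = [
    "GeneCluster",
    "EligibilityVerdict",
    "check_eligibility",
    "most_common_domains",
    "domain_filter",
    "redundancy_filter",
    "read_cluster_tables",
]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneCluster:
    """A gene cluster: member ids plus optional per-member annotations.

    ``identities`` maps unordered gene pairs (stored with the smaller id
    first) to percent identity in [0, 100].
    """

    cluster_id: str
    members: frozenset[str]
    domains: Mapping[str, frozenset[str]] = field(default_factory=dict)
    lengths: Mapping[str, int] = field(default_factory=dict)
    identities: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for (a, b), pct in self.identities.items():
            if (a, b) != _canonical_pair(a, b):
                raise AnalysisInputError(
                    f"identity pair ({a}, {b}) not stored canonically"
                )
            if not (0.0 <= pct <= 100.0):
                raise AnalysisInputError(f"identity {pct} outside [0, 100]")

    @classmethod
    def build(
        cls,
        cluster_id: str,
        members,
        domains: Optional[Mapping[str, set]] = None,
        lengths: Optional[Mapping[str, int]] = None,
        identity_rows=None,
    ) -> "GeneCluster":
        """Build from loose inputs; ``identity_rows`` is an iterable of
        (gene_a, gene_b, pct) triples and is checked for symmetry: a pair
        listed in both orientations must carry the same value."""
        members = frozenset(members)
        identities: dict[tuple[str, str], float] = {}
        for a, b, pct in identity_rows or ():
            key = _canonical_pair(a, b)
            pct = float(pct)
            if key in identities and identities[key] != pct:
                raise AnalysisInputError(
                    f"asymmetric identity entries for pair {key}: "
                    f"{identities[key]} vs {pct}"
                )
            identities[key] = pct
        return cls(
            cluster_id=cluster_id,
            members=members,
            domains={g: frozenset(d) for g, d in (domains or {}).items() if g in members},
            lengths=dict(lengths or {}),
            identities=identities,
        )

    def identity(self, a: str, b: str) -> Optional[float]:
        return self.identities.get(_canonical_pair(a, b))

    def restrict(self, keep: frozenset[str]) -> "GeneCluster":
        return replace(
            self,
            members=keep,
            domains={g: d for g, d in self.domains.items() if g in keep},
            lengths={g: n for g, n in self.lengths.items() if g in keep},
            identities={
                pair: pct
                for pair, pct in self.identities.items()
                if pair[0] in keep and pair[1] in keep
            },
        )


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reason: str  # "ok" or the first failed requirement


def check_eligibility(cluster: GeneCluster, taxa: TaxonMap, analysis: str) -> EligibilityVerdict:
    """Lineage-composition eligibility of a cluster for one of the three
    analyses.  The reason code names the first failed requirement."""
    if analysis not in ("I", "II", "III"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if not cluster.members:
        return EligibilityVerdict(False, "no-members")
    counts = taxa.tally(cluster.members)
    n_prok = counts[Group.PROK]
    n_euk = sum(counts[g] for g in (Group.R, Group.O, Group.PROTIST))
    if analysis in ("I", "III"):
        if n_prok < 1:
            return EligibilityVerdict(False, "no-prokaryote")
        if n_euk < 3:
            return EligibilityVerdict(False, "fewer-than-3-eukaryotes")
        if counts[Group.R] < 1:
            return EligibilityVerdict(False, "no-archaeplastida")
        if counts[Group.O] < 1:
            return EligibilityVerdict(False, "no-opisthokont")
    else:  # analysis II: eukaryote-specific clusters
        if n_prok > 0:
            return EligibilityVerdict(False, "prokaryote-present")
        if counts[Group.R] < 2:
            return EligibilityVerdict(False, "fewer-than-2-archaeplastida")
        if counts[Group.O] < 2:
            return EligibilityVerdict(False, "fewer-than-2-opisthokonts")
    return EligibilityVerdict(True, "ok")


def most_common_domains(cluster: GeneCluster) -> frozenset[str]:
    """Domain accession(s) present on the largest number of members.  All
    tied accessions are returned; a cluster with no domain annotation at all
    yields the empty set (callers treat this as 'no-domain-information')."""
    prevalence: dict[str, int] = {}
    for gene in cluster.members:
        for acc in cluster.domains.get(gene, ()):
            prevalence[acc] = prevalence.get(acc, 0) + 1
    if not prevalence:
        return frozenset()
    top = max(prevalence.values())
    return frozenset(acc for acc, n in prevalence.items() if n == top)


def domain_filter(cluster: GeneCluster) -> tuple[GeneCluster, frozenset[str]]:
    """Drop members that carry none of the most common domain(s).

    Returns the filtered cluster and the removed ids.  A member survives if
    it carries at least one of the tied top accessions.  Clusters without any
    domain information are returned unchanged.
    """
    common = most_common_domains(cluster)
    if not common:
        return cluster, frozenset()
    removed = frozenset(
        g for g in cluster.members if not (cluster.domains.get(g, frozenset()) & common)
    )
    if not removed:
        return cluster, removed
    return cluster.restrict(cluster.members - removed), removed


def redundancy_filter(
    cluster: GeneCluster, taxa: TaxonMap, threshold: float = 80.0
) -> tuple[GeneCluster, frozenset[str]]:
    """Collapse highly similar same-species members.

    Within each species, members are grouped by single-linkage over pairs
    with identity strictly greater than ``threshold`` (missing pairs count as
    below threshold).  Each group keeps one representative: the longest
    sequence, ties broken by the lexicographically smallest gene id.
    """
    by_species: dict[str, list[str]] = {}
    for gene in sorted(cluster.members):
        by_species.setdefault(taxa.species_of(gene), []).append(gene)

    parent: dict[str, str] = {g: g for g in cluster.members}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for genes in by_species.values():
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                pct = cluster.identity(a, b)
                if pct is not None and pct > threshold:
                    union(a, b)

    groups: dict[str, list[str]] = {}
    for gene in cluster.members:
        groups.setdefault(find(gene), []).append(gene)

    removed: set[str] = set()
    for group in groups.values():
        if len(group) < 2:
            continue
        representative = min(group, key=lambda g: (-cluster.lengths.get(g, 0), g))
        removed.update(g for g in group if g != representative)
    if not removed:
        return cluster, frozenset()
    return cluster.restrict(cluster.members - frozenset(removed)), frozenset(removed)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_cluster_tables(
    clusters_path: Union[str, Path],
    domains_path: Optional[Union[str, Path]] = None,
    identities_path: Optional[Union[str, Path]] = None,
    lengths_path: Optional[Union[str, Path]] = None,
) -> list[GeneCluster]:
    """Read clusters.tsv (cluster_id, gene_id) plus optional domains.tsv
    (gene_id, domain_accession), identities.tsv (gene_a, gene_b,
    pct_identity) and lengths.tsv (gene_id, length)."""
    membership: dict[str, list[str]] = {}
    for row in _rows(clusters_path, 2):
        if row[0].lower() == "cluster_id":
            continue
        membership.setdefault(row[0], []).append(row[1])

    domains: dict[str, set[str]] = {}
    if domains_path is not None:
        for row in _rows(domains_path, 2):
            if row[0].lower() == "gene_id":
                continue
            domains.setdefault(row[0], set()).add(row[1])

    lengths: dict[str, int] = {}
    if lengths_path is not None:
        for row in _rows(lengths_path, 2):
            if row[0].lower() == "gene_id":
                continue
            lengths[row[0]] = int(row[1])

    identity_rows: list[tuple[str, str, float]] = []
    if identities_path is not None:
        for row in _rows(identities_path, 3):
            if row[0].lower() == "gene_a":
                continue
            identity_rows.append((row[0], row[1], float(row[2])))

    clusters = []
    for cid in sorted(membership):
        members = set(membership[cid])
        clusters.append(
            GeneCluster.build(
                cid,
                members,
                domains={g: d for g, d in domains.items() if g in members},
                lengths={g: n for g, n in lengths.items() if g in members},
                identity_rows=[
                    r for r in identity_rows if r[0] in members and r[1] in members
                ],
            )
        )
    return clusters


def _rows(path: Union[str, Path], width: int) -> list[list[str]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < width:
                raise AnalysisInputError(f"{path}: expected {width} columns, got {row!r}")
            out.append([cell.strip() for cell in row[:width]])
    return out
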