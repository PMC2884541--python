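"""Gene→species→lineage resolution.

The screening logic only ever needs four coarse groups derived from the
lineage tags:

* ``R``   — Archaeplastida (plants and green algae)
* ``O``   — Opisthokonta (animals + fungi)
* ``PROK``    — bacteria + archaea, used as the rooting outgroup
* ``PROTIST`` — Excavata / Chromalveolata / Amoebozoa, used only when placing
  duplications relative to deep-branching protists

Eukaryote = R ∪ O ∪ PROTIST.  The four groups partition the lineage tags.
"""

from __future__ import annotations

import csv
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .errors import TaxonMapError

__all__ = ["Lineage", "Group", "TaxonMap"]


class Lineage(str, Enum):
    ARCHAEPLASTIDA = "ARCHAEPLASTIDA"
    ANIMAL = "ANIMAL"
    FUNGUS = "FUNGUS"
    BACTERIA = "BACTERIA"
    ARCHAEA = "ARCHAEA"
    EXCAVATA = "EXCAVATA"
    CHROMALVEOLATA = "CHROMALVEOLATA"
    AMOEBOZOA = "AMOEBOZOA"


class Group(str, Enum):
    R = "R"
    O = "O"
    PROK = "PROK"
    PROTIST = "PROTIST"


_GROUP_OF = {
    Lineage.ARCHAEPLASTIDA: Group.R,
    Lineage.ANIMAL: Group.O,
    Lineage.FUNGUS: Group.O,
    Lineage.BACTERIA: Group.PROK,
    Lineage.ARCHAEA: Group.PROK,
    Lineage.EXCAVATA: Group.PROTIST,
    Lineage.CHROMALVEOLATA: Group.PROTIST,
    Lineage.AMOEBOZOA: Group.PROTIST,
}


class TaxonMap:
    """Resolves gene ids to species and species to lineage groups.

    Parameters
    ----------
    gene_to_species:
        Explicit gene→species mapping.  May be empty when
        ``species_prefix_fallback`` is enabled.
    species_to_lineage:
        species→:class:`Lineage` mapping (string values accepted).
    species_prefix_fallback:
        If true, a gene absent from the explicit table is resolved to the
        prefix before its first underscore (the convention used by the
        bundled simulator, e.g. ``Ath_12_0`` → ``Ath``).
    """

    def __init__(
        self,
        gene_to_species: Mapping[str, str],
        species_to_lineage: Mapping[str, Union[str, Lineage]],
        species_prefix_fallback: bool = False,
    ):
        self.gene_to_species = dict(gene_to_species)
        self.species_to_lineage = {
            sp: Lineage(lin) for sp, lin in species_to_lineage.items()
        }
        self.species_prefix_fallback = species_prefix_fallback

    # -- construction --------------------------------------------------
    @classmethod
    def from_tsv(
        cls,
        genes_path: Union[str, Path],
        species_path: Union[str, Path],
        species_prefix_fallback: bool = False,
    ) -> "TaxonMap":
        """Load from ``genes.tsv`` (gene_id, species_id) and ``species.tsv``
        (species_id, lineage_tag).  Header rows are optional and detected by
        the literal column names."""
        genes = {}
        for row in _read_tsv(genes_path):
            if row[0].lower() == "gene_id":
                continue
            genes[row[0]] = row[1]
        species = {}
        for row in _read_tsv(species_path):
            if row[0].lower() == "species_id":
                continue
            try:
                species[row[0]] = Lineage(row[1])
            except ValueError:
                raise TaxonMapError(
                    f"unknown lineage tag {row[1]!r} for species {row[0]!r}"
                )
        return cls(genes, species, species_prefix_fallback=species_prefix_fallback)

    @classmethod
    def from_tsv_species_only(cls, species_path: Union[str, Path]) -> "TaxonMap":
        """Load only a species table; genes resolve via the underscore-prefix
        convention (``Ath_12_0`` → ``Ath``)."""
        species = {}
        for row in _read_tsv(species_path):
            if row[0].lower() == "species_id":
                continue
            try:
                species[row[0]] = Lineage(row[1])
            except ValueError:
                raise TaxonMapError(
                    f"unknown lineage tag {row[1]!r} for species {row[0]!r}"
                )
        return cls({}, species, species_prefix_fallback=True)

    # -- resolution ----------------------------------------------------
    def species_of(self, gene: str) -> str:
        species = self.gene_to_species.get(gene)
        if species is None and self.species_prefix_fallback and "_" in gene:
            prefix = gene.split("_", 1)[0]
            if prefix in self.species_to_lineage:
                species = prefix
        if species is None:
            raise TaxonMapError(f"gene {gene!r} not resolvable to a species")
        return species

    def lineage_of_species(self, species: str) -> Lineage:
        try:
            return self.species_to_lineage[species]
        except KeyError:
            raise TaxonMapError(f"species {species!r} has no lineage tag")

    def lineage_of(self, gene: str) -> Lineage:
        return self.lineage_of_species(self.species_of(gene))

    def group_of(self, gene: str) -> Group:
        return _GROUP_OF[self.lineage_of(gene)]

    # -- predicates ----------------------------------------------------
    def is_prokaryote(self, gene: str) -> bool:
        return self.group_of(gene) is Group.PROK

    def is_eukaryote(self, gene: str) -> bool:
        return self.group_of(gene) is not Group.PROK

    def is_R(self, gene: str) -> bool:
        return self.group_of(gene) is Group.R

    def is_O(self, gene: str) -> bool:
        return self.group_of(gene) is Group.O

    def is_protist(self, gene: str) -> bool:
        return self.group_of(gene) is Group.PROTIST

    # -- tallies -------------------------------------------------------
    def tally(self, genes: Iterable[str]) -> dict[Group, int]:
        counts = {g: 0 for g in Group}
        for gene in genes:
            counts[self.group_of(gene)] += 1
        return counts

    def species_set(self, genes: Iterable[str]) -> frozenset[str]:
        return frozenset(self.species_of(g) for g in genes)

    # -- output --------------------------------------------------------
    def to_tsv(self, genes_path: Union[str, Path], species_path: Union[str, Path]) -> None:
        with open(genes_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_id", "species_id"])
            for gene in sorted(self.gene_to_species):
                writer.writerow([gene, self.gene_to_species[gene]])
        with open(species_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["species_id", "lineage_tag"])
            for sp in sorted(self.species_to_lineage):
                writer.writerow([sp, self.species_to_lineage[sp].value])


def _read_tsv(path: Union[str, Path]) -> list[list[str]]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise TaxonMapError(f"{path}: expected 2 columns, got {row!r}")
            rows.append([cell.strip() for cell in row[:2]])
    return rows
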