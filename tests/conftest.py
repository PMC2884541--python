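"""Shared fixtures: taxon maps and small hand-built trees."""

import pytest

from paleodup.simulate import default_taxon_map
from paleodup.taxa import Lineage, TaxonMap


@pytest.fixture(scope="session")
def taxa() -> TaxonMap:
    """The 14-species map (3 plants, 3 animals, 2 fungi, 3 bacteria,
    3 archaea) with gene ids resolved by underscore-prefix."""
    return default_taxon_map()


@pytest.fixture(scope="session")
def taxa_with_protists() -> TaxonMap:
    """14-species map extended with deep-branching protist exemplars."""
    mapping = dict(default_taxon_map().species_to_lineage)
    mapping.update(
        {
            "Ddi": Lineage.AMOEBOZOA,  # Dictyostelium
            "Tbr": Lineage.EXCAVATA,  # Trypanosoma
            "Pfa": Lineage.CHROMALVEOLATA,  # Plasmodium
        }
    )
    return TaxonMap({}, mapping, species_prefix_fallback=True)
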