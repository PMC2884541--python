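"""Exception hierarchy shared across the pipeline stages."""


class PaleodupError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PaleodupError, ValueError):
    """Malformed newick input; carries the character offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(PaleodupError, ValueError):
    """A tree violates a structural invariant (duplicate leaves, bad support)."""


class TaxonMapError(PaleodupError, KeyError):
    """A gene or species could not be resolved to a lineage."""


class OutgroupRootingError(PaleodupError, ValueError):
    """Outgroup rooting is impossible; callers should fall back to the
    outgroup-free bipartition method."""


class AnalysisInputError(PaleodupError, ValueError):
    """An operation received input outside its contract (e.g. prokaryotic
    leaves passed to the eukaryote-only bipartition screen)."""
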