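"""Exception hierarchy for the mnbc package."""


class MnbcError(Exception):
    """Base class for all mnbc errors."""


class AmbiguousBaseError(MnbcError):
    """A k-mer operation received a base outside {A, C, G, T}."""


class GenomeTooShortError(MnbcError):
    """No record in a genome is long enough to yield a single k-mer."""


class IndexFormatError(MnbcError):
    """A genome index file could not be parsed."""


class TaxonomyError(MnbcError):
    """The taxonomy table is malformed or inconsistent with the genomes."""


class DatabaseError(MnbcError):
    """Database-level inconsistency (duplicate ids, k mismatch, missing genome)."""


class ConfigurationError(MnbcError):
    """Classifier parameters violate their constraints."""
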