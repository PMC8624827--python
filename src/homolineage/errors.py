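"""Exception hierarchy shared across the package.

All homolineage-specific failures derive from :class:`HomolineageError`
so callers (and the CLI, which maps them to exit code 3) can catch one
base class.
"""


class HomolineageError(Exception):
    """Base class for all errors raised by homolineage."""


class ParseError(HomolineageError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(HomolineageError):
    """A parsed value violates its documented range or invariant."""


class DomainError(HomolineageError):
    """An argument is outside the domain of an operation."""


class LabelingError(HomolineageError):
    """A gene is missing from the species/family assignment map."""


class ContractError(HomolineageError):
    """An input object violates a cross-operation contract (e.g. a
    non-nested lineage chart, or trees with unequal leaf sets)."""


class TaxonomyLookupError(HomolineageError):
    """Requested labels could not be resolved in the taxonomy table."""


class EmptyTreeError(HomolineageError):
    """A tree operation produced no usable leaves (e.g. no species has
    a homolog of the focal gene)."""


class ExportError(HomolineageError):
    """An export referenced data (e.g. a sequence) that is unavailable."""


class ConfigError(HomolineageError):
    """A simulation or pipeline configuration is invalid."""
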