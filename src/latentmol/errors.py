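"""Structured exceptions shared across the package."""


class LatentMolError(Exception):
    """Base class for all package errors."""


class ParseError(LatentMolError):
    """A SMILES string could not be parsed into a molecule."""


class VocabularyError(LatentMolError):
    """A molecule contains an atom type outside the configured vocabulary."""


class CapacityError(LatentMolError):
    """A molecule exceeds the maximum node capacity dn."""


class GraphContractError(LatentMolError):
    """A graph tensor violates the one-hot / symmetry / padding invariants."""


class SchemaError(LatentMolError):
    """An input table is missing a required column."""


class ConfigError(LatentMolError):
    """An invalid configuration value (e.g. dequantization noise scale)."""


class UnderflowError(LatentMolError):
    """A coupling inverse hit a numerically vanishing sigmoid scale."""


class FeasibilityError(LatentMolError):
    """A fixture specification demands more unique molecules than reachable."""


class EmptySeedError(LatentMolError):
    """A seed list contained no valid molecules."""
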