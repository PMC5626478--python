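"""Exception hierarchy for the ctai package."""


class CtaiError(Exception):
    """Base class for all package-specific errors."""


class PoolValidationError(CtaiError, ValueError):
    """A tRNA read-count table violates an invariant (duplicates, bad counts,
    codon/amino-acid mismatches, malformed shorthand)."""


class PairingError(CtaiError, ValueError):
    """A codon:anticodon pair cannot be classified or is not decodable."""


class ConfigurationError(CtaiError, ValueError):
    """A constraint table is missing a pairing class needed for scoring."""


class ScoringError(CtaiError, ValueError):
    """An ORF contains a codon that cannot be scored (w = 0 or absent)."""


class DegenerateFitError(CtaiError, ValueError):
    """Regression is undefined: zero variance in scores or expression."""


class InsufficientDataError(CtaiError, ValueError):
    """Fewer shared constructs than the regression requires."""


class ScenarioError(CtaiError, ValueError):
    """A synthetic-data scenario is infeasible as parameterized."""
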