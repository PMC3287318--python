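"""Exception hierarchy."""


class ChronodivError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(ChronodivError, ValueError):
    """The input could not be parsed as Newick."""


class UltrametricityError(ChronodivError, ValueError):
    """Root-to-tip path lengths disagree beyond tolerance."""


class InsufficientTipsError(ChronodivError, ValueError):
    """The tree has too few tips for the requested computation."""


class DomainError(ChronodivError, ValueError):
    """An argument falls outside its mathematical domain."""


class DegenerateTreeError(ChronodivError, ValueError):
    """The tree carries no usable branch length information."""


class SimulationError(ChronodivError, RuntimeError):
    """A stochastic simulation could not reach its stopping target."""


class UntestableError(ChronodivError, ValueError):
    """The permutation null is degenerate at the requested threshold."""
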