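"""Exception hierarchy for the tnfpop package."""


class TnfpopError(Exception):
    """Base class for all package errors."""


class SBMLParseError(TnfpopError):
    """Malformed SBML; the message names the offending element."""


class UnsupportedSBMLError(TnfpopError):
    """A well-formed SBML construct this package deliberately refuses.

    Events, rules, function definitions and similar constructs change the
    ODE semantics; silently dropping them would corrupt every downstream
    number, so they fail hard.
    """


class NetworkValidationError(TnfpopError):
    """A ReactionNetwork violates one of its structural invariants."""


class ProductionRateError(TnfpopError):
    """A zeroth-order synthesis reaction has no identifiable rate constant."""


class ConfigurationError(TnfpopError):
    """Missing or inconsistent run configuration (e.g. no dose conversion)."""


class EquilibrationError(TnfpopError):
    """The unstimulated model failed to reach an admissible steady state."""


class SimulationError(TnfpopError):
    """A single-cell integration failed; carries cell and protocol context."""


class PopulationSimulationError(TnfpopError):
    """Too many individual cell simulations failed (> failure budget)."""


class InsufficientDeathsError(TnfpopError):
    """Fewer than three dying cells: the log-log regression is undefined."""
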