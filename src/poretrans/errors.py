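"""Exception types shared across the simulator."""


class PoreTransError(Exception):
    """Base class for all simulator errors."""


class GrowthError(PoreTransError):
    """Self-avoiding chain growth could not be completed within the retry budget."""


class CommensurabilityError(PoreTransError):
    """Requested membrane extent is not commensurate with the lattice period."""


class BondBreakError(PoreTransError):
    """A FENE bond was stretched to or beyond its maximum extension.

    Usually signals a too-large time step or an excessive pulling force.
    """


class NonFiniteError(PoreTransError):
    """A force component or coordinate became non-finite."""


class NoSuccessfulTranslocations(PoreTransError):
    """Translocation-time statistics requested on an ensemble with no successes."""


class FitError(PoreTransError):
    """A statistical fit was degenerate or did not converge."""
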