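"""Exception hierarchy for mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A config file, column map, or preset name is invalid."""


class EmptyInputError(MRKitError):
    """No usable rows survived reading or intersection."""


class UndefinedRatioError(MRKitError):
    """Wald ratio requested with a zero exposure effect."""


class InsufficientInstrumentsError(MRKitError):
    """Fewer SNPs than the method's minimum (carries the minimum)."""

    def __init__(self, needed: int, got: int, method: str = ""):
        self.needed, self.got, self.method = needed, got, method
        super().__init__(
            f"{method or 'method'} requires >= {needed} instruments, got {got}"
        )


class SingularDesignError(MRKitError):
    """Regression design is degenerate (e.g. all exposure betas equal)."""


class CollinearityError(MRKitError):
    """MVMR design is rank deficient; names the offending exposures."""

    def __init__(self, exposures):
        self.exposures = list(exposures)
        super().__init__(
            "MVMR exposure-beta matrix is rank deficient; offending exposures: "
            + ", ".join(self.exposures)
        )


class UnderIdentifiedError(MRKitError):
    """MVMR with J <= K after filtering."""


class MissingLDError(MRKitError):
    """A pairwise r2 needed for clumping is absent from the LD source."""


class FeasibilityError(MRKitError):
    """A simulation config cannot produce genome-wide-significant instruments."""
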