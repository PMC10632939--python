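"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input (grid, rate table, policy state, config) violates its contract."""


class InfeasibleTargetError(ValidationError):
    """A calibration/prevalence target cannot be reached by the generator."""


class HorizonError(ValidationError):
    """A requested year lies outside the simulation horizon."""
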