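"""Exception types shared across the package."""


class AgefluxError(Exception):
    """Base class for all package errors."""


class ValidationError(AgefluxError, ValueError):
    """Malformed input: bad profiles, states, schedules or series."""


class ConfigurationError(AgefluxError, ValueError):
    """Invalid configuration file or incompatible option combination."""


class BudgetExceededError(AgefluxError, RuntimeError):
    """A grid search would exceed the configured evaluation budget."""

    def __init__(self, cardinality: int, budget: int):
        self.cardinality = cardinality
        self.budget = budget
        super().__init__(
            f"grid search cardinality {cardinality} exceeds the evaluation "
            f"budget {budget}; shrink the grids or raise max_evaluations"
        )
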