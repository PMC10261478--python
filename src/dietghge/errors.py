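"""Exception hierarchy shared across the pipeline stages."""


class DietGhgeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DietGhgeError):
    """An input table is missing required columns or has an unknown layout."""


class TableRowError(DietGhgeError):
    """A row of an input table violates a type invariant.

    Carries the zero-based row index of the offending row so that the
    message can point back into the source file.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class RecipeCycleError(DietGhgeError):
    """The recipe graph contains a cycle; the message names the dish chain."""

    def __init__(self, chain):
        self.chain = list(chain)
        super().__init__("cyclic recipe reference: " + " -> ".join(self.chain))


class UnresolvedFoodError(DietGhgeError):
    """A food or dish id does not resolve to any component, recipe or factor."""


class ConfigError(DietGhgeError):
    """The analysis configuration is incomplete or inconsistent."""


class RuleTableError(DietGhgeError):
    """Sex/age dispatch of the rule table yields zero or multiple rules."""


class MissingNutrientError(DietGhgeError):
    """A rule refers to a nutrient that the intake profile does not carry."""


class DegenerateDataError(DietGhgeError):
    """The data do not support the requested statistical operation
    (e.g. constant energy intake for the residual adjustment)."""


class EmptyRecordError(DietGhgeError):
    """A participant (or group) has no food-record entries."""
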