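"""Exception types used across the package."""


class SchemaError(ValueError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(ValueError):
    """A row violates a documented invariant (range, uniqueness, coverage)."""


class SolverStateError(RuntimeError):
    """An operation requiring an optimal solution was called on a non-optimal one."""
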