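"""Exception types shared across the package."""


class GcasKitError(Exception):
    """Base class for all package errors."""


class SchemaError(GcasKitError):
    """A CSV/YAML input violates the documented schema.

    The message names the offending file, row and field where possible.
    """


class NoExamError(GcasKitError):
    """An operation requiring a performed ultrasound exam got a skipped one.

    Distinct from an empty involvement set: a performed exam with no positive
    findings is informative, a skipped exam is not.
    """


class NotClassifiableError(GcasKitError):
    """A diagnosis exam has no involved segments, so no GCA subtype exists."""


class EmptyTableError(GcasKitError):
    """No eligible visits remain after missingness exclusions."""


class UndefinedStatisticError(GcasKitError):
    """A 2x2 statistic is undefined (zero margin); never silently 0."""
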