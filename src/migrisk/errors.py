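"""Exception hierarchy.

All errors raised on invalid scientific input derive from
:class:`MigriskError` so callers can catch package failures with one clause.
Row-level problems in tabular inputs are *collected* as diagnostics rather
than raised (see :mod:`migrisk.dataset`); only structural problems raise.
"""


class MigriskError(Exception):
    """Base class for all migrisk errors."""


class DomainError(MigriskError, ValueError):
    """A numeric input lies outside the mathematical domain of an operation
    (non-positive volume, negative time, zero body weight, ...)."""


class UnsupportedMaterialError(MigriskError, KeyError):
    """A material has no coefficient set in the loaded material library."""

    def __init__(self, material: str, known: tuple = ()):
        self.material = material
        self.known = tuple(known)
        msg = f"no QSPR coefficients for material {material!r}"
        if known:
            msg += f" (known: {', '.join(sorted(self.known))})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class MissingPredictorError(MigriskError, KeyError):
    """A regression model needs a predictor value that was not supplied."""

    def __str__(self) -> str:
        return self.args[0]


class SchemaError(MigriskError, ValueError):
    """A tabular input is missing mandatory columns or is structurally unreadable."""


class FoldError(MigriskError, ValueError):
    """A cross-validation scheme cannot form valid folds on the given data."""


class UndefinedRateError(DomainError):
    """Migration rate is undefined (zero contact time); the fraction may still be."""
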