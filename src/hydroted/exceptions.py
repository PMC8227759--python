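"""Structured exceptions and warnings for the hydration-analysis pipeline."""

from __future__ import annotations


class HydrotedError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(HydrotedError, ValueError):
    """Too few points for the requested fit (the dual model needs >= 4)."""


class DomainError(HydrotedError, ValueError):
    """Input outside the physical domain (non-positive T, K <= 0, ...)."""


class SingularFitError(HydrotedError, ValueError):
    """Design matrix numerically singular (pathological temperature grid,
    or a family in which every compound shares the same xi_w)."""


class ConfigurationError(HydrotedError, ValueError):
    """Inconsistent configuration (e.g. class label contradicting slope signs
    in a synthetic family truth)."""


class ParseError(HydrotedError, ValueError):
    """Malformed input table; carries the offending row numbers when known."""

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class UnknownPresetError(HydrotedError, KeyError):
    """Requested synthetic scenario name is not registered."""


class SignConventionWarning(UserWarning):
    """A family regression violated the expected slope-sign convention for
    its hydration class (Class A slopes negative, Class B positive)."""
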