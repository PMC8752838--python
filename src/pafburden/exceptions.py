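"""Structured error types for the burden pipeline.

Every validation failure carries enough context (file, row, column) for a
user to locate the offending cell in their input tables.
"""

from __future__ import annotations


class PafBurdenError(Exception):
    """Base class for all package errors."""


class DomainError(PafBurdenError, ValueError):
    """A mathematically invalid argument (rr <= 0, paf outside [0, 1], ...)."""


class DataGapError(PafBurdenError, LookupError):
    """A (factor, cancer, sex, level) cell the run needs is absent.

    Deliberate null associations must be stated via ``significant=False``;
    a missing row is always an error, never a silent RR = 1.
    """


class ConfigurationError(PafBurdenError):
    """An inconsistent or incomplete run configuration."""


class TableValidationError(PafBurdenError):
    """A malformed cell or row in an input table.

    Parameters
    ----------
    message : str
        Human-readable description of the problem.
    file : str, optional
        Path of the offending file.
    row : int, optional
        1-based data-row number (header excluded).
    column : str, optional
        Column name.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        self.file = file
        self.row = row
        self.column = column
        loc = []
        if file is not None:
            loc.append(f"file={file}")
        if row is not None:
            loc.append(f"row={row}")
        if column is not None:
            loc.append(f"column={column}")
        suffix = f" [{', '.join(loc)}]" if loc else ""
        super().__init__(message + suffix)
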