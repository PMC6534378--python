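"""Diagnostics carried by validation and build steps.

Every structural problem is reported as a :class:`Diagnostic` with a
dot-path into the offending document plus a human-readable message,
so callers can collect all problems in one pass instead of failing on
the first one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Diagnostic:
    path: str
    message: str
    level: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.level}: {self.path}: {self.message}"


class BuildError(Exception):
    """Raised when network instantiation cannot proceed.

    Carries the list of diagnostics that caused the failure.
    """

    def __init__(self, diagnostics):
        if isinstance(diagnostics, Diagnostic):
            diagnostics = [diagnostics]
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in self.diagnostics))


class SimulationError(Exception):
    """Raised when the engine hits a non-recoverable runtime problem."""

    def __init__(self, message, t=None, gid=None):
        self.t = t
        self.gid = gid
        ctx = []
        if t is not None:
            ctx.append(f"t={t} ms")
        if gid is not None:
            ctx.append(f"gid={gid}")
        super().__init__(message + (f" [{', '.join(ctx)}]" if ctx else ""))
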