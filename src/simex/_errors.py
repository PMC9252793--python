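"""Exception type carrying a stable machine-readable code.

Every operational failure in the package raises :class:`SimexError` with a
short uppercase code (e.g. ``MANIFEST_MISSING``, ``TARGET_AMBIGUOUS``) so
callers — in particular the validation layer, which converts exceptions into
report issues — can dispatch on the code rather than on message text.
"""

from __future__ import annotations


class SimexError(Exception):
    """An error with a stable, machine-readable ``code`` attribute."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SimexError({self.code!r}, {self.message!r})"
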