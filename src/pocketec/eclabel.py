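"""Enzyme Commission (EC) numbers with hierarchy-truncation semantics.

An EC number has four dot-separated levels — main class, subclass,
sub-subclass, and the serial designation, e.g. ``2.7.10.1`` (a transferase
(2), transferring phosphorus-containing groups (2.7), protein-tyrosine
kinase (2.7.10)).  Coarser predictions are obtained by truncating a full
designation, never by separate heads.
"""

from __future__ import annotations

import dataclasses

__all__ = ["ECLabel"]

LEVEL_NAMES = ("main", "sub", "subsub", "designation")


@dataclasses.dataclass(frozen=True, order=True)
class ECLabel:
    """A dotted EC string, stored as up to four level strings."""

    levels: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.levels) <= 4:
            raise ValueError(f"EC label needs 1-4 levels, got {self.levels!r}")
        if any(not lv for lv in self.levels):
            raise ValueError(f"empty EC level in {self.levels!r}")

    @classmethod
    def parse(cls, text: str) -> "ECLabel":
        return cls(tuple(part.strip() for part in str(text).split(".")))

    def truncate(self, depth: int) -> "ECLabel":
        """Keep the first ``depth`` levels (1 = main class ... 4 = designation)."""
        if not 1 <= depth <= 4:
            raise ValueError(f"depth must be in 1..4, got {depth}")
        return ECLabel(self.levels[: min(depth, len(self.levels))])

    @property
    def main(self) -> str:
        return self.levels[0]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def __str__(self) -> str:
        return ".".join(self.levels)
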