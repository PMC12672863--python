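"""The fixed 27-symbol character alphabet: a-z followed by the space token.

Every downstream object (transition matrices, stationary vectors, feature
matrices) is indexed against this single ordered vocabulary, so it lives in
its own module and is treated as immutable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field


SPACE = " "
#: Column-header token used for the space symbol in CSV output, where a bare
#: whitespace header would be ambiguous.
SPACE_TOKEN = "space"
#: Glyph used for the space node in network exports.
SPACE_GLYPH = "␣"


@dataclass(frozen=True)
class Alphabet:
    """Ordered 27-symbol vocabulary (26 lowercase letters, then space)."""

    symbols: tuple[str, ...] = tuple(string.ascii_lowercase) + (SPACE,)
    index_of: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if SPACE not in self.symbols:
            raise ValueError("alphabet must contain the space symbol")
        object.__setattr__(
            self, "index_of", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def space_index(self) -> int:
        return self.index_of[SPACE]

    def display_names(self) -> list[str]:
        """Symbol names safe for CSV headers (space rendered as 'space')."""
        return [SPACE_TOKEN if s == SPACE else s for s in self.symbols]


#: The canonical 27-symbol alphabet shared across the package.
ALPHABET = Alphabet()
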