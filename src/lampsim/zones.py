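"""Zone-string algebra for symbolic LAMP products.

A LAMP target and every product derived from it ("lamplicon") is modelled
as a string of *zones*: primer-annealing segments written 5'->3'.  Each zone
is a single letter; uppercase letters denote segments of the presumed upper
(plus) strand and lowercase letters their reverse complements on the lower
(minus) strand.  The classic six-zone layout is ``FABCDE``; the
pseudo-hemi-nested (phn) layout adds two extra inner-primer zones, ``M`` and
``N``, giving ``FABCDMNE``.  Loop-primer zones ``X``/``Y`` are accepted by
the parser for completeness but are not used by the reaction engine.

Positions are 1-based and counted 5'->3' throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


#: Zone letters of the classic four-primer LAMP layout.
CLASSIC_LETTERS = frozenset("FABCDE")

#: Default alphabet: classic letters plus the phn extra-inner-primer zones
#: M/N and the (engine-unused) loop-primer zones X/Y.
DEFAULT_LETTERS = frozenset("FABCDEMNXY")


class Provenance(str, Enum):
    """How a strand came into existence."""

    TARGET = "target"
    PRIMER_EXTENSION = "primer_extension"
    DISPLACED = "displaced"
    SELF_EXTENSION = "self_extension"
    FOLD_BACK = "fold_back"


class ZoneParseError(ValueError):
    """Raised when a zone string contains a letter outside the alphabet."""

    def __init__(self, char: str, position: int, alphabet: frozenset[str]):
        self.char = char
        self.position = position
        super().__init__(
            f"character {char!r} at position {position} is not a zone of the "
            f"alphabet {{{', '.join(sorted(alphabet))}}}"
        )


@dataclass(frozen=True, order=True)
class ZoneToken:
    """One primer-annealing zone with its strand sense.

    ``letter`` is always stored uppercase; ``plus`` selects the rendering
    case (uppercase for the plus sense, lowercase for the minus sense).
    """

    letter: str
    plus: bool

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isalpha() or not self.letter.isupper():
            raise ValueError(f"zone letter must be a single uppercase letter, got {self.letter!r}")

    @classmethod
    def from_char(cls, char: str) -> "ZoneToken":
        return cls(char.upper(), char.isupper())

    @property
    def char(self) -> str:
        return self.letter if self.plus else self.letter.lower()

    def complement(self) -> "ZoneToken":
        """Same letter, flipped sense.  An involution."""
        return ZoneToken(self.letter, not self.plus)

    def pairs_with(self, other: "ZoneToken") -> bool:
        """True when the two zones can hybridize (complementary senses)."""
        return self.letter == other.letter and self.plus != other.plus

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.char


def complement_token(t: ZoneToken) -> ZoneToken:
    """Complement of a single zone token (case flip)."""
    return t.complement()


@dataclass(frozen=True)
class ZoneStrand:
    """An ordered 5'->3' run of zone tokens.

    Immutable; equality and hashing are by token content only, so two
    strands with the same zone string compare equal regardless of their
    provenance or id.  Rendering (``str``) and :func:`parse_zone_string`
    round-trip exactly.
    """

    tokens: tuple[ZoneToken, ...]
    id: str = field(default="", compare=False)
    provenance: Provenance = field(default=Provenance.TARGET, compare=False)
    #: Optional flank markers: the paper draws target strands T1-T4 with
    #: flanking sequence of indefinite length (dotted lines); flanks carry
    #: no zone identity and never participate in the algebra.
    flank5: bool = field(default=False, compare=False)
    flank3: bool = field(default=False, compare=False)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[ZoneToken]:
        return iter(self.tokens)

    def __getitem__(self, idx):
        return self.tokens[idx]

    def token_at(self, pos: int) -> ZoneToken:
        """Token at 1-based position ``pos`` (5'->3')."""
        if not 1 <= pos <= len(self.tokens):
            raise IndexError(f"position {pos} outside strand of {len(self.tokens)} zones")
        return self.tokens[pos - 1]

    def prefix(self, upto: int) -> "ZoneStrand":
        """Zones strictly 5' of 1-based position ``upto`` (i.e. s[1..upto-1])."""
        return ZoneStrand(self.tokens[: max(upto - 1, 0)])

    def text(self) -> str:
        return "".join(t.char for t in self.tokens)

    def __str__(self) -> str:
        return self.text()

    def with_meta(
        self,
        *,
        id: str | None = None,
        provenance: Provenance | None = None,
    ) -> "ZoneStrand":
        return ZoneStrand(
            self.tokens,
            id=self.id if id is None else id,
            provenance=self.provenance if provenance is None else provenance,
            flank5=self.flank5,
            flank3=self.flank3,
        )

    def concat(self, other: "ZoneStrand | Iterable[ZoneToken]") -> "ZoneStrand":
        tokens = other.tokens if isinstance(other, ZoneStrand) else tuple(other)
        return ZoneStrand(self.tokens + tokens, id=self.id, provenance=self.provenance)


def parse_zone_string(
    text: str,
    alphabet: Iterable[str] = DEFAULT_LETTERS,
    **meta,
) -> ZoneStrand:
    """Parse a plain zone string such as ``"bABCDc"`` into a strand.

    One token per character; case sets the sense.  Characters outside the
    declared alphabet raise :class:`ZoneParseError` naming the 1-based
    position.  The empty string parses to an empty strand (permitted by the
    algebra; the reaction engine rejects empty species).
    """
    letters = frozenset(c.upper() for c in alphabet)
    tokens = []
    for i, char in enumerate(text, start=1):
        if char.upper() not in letters:
            raise ZoneParseError(char, i, letters)
        tokens.append(ZoneToken.from_char(char))
    return ZoneStrand(tuple(tokens), **meta)


def strand(text: str, **meta) -> ZoneStrand:
    """Shorthand for :func:`parse_zone_string` with the default alphabet."""
    return parse_zone_string(text, DEFAULT_LETTERS, **meta)


def reverse_complement(s: ZoneStrand) -> ZoneStrand:
    """Zone-level reverse complement: reverse the token order and flip every
    sense.  An involution; e.g. ``bABCDc`` <-> ``CdcbaB`` (the two mirror-twin
    dumbbell strands Z6_dmb(1)/Z6_dmb(2))."""
    return ZoneStrand(
        tuple(t.complement() for t in reversed(s.tokens)),
        id=s.id,
        provenance=s.provenance,
        flank5=s.flank3,
        flank3=s.flank5,
    )


def zone_count(s: ZoneStrand) -> int:
    """Number of zones in a strand — the N of the Z{N} product names."""
    return len(s)
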