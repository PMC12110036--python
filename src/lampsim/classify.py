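"""Classification of LAMP products into the ten named lamplicon types.

The model distinguishes ten product types: four reaction intermediates
(dumbbells ``Z_dmb``, elongated dumbbells, hairpins ``Z_hp``, linearized
single/double strands ``Z_li``), two terminated products (fully duplexed
``ZzS`` and dead-end hairpins ``Z_hpS``), two rare stem-bulged dumbbells
(``Z_dmb_hp``, ``Z_dmb_hpS``), and two late-stage tangles (``Z_mtlp`` and
cauliflower-like structures, classification labels only — the engine never
generates them because no deterministic rule produces them).

A product is *terminated* when no primer can anneal on any accessible
single-stranded region and its 3' end is unavailable for self-priming:
fully double-stranded lamplicons and hairpins whose loops offer no primer
site drop out of the amplification cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .rules import FoldBackResult, Primer, find_anneal_sites, find_self_prime_sites
from .zones import ZoneStrand, reverse_complement, zone_count


class StructureType(str, Enum):
    """The ten lamplicon type labels."""

    DMB = "Z_dmb"
    DMB_ELONGATED = "Z_dmb_elongated"
    HP = "Z_hp"
    LI = "Z_li"
    ZZS = "ZzS"
    HPS = "Z_hpS"
    DMB_HP = "Z_dmb_hp"
    DMB_HPS = "Z_dmb_hpS"
    MTLP = "Z_mtlp"
    CAULIFLOWER = "cauliflower"


TERMINATED_TYPES = frozenset({StructureType.ZZS, StructureType.HPS, StructureType.DMB_HPS})


class UnsupportedVariantError(ValueError):
    """Raised for semi-dumbbell (sdmb) products of loop-/stem-primer LAMP,
    which this model does not cover."""


class ClassificationError(ValueError):
    """Raised when a structure matches none of the ten lamplicon types."""


@dataclass(frozen=True)
class FoldedStructure:
    """A strand with its intramolecular pairings and optional partner.

    ``stem_pairs`` are (i, j) with i < j, nested (no pseudoknots) and
    complementary.  ``partner`` is a second strand forming an inter-strand
    duplex; ``partner_extent`` lists the template (this strand's) positions
    covered by the partner.  ``tag`` carries caller-supplied provenance for
    the non-generated labels (``"mtlp"``, ``"cauliflower"``, ``"sdmb"``).
    """

    strand: ZoneStrand
    stem_pairs: tuple[tuple[int, int], ...] = ()
    partner: ZoneStrand | None = None
    partner_extent: tuple[int, ...] = ()
    tag: str | None = None

    def __post_init__(self) -> None:
        n = zone_count(self.strand)
        for i, j in self.stem_pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"stem pair ({i},{j}) outside strand of {n} zones")
            if not self.strand.token_at(i).pairs_with(self.strand.token_at(j)):
                raise ValueError(
                    f"stem pair ({i},{j}) is not complementary: "
                    f"{self.strand.token_at(i)}/{self.strand.token_at(j)}"
                )
        for (i1, j1) in self.stem_pairs:  # nestedness (no pseudoknots)
            for (i2, j2) in self.stem_pairs:
                if i1 < i2 < j1 < j2:
                    raise ValueError(f"crossing stem pairs ({i1},{j1}) and ({i2},{j2})")

    # -- geometry ---------------------------------------------------------

    @property
    def paired_positions(self) -> frozenset[int]:
        intra = {p for pair in self.stem_pairs for p in pair}
        return frozenset(intra | set(self.partner_extent))

    def loops(self) -> list[tuple[int, ...]]:
        """Maximal runs of unpaired positions (they partition the unpaired
        set)."""
        n = zone_count(self.strand)
        paired = self.paired_positions
        runs: list[tuple[int, ...]] = []
        run: list[int] = []
        for p in range(1, n + 1):
            if p in paired:
                if run:
                    runs.append(tuple(run))
                    run = []
            else:
                run.append(p)
        if run:
            runs.append(tuple(run))
        return runs

    def _closed(self, run: tuple[int, ...]) -> bool:
        """A run is a closed hairpin loop when its two flanking positions
        are paired *to each other* (a stem encloses it)."""
        lo, hi = run[0] - 1, run[-1] + 1
        return (lo, hi) in self.stem_pairs

    def accessible_positions(self) -> tuple[int, ...]:
        """Positions a primer zone could pair with.

        Open single-stranded runs (dumbbell middles, 3' tails) are fully
        accessible.  Closed hairpin loops first zip up: complementary
        positions pair inward from the loop ends, and only the unzippable
        innermost remainder stays accessible.  This reproduces the single
        accessible loop letters of the paper's hairpins (D of Z9_hp, A and
        d of the two Z21_hpS).
        """
        out: list[int] = []
        for run in self.loops():
            if not self._closed(run):
                out.extend(run)
                continue
            a, b = 0, len(run) - 1
            while a < b and self.strand.token_at(run[a]).pairs_with(self.strand.token_at(run[b])):
                a += 1
                b -= 1
            out.extend(run[a : b + 1])
        return tuple(sorted(out))

    def three_prime_free(self) -> bool:
        """True when the 3' terminus is not locked in a stem or duplex
        (self-priming remains possible)."""
        n = zone_count(self.strand)
        # A 3' end paired by a *terminal* fold-back or duplex is buried; an
        # end paired by its own self-priming event can still breathe via
        # intermediate linearization, which we model by treating the 3'
        # terminus as free unless position n pairs position 1 (a complete
        # terminal stem) or the partner covers it.
        if n in self.partner_extent:
            return False
        return (1, n) not in self.stem_pairs

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_fold_back(cls, fb: FoldBackResult) -> "FoldedStructure":
        return cls(strand=fb.strand, stem_pairs=fb.stem_pairs)

    @classmethod
    def from_self_extension(cls, extended: ZoneStrand, site: int, parent_len: int) -> "FoldedStructure":
        """Hairpin produced by self-priming at ``site`` of a strand that had
        ``parent_len`` zones: the old 3' terminus pairs ``site`` and the new
        tail pairs the old prefix inward."""
        pairs = [(site, parent_len)]
        new_len = zone_count(extended)
        for k in range(1, new_len - parent_len + 1):
            pairs.append((site - 1 - (k - 1), parent_len + k))
        pairs = [(i, j) for i, j in pairs if i >= 1]
        return cls(strand=extended, stem_pairs=tuple(sorted(pairs)))

    @classmethod
    def dumbbell(cls, s: ZoneStrand) -> "FoldedStructure":
        """Fold a dumbbell: terminal hairpins at both ends, open middle.

        The 5' arm pairs position 1 with the nearest complement; the 3' arm
        pairs position n with the farthest (3'-most) complement.  Raises
        :class:`ClassificationError` when either arm cannot form.
        """
        n = zone_count(s)
        if n < 4:
            raise ClassificationError(f"{s}: too short for a dumbbell")
        t5, t3 = s.token_at(1), s.token_at(n)
        j5 = next((j for j in range(2, n) if s.token_at(j).pairs_with(t5)), None)
        i3 = next((i for i in range(n - 1, 1, -1) if s.token_at(i).pairs_with(t3)), None)
        if j5 is None or i3 is None or not (j5 < i3):
            raise ClassificationError(f"{s}: both termini must fold back for a dumbbell")
        return cls(strand=s, stem_pairs=((1, j5), (i3, n)))

    @classmethod
    def duplex(cls, s: ZoneStrand, partner: ZoneStrand, extent: Sequence[int] | None = None) -> "FoldedStructure":
        n = zone_count(s)
        ext = tuple(range(1, n + 1)) if extent is None else tuple(sorted(extent))
        return cls(strand=s, partner=partner, partner_extent=ext)


@dataclass(frozen=True)
class Classification:
    type_label: StructureType
    canonical_name: str
    terminated: bool
    #: Accessible loop letters (e.g. ("D",) for Z9_hp_D), when meaningful.
    loop_letters: tuple[str, ...] = ()
    #: Loop-qualified display name, e.g. "Z9_hp_D"; equals canonical_name
    #: when no single accessible loop letter applies.
    name_with_loop: str = field(default="")

    def __post_init__(self) -> None:
        if not self.name_with_loop:
            object.__setattr__(self, "name_with_loop", self.canonical_name)


#: Basic dumbbells seed LAMP cycles; anything larger is "elongated".  The
#: basic size is 6 zones for the classic layout and 8 for strands carrying
#: the phn extra zones M/N.
def _basic_dmb_size(s: ZoneStrand) -> int:
    return 8 if any(t.letter in ("M", "N") for t in s) else 6


def _primer_site_on(
    structure: FoldedStructure, primers: Sequence[Primer], positions: Sequence[int]
) -> bool:
    if not positions:
        return False
    for p in primers:
        if find_anneal_sites(p, structure.strand, positions, allow_one_zone=True):
            return True
    return False


def classify(structure: FoldedStructure, primers: Sequence[Primer] = ()) -> Classification:
    """Assign the lamplicon type, canonical name and termination flag."""
    s = structure.strand
    n = zone_count(s)

    if structure.tag == "sdmb":
        raise UnsupportedVariantError(
            "semi-dumbbell (sdmb) products arise only in loop-/stem-primer "
            "LAMP variants, which this model does not support"
        )
    if structure.tag == "mtlp":
        return Classification(StructureType.MTLP, f"Z{n}_mtlp", False)
    if structure.tag == "cauliflower":
        return Classification(StructureType.CAULIFLOWER, "cauliflower", False)

    if structure.partner is not None:
        covered = set(structure.partner_extent)
        gaps = [p for p in range(1, n + 1) if p not in covered]
        if not gaps:
            return Classification(StructureType.ZZS, f"Zz{n}S", True)
        # Partially double-stranded: linear, still primable on the gaps.
        return Classification(StructureType.LI, f"Z{n}_li", False)

    pairs = structure.stem_pairs
    if not pairs:
        # Bare strand: a dumbbell if both termini fold back.
        return classify(FoldedStructure.dumbbell(s), primers)

    arms = _terminal_arms(structure)
    if arms == "both":
        inner = _internal_pairs(structure)
        loops = _single_letter_loops(structure)
        if inner:
            # Stem-bulged dumbbell: Z_dmb_hp when a primer reaches the bulge
            # loop, Z_dmb_hpS otherwise.  Supplied, never generated.
            accessible = structure.accessible_positions()
            if _primer_site_on(structure, primers, accessible):
                return Classification(StructureType.DMB_HP, f"Z{n}_dmb_hp", False, loops)
            return Classification(StructureType.DMB_HPS, f"Z{n}_dmb_hpS", True, loops)
        label = StructureType.DMB if n <= _basic_dmb_size(s) else StructureType.DMB_ELONGATED
        name = f"Z{n}_dmb"
        with_loop = f"Z{n}_dmb({loops[-1]})" if loops else name
        return Classification(label, name, False, loops, with_loop)

    # Single hairpin: terminated (hpS) when no primer can anneal on any
    # accessible loop position and the 3' end cannot self-prime.
    accessible = structure.accessible_positions()
    primable = _primer_site_on(structure, primers, accessible)
    can_self_prime = structure.three_prime_free() and any(
        i > 1 for i in find_self_prime_sites(s)
    )
    loops = _single_letter_loops(structure)
    if primable or can_self_prime:
        name = f"Z{n}_hp"
        with_loop = f"Z{n}_hp_{loops[0]}" if len(loops) == 1 else name
        return Classification(StructureType.HP, name, False, loops, with_loop)
    return Classification(StructureType.HPS, f"Z{n}_hpS", True, loops)


def _terminal_arms(structure: FoldedStructure) -> str:
    """"both" when two disjoint terminal hairpins exist (a dumbbell),
    "three_prime"/"five_prime" for single hairpins, "" otherwise."""
    n = zone_count(structure.strand)
    pairs = set(structure.stem_pairs)
    has5 = any(i == 1 for i, _ in pairs)
    has3 = any(j == n for _, j in pairs)
    if has5 and has3 and (1, n) not in pairs:
        # Disjoint arms: the 5' arm closes before the 3' arm opens.
        j5 = max(j for i, j in pairs if i == 1)
        i3 = min(i for i, j in pairs if j == n)
        if j5 < i3:
            return "both"
    if has3 or has5:
        return "three_prime" if has3 else "five_prime"
    return "hairpin"  # internal stem only (self-priming pair)


def _internal_pairs(structure: FoldedStructure) -> list[tuple[int, int]]:
    """Stem pairs not part of either terminal arm cluster (bulges)."""
    n = zone_count(structure.strand)
    pairs = sorted(structure.stem_pairs)
    j5 = max((j for i, j in pairs if i == 1), default=0)
    i3 = min((i for i, j in pairs if j == n), default=n + 1)
    return [
        (i, j)
        for i, j in pairs
        if not (j <= j5 or i >= i3)
    ]


def _single_letter_loops(structure: FoldedStructure) -> tuple[str, ...]:
    """Letters of accessible single-zone loops, 5'->3' (e.g. the A and D
    loops of a basic dumbbell, or the lone D loop of Z9_hp_D)."""
    acc = set(structure.accessible_positions())
    letters = []
    for run in structure.loops():
        inner = [p for p in run if p in acc]
        if len(inner) == 1:
            letters.append(structure.strand.token_at(inner[0]).char)
    return tuple(letters)


def is_terminated(structure: FoldedStructure, primers: Sequence[Primer]) -> bool:
    """True iff no reaction rule can produce a new strand from the
    structure: no primer anneal site on accessible positions and no usable
    self-priming 3' end."""
    return classify(structure, primers).terminated


class TwinNamer:
    """Assigns the (1)/(2) suffixes for dual mirror twins.

    The first-generated strand of a mirror pair gets (1) and its zone-level
    reverse complement gets (2), matching the narrative order in which
    Z6_dmb(1) precedes Z6_dmb(2).  Names are stable across repeated
    queries, so duplicated species within a cycle share one name.
    """

    def __init__(self) -> None:
        self._names: dict[str, str] = {}

    def name(self, s: ZoneStrand, base: str) -> str:
        key = str(s)
        if key in self._names:
            return self._names[key]
        twin = str(reverse_complement(s))
        if twin in self._names and self._names[twin].endswith("(1)"):
            name = f"{base}(2)"
        else:
            name = f"{base}(1)"
        self._names[key] = name
        return name


def canonical_name(
    structure: FoldedStructure,
    primers: Sequence[Primer] = (),
    namer: TwinNamer | None = None,
) -> str:
    """Deterministic canonical name; dumbbell mirror twins get (1)/(2)
    suffixes in provenance order when a :class:`TwinNamer` is supplied."""
    c = classify(structure, primers)
    if namer is not None and c.type_label in (StructureType.DMB, StructureType.DMB_ELONGATED):
        return namer.name(structure.strand, c.canonical_name)
    return c.canonical_name
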