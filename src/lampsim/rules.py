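"""The four rewrite rules of the symbolic LAMP model.

Every event in a LAMP reaction is one of:

* **primer annealing** — a 1- or 2-zone primer pairs its 3'-terminal zone
  (and, for two-zone sites, its 5' zone) with complementary template zones;
* **elongation with strand displacement** — the polymerase copies the
  template 5'-ward of the annealing site, displacing anything paired there;
* **self-priming extension** — a strand's 3'-terminal zone anneals on an
  internal complementary zone of the same strand and is extended, growing
  the strand by the 2n-3 rule;
* **fold-back** — spontaneous terminal self-annealing without extension,
  producing a hairpin (the Z_hpS route).

Templates are never mutated: each rule returns new strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .zones import (
    Provenance,
    ZoneStrand,
    ZoneToken,
    reverse_complement,
    strand,
    zone_count,
)


class PrimerTier(str, Enum):
    """Concentration tier: inner primers are present in excess and act first;
    outer primers act with a delay (lower concentration)."""

    INNER = "inner"
    OUTER = "outer"


@dataclass(frozen=True)
class Primer:
    """A LAMP primer as a 1- or 2-zone strand.

    Classic set: outer ``F`` (F3) and ``e`` (B3); inner composite ``bA``
    (FIP = F1c|F2) and ``Cd`` (BIP = B1c|B2).  phn-LAMP adds the extra
    inner primer ``Mn`` (eFIP or eBIP depending on the arrangement).
    """

    name: str
    tokens: ZoneStrand
    tier: PrimerTier

    def __post_init__(self) -> None:
        if len(self.tokens) not in (1, 2):
            raise ValueError(f"primer {self.name!r} must have 1 or 2 zones, got {len(self.tokens)}")
        if self.tier is PrimerTier.INNER and len(self.tokens) != 2:
            raise ValueError(f"inner primer {self.name!r} must be a 2-zone composite")
        if self.tier is PrimerTier.OUTER and len(self.tokens) != 1:
            raise ValueError(f"outer primer {self.name!r} must be a single zone")

    @classmethod
    def make(cls, text: str, tier: str | PrimerTier, name: str | None = None) -> "Primer":
        s = strand(text)
        return cls(name or text, s, PrimerTier(tier))

    @property
    def three_prime(self) -> ZoneToken:
        return self.tokens[-1]

    @property
    def five_prime(self) -> ZoneToken:
        return self.tokens[0]

    def __str__(self) -> str:  # pragma: no cover - trivial
        return str(self.tokens)


@dataclass(frozen=True)
class AnnealSite:
    """A primer annealing site on a template.

    ``template_pos`` is the 1-based template position paired with the
    primer's 3'-terminal zone; for ``span == 2`` the position
    ``template_pos + 1`` pairs the primer's 5' zone.
    """

    template_pos: int
    span: int

    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.template_pos, self.template_pos + self.span))


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of elongating a primer (or a self-priming 3' end).

    ``new_strand`` is the built strand (primer + copied template
    complement); ``duplex_extent`` pairs new-strand positions with template
    positions; ``displaced`` lists strands that were paired 5' of the site
    and are released by the strand-displacing polymerase; ``null`` marks a
    site at template position 1, where elongation adds nothing.
    """

    new_strand: ZoneStrand
    duplex_extent: tuple[tuple[int, int], ...]
    displaced: tuple[ZoneStrand, ...] = ()
    null: bool = False


def find_anneal_sites(
    p: Primer,
    template: ZoneStrand,
    available: Sequence[int] | None = None,
    *,
    allow_one_zone: bool = False,
) -> list[AnnealSite]:
    """All sites where primer ``p`` can anneal on ``template``.

    ``available`` is the set of template positions currently single-stranded
    (the whole strand when ``None``).  Both positions of a two-zone site
    must be available.  One-zone annealing by a two-zone primer is permitted
    only when ``allow_one_zone`` is set — the engine sets it for loop
    positions of folded structures and for target-provenance templates in
    the preamplification phase, where the paper shows inner primers
    annealing "at first with one zone".
    """
    n = zone_count(template)
    avail = set(range(1, n + 1)) if available is None else set(available)
    want3 = p.three_prime.complement()
    sites: list[AnnealSite] = []
    for i in range(1, n + 1):
        if i not in avail or template.token_at(i) != want3:
            continue
        if len(p.tokens) == 2:
            two_zone = (
                i + 1 <= n
                and i + 1 in avail
                and template.token_at(i + 1) == p.five_prime.complement()
            )
            if two_zone:
                sites.append(AnnealSite(i, 2))
            elif allow_one_zone:
                sites.append(AnnealSite(i, 1))
        else:
            sites.append(AnnealSite(i, 1))
    return sites


def extend_primer(
    p: Primer,
    template: ZoneStrand,
    site: AnnealSite,
    paired: Sequence[ZoneStrand] = (),
) -> ExtensionResult:
    """Elongate primer ``p`` annealed at ``site`` on ``template``.

    The polymerase copies the template from the site to its 5' end:
    ``new_strand = p.tokens + reverse_complement(template[1 .. pos-1])``.
    Displacement is all-or-nothing: every strand in ``paired`` (strands the
    caller knows to be paired 5' of the site) is returned displaced.  A site
    at position 1 yields a null extension (the primer alone, no new zones).
    """
    pos = site.template_pos
    tmpl_tok = template.token_at(pos)
    if not tmpl_tok.pairs_with(p.three_prime):
        raise ValueError(
            f"invalid site: template zone {tmpl_tok} at {pos} does not pair "
            f"primer 3' zone {p.three_prime}"
        )
    if pos == 1:
        return ExtensionResult(
            new_strand=p.tokens.with_meta(provenance=Provenance.PRIMER_EXTENSION),
            duplex_extent=tuple((k, pos + len(p.tokens) - k) for k in range(1, len(p.tokens) + 1)),
            displaced=tuple(paired),
            null=True,
        )
    copied = reverse_complement(template.prefix(pos))
    new = p.tokens.concat(copied).with_meta(provenance=Provenance.PRIMER_EXTENSION)
    # Pair new-strand positions with template positions: the primer occupies
    # template [pos, pos+span-1]; the copied run covers template [1, pos-1].
    extent = []
    for k in range(1, site.span + 1):
        # primer token index (from 3' end) k pairs template pos+k-1
        extent.append((len(p.tokens) - k + 1, pos + k - 1))
    for k in range(1, pos):
        extent.append((len(p.tokens) + k, pos - k))
    return ExtensionResult(
        new_strand=new,
        duplex_extent=tuple(extent),
        displaced=tuple(s.with_meta(provenance=Provenance.DISPLACED) for s in paired),
    )


def find_self_prime_sites(s: ZoneStrand) -> list[int]:
    """Positions i < n where zone i complements the 3'-terminal zone.

    Ordered 3'->5' (largest i first): the paper's self-priming events use
    the 3'-most available site, which gives the 2n-3 growth law.  Within
    the LAMP cycle only zones 'c' and 'B' ever act as the self-priming
    3' termini, a direct consequence of the FIP/BIP 5' halves.
    """
    n = zone_count(s)
    if n < 2:
        return []
    want = s.token_at(n).complement()
    return [i for i in range(n - 1, 0, -1) if s.token_at(i) == want]


def self_extend(s: ZoneStrand, i: int) -> ZoneStrand:
    """Extend a self-primed 3' end: returns ``s + revcomp(s[1 .. i-1])``.

    For the canonical site at i = n - 2 the product has 2n - 3 zones, the
    growth law behind the printed size series.  ``i = 1`` is a null
    extension and returns the strand unchanged.
    """
    if i not in find_self_prime_sites(s):
        raise ValueError(f"position {i} is not a self-priming site of {s}")
    if i == 1:
        return s.with_meta(provenance=Provenance.SELF_EXTENSION)
    return s.concat(reverse_complement(s.prefix(i))).with_meta(
        provenance=Provenance.SELF_EXTENSION
    )


#: Minimum number of zones a fold-back hairpin loop must retain.  Zones are
#: tens of nucleotides long, so this is a conservative geometric choice for
#: spontaneous (extension-free) terminal self-annealing; rule-driven
#: self-priming hairpins may have single-zone loops (the D loop of Z9_hp).
MIN_FOLDBACK_LOOP = 3


@dataclass(frozen=True)
class FoldBackResult:
    """Greedy terminal pairing of a strand onto itself (no elongation)."""

    strand: ZoneStrand
    stem_pairs: tuple[tuple[int, int], ...]

    @property
    def loop(self) -> tuple[int, ...]:
        paired = {p for pair in self.stem_pairs for p in pair}
        return tuple(p for p in range(1, zone_count(self.strand) + 1) if p not in paired)


def fold_back(s: ZoneStrand) -> FoldBackResult:
    """Terminal self-annealing: pair position k with position n+1-k inward
    while complementary, stopping at the first non-complementary pair or
    when the enclosed loop would fall below :data:`MIN_FOLDBACK_LOOP`
    zones.  Returns an empty stem when even the terminal pair fails."""
    if zone_count(s) < 3:
        raise ValueError("fold_back requires at least 3 zones")
    n = zone_count(s)
    pairs = []
    k = 1
    while True:
        i, j = k, n + 1 - k
        if j - i - 1 < MIN_FOLDBACK_LOOP:
            break
        if not s.token_at(i).pairs_with(s.token_at(j)):
            break
        pairs.append((i, j))
        k += 1
    return FoldBackResult(
        strand=s.with_meta(provenance=Provenance.FOLD_BACK),
        stem_pairs=tuple(pairs),
    )
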