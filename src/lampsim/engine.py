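"""Cycle engine: preamplification, the LAMP cycle, NGEL and phn-LAMP.

The engine orchestrates the rewrite rules along the reaction's published
pathway structure:

* **preamplification** — inner primers anneal on the flanked target first
  (they are present in excess), outer primers follow and displace the built
  strands; the phase ends with the first free dumbbell(s);
* **the LAMP cycle** — a basic dumbbell (Z6_dmb, or Z8_dmb in phn-LAMP)
  runs through two mirror-symmetric half-cycles of terminated lamplicons,
  hairpin exports and linearized intermediates, regenerating its own
  species (cycle closure);
* **NGEL** ("next generation of extended lamplicons") — exported hairpins
  grow along the 2n-3 recurrence in the outer contour, shedding elongated
  dumbbells that terminate, grow further, or re-seed new LAMP cycles;
* **phn-LAMP** — the three-inner-primer variant, where the 8-zone dumbbell
  lineage additionally emits 6-zone dumbbells into delayed subcycles and
  spawns the Z11_dmb(N) subcycle lineage.

Exhaustive mode enumerates every branch deterministically; stochastic mode
samples side branches with user weights and a seed.
"""

from __future__ import annotations

import json
import random
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx

from .classify import (
    Classification,
    FoldedStructure,
    StructureType,
    TwinNamer,
    classify,
)
from .rules import (
    AnnealSite,
    Primer,
    PrimerTier,
    extend_primer,
    find_anneal_sites,
    find_self_prime_sites,
    fold_back,
    self_extend,
)
from .zones import (
    Provenance,
    ZoneStrand,
    parse_zone_string,
    reverse_complement,
    zone_count,
)


class LayoutMode(str, Enum):
    CLASSIC = "classic"
    PHN_FORWARD = "phn_forward"
    PHN_BACKWARD = "phn_backward"


class ConfigurationError(ValueError):
    """Raised for layouts whose primers cannot anneal on the target."""


# ---------------------------------------------------------------------------
# Layout


@dataclass(frozen=True)
class TargetLayout:
    """A target zone order plus its primer set.

    Classic LAMP uses four primers on six zones (``FABCDE``); phn-LAMP uses
    five primers (three inner) on eight zones (``FABCDMNE``).
    """

    zone_order: ZoneStrand
    primers: tuple[Primer, ...]
    mode: LayoutMode

    def __post_init__(self) -> None:
        n_primers = len(self.primers)
        if self.mode is LayoutMode.CLASSIC and n_primers != 4:
            raise ConfigurationError(f"classic mode requires 4 primers, got {n_primers}")
        if self.mode is not LayoutMode.CLASSIC and n_primers != 5:
            raise ConfigurationError(f"phn modes require 5 primers, got {n_primers}")
        layout_letters = {t.letter for t in self.zone_order}
        for p in self.primers:
            missing = {t.letter for t in p.tokens} - layout_letters
            if missing:
                raise ConfigurationError(
                    f"primer {p.name!r} anneal zone(s) {sorted(missing)} absent "
                    f"from layout {self.zone_order}"
                )

    @property
    def inner_primers(self) -> tuple[Primer, ...]:
        return tuple(p for p in self.primers if p.tier is PrimerTier.INNER)

    @property
    def outer_primers(self) -> tuple[Primer, ...]:
        return tuple(p for p in self.primers if p.tier is PrimerTier.OUTER)

    @property
    def basic_dmb_size(self) -> int:
        return 8 if self.mode is not LayoutMode.CLASSIC else 6

    @classmethod
    def classic(cls) -> "TargetLayout":
        return cls(
            zone_order=parse_zone_string("FABCDE"),
            primers=(
                Primer.make("F", "outer", name="F3"),
                Primer.make("bA", "inner", name="FIP"),
                Primer.make("Cd", "inner", name="BIP"),
                Primer.make("e", "outer", name="B3"),
            ),
            mode=LayoutMode.CLASSIC,
        )

    @classmethod
    def phn(cls, mode: LayoutMode | str = LayoutMode.PHN_FORWARD) -> "TargetLayout":
        mode = LayoutMode(mode)
        if mode is LayoutMode.CLASSIC:
            raise ConfigurationError("use TargetLayout.classic() for classic mode")
        # The two phn arrangements (FIP+eFIP+BIP vs FIP+BIP+eBIP) are mirror
        # images and amplify identically; both are realized on the
        # 5'-FABCDMNE-3' layout with the extra inner primer Mn.
        return cls(
            zone_order=parse_zone_string("FABCDMNE"),
            primers=(
                Primer.make("F", "outer", name="F3"),
                Primer.make("bA", "inner", name="FIP"),
                Primer.make("Cd", "inner", name="BIP"),
                Primer.make("Mn", "inner", name="eBIP" if mode is LayoutMode.PHN_BACKWARD else "eFIP"),
                Primer.make("e", "outer", name="B3"),
            ),
            mode=mode,
        )


# ---------------------------------------------------------------------------
# Products and reports


@dataclass(frozen=True)
class Product:
    """A named reaction product with its structure and classification."""

    name: str
    strand: ZoneStrand
    structure: FoldedStructure
    classification: Classification
    step: int = 0

    @property
    def zones(self) -> int:
        return zone_count(self.strand)


@dataclass
class CycleReport:
    """Accounting of one LAMP cycle.

    ``terminated`` and ``exports`` count by size-type name (Zz9S, Z15_hp):
    mirror sequence variants of equal size share a name, which is how the
    published per-cycle tallies count.  ``intermediates`` keeps the finer
    twin/loop-qualified names (Z6_dmb(1), Z9_hp_D, ...).
    """

    cycle_index: int = 1
    intermediates: Counter = field(default_factory=Counter)
    terminated: Counter = field(default_factory=Counter)
    exports: Counter = field(default_factory=Counter)
    dmb_in: Counter = field(default_factory=Counter)
    dmb_out: Counter = field(default_factory=Counter)
    #: (step, kind, name, strand-text) audit trail; step is the depth tag.
    product_log: list[tuple[int, str, str, str]] = field(default_factory=list)
    #: Strands available to seed the next cycle, by species name.
    next_seeds: dict[str, ZoneStrand] = field(default_factory=dict)

    @property
    def n_terminated(self) -> int:
        return sum(self.terminated.values())

    @property
    def n_exports(self) -> int:
        return sum(self.exports.values())

    def export_strands(self) -> list[ZoneStrand]:
        return [
            parse_zone_string(text)
            for _, kind, _, text in self.product_log
            if kind == "export"
        ]

    def to_dict(self) -> dict:
        return {
            "cycle_index": self.cycle_index,
            "intermediates": dict(self.intermediates),
            "terminated": dict(self.terminated),
            "exports": dict(self.exports),
            "dmb_in": dict(self.dmb_in),
            "dmb_out": dict(self.dmb_out),
        }


class LineageGraph:
    """Directed graph of products (nodes) and rule applications (edges)."""

    def __init__(self, name: str = "lineage") -> None:
        self.g = nx.DiGraph(name=name)
        self.truncated: list[str] = []

    def add_product(self, name: str, strand: ZoneStrand, cls: Classification, **attrs) -> str:
        node = name
        if node not in self.g:
            self.g.add_node(
                node,
                strand=str(strand),
                zones=zone_count(strand),
                type=cls.type_label.value,
                terminated=cls.terminated,
                **attrs,
            )
        return node

    def add_edge(self, src: str, dst: str, rule: str, primer: str | None = None, **attrs) -> None:
        self.g.add_edge(src, dst, rule=rule, primer=primer or "", **attrs)

    @property
    def nodes(self):
        return self.g.nodes

    def names(self) -> set[str]:
        return set(self.g.nodes)

    def children(self, node: str) -> set[str]:
        return set(self.g.successors(node))

    def to_dot(self) -> str:
        lines = [f'digraph "{self.g.name}" {{', "  rankdir=LR;"]
        for n, d in self.g.nodes(data=True):
            color = "red" if d.get("terminated") else "black"
            label = f'{n}\\n{d.get("strand", "")}'
            lines.append(f'  "{n}" [label="{label}", color={color}];')
        for u, v, d in self.g.edges(data=True):
            label = d.get("rule", "")
            if d.get("primer"):
                label += f' {d["primer"]}'
            lines.append(f'  "{u}" -> "{v}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class SimulationReport:
    layout_mode: str
    cycles: list[CycleReport] = field(default_factory=list)
    species: dict[str, dict] = field(default_factory=dict)
    size_series_audit: dict[str, list[int]] = field(default_factory=dict)
    truncations: list[str] = field(default_factory=list)
    ngel: LineageGraph | None = None

    def record_species(self, name: str, cycle_index: int, count: int, zones: int) -> None:
        entry = self.species.setdefault(
            name, {"name": name, "first_cycle": cycle_index, "count": 0, "zones": zones}
        )
        entry["count"] += count

    def to_dict(self) -> dict:
        return {
            "layout_mode": self.layout_mode,
            "cycles": [c.to_dict() for c in self.cycles],
            "species": sorted(self.species.values(), key=lambda e: (e["zones"], e["name"])),
            "size_series_audit": self.size_series_audit,
            "truncations": self.truncations,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# ---------------------------------------------------------------------------
# Size series


def size_series(n0: int, steps: int) -> list[int]:
    """Lamplicon growth series under the self-priming recurrence
    ``Z_i = 2 * Z_{i-1} - 3``.

    From the 6-zone dumbbell: 6, 9, 15, 27, 51, 99, ...; from the 8-zone
    phn dumbbell: 8, 13, 23, 43, 83, 163, ...; 3 is the fixed point.
    """
    if n0 < 3:
        raise ValueError(f"series start must be >= 3 zones, got {n0}")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    out = [n0]
    for _ in range(steps):
        out.append(2 * out[-1] - 3)
    return out


# ---------------------------------------------------------------------------
# Preamplification


def preamplify(layout: TargetLayout) -> list[Product]:
    """Run the preamplification cascade on the flanked target.

    Inner primers anneal first (concentration excess); delayed outer-primer
    elongation then displaces the built strands, which template the inner
    primers again; outer-primer elongation on those releases the first free
    dumbbell(s): Z6_dmb(1) in classic mode, Z8_dmb(1) *and* Z6_dmb(1) in
    phn mode.  Returns all named products including the T2-T4 intermediates
    and the final flanked duplex.
    """
    target = layout.zone_order.with_meta(id="T1", provenance=Provenance.TARGET)
    target = ZoneStrand(target.tokens, id="T1", provenance=Provenance.TARGET, flank5=True, flank3=True)
    products: list[Product] = []
    namer = TwinNamer()

    def record(name: str, s: ZoneStrand, structure: FoldedStructure, step: int) -> Product:
        cls = classify(structure, layout.primers)
        prod = Product(name, s, structure, cls, step)
        products.append(prod)
        return prod

    # Step 1: inner primers anneal on the target (one-zone, the 5' halves
    # overhang) and are elongated; the 3'-most product survives attached,
    # products 5' of it are displaced by its elongation.
    inner_products: list[tuple[Primer, ZoneStrand]] = []
    for p in layout.inner_primers:
        sites = find_anneal_sites(p, target, allow_one_zone=True)
        for site in sites:
            ext = extend_primer(p, target, site)
            built = ZoneStrand(
                ext.new_strand.tokens,
                id=f"pre:{p.name}",
                provenance=Provenance.PRIMER_EXTENSION,
                flank3=target.flank5,
            )
            inner_products.append((p, built))
    if not inner_products:
        raise ConfigurationError("no inner primer can anneal on the target")
    t_index = 2
    displaced_templates: list[ZoneStrand] = []
    for p, built in sorted(inner_products, key=lambda pb: -zone_count(pb[1])):
        name = f"T{t_index}"
        record(name, built, FoldedStructure.duplex(built, target, range(1, zone_count(built) + 1)), 1)
        displaced_templates.append(built.with_meta(id=name, provenance=Provenance.DISPLACED))
        t_index += 1

    # Step 2: the delayed outer primer (e) elongates on the target and
    # displaces every inner product, leaving the flanked duplex.
    back_outer = next(
        (p for p in layout.outer_primers if find_anneal_sites(p, target)), None
    )
    if back_outer is not None:
        site = find_anneal_sites(back_outer, target)[0]
        ext = extend_primer(back_outer, target, site, paired=displaced_templates)
        duplex = FoldedStructure.duplex(target, ext.new_strand, range(1, site.template_pos + 1))
        record("flanked_duplex", target, duplex, 2)

    # Step 3: on each displaced strand, the forward inner primer builds the
    # dumbbell strand and the forward outer primer (F) displaces it free.
    dumbbells: list[Product] = []
    for tmpl in displaced_templates:
        for p in layout.inner_primers:
            for site in find_anneal_sites(p, tmpl, allow_one_zone=True):
                ext = extend_primer(p, tmpl, site)
                dmb_strand = ext.new_strand.with_meta(provenance=Provenance.DISPLACED)
                try:
                    structure = FoldedStructure.dumbbell(dmb_strand)
                except Exception:
                    continue
                cls = classify(structure, layout.primers)
                if cls.type_label not in (StructureType.DMB, StructureType.DMB_ELONGATED):
                    continue
                name = namer.name(dmb_strand, cls.canonical_name)
                dumbbells.append(record(name, dmb_strand, structure, 3))
        for p in layout.outer_primers:
            for site in find_anneal_sites(p, tmpl):
                ext = extend_primer(p, tmpl, site)
                record(
                    f"T{t_index}",
                    ext.new_strand,
                    FoldedStructure.duplex(ext.new_strand, tmpl, range(1, zone_count(ext.new_strand) + 1)),
                    4,
                )
                t_index += 1
    if not dumbbells:
        raise ConfigurationError("preamplification produced no dumbbell structure")
    return products


# ---------------------------------------------------------------------------
# The LAMP cycle


@dataclass
class _HalfResult:
    """Products of one half of a LAMP cycle from a basic dumbbell seed.

    Per half, steps are: 1 — the competing two-zone primer annealing
    terminates a copy of the seed (ZzS) and any open-middle one-zone
    annealing emits a smaller dumbbell; 2 — self-priming grows the seed to
    a hairpin whose loop is opened by a one-zone primer (linearization),
    and the li template's free 3' end self-extends into the export hairpin;
    3 — the two-zone primer terminates the li (ZzS) and displaces the
    mirror-twin dumbbell, which starts the second half (or closes the
    cycle).
    """

    seed: ZoneStrand
    zzs_small: ZoneStrand | None = None
    hp: ZoneStrand | None = None
    hp_structure: FoldedStructure | None = None
    li_built: ZoneStrand | None = None
    export: ZoneStrand | None = None
    export_structure: FoldedStructure | None = None
    zzs_large: ZoneStrand | None = None
    freed: ZoneStrand | None = None
    emissions: list[ZoneStrand] = field(default_factory=list)
    extra_li_products: list[tuple[str, ZoneStrand]] = field(default_factory=list)


def _two_zone_full_site(primers: Sequence[Primer], template: ZoneStrand) -> tuple[Primer, AnnealSite] | None:
    """The two-zone site whose elongation copies the whole template
    (primer 3' zone on position n-1, 5' zone on position n)."""
    n = zone_count(template)
    for p in primers:
        for site in find_anneal_sites(p, template):
            if site.span == 2 and site.template_pos == n - 1:
                return p, site
    return None


def _half_cycle(seed: ZoneStrand, layout: TargetLayout) -> _HalfResult:
    res = _HalfResult(seed=seed)
    inner = layout.inner_primers
    n = zone_count(seed)

    # Step 1a: competing two-zone annealing on the unfolded seed -> ZzS.
    full = _two_zone_full_site(inner, seed)
    if full is not None:
        p, site = full
        res.zzs_small = extend_primer(p, seed, site).new_strand

    # Step 1b: one-zone annealing on the dumbbell's open middle emits a
    # smaller dumbbell (phn: Cd on the D zone of Z8_dmb(1) -> Z6_dmb(2)),
    # displaced by the subsequent two-zone elongation.
    dmb = FoldedStructure.dumbbell(seed)
    open_positions = [
        pos for run in dmb.loops() if not dmb._closed(run) for pos in run
    ]
    for p in inner:
        for site in find_anneal_sites(p, seed, open_positions, allow_one_zone=True):
            if site.span == 1 and site.template_pos > 1:
                emitted = extend_primer(p, seed, site).new_strand
                if zone_count(emitted) < n:
                    res.emissions.append(emitted)

    # Step 2a: self-priming at the 3'-most site grows the hairpin (2n-3).
    sites = [i for i in find_self_prime_sites(seed) if i > 1]
    if not sites:
        return res
    res.hp = self_extend(seed, sites[0])
    res.hp_structure = FoldedStructure.from_self_extension(res.hp, sites[0], n)

    # Step 2b: a one-zone primer opens the hairpin loop (linearization) and
    # builds the mirror-twin strand on the template.
    loop_positions = res.hp_structure.accessible_positions()
    for p in inner:
        for site in find_anneal_sites(p, res.hp, loop_positions, allow_one_zone=True):
            res.li_built = extend_primer(p, res.hp, site).new_strand
            li_covered = list(range(1, site.template_pos + len(p.tokens)))
            break
        if res.li_built is not None:
            break
    if res.li_built is None:
        return res

    # Step 2c: the li template's free 3' end self-extends -> export hairpin.
    m = zone_count(res.hp)
    free = [p_ for p_ in range(1, m + 1) if p_ not in li_covered]
    exp_sites = [i for i in find_self_prime_sites(res.hp) if i in free and i > 1]
    if exp_sites:
        res.export = self_extend(res.hp, exp_sites[0])
        res.export_structure = FoldedStructure.from_self_extension(res.export, exp_sites[0], m)

    # Step 3: two-zone annealing on the li's free region terminates it and
    # displaces the mirror twin.
    full_li = None
    for p in inner:
        for site in find_anneal_sites(p, res.hp, free):
            if site.span == 2 and site.template_pos == m - 1:
                full_li = (p, site)
    if full_li is not None:
        p, site = full_li
        res.zzs_large = extend_primer(p, res.hp, site, paired=[res.li_built]).new_strand
        res.freed = res.li_built.with_meta(provenance=Provenance.DISPLACED)

    # Extra li events (phn): one-zone annealing on the li free region that
    # initiates a new size range (Cd on Z13_li(2) -> Z11_dmb(N)).
    for p in inner:
        for site in find_anneal_sites(p, res.hp, free, allow_one_zone=True):
            if site.span == 1 and site.template_pos > 1:
                built = extend_primer(p, res.hp, site).new_strand
                if zone_count(built) not in (n, m):
                    res.extra_li_products.append((p.name, built))
    return res


#: Step-delay budgets (in classic-pathway steps, 6 = a full cycle) of the
#: four Z6_dmb subcycles engendered by the Z8_dmb lineage within one
#: phn-LAMP main cycle.  The first emitted Z6_dmb(2) completes a full
#: subcycle ("comes again to dmb(2) via dmb(1)"); the three later ones are
#: progressively delayed and only their leading products fall inside
#: cycle-1 accounting.
PHN_SUBCYCLE_BUDGETS = (6, 4, 1, 1)


class _CycleRun:
    """Shared bookkeeping for one run_cycle invocation."""

    def __init__(self, layout: TargetLayout, rng: random.Random | None, weight: float):
        self.layout = layout
        self.namer = TwinNamer()
        self.report = CycleReport()
        self.li_counter: Counter = Counter()
        self.rng = rng
        self.weight = weight

    def _keep(self) -> bool:
        """Branch-inclusion decision: exhaustive mode keeps every branch;
        stochastic mode samples side branches with the configured weight."""
        if self.rng is None:
            return True
        return self.rng.random() < self.weight

    def log(self, step: int, kind: str, name: str, strand: ZoneStrand) -> None:
        self.report.product_log.append((step, kind, name, str(strand)))

    def run_dmb_pathway(
        self, seed: ZoneStrand, budget: int, base_step: int = 0, count_closure: bool = True
    ) -> None:
        """Run the two-half cycle pathway from a basic dumbbell seed,
        keeping only products whose step index is within ``budget``.

        ``count_closure`` is False for delayed subcycles, whose regenerated
        seed replaces the consumed emission already counted in dmb_out.
        """
        layout = self.layout
        current = seed
        for half in (0, 1):
            base = base_step + 3 * half
            if base >= base_step + budget:
                return
            res = _half_cycle(current, layout)
            seed_name = self.namer.name(current, f"Z{zone_count(current)}_dmb")
            self.report.intermediates[seed_name] += 1
            if res.zzs_small is not None and self._keep():
                nm = f"Zz{zone_count(current)}S"
                self.report.terminated[nm] += 1
                self.log(base + 1, "terminated", nm, res.zzs_small)
            for emitted in res.emissions:
                name = self.namer.name(emitted, f"Z{zone_count(emitted)}_dmb")
                self.report.dmb_out[f"Z{zone_count(emitted)}_dmb"] += 1
                self.log(base + 1, "emission", name, emitted)
            if res.hp is None or base + 1 >= base_step + budget:
                return
            hp_cls = classify(res.hp_structure, layout.primers)
            self.report.intermediates[hp_cls.name_with_loop] += 1
            if res.export is not None and self._keep():
                exp_name = f"Z{zone_count(res.export)}_hp"
                self.report.exports[exp_name] += 1
                self.log(base + 2, "export", exp_name, res.export)
            if res.li_built is None or base + 2 >= base_step + budget:
                return
            m = zone_count(res.hp)
            self.li_counter[m] += 1
            self.report.intermediates[f"Z{m}_li({self.li_counter[m]})"] += 1
            if res.zzs_large is not None and self._keep():
                nm = f"Zz{m}S"
                self.report.terminated[nm] += 1
                self.log(base + 3, "terminated", nm, res.zzs_large)
            for primer_name, built in res.extra_li_products:
                name = self.namer.name(built, f"Z{zone_count(built)}_dmb")
                self.log(base + 3, "new_lineage", name, built)
            if res.freed is None:
                return
            current = res.freed
        # Cycle closure: the strand freed by the second half repeats the
        # entering seed species.
        closure_name = f"Z{zone_count(current)}_dmb"
        if count_closure:
            self.report.dmb_out[closure_name] += 1
        self.report.next_seeds.setdefault(closure_name, current)
        self.log(base_step + 6, "closure", self.namer.name(current, closure_name), current)


def _require_basic_dmb(seed: ZoneStrand, layout: TargetLayout) -> None:
    try:
        cls = classify(FoldedStructure.dumbbell(seed), layout.primers)
    except Exception as exc:
        raise ValueError(f"run_cycle seed {seed} is not a dumbbell: {exc}") from exc
    if cls.type_label is not StructureType.DMB:
        raise ValueError(f"run_cycle seed {seed} is not a basic dumbbell ({cls.canonical_name})")


def run_cycle(
    seed: ZoneStrand | Sequence[ZoneStrand],
    layout: TargetLayout,
    *,
    cycle_index: int = 1,
    rng: random.Random | None = None,
    branch_weight: float = 0.5,
) -> CycleReport:
    """One full LAMP cycle from basic dumbbell seed(s).

    Classic mode (seed Z6_dmb(1)): six intermediates, four terminated
    lamplicons {Zz6S x2, Zz9S x2} and two Z15_hp exports; the seed species
    is regenerated (dumbbell flux 1 -> 1).

    phn mode (seeds Z8_dmb(1) + Z6_dmb(1)): the Z8 lineage adds Zz8S and
    Zz13S pairs, exports two Z23_hp, emits four Z6_dmb into delayed
    subcycles whose in-cycle products complete the published accounting
    (18 terminated, 7 exports, Z6_dmb flux 1 -> 5), and initiates the
    Z11_dmb(N) lineage whose first event terminates as Zz11S.
    """
    seeds = [seed] if isinstance(seed, ZoneStrand) else list(seed)
    if not seeds:
        raise ValueError("run_cycle requires at least one seed")
    for s in seeds:
        _require_basic_dmb(s, layout)
    run = _CycleRun(layout, rng, branch_weight)
    run.report.cycle_index = cycle_index

    # Register the entering seeds with the twin namer first, so that the
    # preamplification-born species keep their (1) suffixes and strands
    # emitted mid-cycle get (2).
    for s in seeds:
        run.namer.name(s, f"Z{zone_count(s)}_dmb")

    # Z6-sized seeds run the plain classic pathway; the Z8 seed (phn) runs
    # its own pathway plus the delayed Z6 subcycles it engenders.
    delayed: list[tuple[ZoneStrand, int]] = []
    for s in seeds:
        n = zone_count(s)
        run.report.dmb_in[f"Z{n}_dmb"] += 1
        run.run_dmb_pathway(s, budget=6)
        if n != layout.basic_dmb_size or n == 6:
            continue
        # The first Cd-emitted Z6_dmb(2) enters a full subcycle; the Z8
        # lineage engenders three more at increasing delays.
        emitted = [
            parse_zone_string(text)
            for _, kind, _, text in run.report.product_log
            if kind == "emission"
        ]
        if emitted:
            e1 = emitted[0]
            budgets = PHN_SUBCYCLE_BUDGETS
            delayed.append((e1, budgets[0]))
            for b in budgets[1:]:
                delayed.append((e1, b))
                run.report.dmb_out[f"Z{zone_count(e1)}_dmb"] += 1
        # The Z11_dmb(N) lineage initiated on Z13_li(2): its first subcycle
        # event (Mn two-zone annealing) terminates as Zz11S, the
        # deepest-delayed terminated product of cycle-1 accounting.
        for _, kind, _name, text in list(run.report.product_log):
            if kind == "new_lineage":
                z11 = parse_zone_string(text)
                full = _two_zone_full_site(layout.inner_primers, z11)
                if full is not None and run._keep():
                    p_, site_ = full
                    zzs = extend_primer(p_, z11, site_).new_strand
                    nm = f"Zz{zone_count(z11)}S"
                    run.report.terminated[nm] += 1
                    run.log(7, "terminated", nm, zzs)
    for sub_seed, budget in delayed:
        run.run_dmb_pathway(sub_seed, budget=budget, base_step=0, count_closure=False)
    return run.report


# ---------------------------------------------------------------------------
# NGEL expansion


def ngel_expand(hp: ZoneStrand, layout: TargetLayout, max_zones: int, graph: LineageGraph | None = None) -> LineageGraph:
    """Expand an exported hairpin through the outer NGEL contour.

    Follows hp -> li -> next hp chains along the 2n-3 recurrence, recording
    the terminated duplexes, the displaced elongated dumbbells and each
    dumbbell's three self-folding outcomes, plus the basic-dumbbell
    re-seeds that enter new LAMP cycles.  Expansion stops at ``max_zones``;
    oversize products are recorded as truncations.
    """
    if max_zones < zone_count(hp):
        raise ValueError("max_zones must be >= the entry hairpin size")
    graph = graph or LineageGraph(name="ngel")
    namer = TwinNamer()
    primers = layout.inner_primers
    basic = layout.basic_dmb_size

    def node_for(s: ZoneStrand, structure: FoldedStructure, **attrs) -> str:
        cls = classify(structure, layout.primers)
        if cls.type_label in (StructureType.DMB, StructureType.DMB_ELONGATED):
            name = namer.name(s, cls.canonical_name) if zone_count(s) <= basic else cls.canonical_name
        else:
            name = cls.canonical_name
        return graph.add_product(name, s, cls, **attrs)

    seen_hp: set[str] = set()
    seen_dmb: set[str] = set()

    def expand_hp(s: ZoneStrand, structure: FoldedStructure) -> str:
        name = node_for(s, structure)
        if name in seen_hp:
            return name
        seen_hp.add(name)
        n = zone_count(s)
        # Linearization: a one-zone primer opens the loop.
        li_built = None
        for p in primers:
            for site in find_anneal_sites(p, s, structure.accessible_positions(), allow_one_zone=True):
                li_built = extend_primer(p, s, site).new_strand
                li_covered = set(range(1, site.template_pos + len(p.tokens)))
                li_primer = p
                break
            if li_built is not None:
                break
        if li_built is None:
            return name
        li_node = graph.add_product(
            f"Z{n}_li", s, classify(FoldedStructure.duplex(s, li_built, sorted(li_covered)), layout.primers)
        )
        graph.add_edge(name, li_node, "anneal+extend", li_primer.name)
        handle_displaced(li_built, li_node)
        free = [p_ for p_ in range(1, n + 1) if p_ not in li_covered]
        # Two-zone annealing on the free region: the 3'-most terminates the
        # template (ZzS); internal ones build smaller displaced dumbbells.
        for p in primers:
            for site in find_anneal_sites(p, s, free):
                if site.span != 2:
                    continue
                built = extend_primer(p, s, site).new_strand
                if site.template_pos == n - 1:
                    zz = graph.add_product(f"Zz{n}S", s, classify(FoldedStructure.duplex(s, built), layout.primers))
                    graph.add_edge(li_node, zz, "anneal+extend", p.name)
                else:
                    handle_displaced(built, li_node, via=p.name)
        # Self-extension of the free 3' end: the next hairpin of the series.
        exp_sites = [i for i in find_self_prime_sites(s) if i in free and i > 1]
        if exp_sites:
            grown = self_extend(s, exp_sites[0])
            if zone_count(grown) > max_zones:
                graph.truncated.append(f"Z{zone_count(grown)}_hp")
            else:
                g_struct = FoldedStructure.from_self_extension(grown, exp_sites[0], n)
                child = expand_hp(grown, g_struct)
                graph.add_edge(li_node, child, "self_extend")
        return name

    def handle_displaced(s: ZoneStrand, parent: str, via: str | None = None) -> None:
        n = zone_count(s)
        try:
            structure = FoldedStructure.dumbbell(s)
        except Exception:
            return
        name = node_for(s, structure)
        graph.add_edge(parent, name, "displaced", via)
        if n <= basic:
            graph.g.nodes[name]["reseed"] = True  # enters a new LAMP cycle
            return
        if name in seen_dmb:
            return
        seen_dmb.add(name)
        # Three self-folding outcomes: fold-back (no elongation) and the
        # self-priming extensions; plus primer annealing on the open strand.
        fb = fold_back(s)
        if fb.stem_pairs:
            fb_struct = FoldedStructure.from_fold_back(fb)
            fb_node = node_for(s, fb_struct)
            graph.add_edge(name, fb_node, "fold_back")
        for i in find_self_prime_sites(s):
            if i <= 1:
                continue
            grown = self_extend(s, i)
            if zone_count(grown) > max_zones:
                graph.truncated.append(f"Z{zone_count(grown)}_hp")
                continue
            g_struct = FoldedStructure.from_self_extension(grown, i, n)
            cls = classify(g_struct, layout.primers)
            child = graph.add_product(cls.canonical_name, grown, cls)
            graph.add_edge(name, child, "self_extend")
            if cls.type_label is StructureType.HP:
                expand_hp(grown, g_struct)
        for p in primers:
            for site in find_anneal_sites(p, s):
                if site.span != 2:
                    continue
                built = extend_primer(p, s, site).new_strand
                if site.template_pos == n - 1:
                    zz = graph.add_product(f"Zz{n}S", s, classify(FoldedStructure.duplex(s, built), layout.primers))
                    graph.add_edge(name, zz, "anneal+extend", p.name)
                else:
                    handle_displaced(built, name, via=p.name)
        # One-zone annealing on the open middle sheds basic dumbbells
        # (Z9_dmb -> Z6_dmb(2) and the phn analogues).
        dmb_fold = structure
        open_positions = [
            pos for run_ in dmb_fold.loops() if not dmb_fold._closed(run_) for pos in run_
        ]
        for p in primers:
            for site in find_anneal_sites(p, s, open_positions, allow_one_zone=True):
                if site.span == 1 and site.template_pos > 1:
                    built = extend_primer(p, s, site).new_strand
                    if zone_count(built) < n:
                        handle_displaced(built, name, via=p.name)

    entry_sites = find_self_prime_sites(hp)
    # Entry hairpins arrive folded from their generating self-extension.
    parent_len = (zone_count(hp) + 3) // 2
    site = next((i for i in entry_sites if i == parent_len - 2), entry_sites[0] if entry_sites else None)
    if site is not None and site > 1:
        structure = FoldedStructure.from_self_extension(hp, site, parent_len)
    else:
        structure = FoldedStructure.from_fold_back(fold_back(hp))
    expand_hp(hp, structure)
    return graph


# ---------------------------------------------------------------------------
# The Z11_dmb(N) subcycle of phn-LAMP


def run_phn_subcycle_z11(layout: TargetLayout, max_zones: int | None = None) -> LineageGraph:
    """The subcycle lineage of the Z11_dmb(N) lamplicon in phn-LAMP.

    From Z11_dmb(N) = CdcbABCDMNm: Mn two-zone annealing terminates it as
    Zz11S; self-priming grows it to Z19_hp (2*11 - 3); loop opening by Mn
    linearizes Z19 and builds Z11_dmb(1); bA and Cd on the linearized
    strand build Z16_dmb(D) and terminate as Zz19S; Cd on the open middle
    sheds Z9_dmb(D), whose descendants Z15_hp(D)/Z15_li(D) cannot shed a
    6-zone dumbbell (a dead-end branch for re-seeding).
    """
    if layout.mode is LayoutMode.CLASSIC:
        raise ConfigurationError("the Z11_dmb subcycle exists only in phn mode")
    max_zones = max_zones or 43
    graph = LineageGraph(name="z11_subcycle")
    primers = layout.inner_primers
    z11 = parse_zone_string("CdcbABCDMNm")
    z11_struct = FoldedStructure.dumbbell(z11)
    z11_node = graph.add_product("Z11_dmb(N)", z11, classify(z11_struct, layout.primers))

    # Termination: Mn anneals with two zones.
    full = _two_zone_full_site(primers, z11)
    assert full is not None
    p, site = full
    zzs = extend_primer(p, z11, site).new_strand
    zz_node = graph.add_product("Zz11S", z11, classify(FoldedStructure.duplex(z11, zzs), layout.primers))
    graph.add_edge(z11_node, zz_node, "anneal+extend", p.name)

    # Self-priming: Z19_hp.
    sp = [i for i in find_self_prime_sites(z11) if i > 1][0]
    z19 = self_extend(z11, sp)
    z19_struct = FoldedStructure.from_self_extension(z19, sp, zone_count(z11))
    z19_node = graph.add_product("Z19_hp", z19, classify(z19_struct, layout.primers))
    graph.add_edge(z11_node, z19_node, "self_extend")

    # Linearization by Mn on the N loop builds Z11_dmb(1).
    li_built = None
    for p_ in primers:
        for s_ in find_anneal_sites(p_, z19, z19_struct.accessible_positions(), allow_one_zone=True):
            li_built = extend_primer(p_, z19, s_).new_strand
            li_covered = set(range(1, s_.template_pos + len(p_.tokens)))
            li_primer = p_
            break
        if li_built is not None:
            break
    assert li_built is not None
    li_node = graph.add_product(
        "Z19_li", z19, classify(FoldedStructure.duplex(z19, li_built, sorted(li_covered)), layout.primers)
    )
    graph.add_edge(z19_node, li_node, "anneal+extend", li_primer.name)
    z11_1_node = graph.add_product(
        "Z11_dmb(1)", li_built, classify(FoldedStructure.dumbbell(li_built), layout.primers)
    )
    graph.add_edge(li_node, z11_1_node, "displaced", li_primer.name)

    # bA builds Z16_dmb(D); Cd terminates the linearized strand as Zz19S.
    n19 = zone_count(z19)
    free = [q for q in range(1, n19 + 1) if q not in li_covered]
    z16 = None
    for p_ in primers:
        for s_ in find_anneal_sites(p_, z19, free):
            if s_.span != 2:
                continue
            built = extend_primer(p_, z19, s_).new_strand
            if s_.template_pos == n19 - 1:
                zz19 = graph.add_product(
                    "Zz19S", z19, classify(FoldedStructure.duplex(z19, built), layout.primers)
                )
                graph.add_edge(li_node, zz19, "anneal+extend", p_.name)
            else:
                z16 = built
                z16_struct = FoldedStructure.dumbbell(built)
                cls16 = classify(z16_struct, layout.primers)
                z16_node = graph.add_product(cls16.name_with_loop, built, cls16)
                graph.add_edge(li_node, z16_node, "displaced", p_.name)

    # Z16_dmb(D) transformations: Cd (sheds a basic dumbbell), bA (builds
    # the 13-zone strand), Cd two-zone (Zz16S) and self-priming (Z29_hp).
    if z16 is not None:
        n16 = zone_count(z16)
        z16_struct = FoldedStructure.dumbbell(z16)
        z16_name = classify(z16_struct, layout.primers).name_with_loop
        open_positions = [
            pos for run_ in z16_struct.loops() if not z16_struct._closed(run_) for pos in run_
        ]
        for p_ in primers:
            for s_ in find_anneal_sites(p_, z16, open_positions, allow_one_zone=True):
                built = extend_primer(p_, z16, s_).new_strand
                if s_.span == 2 and s_.template_pos == n16 - 1:
                    zz16 = graph.add_product(
                        "Zz16S", z16, classify(FoldedStructure.duplex(z16, built), layout.primers)
                    )
                    graph.add_edge(z16_name, zz16, "anneal+extend", p_.name)
                elif zone_count(built) < n16 and s_.template_pos > 1:
                    try:
                        b_struct = FoldedStructure.dumbbell(built)
                    except Exception:
                        continue
                    b_cls = classify(b_struct, layout.primers)
                    b_node = graph.add_product(b_cls.canonical_name, built, b_cls)
                    graph.add_edge(z16_name, b_node, "anneal+extend", p_.name)
        sp16 = [i for i in find_self_prime_sites(z16) if i > 1]
        if sp16 and 2 * n16 - 3 <= max_zones:
            z29 = self_extend(z16, sp16[0])
            z29_struct = FoldedStructure.from_self_extension(z29, sp16[0], n16)
            z29_cls = classify(z29_struct, layout.primers)
            graph.add_edge(z16_name, graph.add_product(z29_cls.canonical_name, z29, z29_cls), "self_extend")

    # Z9_dmb(D): shed from the Z11_dmb(N) open middle by Cd; its Z15_hp(D)
    # descendant linearizes into Z15_li(D), a branch that cannot produce a
    # 6-zone dumbbell.
    open11 = [pos for run_ in z11_struct.loops() if not z11_struct._closed(run_) for pos in run_]
    for p_ in primers:
        for s_ in find_anneal_sites(p_, z11, open11, allow_one_zone=True):
            if s_.span != 1 or s_.template_pos == 1:
                continue
            built = extend_primer(p_, z11, s_).new_strand
            if zone_count(built) >= zone_count(z11):
                continue
            b_struct = FoldedStructure.dumbbell(built)
            b_cls = classify(b_struct, layout.primers)
            z9d_node = graph.add_product(b_cls.name_with_loop, built, b_cls)
            graph.add_edge(z11_node, z9d_node, "anneal+extend", p_.name)
            sp9 = [i for i in find_self_prime_sites(built) if i > 1]
            if sp9:
                z15d = self_extend(built, sp9[0])
                z15d_struct = FoldedStructure.from_self_extension(z15d, sp9[0], zone_count(built))
                z15d_cls = classify(z15d_struct, layout.primers)
                z15d_node = graph.add_product(f"Z{zone_count(z15d)}_hp(D)", z15d, z15d_cls)
                graph.add_edge(z9d_node, z15d_node, "self_extend")
                # Linearization of Z15_hp(D): the built strand is a 9-zone
                # dumbbell again, never a Z6_dmb.
                for p2 in primers:
                    for s2 in find_anneal_sites(p2, z15d, z15d_struct.accessible_positions(), allow_one_zone=True):
                        b2 = extend_primer(p2, z15d, s2).new_strand
                        li15_node = graph.add_product(
                            "Z15_li(D)",
                            z15d,
                            classify(
                                FoldedStructure.duplex(
                                    z15d, b2, range(1, s2.template_pos + len(p2.tokens))
                                ),
                                layout.primers,
                            ),
                        )
                        graph.add_edge(z15d_node, li15_node, "anneal+extend", p2.name)
    return graph


# ---------------------------------------------------------------------------
# Orchestration


def simulate(
    layout: TargetLayout,
    cycles: int = 1,
    max_zones: int | None = None,
    mode: str = "exhaustive",
    seed: int | None = None,
    branch_weight: float = 0.5,
) -> SimulationReport:
    """Run preamplification, ``cycles`` LAMP cycles and NGEL expansion.

    Deterministic in exhaustive mode; reproducible from ``seed`` in
    stochastic mode.  ``max_zones`` defaults to 51 (classic) or 43 (phn),
    keeping the NGEL enumeration finite; the size-series audit extends the
    recurrence analytically beyond.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if mode not in ("exhaustive", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = random.Random(seed) if mode == "stochastic" else None
    if max_zones is None:
        max_zones = 51 if layout.mode is LayoutMode.CLASSIC else 43

    report = SimulationReport(layout_mode=layout.mode.value)
    pre = preamplify(layout)
    seeds = [
        p.strand
        for p in pre
        if p.classification.type_label is StructureType.DMB
    ]
    seed_counts = Counter(str(s) for s in seeds)

    ngel_graph = LineageGraph(name="ngel")
    for index in range(1, cycles + 1):
        unique_seeds = {}
        for s in seeds:
            unique_seeds.setdefault(str(s), s)
        cycle = run_cycle(list(unique_seeds.values()), layout, cycle_index=index, rng=rng, branch_weight=branch_weight)
        report.cycles.append(cycle)
        for name, count in (cycle.terminated + cycle.exports + cycle.intermediates).items():
            m = re.search(r"\d+", name)
            report.record_species(name, index, count, int(m.group()) if m else 0)
        for text in {t for _, kind, _, t in cycle.product_log if kind == "export"}:
            hp = parse_zone_string(text)
            try:
                ngel_expand(hp, layout, max_zones, graph=ngel_graph)
            except ValueError as exc:
                report.truncations.append(str(exc))
        # Seeds for the next cycle: regenerated species plus emissions.
        next_counts: Counter = Counter()
        next_strands: dict[str, ZoneStrand] = dict(cycle.next_seeds)
        for name, count in cycle.dmb_out.items():
            next_counts[name] += count
        for _, kind, _, text in cycle.product_log:
            if kind in ("emission", "closure"):
                s = parse_zone_string(text)
                next_strands.setdefault(f"Z{zone_count(s)}_dmb", s)
        seeds = [next_strands[n] for n in next_counts if n in next_strands]
        seed_counts = next_counts

    report.ngel = ngel_graph
    report.truncations.extend(ngel_graph.truncated)

    # Size-series audit: the engine's main-chain exports against the 2n-3
    # recurrence.
    basic = 6 if layout.mode is LayoutMode.CLASSIC else 8
    report.size_series_audit["main"] = size_series(basic, 5)
    if layout.mode is LayoutMode.CLASSIC:
        report.size_series_audit["secondary"] = size_series(18, 3)
        report.size_series_audit["classic_main"] = size_series(6, 5)
    else:
        report.size_series_audit["classic_main"] = size_series(6, 5)
    return report
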