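"""Bridge between the symbolic zone model and nucleotide space.

Real LAMP assays are designed on DNA: a target sequence carries the
primer-annealing zones as actual subsequences, and the composite inner
primers FIP/BIP (and eFIP/eBIP in phn-LAMP) are concatenations of two zone
sequences.  This module locates a zone layout on a target by exact
matching, expands symbolic lamplicons into DNA, generates synthetic
targets for testing, and writes simulation products to FASTA/JSON/DOT.

Coordinates are 0-based, half-open, on the plus strand.  Matching is exact
by design: the symbolic model assumes perfect annealing, and
mismatch-tolerant site finding is out of scope.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engine import LayoutMode, SimulationReport, TargetLayout
from .zones import ZoneStrand, zone_count

_ZONE_ORDER = {
    LayoutMode.CLASSIC: "FABCDE",
    LayoutMode.PHN_FORWARD: "FABCDMNE",
    LayoutMode.PHN_BACKWARD: "FABCDMNE",
}


class ZoneLocationError(ValueError):
    """A zone could not be located (missing, duplicated or out of order)."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ZoneNucleotideMap:
    """Plus-sense DNA sequence of every zone letter, plus optional flanks."""

    zones: dict[str, str]
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        for letter, seq in self.zones.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"zone {letter}: sequence must be non-empty uppercase ACGT")

    def sequence_of(self, letter: str, plus: bool) -> str:
        try:
            seq = self.zones[letter.upper()]
        except KeyError:
            raise KeyError(f"zone letter {letter!r} is not mapped") from None
        return seq if plus else _revcomp(seq)


@dataclass(frozen=True)
class LocatedLayout:
    """A target layout with per-zone coordinates on the plus strand."""

    layout: TargetLayout
    #: letter -> (start, end), 0-based half-open, plus strand, 5'->3' order.
    coordinates: dict[str, tuple[int, int]]
    nucleotide_map: ZoneNucleotideMap

    def to_dict(self) -> dict:
        return {
            "mode": self.layout.mode.value,
            "zone_order": str(self.layout.zone_order),
            "coordinates": {k: list(v) for k, v in self.coordinates.items()},
        }


def expand(s: ZoneStrand, nmap: ZoneNucleotideMap) -> str:
    """Expand a zone strand to DNA: concatenation 5'->3', with minus-sense
    tokens expanded as nucleotide reverse complements.  A monoid
    homomorphism that commutes with reverse complement."""
    return "".join(nmap.sequence_of(t.letter, t.plus) for t in s)


def primer_sequences(layout: TargetLayout, nmap: ZoneNucleotideMap) -> dict[str, str]:
    """Nucleotide sequences of the layout's primers (FIP = F1c|F2 etc.)."""
    return {p.name: expand(p.tokens, nmap) for p in layout.primers}


def locate_zones(
    target: str,
    primers: dict[str, str],
    mode: LayoutMode | str = LayoutMode.CLASSIC,
    *,
    fip_split: int | None = None,
    bip_split: int | None = None,
    efip_split: int | None = None,
) -> LocatedLayout:
    """Locate the zone layout on ``target`` from primer sequences.

    ``primers`` maps conventional names (F3, B3, FIP, BIP, and eFIP or
    eBIP for phn modes) to 5'->3' DNA.  The composite primers are split
    into their two zone halves at the declared split points (length of the
    5' half; defaults to half the primer).  Every zone must occur exactly
    once, in the layout's 5'->3' order, without overlap.
    """
    mode = LayoutMode(mode)
    target = target.upper()
    if set(target) - set("ACGT"):
        raise ValueError("target must be uppercase ACGT")

    def split(name: str, at: int | None) -> tuple[str, str]:
        seq = primers[name]
        at = at if at is not None else len(seq) // 2
        return seq[:at], seq[at:]

    f1c, f2 = split("FIP", fip_split)
    b1c, b2 = split("BIP", bip_split)
    # Zone plus-strand sequences induced by the primers: F3 and the FIP/BIP
    # halves read directly or via reverse complement depending on which
    # strand they anneal to.
    zone_seqs = {
        "F": primers["F3"],
        "A": f2,
        "B": _revcomp(f1c),
        "C": b1c,
        "D": _revcomp(b2),
        "E": _revcomp(primers["B3"]),
    }
    if mode is not LayoutMode.CLASSIC:
        extra = "eFIP" if "eFIP" in primers else "eBIP"
        m1c, n2 = split(extra, efip_split)
        zone_seqs["M"] = m1c
        zone_seqs["N"] = _revcomp(n2)

    order = _ZONE_ORDER[mode]
    coords: dict[str, tuple[int, int]] = {}
    for letter in order:
        seq = zone_seqs[letter]
        first = target.find(seq)
        if first < 0:
            raise ZoneLocationError(f"zone {letter} ({seq}) not found on target")
        if target.find(seq, first + 1) >= 0:
            raise ZoneLocationError(f"zone {letter} ({seq}) found more than once on target")
        coords[letter] = (first, first + len(seq))
    prev_end = -1
    for letter in order:
        start, end = coords[letter]
        if start < prev_end:
            raise ZoneLocationError(
                f"zone {letter} at {coords[letter]} out of order or overlapping "
                f"for the {mode.value} layout {order}"
            )
        prev_end = end
    layout = TargetLayout.classic() if mode is LayoutMode.CLASSIC else TargetLayout.phn(mode)
    nmap = ZoneNucleotideMap(
        zones=zone_seqs,
        flank5=target[: coords[order[0]][0]],
        flank3=target[coords[order[-1]][1] :],
    )
    return LocatedLayout(layout=layout, coordinates=coords, nucleotide_map=nmap)


def gen_synthetic_target(
    zone_lengths: dict[str, int] | int = 20,
    gc: float = 0.5,
    seed: int = 0,
    mode: LayoutMode | str = LayoutMode.CLASSIC,
    *,
    flank_length: int = 30,
    spacer_length: int = 0,
    max_retries: int = 100,
) -> tuple[SeqRecord, ZoneNucleotideMap, LocatedLayout]:
    """Generate a synthetic LAMP target with its zone map and layout.

    Zones are independent random sequences of the requested GC fraction,
    assembled in the layout order with flanks (and optional fixed-length
    inter-zone spacers, since real targets have gaps between zones).
    Deterministic per seed.  Each zone (and its reverse complement) is
    required to be unique within the target; collisions trigger re-draws.
    """
    mode = LayoutMode(mode)
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    order = _ZONE_ORDER[mode]
    lengths = (
        {letter: zone_lengths for letter in order}
        if isinstance(zone_lengths, int)
        else dict(zone_lengths)
    )
    for letter in order:
        if lengths.get(letter, 0) < 10:
            raise ValueError(f"zone {letter}: length must be >= 10")
    rng = random.Random(seed)

    def draw(length: int) -> str:
        return "".join(
            rng.choice("GC") if rng.random() < gc else rng.choice("AT") for _ in range(length)
        )

    for _ in range(max_retries):
        zones = {letter: draw(lengths[letter]) for letter in order}
        flank5, flank3 = draw(flank_length), draw(flank_length)
        spacers = [draw(spacer_length) for _ in order]
        parts = [flank5]
        for letter, spacer in zip(order, spacers):
            parts.append(zones[letter])
            parts.append(spacer)
        parts.append(flank3)
        target = "".join(parts)
        ok = all(
            target.count(seq) == 1 and target.count(_revcomp(seq)) == 0
            for seq in zones.values()
        )
        if ok:
            break
    else:
        raise RuntimeError(f"could not build unique zones after {max_retries} retries")

    nmap = ZoneNucleotideMap(zones=zones, flank5=flank5, flank3=flank3)
    layout = TargetLayout.classic() if mode is LayoutMode.CLASSIC else TargetLayout.phn(mode)
    coords: dict[str, tuple[int, int]] = {}
    pos = len(flank5)
    for letter, spacer in zip(order, spacers):
        coords[letter] = (pos, pos + lengths[letter])
        pos += lengths[letter] + len(spacer)
    record = SeqRecord(
        Seq(target),
        id=f"synthetic_{mode.value}_{seed}",
        description=f"synthetic LAMP target, mode={mode.value}, seed={seed}",
    )
    return record, nmap, LocatedLayout(layout=layout, coordinates=coords, nucleotide_map=nmap)


def write_products(
    report: SimulationReport,
    nmap: ZoneNucleotideMap,
    path: str | Path,
    *,
    write_dot: bool = False,
) -> dict[str, Path]:
    """Write simulation products: a multi-FASTA of realized lamplicons (one
    record per species, named by canonical name), the JSON report, and
    optionally the NGEL lineage graph as DOT.  Returns the written paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    records = []
    seen: set[str] = set()
    for cycle in report.cycles:
        for _, kind, name, text in cycle.product_log:
            if name in seen or not text:
                continue
            seen.add(name)
            from .zones import parse_zone_string

            s = parse_zone_string(text)
            try:
                dna = expand(s, nmap)
            except KeyError as exc:
                raise ValueError(f"cannot realize {name}: {exc}") from exc
            records.append(
                SeqRecord(Seq(dna), id=name, description=f"{zone_count(s)} zones {text} ({kind})")
            )
    fasta = path / "lamplicons.fasta"
    try:
        SeqIO.write(records, fasta, "fasta")
    except OSError as exc:
        raise OSError(f"writing {fasta}: {exc}") from exc
    written["fasta"] = fasta

    report_path = path / "report.json"
    report_path.write_text(report.to_json())
    written["report"] = report_path

    if write_dot and report.ngel is not None:
        dot = path / "lineage.dot"
        dot.write_text(report.ngel.to_dot())
        written["dot"] = dot
    return written
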