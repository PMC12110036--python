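# lampsim

A symbolic simulator of **loop-mediated isothermal amplification (LAMP)**
and its **pseudo-hemi-nested (phn-LAMP)** variant, for people who design
LAMP primer systems or study what the reaction actually produces.

LAMP runs at constant temperature with a strand-displacing polymerase and
four primers — two outer (F3, B3) and two composite inner primers
(FIP = F1c|F2, BIP = B1c|B2) — and yields a zoo of products
("lamplicons") rather than a single amplicon. `lampsim` models the
reaction as a string-rewriting system over *zones*: each primer-annealing
segment of the target is one letter, uppercase on the plus strand and
lowercase for its reverse complement. The classic target reads
`5'-FABCDE-3'`; the primers are `F`, `bA` (FIP), `Cd` (BIP) and `e`. The
phn-LAMP variant adds a third inner primer `Mn` on the
`5'-FABCDMNE-3'` layout.

Four rewrite rules drive everything:

* **primer annealing** — a primer pairs its 3' zone (and, on open
  templates, its 5' zone too) with complementary template zones;
* **elongation + strand displacement** — the new strand is
  `primer + revcomp(template[1 .. site-1])`, displacing anything paired
  5' of the site;
* **self-priming** — a strand's 3'-terminal zone anneals on an internal
  complement and extends, growing `n` zones to `2n - 3` (hence the
  product ladders `6 → 9 → 15 → 27 → 51 → 99` and, for phn-LAMP,
  `8 → 13 → 23 → 43 → 83 → 163`);
* **fold-back** — spontaneous terminal self-annealing into a hairpin.

Products are classified into ten named types: dumbbells (`Z6_dmb`),
elongated dumbbells, hairpins (`Z9_hp_D`), linearized strands (`Z9_li`),
terminated duplexes (`Zz6S`), dead-end hairpins (`Z9_hpS`), two
stem-bulged dumbbell types, multi-loop structures and cauliflower-like
tangles. The engine reproduces the preamplification cascade, the basic
LAMP cycle (six intermediates, four terminated lamplicons, two exported
`Z15_hp` hairpins per cycle), NGEL growth of exports in the outer
contour, and the phn-LAMP accounting in which one cycle yields 18
terminated lamplicons, 7 exports, and five `Z6_dmb` for every one that
entered. A sequence-level bridge locates zone layouts on real targets by
exact matching and expands symbolic products to DNA (FASTA in/out).

## Worked example

One classic LAMP cycle from the first dumbbell:

```pycon
>>> import lampsim as L
>>> layout = L.TargetLayout.classic()
>>> [str(p.strand) for p in L.preamplify(layout) if p.name.startswith("Z6")]
['bABCDc']
>>> rep = L.run_cycle(L.strand("bABCDc"), layout)
>>> dict(rep.intermediates)
{'Z6_dmb(1)': 1, 'Z9_hp_D': 1, 'Z9_li(1)': 1, 'Z6_dmb(2)': 1, 'Z9_hp_a': 1, 'Z9_li(2)': 1}
>>> dict(rep.terminated), dict(rep.exports)
({'Zz6S': 2, 'Zz9S': 2}, {'Z15_hp': 2})
```

Reading: the entering dumbbell `bABCDc` either terminates as the duplex
`Zz6S` (BIP anneals by two zones at once) or self-primes into the hairpin
`Z9_hp_D`; opening the D loop linearizes it (`Z9_li(1)`) and builds the
mirror-twin dumbbell `CdcbaB = Z6_dmb(2)`, which repeats the steps on the
complementary strand and regenerates `bABCDc` — cycle closure. The two
15-zone hairpins leave for the outer contour, where

```pycon
>>> g = L.ngel_expand(L.self_extend(L.strand("bABCDcbaB"), 7), layout, max_zones=51)
>>> sorted(n for n in g.names() if n.endswith("_hp"))
['Z15_hp', 'Z21_hp', 'Z27_hp', 'Z33_hp', 'Z39_hp', 'Z45_hp', 'Z51_hp']
```

the main chain grows along the `2n - 3` ladder (15, 27, 51), the
secondary `Z18 → Z33` series and off-series multiples of three fill in
the familiar gel ladder, and the chains shed elongated dumbbells
(`Z15_dmb`, `Z18_dmb`), dead-end hairpins (`Z15_hpS`, `Z21_hpS`, ...) and
fresh `Z6_dmb` seeds for new cycles.

The same machinery in phn mode:

```pycon
>>> rep = L.run_cycle([L.strand("bABCDMNm"), L.strand("bABCDc")], L.TargetLayout.phn())
>>> rep.n_terminated, rep.n_exports, rep.dmb_out["Z6_dmb"]
(18, 7, 5)
```

A shell interface mirrors the library: `lampsim simulate`, `lampsim
classify bABCDc`, `lampsim series 8 5`, `lampsim fixture --seed 3 --out
fx/` (synthetic target bundle), `lampsim realize` (products to FASTA).

## Scope

Kinetics in physical time, rate constants, polymerase processivity,
thermodynamic primer design, loop-/stem-primer LAMP variants and their
semi-dumbbell products, and gel-mobility prediction are out of scope; see
`docs/methods.md` for the model's assumptions and limitations.
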