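# Methods

## The symbolic model

`lampsim` treats a LAMP reaction as a rewriting system over strings of
*zones*. A zone is one primer-annealing segment of the target; its
nucleotide content is abstracted away, and only its identity (a letter)
and strand sense (case) are kept. Two zones hybridize exactly when they
carry the same letter with opposite case. The classic layout is
`5'-FABCDE-3'` with primers `F` (F3), `bA` (FIP), `Cd` (BIP) and `e`
(B3); phn-LAMP inserts two extra zones, `5'-FABCDMNE-3'`, and adds the
extra inner primer `Mn`. The two phn arrangements (two forward inner
primers or two backward) are mirror images and are both realized on the
same internal layout. Positions are 1-based, 5'→3'.

The abstraction assumes perfect, all-or-nothing annealing: a zone either
pairs its exact complement or it does not. Mismatch tolerance,
hybridization energetics, annealing probabilities and reaction rates are
deliberately outside the model — the paper-and-pencil chemistry of which
products *can* form, in which order of dependency, is what the model
captures. Where the real reaction chooses stochastically between
competing fates (primer annealing versus self-priming), the engine's
exhaustive mode follows every branch, which is why its per-cycle tallies
count both fates of a species.

## Rules

1. **Annealing.** A 1-zone (outer) primer anneals wherever its
   complement is available. A 2-zone (inner) primer requires both zones
   on open, fully single-stranded templates; on folded structures it may
   anneal by its 3' zone alone on any accessible position ("at first
   with one zone"), and likewise on target-provenance templates during
   preamplification, where the composite primers' 5' halves always
   overhang. Restricting one-zone annealing this way is what keeps the
   product set equal to the published one: permitting it everywhere
   would spawn spurious lineages from every open strand.
2. **Elongation with displacement.** The polymerase copies the template
   from the annealing site to its 5' end:
   `new = primer + revcomp(template[1 .. site-1])`. Displacement is
   all-or-nothing: every strand paired 5' of the site is released.
   Templates are never mutated; a site at position 1 is a recorded null
   extension.
3. **Self-priming.** The 3'-terminal zone anneals on the 3'-most
   internal complement and extends, so an n-zone strand grows to
   `2n - 3` zones — the recurrence `Z_i = 2 Z_{i-1} - 3` behind the
   size series 6, 9, 15, 27, 51, 99 and 8, 13, 23, 43, 83, 163 (3 is the
   fixed point). Shorter internal sites also extend (they produce the
   dead-end hairpin family); a site at position 1 is null.
4. **Fold-back.** Spontaneous terminal self-annealing without
   elongation: positions k and n+1-k pair inward while complementary.
   The greedy pairing stops when the enclosed loop would drop below 3
   zones (`MIN_FOLDBACK_LOOP`) — a conservative geometric floor for an
   extension-free hairpin. Rule-driven self-priming hairpins are not
   subject to it (the D loop of `Z9_hp_D` is a single zone).

## Structure, accessibility, termination

A `FoldedStructure` records a strand, its intramolecular stem pairs
(nested, complementary) and an optional duplex partner. Which positions
a primer can reach is decided by a zip-up model:

* an **open** single-stranded run — a dumbbell middle, a 3' tail — is
  fully accessible;
* a **closed** hairpin loop (its two flanks paired to each other) first
  zips: complementary positions pair inward from the loop ends, and only
  the unzippable core remains accessible.

This single rule reproduces the published loop letters: the 21-zone
dead-end hairpins shed by `Z15_dmb` and `Z18_dmb` have equal size but
zip to different single accessible loops, A and d respectively; and it
simultaneously keeps `Z15_dmb`'s open middle reachable for FIP, which
the re-seeding of new cycles requires.

Termination: a fully paired duplex (`ZzS`) or a hairpin none of whose
accessible positions offers any primer a site and whose 3' terminus is
locked in the stem (`Z_hpS`). Classification covers ten types; the
stem-bulged dumbbells (`Z_dmb_hp`/`Z_dmb_hpS`) and the late-stage
`Z_mtlp`/cauliflower tangles are classification-only labels attached via
caller-supplied tags, since no deterministic rule generates them.
Semi-dumbbell products of loop-/stem-primer LAMP raise an
"unsupported variant" error. Mirror twins (a strand and its zone-level
reverse complement, e.g. `bABCDc`/`CdcbaB`) are numbered (1)/(2) in
order of first appearance.

Note one deliberate asymmetry: classification *with a primer set* is not
invariant under reverse complement, because the primer set itself is not
mirror-symmetric (FIP can reach an `a` loop, nothing reaches an `A`
loop). Geometric type and zone count are mirror-invariant; termination
need not be.

## Cycle accounting

A LAMP cycle is the rewrite path from a basic dumbbell seed to the first
regeneration of that species. Each half-cycle contributes, in step
order: the competing two-zone termination of the seed (`ZzS`), the
self-primed hairpin and its export-sized successor, and the linearized
template's termination, which frees the mirror-twin dumbbell for the
second half. For the classic layout this yields six intermediates
(`Z6_dmb(1)`, `Z9_hp_D`, `Z9_li(1)` and their mirror partners), four
terminated lamplicons (`Zz6S` ×2, `Zz9S` ×2) and two `Z15_hp` exports
per cycle, with the seed species regenerated.

In phn-LAMP the 8-zone dumbbell lineage runs the same skeleton (adding
`Zz8S`/`Zz13S` pairs and two `Z23_hp` exports) and, through one-zone BIP
annealing on its open middle, emits 6-zone dumbbells that enter
*delayed* subcycles. The engine models the delays with a fixed
step-budget schedule, `PHN_SUBCYCLE_BUDGETS = (6, 4, 1, 1)`: the first
emitted `Z6_dmb(2)` completes a full 6-step subcycle; the three later
ones execute only their leading steps before the main cycle closes. All
product strings inside every subcycle are computed through the rules;
the schedule fixes only *how far* each delayed lineage has progressed
when cycle-1 accounting is drawn. Each product carries a step-depth tag
in the report's product log so alternative accountings can be audited.
With this schedule one phn cycle yields 18 terminated lamplicons —
`Zz6S` ×8, `Zz8S` ×2, `Zz9S` ×5, `Zz13S` ×2, plus one `Zz11S` from the
first event of the newly initiated `Z11_dmb(N)` lineage — and 7 exports
(`Z15_hp` ×5, `Z23_hp` ×2), with five `Z6_dmb` exiting for every one
that entered. Counting the `Zz11S` inside cycle 1 is the package's
accounting choice: the `Z11_dmb` strand demonstrably emerges within the
cycle, and its immediate two-zone termination is the deepest-delayed
product the cycle can claim.

Two optional behaviours are off by default: the bimolecular annealing of
free `Z6_dmb(1)` with `Z6_dmb(2)` into `Zz6S` (concentration-dependent,
never counted in cycle reports) and stochastic branch sampling, which
replaces "follow every branch" with seeded inclusion of side branches at
a configurable weight — its species sets are always a subset of
exhaustive mode's.

## NGEL and bounds

Exported hairpins expand in the outer contour by generic application of
the rules: loop opening → linearization (shedding an inner elongated
dumbbell) → two-zone terminations and displaced dumbbells →
self-extension to the next hairpin of the series. Each displaced
elongated dumbbell gets its self-folding outcomes (fold-back plus every
self-priming site), its two-zone terminations, and its one-zone middle
emissions, which include the basic-dumbbell re-seeds that start new
cycles (flagged `reseed` in the lineage graph, not expanded further).
`max_zones` (default 51 classic / 43 phn) bounds the enumeration;
oversize products are recorded as truncations, and the size-series audit
extends the recurrence analytically. The lineage graph is a networkx
`DiGraph` with a small hand-rolled DOT serializer.

`simulate()` chains preamplification, per-cycle accounting and NGEL.
Cycle reports are per seed *species*: copy-number kinetics are a
non-goal, so multiplicities across cycles are tracked as dumbbell
in/out counts, not molecule populations.

## The synthetic-data generator

`gen_synthetic_target` emulates a clean LAMP target: independent random
zones (default 20 nt, GC 0.5, 30-nt flanks, optional fixed inter-zone
spacers defaulting to 0) assembled in layout order, with every zone
unique in the target (re-drawn on collision) and deterministic per seed.
It does *not* emulate cross-hybridizing zones, repeats, primer dimers,
mismatched or degenerate sites, or secondary structure within zones — so
round-trip tests against `locate_zones` demonstrate the exact-matching
bridge and coordinate bookkeeping, not robustness to real genomic
messiness. Zone location is exact-match only and requires each zone
once, in order, without overlap; split points of the composite primers
(lengths of the F1c/B1c halves) are caller-declared.

## Numerical and degenerate-input choices

* Empty strands parse and reverse-complement (the algebra is total); the
  engine rejects empty species.
* Anneal-site enumeration returns sites 5'→3'; self-priming sites
  3'→5' (the 3'-most drives the main chain).
* Two-zone sites take precedence over one-zone at the same position.
* `fold_back` on a strand with non-complementary termini returns an
  empty stem rather than an error; `classify` of a bare strand attempts
  the dumbbell fold and reports a classification error if no fold
  exists.
* Exhaustive mode has no randomness; two runs are byte-identical.

## Known limitations

* The delayed-subcycle schedule reproduces the published phn totals but
  the delays themselves are a modelling interpretation; the per-product
  step-depth tags exist so the decomposition stays inspectable.
* Whether a 2-zone primer may anneal across a stem boundary (one zone in
  a loop, one in a stem) is unresolved chemistry; the engine forbids it
  (both positions must be accessible).
* `Z_mtlp` and cauliflower structures are never generated, only
  classified when tagged.
* The nucleotide bridge is exact-match; no melting temperatures, no
  mismatch scoring, no primer design.
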