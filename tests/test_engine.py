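"""Cycle engine: preamplification, LAMP cycle accounting, NGEL, phn-LAMP."""

import re

import pytest

from lampsim import (
    ConfigurationError,
    LayoutMode,
    Primer,
    TargetLayout,
    ngel_expand,
    parse_zone_string,
    preamplify,
    reverse_complement,
    run_cycle,
    run_phn_subcycle_z11,
    self_extend,
    simulate,
    size_series,
    strand,
)

Z6 = strand("bABCDc")
Z8 = strand("bABCDMNm")


class TestSizeSeries:
    @pytest.mark.parametrize(
        "n0,steps,expected",
        [
            (6, 5, [6, 9, 15, 27, 51, 99]),  # classic main series
            (18, 3, [18, 33, 63, 123]),  # secondary series from Z18_dmb
            (8, 5, [8, 13, 23, 43, 83, 163]),  # phn main series
            (3, 4, [3, 3, 3, 3, 3]),  # fixed point of the recurrence
        ],
    )
    def test_recurrence(self, n0, steps, expected):
        assert size_series(n0, steps) == expected

    def test_start_below_validity_is_rejected(self):
        with pytest.raises(ValueError):
            size_series(2, 3)


class TestLayout:
    def test_classic_has_four_primers_phn_five(self, classic_layout, phn_layout):
        assert len(classic_layout.primers) == 4
        assert len(phn_layout.primers) == 5
        assert len(phn_layout.inner_primers) == 3  # three inner primers

    def test_missing_anneal_zone_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            TargetLayout(
                zone_order=parse_zone_string("FABCE"),  # no D for primer Cd
                primers=(
                    Primer.make("F", "outer"),
                    Primer.make("bA", "inner"),
                    Primer.make("Cd", "inner"),
                    Primer.make("e", "outer"),
                ),
                mode=LayoutMode.CLASSIC,
            )


class TestPreamplification:
    def test_classic_yields_the_first_dumbbell(self, classic_layout):
        names = {p.name: str(p.strand) for p in preamplify(classic_layout)}
        assert names["Z6_dmb(1)"] == "bABCDc"
        assert "flanked_duplex" in names
        assert any(n.startswith("T") for n in names)

    def test_phn_yields_both_dumbbells(self, phn_layout):
        strands = {str(p.strand) for p in preamplify(phn_layout)}
        assert {"bABCDMNm", "bABCDc"} <= strands


class TestClassicCycle:
    def test_accounting_six_four_two(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        assert sum(rep.intermediates.values()) == 6
        assert dict(rep.terminated) == {"Zz6S": 2, "Zz9S": 2}
        assert dict(rep.exports) == {"Z15_hp": 2}

    def test_intermediates_are_the_six_cycle_species(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        assert set(rep.intermediates) == {
            "Z6_dmb(1)", "Z9_hp_D", "Z9_li(1)", "Z6_dmb(2)", "Z9_hp_a", "Z9_li(2)",
        }

    def test_cycle_closure_regenerates_the_seed_species(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        assert str(rep.next_seeds["Z6_dmb"]) == str(Z6)
        assert dict(rep.dmb_in) == dict(rep.dmb_out) == {"Z6_dmb": 1}

    def test_mirror_twin_dumbbells_are_reverse_complements(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        freed = [
            parse_zone_string(t)
            for _, kind, name, t in rep.product_log
            if kind == "closure"
        ]
        assert freed and freed[0] == Z6
        # The mid-cycle twin equals the seed's reverse complement.
        assert "Z6_dmb(2)" in rep.intermediates
        assert str(reverse_complement(Z6)) == "CdcbaB"

    def test_terminated_zone_counts_are_multiples_of_three(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        for name in rep.terminated:
            assert int(re.search(r"\d+", name).group()) % 3 == 0

    def test_export_sizes_follow_the_growth_recurrence(self, classic_layout):
        rep = run_cycle(Z6, classic_layout)
        for name in rep.exports:
            n = int(re.search(r"\d+", name).group())
            assert n == 2 * 9 - 3  # exports grow from the 9-zone hairpin

    def test_non_dumbbell_seed_is_rejected(self, classic_layout):
        with pytest.raises(ValueError):
            run_cycle(strand("FABCDE"), classic_layout)
        with pytest.raises(ValueError):
            run_cycle(strand("CdcbABCDc"), classic_layout)  # elongated, not basic


@pytest.fixture(scope="module")
def rep(phn_layout):
    return run_cycle([Z8, Z6], phn_layout)


class TestPhnCycle:

    def test_terminated_breakdown(self, rep):
        assert rep.terminated["Zz6S"] == 8
        assert rep.terminated["Zz8S"] == 2
        assert rep.terminated["Zz9S"] == 5
        assert rep.terminated["Zz13S"] == 2
        assert rep.n_terminated == 18

    def test_exports_breakdown(self, rep):
        assert dict(rep.exports) == {"Z15_hp": 5, "Z23_hp": 2}
        assert rep.n_exports == 7

    def test_dumbbell_flux_one_to_five(self, rep):
        assert rep.dmb_in["Z6_dmb"] == 1
        assert rep.dmb_out["Z6_dmb"] == 5
        assert rep.dmb_in["Z8_dmb"] == rep.dmb_out["Z8_dmb"] == 1

    def test_z8_mirror_twin_appears(self, rep):
        texts = {t for _, _, _, t in rep.product_log}
        assert str(reverse_complement(Z8)) == "MnmdcbaB"
        assert "Z8_dmb(2)" in set(rep.intermediates)

    def test_z11_lineage_initiated(self, rep):
        lineage = [name for _, kind, name, _ in rep.product_log if kind == "new_lineage"]
        assert "Z11_dmb(2)" in lineage or any("Z11" in n for n in lineage)


class TestNgel:
    def test_z15_expansion_contains_the_published_conversions(self, classic_layout):
        z15 = self_extend(strand("bABCDcbaB"), 7)
        g = ngel_expand(z15, classic_layout, max_zones=27)
        assert {"Z15_li", "Zz15S", "Z27_hp", "Z9_dmb", "Z9_hpS"} <= g.names()

    def test_z15_dmb_three_hairpin_outcomes_and_reseed(self, classic_layout):
        z15 = self_extend(strand("bABCDcbaB"), 7)
        g = ngel_expand(z15, classic_layout, max_zones=33)
        kids = g.children("Z15_dmb")
        assert {"Z15_hpS", "Z21_hpS", "Z27_hp"} <= kids
        assert "Z6_dmb(1)" in g.names()
        assert g.nodes["Z6_dmb(1)"].get("reseed")

    def test_z18_dmb_three_hairpin_outcomes(self, classic_layout):
        z15 = self_extend(strand("bABCDcbaB"), 7)
        g = ngel_expand(z15, classic_layout, max_zones=33)
        kids = g.children("Z18_dmb")
        assert {"Z21_hpS", "Z27_hpS", "Z33_hp"} <= kids
        assert "Z9_dmb" in g.names()

    def test_terminated_and_deadend_sizes_are_multiples_of_three(self, classic_layout):
        z15 = self_extend(strand("bABCDcbaB"), 7)
        g = ngel_expand(z15, classic_layout, max_zones=51)
        for name, data in g.nodes(data=True):
            if data.get("terminated"):
                assert data["zones"] % 3 == 0, name

    def test_every_self_extension_edge_obeys_the_recurrence(self, classic_layout):
        """Each self-priming growth step in the NGEL graph multiplies the
        zone count by the 2n-3 law, so chain sizes audit against the
        printed series."""
        z15 = self_extend(strand("bABCDcbaB"), 7)
        g = ngel_expand(z15, classic_layout, max_zones=51)
        checked = 0
        for u, v, data in g.g.edges(data=True):
            # Main-chain growth: the linearized template self-extends at
            # its 3'-most site.  (Dumbbells also self-extend at shorter
            # sites, yielding off-series hairpins and hpS dead ends.)
            if data.get("rule") == "self_extend" and re.fullmatch(r"Z\d+_li", u):
                assert g.nodes[v]["zones"] == 2 * g.nodes[u]["zones"] - 3
                checked += 1
        assert checked >= 2
        hp_sizes = {g.nodes[n]["zones"] for n in g.names() if re.fullmatch(r"Z\d+_hp", n)}
        assert {15, 27, 51} <= hp_sizes
        # Every product size in the graph is a multiple of three.
        assert all(data["zones"] % 3 == 0 for _, data in g.nodes(data=True))

    def test_max_zones_below_entry_is_rejected(self, classic_layout):
        with pytest.raises(ValueError):
            ngel_expand(self_extend(strand("bABCDcbaB"), 7), classic_layout, max_zones=9)


class TestZ11Subcycle:
    def test_named_products(self, phn_layout):
        g = run_phn_subcycle_z11(phn_layout)
        assert {"Z11_dmb(N)", "Zz11S", "Z19_hp", "Zz19S"} <= g.names()
        assert g.nodes["Z19_hp"]["zones"] == 2 * 11 - 3

    def test_z16_and_z9d_branches(self, phn_layout):
        g = run_phn_subcycle_z11(phn_layout)
        assert "Z16_dmb(D)" in g.names()
        assert "Z9_dmb(D)" in g.names()
        assert "Z15_li(D)" in g.names()

    def test_z15_li_d_branch_cannot_shed_a_six_zone_dumbbell(self, phn_layout):
        """The Z15_li(D) dead end: once the loop-opening extension covers
        the 5' half, no primer application on the remaining single-stranded
        region yields a 6-zone dumbbell (brute-force over anneal sites)."""
        from lampsim import FoldedStructure, extend_primer, find_anneal_sites

        g = run_phn_subcycle_z11(phn_layout)
        z15d = parse_zone_string(g.nodes["Z15_hp(D)"]["strand"])
        # Re-derive the linearization: a one-zone primer opens the hairpin
        # loop and its extension covers the template 5' of the site.
        hp_struct = FoldedStructure.from_self_extension(z15d, 7, 9)
        opener = next(
            (p, s)
            for p in phn_layout.inner_primers
            for s in find_anneal_sites(p, z15d, hp_struct.accessible_positions(), allow_one_zone=True)
        )
        covered = set(range(1, opener[1].template_pos + len(opener[0].tokens)))
        free = [q for q in range(1, 16) if q not in covered]
        for p in phn_layout.inner_primers:
            for site in find_anneal_sites(p, z15d, free, allow_one_zone=True):
                built = extend_primer(p, z15d, site).new_strand
                assert len(built.tokens) != 6

    def test_classic_mode_is_rejected(self, classic_layout):
        with pytest.raises(ConfigurationError):
            run_phn_subcycle_z11(classic_layout)


class TestSimulate:
    def test_one_classic_cycle_matches_run_cycle(self, classic_layout):
        rep = simulate(classic_layout, cycles=1)
        cyc = rep.cycles[0]
        assert dict(cyc.terminated) == {"Zz6S": 2, "Zz9S": 2}
        assert dict(cyc.exports) == {"Z15_hp": 2}

    def test_one_phn_cycle_matches_published_accounting(self, phn_layout):
        rep = simulate(phn_layout, cycles=1)
        cyc = rep.cycles[0]
        assert cyc.n_terminated == 18
        assert cyc.n_exports == 7

    def test_exhaustive_mode_is_deterministic(self, classic_layout):
        a = simulate(classic_layout, cycles=2).to_dict()
        b = simulate(classic_layout, cycles=2).to_dict()
        assert a == b

    def test_stochastic_mode_reproducible_and_subset_of_exhaustive(self, classic_layout):
        full = simulate(classic_layout, cycles=1)
        s1 = simulate(classic_layout, cycles=1, mode="stochastic", seed=11)
        s2 = simulate(classic_layout, cycles=1, mode="stochastic", seed=11)
        assert s1.to_dict() == s2.to_dict()
        assert set(s1.cycles[0].terminated) <= set(full.cycles[0].terminated)
        assert set(s1.cycles[0].exports) <= set(full.cycles[0].exports)

    def test_zero_cycles_is_an_error(self, classic_layout):
        with pytest.raises(ValueError):
            simulate(classic_layout, cycles=0)

    def test_size_series_audit_in_report(self, classic_layout):
        rep = simulate(classic_layout, cycles=1)
        assert rep.size_series_audit["main"] == [6, 9, 15, 27, 51, 99]

    def test_truncation_is_recorded_not_raised(self, classic_layout):
        rep = simulate(classic_layout, cycles=1, max_zones=27)
        assert any("51" in t for t in rep.truncations)

    def test_dot_export_mentions_products(self, classic_layout):
        rep = simulate(classic_layout, cycles=1)
        dot = rep.ngel.to_dot()
        assert dot.startswith("digraph") and "Z15_hp" in dot
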