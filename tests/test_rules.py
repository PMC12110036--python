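"""The four rewrite rules: annealing, elongation/displacement,
self-priming extension and fold-back."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lampsim import (
    AnnealSite,
    Primer,
    extend_primer,
    find_anneal_sites,
    find_self_prime_sites,
    fold_back,
    reverse_complement,
    self_extend,
    strand,
    zone_count,
)

CD = Primer.make("Cd", "inner", name="BIP")
BA = Primer.make("bA", "inner", name="FIP")
MN = Primer.make("Mn", "inner", name="eFIP")


def brute_force_sites(primer, template, available=None, allow_one_zone=False):
    """Independent oracle: scan every position for a complementary pair."""
    n = zone_count(template)
    avail = set(range(1, n + 1)) if available is None else set(available)
    out = []
    for i in range(1, n + 1):
        if i not in avail:
            continue
        if not template.token_at(i).pairs_with(primer.three_prime):
            continue
        two = (
            len(primer.tokens) == 2
            and i + 1 in avail
            and template.token_at(i + 1).pairs_with(primer.five_prime)
        )
        if two:
            out.append((i, 2))
        elif allow_one_zone and len(primer.tokens) == 2:
            out.append((i, 1))
        elif len(primer.tokens) == 1:
            out.append((i, 1))
    return out


class TestAnnealing:
    def test_cd_anneals_two_zones_on_the_basic_dumbbell(self):
        sites = find_anneal_sites(CD, strand("bABCDc"))
        assert [(s.template_pos, s.span) for s in sites] == [(5, 2)]

    def test_cd_anneals_one_zone_on_the_d_loop_of_the_folded_hairpin(self):
        # Folded Z9_hp_D exposes only the single-position loop {5}.
        sites = find_anneal_sites(CD, strand("bABCDcbaB"), [5], allow_one_zone=True)
        assert [(s.template_pos, s.span) for s in sites] == [(5, 1)]

    def test_no_site_when_no_complement_exists(self):
        assert find_anneal_sites(BA, strand("bABCDc")) == []
        assert brute_force_sites(BA, strand("bABCDc")) == []

    def test_two_zone_sites_require_both_positions_available(self):
        # Zone d available but the adjacent c is not: no two-zone site, and
        # one-zone only when explicitly allowed (loop annealing).
        t = strand("bABCDc")
        assert find_anneal_sites(CD, t, [5]) == []
        assert find_anneal_sites(CD, t, [5], allow_one_zone=True) == [AnnealSite(5, 1)]

    @given(st.text(st.sampled_from("FABCDEMNfabcdemn"), min_size=1, max_size=15))
    def test_sites_agree_with_brute_force_scan(self, text):
        t = strand(text)
        for p in (CD, BA, MN):
            got = [(s.template_pos, s.span) for s in find_anneal_sites(p, t, allow_one_zone=True)]
            assert got == brute_force_sites(p, t, allow_one_zone=True)


class TestElongation:
    def test_displacing_extension_builds_the_mirror_dumbbell(self):
        res = extend_primer(CD, strand("bABCDcbaB"), AnnealSite(5, 1))
        assert str(res.new_strand) == "CdcbaB"

    def test_full_two_zone_extension_is_the_exact_complement(self):
        t = strand("bABCDc")
        res = extend_primer(CD, t, AnnealSite(5, 2))
        assert str(res.new_strand) == "CdcbaB"
        assert res.new_strand == reverse_complement(t)
        # Every template position is covered by the duplex.
        assert sorted(j for _, j in res.duplex_extent) == list(range(1, 7))

    def test_recovers_z8_dmb1_from_its_twin(self):
        # bA on MnmdcbaB: 3' zone A pairs 'a' at position 7; the copied
        # prefix Mnmdcb reverse-complements to BCDMNm.
        res = extend_primer(BA, strand("MnmdcbaB"), AnnealSite(7, 2))
        assert str(res.new_strand) == "bABCDMNm"

    def test_template_is_never_mutated_and_displaced_are_preserved(self):
        t = strand("bABCDcbaB")
        before = str(t)
        paired = [strand("CdcbaB")]
        res = extend_primer(BA, t, AnnealSite(8, 2), paired=paired)
        assert str(t) == before
        assert [str(d) for d in res.displaced] == ["CdcbaB"]

    def test_site_at_position_one_is_a_null_extension(self):
        res = extend_primer(CD, strand("Dc"), AnnealSite(1, 2))
        assert res.null and str(res.new_strand) == "Cd"

    def test_invalid_site_is_rejected(self):
        with pytest.raises(ValueError):
            extend_primer(CD, strand("bABCDc"), AnnealSite(3, 1))

    def test_every_duplex_pair_is_complementary(self):
        t = strand("bABCDcbaB")
        res = extend_primer(BA, t, AnnealSite(8, 2))
        new = res.new_strand
        for i, j in res.duplex_extent:
            assert new.token_at(i).pairs_with(t.token_at(j))


class TestSelfPriming:
    @pytest.mark.parametrize(
        "text,sites",
        [
            ("bABCDc", [4]),
            ("CdcbABCDc", [7, 1]),
            ("bABCDcbaB", [7, 1]),  # terminal B pairs the b zones at 7 and 1
        ],
    )
    def test_sites_ordered_three_prime_first(self, text, sites):
        assert find_self_prime_sites(strand(text)) == sites

    @pytest.mark.parametrize(
        "text,site,expected",
        [
            ("bABCDc", 4, "bABCDcbaB"),  # Z6_dmb(1) -> Z9_hp_D
            ("bABCDMNm", 6, "bABCDMNmdcbaB"),  # Z8_dmb(1) -> Z13_hp(1)
            ("bABCDcbaB", 7, "bABCDcbaBCdcbaB"),  # Z9 -> Z15_hp export
        ],
    )
    def test_extension_products(self, text, site, expected):
        assert str(self_extend(strand(text), site)) == expected

    def test_site_one_returns_strand_unchanged(self):
        s = strand("CdcbABCDc")
        assert self_extend(s, 1) == s

    def test_invalid_site_is_rejected(self):
        with pytest.raises(ValueError):
            self_extend(strand("bABCDc"), 3)

    @given(st.text(st.sampled_from("FABCDEMNfabcdemn"), min_size=4, max_size=20))
    def test_growth_law_two_n_minus_three(self, text):
        """Self-priming at position n-2 always grows a strand of n zones to
        2n-3 zones — the recurrence behind the printed size series."""
        s = strand(text)
        n = zone_count(s)
        if (n - 2) in find_self_prime_sites(s):
            assert zone_count(self_extend(s, n - 2)) == 2 * n - 3


class TestFoldBack:
    def test_z9_hps_stem_and_loop(self):
        fb = fold_back(strand("CdcbABCDc"))
        assert fb.stem_pairs == ((1, 9), (2, 8), (3, 7))
        assert fb.loop == (4, 5, 6)  # bAB

    def test_non_complementary_termini_give_empty_stem(self):
        assert fold_back(strand("bABCDc")).stem_pairs == ()

    def test_all_plus_sense_strand_cannot_fold(self):
        assert fold_back(strand("FABCDE")).stem_pairs == ()

    def test_stem_pairs_are_complementary(self):
        fb = fold_back(strand("CdcbaBCdcbABCDc"))  # Z15_dmb
        assert fb.stem_pairs  # Z15_hpS route exists
        for i, j in fb.stem_pairs:
            assert fb.strand.token_at(i).pairs_with(fb.strand.token_at(j))
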