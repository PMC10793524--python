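"""Mendelian searches versus brute-force genotype-pattern oracles.

The central check enumerates all 27 trio genotype combinations (child,
father, mother each hom_ref / het / hom_alt) and compares every mode's
emitted candidacy with an independently written truth table; the
compound-het check enumerates all 729 genotype combinations of a
two-variant pair inside one peak.
"""

import itertools

import pandas as pd
import pytest

from conftest import make_call, make_variant
from crevar.atlas import build_disease_search_space
from crevar.inheritance import (
    CandidateVariant,
    DeNovoPolicy,
    apply_cohort_exclusion,
    detect_outliers,
    find_compound_het,
    find_de_novo,
    find_dominant,
    find_hom_recessive,
)
from crevar.pedigree import Individual, Pedigree

GTS = ("hom_ref", "het", "hom_alt")


def trio(family_id="F1", child_status="affected",
         father_status="unaffected", mother_status="unaffected",
         disease_group="DRS"):
    return Pedigree(family_id, [
        Individual("fa", family_id, sex="male", status=father_status),
        Individual("mo", family_id, sex="female", status=mother_status),
        Individual("ch", family_id, father_id="fa", mother_id="mo",
                   status=child_status),
    ], disease_group=disease_group)


def trio_variant(child_gt, father_gt, mother_gt, pos=1000):
    return make_variant(pos=pos, calls=[
        make_call("ch", child_gt), make_call("fa", father_gt),
        make_call("mo", mother_gt)])


def peakset_covering(contig="chr1", start=0, end=10_000):
    atlas = pd.DataFrame([{"contig": contig, "start": start, "end": end,
                           "peak_id": "pk1", "cell_type": "cMN6",
                           "timepoint": "e10.5"}])
    return build_disease_search_space(atlas, "DRS")


def carrier(gt):
    return gt in ("het", "hom_alt")


@pytest.mark.parametrize("child,father,mother",
                         list(itertools.product(GTS, repeat=3)))
def test_trio_truth_table_all_modes(child, father, mother):
    fam = trio()
    v = trio_variant(child, father, mother)
    # independent truth table over clean, filter-passing calls
    expect_denovo = child == "het" and father == "hom_ref" and mother == "hom_ref"
    expect_dominant = carrier(child) and not carrier(father) and not carrier(mother)
    expect_dom_incomplete = carrier(child)
    expect_recessive = child == "hom_alt" and father == "het" and mother == "het"

    assert bool(find_de_novo(fam, [v])) == expect_denovo
    assert bool(find_dominant(fam, [v], False)) == expect_dominant
    assert bool(find_dominant(fam, [v], True)) == expect_dom_incomplete
    assert bool(find_hom_recessive(fam, [v])) == expect_recessive


@pytest.mark.parametrize("g1", list(itertools.product(GTS, repeat=3)))
def test_compound_het_pair_truth_table(g1):
    """For each genotype combo of variant 1, sweep all combos of variant 2."""
    fam = trio()
    ps = peakset_covering()

    def origin(child, father, mother):
        if child != "het":
            return None
        if carrier(father) and mother == "hom_ref":
            return "paternal"
        if carrier(mother) and father == "hom_ref":
            return "maternal"
        return None

    o1 = origin(*g1)
    for g2 in itertools.product(GTS, repeat=3):
        v1 = trio_variant(*g1, pos=1000)
        v2 = trio_variant(*g2, pos=2000)
        pairs = find_compound_het(fam, [v1, v2], ps)
        o2 = origin(*g2)
        expected = o1 is not None and o2 is not None and o1 != o2
        assert (len(pairs) == 2) == expected, (g1, g2)
        if expected:
            assert {p.key for p in pairs} == {v1.key, v2.key}
            assert pairs[0].partner_key == pairs[1].key


def test_compound_het_needs_same_peak():
    fam = trio()
    atlas = pd.DataFrame([
        {"contig": "chr1", "start": 0, "end": 1500, "peak_id": "pk1",
         "cell_type": "cMN6", "timepoint": "e10.5"},
        {"contig": "chr1", "start": 1800, "end": 2500, "peak_id": "pk2",
         "cell_type": "cMN6", "timepoint": "e10.5"},
    ])
    ps = build_disease_search_space(atlas, "DRS")
    v1 = trio_variant("het", "het", "hom_ref", pos=1000)   # paternal, pk1
    v2 = trio_variant("het", "hom_ref", "het", pos=2000)   # maternal, pk2
    assert find_compound_het(fam, [v1, v2], ps) == []


def test_compound_het_skipped_when_parent_affected():
    fam = trio(father_status="affected")
    ps = peakset_covering()
    v1 = trio_variant("het", "het", "hom_ref", pos=1000)
    v2 = trio_variant("het", "hom_ref", "het", pos=1200)
    assert find_compound_het(fam, [v1, v2], ps) == []


def test_compound_het_symmetric_under_parent_swap():
    fam = trio()
    ps = peakset_covering()
    v1 = trio_variant("het", "het", "hom_ref", pos=1000)
    v2 = trio_variant("het", "hom_ref", "het", pos=1200)
    pairs = {frozenset((p.key, p.partner_key))
             for p in find_compound_het(fam, [v1, v2], ps)}
    # swap parental genotypes on both variants
    w1 = trio_variant("het", "hom_ref", "het", pos=1000)
    w2 = trio_variant("het", "het", "hom_ref", pos=1200)
    swapped = {frozenset((p.key, p.partner_key))
               for p in find_compound_het(fam, [w1, w2], ps)}
    assert pairs == swapped == {frozenset((v1.key, v2.key))}


def test_de_novo_respects_genotype_filters_and_parental_reads():
    fam = trio()
    low_ab = make_variant(pos=1000, calls=[
        make_call("fa", "hom_ref"), make_call("mo", "hom_ref"),
        type(make_call("ch", "het"))("ch", "het", gq=60, ref_depth=18,
                                     alt_depth=2)])
    assert find_de_novo(fam, [low_ab]) == []
    # a parent with one alt read fails the default zero-read policy
    leaky = make_variant(pos=2000, calls=[
        make_call("ch", "het"), make_call("mo", "hom_ref"),
        type(make_call("fa", "hom_ref"))("fa", "hom_ref", gq=80,
                                         ref_depth=29, alt_depth=1)])
    assert find_de_novo(fam, [leaky]) == []
    assert find_de_novo(fam, [leaky], DeNovoPolicy(max_parental_alt_reads=1))


def test_dominant_multiplex_family():
    fam = Pedigree("F2", [
        Individual("fa", "F2", sex="male", status="affected"),
        Individual("mo", "F2", sex="female", status="unaffected"),
        Individual("ch", "F2", father_id="fa", mother_id="mo",
                   status="affected"),
        Individual("sib", "F2", father_id="fa", mother_id="mo",
                   status="unaffected"),
    ], disease_group="CFP")
    v = make_variant(calls=[make_call("fa", "het"), make_call("mo", "hom_ref"),
                            make_call("ch", "het"), make_call("sib", "hom_ref")])
    assert len(find_dominant(fam, [v])) == 1
    # unaffected sib carrying kills it unless penetrance is relaxed
    v2 = make_variant(pos=2000, calls=[
        make_call("fa", "het"), make_call("mo", "hom_ref"),
        make_call("ch", "het"), make_call("sib", "het")])
    assert find_dominant(fam, [v2]) == []
    assert len(find_dominant(fam, [v2], incomplete_penetrance=True)) == 1
    # affected member with a missing call disqualifies (missing is not a carrier)
    v3 = make_variant(pos=3000, calls=[
        make_call("fa", "missing"), make_call("mo", "hom_ref"),
        make_call("ch", "het"), make_call("sib", "hom_ref")])
    assert find_dominant(fam, [v3]) == []


def test_hom_recessive_rejects_non_het_parent_and_hom_sib():
    fam = Pedigree("F3", [
        Individual("fa", "F3", sex="male", status="unaffected"),
        Individual("mo", "F3", sex="female", status="unaffected"),
        Individual("ch", "F3", father_id="fa", mother_id="mo",
                   status="affected"),
        Individual("sib", "F3", father_id="fa", mother_id="mo",
                   status="unaffected"),
    ], disease_group="DRS")
    good = make_variant(calls=[
        make_call("ch", "hom_alt"), make_call("fa", "het"),
        make_call("mo", "het"), make_call("sib", "het")])
    assert len(find_hom_recessive(fam, [good])) == 1
    bad_parent = make_variant(pos=2000, calls=[
        make_call("ch", "hom_alt"), make_call("fa", "hom_ref"),
        make_call("mo", "het"), make_call("sib", "het")])
    assert find_hom_recessive(fam, [bad_parent]) == []
    hom_sib = make_variant(pos=3000, calls=[
        make_call("ch", "hom_alt"), make_call("fa", "het"),
        make_call("mo", "het"), make_call("sib", "hom_alt")])
    assert find_hom_recessive(fam, [hom_sib]) == []


class TestCohortExclusion:
    def _cohort(self):
        f1 = trio("F1")
        f2 = Pedigree("F2", [
            Individual("u1", "F2", status="unaffected"),
            Individual("a1", "F2", status="affected"),
        ], disease_group="CFP")
        return f1, f2

    def test_dominant_removed_on_unrelated_het(self):
        f1, f2 = self._cohort()
        v = trio_variant("het", "hom_ref", "hom_ref")
        v.calls["u1"] = make_call("u1", "het")
        cands = find_de_novo(f1, [v])
        assert cands
        assert apply_cohort_exclusion(cands, {v.key: v}, [f1, f2]) == []

    def test_recessive_kept_on_het_removed_on_hom(self):
        f1, f2 = self._cohort()
        v = trio_variant("hom_alt", "het", "het")
        v.calls["u1"] = make_call("u1", "het")
        cands = find_hom_recessive(f1, [v])
        assert apply_cohort_exclusion(cands, {v.key: v}, [f1, f2]) == cands
        v.calls["u1"] = make_call("u1", "hom_alt")
        assert apply_cohort_exclusion(cands, {v.key: v}, [f1, f2]) == []

    def test_comp_het_pair_removed_together(self):
        f1, f2 = self._cohort()
        ps = peakset_covering()
        v1 = trio_variant("het", "het", "hom_ref", pos=1000)
        v2 = trio_variant("het", "hom_ref", "het", pos=1200)
        v1.calls["u1"] = make_call("u1", "hom_alt")
        pairs = find_compound_het(f1, [v1, v2], ps)
        assert len(pairs) == 2
        out = apply_cohort_exclusion(pairs, {v1.key: v1, v2.key: v2}, [f1, f2])
        assert out == []  # partner goes down with the excluded member


class TestOutlierDetection:
    def _denovos(self, sample, n):
        return [CandidateVariant(("chr1", i + 1, "A", "G"), "F1", "de_novo",
                                 carriers=[sample]) for i in range(n)]

    def test_76_flagged_75_not(self):
        flagged, _ = detect_outliers(self._denovos("s76", 76))
        assert flagged == {"s76"}
        flagged, _ = detect_outliers(self._denovos("s75", 75))
        assert flagged == set()

    def test_empty_cohort_no_flags(self):
        assert detect_outliers([]) == (set(), set())
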