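"""Multi-hit aggregation and the isolated-vs-syndromic Fisher test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crevar.inheritance import CandidateVariant
from crevar.multihit import (
    isolated_syndromic_enrichment,
    tabulate_multihit_genes,
    tabulate_multihit_peaks,
)


def cand(family, mode, peak="pk1", pos=100, partner=None):
    return CandidateVariant(("chr1", pos, "A", "G"), family, mode,
                            carriers=[f"{family}_p1"], peak_id=peak,
                            partner_key=partner)


class TestMultihitPeaks:
    def test_same_variant_in_two_families_counts_twice(self):
        mh = tabulate_multihit_peaks([cand("F1", "de_novo"),
                                      cand("F2", "dominant")])
        assert len(mh) == 1
        assert mh[0].n_families == 2 and len(mh[0].variant_keys) == 1

    def test_mixed_broad_modes_do_not_aggregate(self):
        mh = tabulate_multihit_peaks([cand("F1", "dominant", pos=100),
                                      cand("F2", "hom_recessive", pos=200)])
        assert mh == []

    def test_comp_het_pair_is_one_family_hit(self):
        pair = [cand("F1", "comp_het", pos=100, partner=("chr1", 200, "A", "G")),
                cand("F1", "comp_het", pos=200, partner=("chr1", 100, "A", "G"))]
        assert tabulate_multihit_peaks(pair) == []
        mh = tabulate_multihit_peaks(pair + [cand("F2", "hom_recessive", pos=300)])
        assert len(mh) == 1 and mh[0].n_families == 2

    def test_large_sv_excluded_before_counting(self):
        svs = [{"contig": "chr1", "start": 0, "end": 150_000, "length": 150_000,
                "overlaps_coding": False, "mode": "de_novo", "family_id": "F2",
                "peak_id": "pk1"}]
        got = tabulate_multihit_peaks([cand("F1", "de_novo")], sv_candidates=svs)
        assert got == []
        svs[0]["end"] = svs[0]["length"] = 50_000
        got = tabulate_multihit_peaks([cand("F1", "de_novo")], sv_candidates=svs)
        assert len(got) == 1 and got[0].n_families == 2
        svs[0]["overlaps_coding"] = True
        assert tabulate_multihit_peaks([cand("F1", "de_novo")],
                                       sv_candidates=svs) == []

    def test_family_order_invariant(self):
        cands = [cand(f, m, peak=p, pos=i * 10 + 1)
                 for i, (f, m, p) in enumerate(itertools.product(
                     ["F1", "F2", "F3"], ["de_novo", "hom_recessive"],
                     ["pk1", "pk2"]))]
        ref = tabulate_multihit_peaks(cands)
        perm = tabulate_multihit_peaks(list(reversed(cands)))
        assert {(m.peak_id, m.broad_mode, m.families) for m in ref} == \
               {(m.peak_id, m.broad_mode, m.families) for m in perm}

    def test_removing_a_family_never_creates_multihits(self):
        cands = [cand("F1", "de_novo"), cand("F2", "dominant"),
                 cand("F3", "de_novo", peak="pk2", pos=500)]
        before = {(m.peak_id, m.broad_mode)
                  for m in tabulate_multihit_peaks(cands)}
        after = {(m.peak_id, m.broad_mode)
                 for m in tabulate_multihit_peaks(
                     [c for c in cands if c.family_id != "F2"])}
        assert after <= before


class TestMultihitGenes:
    def _links(self, pairs):
        return pd.DataFrame(pairs, columns=["peak_id", "gene"])

    def test_two_linked_candidate_peaks(self):
        links = self._links([("pk1", "G"), ("pk2", "G")])
        cands = [cand("F1", "de_novo", peak="pk1"),
                 cand("F2", "dominant", peak="pk2", pos=300)]
        mh = tabulate_multihit_genes(cands, links)
        assert len(mh) == 1
        assert mh[0].gene == "G" and len(mh[0].variant_keys) == 2

    def test_one_candidate_peak_insufficient(self):
        links = self._links([("pk1", "G"), ("pk2", "G")])
        assert tabulate_multihit_genes([cand("F1", "de_novo", peak="pk1")],
                                       links) == []

    def test_two_variants_in_same_peak_count_once(self):
        links = self._links([("pk1", "G")])
        cands = [cand("F1", "de_novo", peak="pk1", pos=100),
                 cand("F2", "dominant", peak="pk1", pos=200)]
        assert tabulate_multihit_genes(cands, links) == []
        # the variant-count reading is available behind min_peaks
        assert len(tabulate_multihit_genes(cands, links, min_peaks=1)) == 1

    def test_recessive_candidates_ignored(self):
        links = self._links([("pk1", "G"), ("pk2", "G")])
        cands = [cand("F1", "hom_recessive", peak="pk1"),
                 cand("F2", "hom_recessive", peak="pk2", pos=300)]
        assert tabulate_multihit_genes(cands, links) == []


def fisher_two_sided_enumeration(table):
    """Oracle: exact enumeration of all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_example_table(self):
        orr, p, _ = isolated_syndromic_enrichment(
            {"m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8", "s1", "s2"},
            {**{f"m{i}": "isolated" for i in range(1, 9)},
             **{f"s{i}": "syndromic" for i in range(1, 3)},
             **{f"i{i}": "isolated" for i in range(20)},
             **{f"y{i}": "syndromic" for i in range(30)}})
        assert orr == pytest.approx(6.0)
        assert p == pytest.approx(fisher_two_sided_enumeration([[8, 2], [20, 30]]),
                                  rel=1e-9)

    def test_balanced_table_is_null(self):
        fams = {**{f"m{i}": "isolated" for i in range(5)},
                **{f"n{i}": "syndromic" for i in range(5)},
                **{f"o{i}": "isolated" for i in range(5)},
                **{f"p{i}": "syndromic" for i in range(5)}}
        multihit = {f"m{i}" for i in range(5)} | {f"n{i}" for i in range(5)}
        orr, p, _ = isolated_syndromic_enrichment(multihit, fams)
        assert orr == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_zero_cells_use_haldane_and_enumeration(self):
        fams = {**{f"m{i}": "isolated" for i in range(5)},
                **{f"y{i}": "syndromic" for i in range(5)}}
        multihit = {f"m{i}" for i in range(5)}
        orr, p, table = isolated_syndromic_enrichment(multihit, fams)
        assert table == [[5, 0], [0, 5]]
        assert orr == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
        assert p == pytest.approx(fisher_two_sided_enumeration([[5, 0], [0, 5]]),
                                  rel=1e-9)

    def test_degenerate_margin(self):
        fams = {"a": "isolated", "b": "isolated"}
        with pytest.warns(UserWarning):
            orr, p, _ = isolated_syndromic_enrichment(set(), fams)
        assert math.isnan(orr) and p == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 16, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            fams = {}
            multihit = set()
            for i in range(a):
                fams[f"a{i}"] = "isolated"; multihit.add(f"a{i}")
            for i in range(b):
                fams[f"b{i}"] = "syndromic"; multihit.add(f"b{i}")
            for i in range(c):
                fams[f"c{i}"] = "isolated"
            for i in range(d):
                fams[f"d{i}"] = "syndromic"
            _, p, table = isolated_syndromic_enrichment(multihit, fams)
            assert p == pytest.approx(
                fisher_two_sided_enumeration([[a, b], [c, d]]), rel=1e-7)
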