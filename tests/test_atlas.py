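"""Disease search spaces and SNV / SV / TE overlay semantics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_call, make_variant
from crevar.atlas import (
    DEFAULT_PHENOTYPE_MAP,
    assign_to_peaks,
    build_disease_search_space,
    filter_sv_candidates,
    filter_te_candidates,
)
from crevar.inheritance import CandidateVariant
from crevar.pedigree import Individual, Pedigree
from crevar.variants import GenotypeCall, SVRecord, TERecord


def atlas_df(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "peak_id",
                                       "cell_type", "timepoint"])


def test_mbs_merges_across_cell_types_with_backrefs():
    atlas = atlas_df([("chr1", 100, 600, "pkA", "cMN6", "e10.5"),
                      ("chr1", 400, 900, "pkB", "cMN7", "e11.5")])
    ps = build_disease_search_space(atlas, "MBS")
    assert ps.intervals[["start", "end"]].values.tolist() == [[100, 900]]
    assert ps.contributing_peaks(0) == ("pkA", "pkB")


def test_drs_uses_only_cmn6_peaks():
    atlas = atlas_df([("chr1", 100, 600, "pkA", "cMN6", "e10.5"),
                      ("chr1", 1000, 1500, "pkB", "cMN7", "e10.5")])
    ps = build_disease_search_space(atlas, "DRS")
    assert ps.n_intervals == 1
    assert ps.contributing_peaks(0) == ("pkA",)


def test_unknown_disease_group_errors_and_empty_atlas_warns():
    atlas = atlas_df([("chr1", 100, 600, "pkA", "cMN6", "e10.5")])
    with pytest.raises(KeyError):
        build_disease_search_space(atlas, "DRS", ctmap={"CFP": {"cMN7"}})
    with pytest.warns(UserWarning, match="no atlas peaks"):
        ps = build_disease_search_space(atlas_df([]), "DRS")
    assert ps.n_intervals == 0


class TestAssignToPeaks:
    def _assign(self, pos, ref, peak):
        atlas = atlas_df([("chr1", peak[0], peak[1], "pk1", "cMN6", "e10.5")])
        ps = build_disease_search_space(atlas, "DRS")
        v = make_variant(pos=pos, ref=ref)
        c = CandidateVariant(v.key, "F1", "de_novo", carriers=["ch"])
        return assign_to_peaks([c], {v.key: v}, ps)

    def test_snv_at_right_edge_of_halfopen_peak_retained(self):
        # 1-based pos 101 occupies [100, 101) -- inside peak [100, 101)
        assert len(self._assign(101, "A", (100, 101))) == 1

    def test_snv_just_left_of_peak_dropped(self):
        # 0-based 100 < 101: outside [101, 200)
        assert self._assign(101, "A", (101, 200)) == []

    def test_deletion_span_reaching_into_peak_retained(self):
        # 5-bp ref starting 2 bp before the peak: span [98, 103) crosses 100
        assert len(self._assign(99, "AAAAA", (100, 200))) == 1


def _sv_trio(disease="DRS", fam="F1"):
    return Pedigree(fam, [
        Individual("fa", fam, sex="male", status="unaffected"),
        Individual("mo", fam, sex="female", status="unaffected"),
        Individual("ch", fam, father_id="fa", mother_id="mo",
                   status="affected"),
    ], disease_group=disease)


def _sv_call(sample, gt):
    return GenotypeCall(sample, gt, gq=99,
                        ref_depth=0 if gt == "hom_alt" else 15,
                        alt_depth=0 if gt == "hom_ref" else 15)


class TestSVFilter:
    def setup_method(self):
        atlas = atlas_df([("chr1", 10_000, 12_000, "pk1", "cMN6", "e10.5")])
        self.ps = build_disease_search_space(atlas, "DRS")
        self.ped = _sv_trio()

    def test_cohort_af_boundary_excluded(self):
        sv = SVRecord("chr1", 10_500, 11_000, "DEL", cohort_af=0.005,
                      calls={"ch": _sv_call("ch", "het"),
                             "fa": _sv_call("fa", "hom_ref"),
                             "mo": _sv_call("mo", "hom_ref")})
        assert filter_sv_candidates([sv], self.ps, [self.ped]) == []

    def test_homozygous_deletion_with_het_parents_is_recessive(self):
        # the consanguineous-proband pattern: hom deletion over a disease peak
        sv = SVRecord("chr1", 9_000, 12_600, "DEL", cohort_af=0.001,
                      calls={"ch": _sv_call("ch", "hom_alt"),
                             "fa": _sv_call("fa", "het"),
                             "mo": _sv_call("mo", "het")})
        out = filter_sv_candidates([sv], self.ps, [self.ped])
        assert [o["mode"] for o in out] == ["hom_recessive"]

    def test_de_novo_deletion_outside_peaks_excluded(self):
        sv = SVRecord("chr1", 50_000, 52_000, "DEL", cohort_af=0.0,
                      calls={"ch": _sv_call("ch", "het"),
                             "fa": _sv_call("fa", "hom_ref"),
                             "mo": _sv_call("mo", "hom_ref")})
        assert filter_sv_candidates([sv], self.ps, [self.ped]) == []


class TestTEFilter:
    def setup_method(self):
        atlas = atlas_df([("chr1", 10_000, 12_000, "pk1", "cMN6", "e10.5")])
        self.ps = build_disease_search_space(atlas, "DRS")
        self.ped = _sv_trio()

    def test_common_insertion_excluded(self):
        te = TERecord("chr1", 10_500, "Alu", "two_side_tprt_both", pop_af=0.02,
                      carrier_support={"ch": 5, "fa": 5, "mo": 0},
                      in_same_family_repeat=False)
        assert filter_te_candidates([te], self.ps, [self.ped]) == []

    def test_single_parental_read_kills_de_novo(self):
        te = TERecord("chr1", 10_500, "L1", "two_side_tprt_both", pop_af=0.0,
                      carrier_support={"ch": 6, "fa": 1, "mo": 0},
                      in_same_family_repeat=False)
        out = filter_te_candidates([te], self.ps, [self.ped])
        assert [o["mode"] for o in out if o["mode"] == "de_novo"] == []

    def test_padding_rescues_nearby_insertion(self):
        # 10 bp outside the peak end: rescued by the 15 bp padding
        te = TERecord("chr1", 12_010, "Alu", "two_side_tprt_both", pop_af=0.0,
                      carrier_support={"ch": 6, "fa": 0, "mo": 0},
                      in_same_family_repeat=False)
        out = filter_te_candidates([te], self.ps, [self.ped])
        assert [o["mode"] for o in out] == ["de_novo"]
        far = TERecord("chr1", 12_050, "Alu", "two_side_tprt_both", pop_af=0.0,
                       carrier_support={"ch": 6, "fa": 0, "mo": 0},
                       in_same_family_repeat=False)
        assert filter_te_candidates([far], self.ps, [self.ped]) == []

    def test_nested_same_family_repeat_excluded_from_inherited(self):
        ped = Pedigree("F2", [
            Individual("fa", "F2", sex="male", status="affected"),
            Individual("ch", "F2", father_id="fa", mother_id=None,
                       status="affected"),
        ], disease_group="DRS")
        # father-only parent: construct with mother absent
        te = TERecord("chr1", 10_500, "L1", "two_side_tprt", pop_af=0.001,
                      carrier_support={"ch": 4, "fa": 4},
                      in_same_family_repeat=True)
        assert filter_te_candidates([te], self.ps, [ped]) == []


def test_search_space_reduction_tracks_peak_fraction(sim_default):
    """Uniform background variants survive the overlay at about the rate of
    genomic peak coverage (binomial error)."""
    cfg, layout, atlas, cohort = sim_default
    ps = build_disease_search_space(atlas, "DRS")
    rng = np.random.default_rng(0)
    n = 4000
    contig = "chr1"
    positions = rng.integers(0, layout.contigs[contig], size=n)
    hits = sum(ps.assign(contig, int(p), int(p) + 1) is not None
               for p in positions)
    in_chr1 = ps.intervals[ps.intervals.contig == contig]
    frac = (in_chr1.end - in_chr1.start).sum() / layout.contigs[contig]
    se = np.sqrt(frac * (1 - frac) / n)
    assert abs(hits / n - frac) < 5 * se
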