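"""Cell-type peak atlases, disease search spaces, and candidate overlay.

Each congenital cranial dysinnervation disorder (CCDD) phenotype maps to
the cranial motor neuron population(s) whose maldevelopment causes it;
the merged accessibility peaks of those cell types (both embryonic
timepoints) form the disease's non-coding search space. Atlases are
consumed as BED already in the cohort's genome build -- any liftover is
upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, merge_intervals, span_overlaps
from .inheritance import (
    MODE_DE_NOVO,
    MODE_DOMINANT,
    MODE_HOM_RECESSIVE,
    CandidateVariant,
)
from .pedigree import Pedigree
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF, SVRecord, TERecord

ATLAS_COLUMNS = ["contig", "start", "end", "peak_id", "cell_type", "timepoint"]

#: Default phenotype -> cell-type map. CFEOM maps to cMN3/4, DRS to cMN6,
#: CFP to cMN7, MBS to cMN6+cMN7; CP and FNP fall back to the combined
#: cMN3/4 dissection (the atlas does not separate cMN3's superior branch
#: from cMN4), and the MGJW / ptosis-MGJWS groups default to cMN3/4+cMN7.
#: All entries are overridable via the ``ctmap`` argument.
DEFAULT_PHENOTYPE_MAP: dict[str, frozenset] = {
    "CFEOM": frozenset({"cMN3/4"}),
    "CP": frozenset({"cMN3/4"}),
    "FNP": frozenset({"cMN3/4"}),
    "DRS": frozenset({"cMN6"}),
    "CFP": frozenset({"cMN7"}),
    "MBS": frozenset({"cMN6", "cMN7"}),
    "MGJW": frozenset({"cMN3/4", "cMN7"}),
    "PTOSIS_MGJWS": frozenset({"cMN3/4", "cMN7"}),
}


def read_atlas_bed(path, layout: GenomeLayout | None = None,
                   on_unknown_contig: str = "error") -> pd.DataFrame:
    """Read a peak atlas BED (chrom, start, end, peak_id, cell_type, timepoint)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=ATLAS_COLUMNS,
                     dtype={"contig": str, "start": np.int64, "end": np.int64,
                            "peak_id": str, "cell_type": str, "timepoint": str})
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"empty/inverted interval at {bad.contig}:{bad.start}")
    if layout is not None:
        known = df["contig"].isin(layout.contigs)
        if not known.all():
            if on_unknown_contig == "skip":
                df = df[known].reset_index(drop=True)
            else:
                raise ValueError(
                    f"unknown contig(s): {sorted(df.loc[~known, 'contig'].unique())}")
        for row in df.itertuples(index=False):
            layout.validate_interval(row.contig, int(row.start), int(row.end))
    return df


def write_atlas_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, columns=ATLAS_COLUMNS)


@dataclass
class DiseasePeakSet:
    """Merged, non-overlapping search space for one disease group.

    ``intervals`` has columns contig/start/end/interval_id/peak_ids where
    ``peak_ids`` is the tuple of contributing atlas peaks -- the
    back-reference needed to report which peaks a candidate hit.
    """

    disease_group: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self._per_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, sub in self.intervals.groupby("contig", sort=False):
            arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
            self._per_contig[contig] = (arr, sub.index.to_numpy())

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        if self.intervals.empty:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def assign(self, contig: str, start: int, end: int):
        """Return ``(interval_index, interval_id)`` for an overlapping span, else None."""
        got = self._per_contig.get(contig)
        if got is None:
            return None
        arr, idx = got
        hit, pos = span_overlaps([start], [end], arr)
        if not hit[0]:
            return None
        row = int(idx[pos[0]])
        return row, self.intervals.at[row, "interval_id"]

    def contributing_peaks(self, interval_index: int) -> tuple:
        return self.intervals.at[interval_index, "peak_ids"]


def build_disease_search_space(
    atlas: pd.DataFrame,
    disease_group: str,
    ctmap: dict | None = None,
) -> DiseasePeakSet:
    """Union of all peaks (both timepoints) of the disease's cell types.

    For disease groups spanning more than one cranial nerve the per-nerve
    peak lists are merged together, so a merged interval can reference
    peaks from multiple cell types.
    """
    ctmap = ctmap or DEFAULT_PHENOTYPE_MAP
    if disease_group not in ctmap:
        raise KeyError(f"disease group {disease_group!r} absent from map")
    cell_types = ctmap[disease_group]
    sub = atlas[atlas["cell_type"].isin(cell_types)]
    rows = []
    if sub.empty:
        warnings.warn(f"no atlas peaks for {disease_group} (cell types {sorted(cell_types)})")
    else:
        for contig in sub["contig"].unique():
            csub = sub[sub["contig"] == contig]
            merged, groups = merge_intervals(
                csub[["start", "end"]].to_numpy(dtype=np.int64),
                return_groups=True)
            ids = csub["peak_id"].to_numpy()
            for gi in range(len(merged)):
                contributing = tuple(sorted(set(ids[groups == gi])))
                rows.append((contig, int(merged[gi, 0]), int(merged[gi, 1]),
                             contributing))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "peak_ids"])
    df = df.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    df["interval_id"] = [
        f"{disease_group}:{r.contig}:{r.start}-{r.end}"
        for r in df.itertuples(index=False)
    ]
    return DiseasePeakSet(disease_group, df[["contig", "start", "end",
                                             "interval_id", "peak_ids"]])


def assign_to_peaks(
    candidates: list[CandidateVariant],
    variants_by_key: dict,
    peakset: DiseasePeakSet,
    padding: int = 0,
) -> list[CandidateVariant]:
    """Retain candidates whose reference span intersects the search space.

    A variant's span is ``[pos-1, pos-1+len(ref))`` optionally padded on
    both sides; candidates are annotated with the merged interval they
    hit. Compound-het candidates arrive pre-assigned (the peak is their
    unit of heredity) and are passed through unchanged.
    """
    out = []
    for c in candidates:
        if c.peak_id is not None:
            out.append(c)
            continue
        v = variants_by_key[c.key]
        s, e = v.span
        hit = peakset.assign(v.contig, s - padding, e + padding)
        if hit is None:
            continue
        _, interval_id = hit
        c.peak_id = interval_id
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Structural variants and transposable-element insertions
# ---------------------------------------------------------------------------

def _sv_gt(rec: SVRecord, sample_id: str) -> str:
    call = rec.calls.get(sample_id)
    return call.gt if call is not None else "missing"


def filter_sv_candidates(
    svs: list[SVRecord],
    peakset: DiseasePeakSet,
    pedigrees: list[Pedigree],
    af_max: float = 0.005,
) -> list[dict]:
    """SV candidates: rare, inheritance-consistent, touching the search space.

    Any SV with cohort AF >= ``af_max`` is excluded regardless of coding
    status. Overlap requires >= 1 bp intersection with the merged disease
    peaks (no reciprocal-overlap requirement). Modes mirror the SNV rules:
    de novo (affected child carrier, both parents confidently hom_ref),
    dominant (all affecteds carry, no unaffected carries) and homozygous
    recessive (affecteds hom_alt, genotyped parents het).
    """
    out = []
    for sv in svs:
        if not (sv.cohort_af < af_max):
            continue
        hit = peakset.assign(sv.contig, sv.start, sv.end)
        if hit is None:
            continue
        _, interval_id = hit
        for ped in pedigrees:
            if ped.solved:
                continue
            affected = ped.affected_members()
            if not affected:
                continue
            gts = {m.id: _sv_gt(sv, m.id) for m in ped.members}
            modes = []
            for child in ped.children_with_parents():
                if not child.affected:
                    continue
                if (gts[child.id] in (GT_HET, GT_HOM_ALT)
                        and gts[child.father_id] == GT_HOM_REF
                        and gts[child.mother_id] == GT_HOM_REF):
                    modes.append((MODE_DE_NOVO, [child.id]))
                if (gts[child.id] == GT_HOM_ALT
                        and gts[child.father_id] == GT_HET
                        and gts[child.mother_id] == GT_HET
                        and not any(gts[m.id] == GT_HOM_ALT
                                    for m in ped.unaffected_members())):
                    modes.append((MODE_HOM_RECESSIVE, [child.id]))
            if (len(affected) >= 2
                    and all(gts[m.id] in (GT_HET, GT_HOM_ALT) for m in affected)
                    and not any(gts[m.id] in (GT_HET, GT_HOM_ALT)
                                for m in ped.unaffected_members())):
                modes.append((MODE_DOMINANT, [m.id for m in affected]))
            for mode, carriers in modes:
                out.append({
                    "sv_id": sv.sv_id, "contig": sv.contig, "start": sv.start,
                    "end": sv.end, "svtype": sv.svtype, "length": sv.length,
                    "overlaps_coding": sv.overlaps_coding,
                    "family_id": ped.family_id, "mode": mode,
                    "carriers": carriers, "peak_id": interval_id,
                })
    return out


TE_HIGH_CONFIDENCE = ("two_side_tprt_both", "two_side_tprt")


def filter_te_candidates(
    tes: list[TERecord],
    peakset: DiseasePeakSet,
    pedigrees: list[Pedigree],
    pop_af_max: float = 0.01,
    padding: int = 15,
) -> list[dict]:
    """Transposable-element insertion candidates on two tracks.

    Rare-inherited: population AF < ``pop_af_max``, high-confidence call
    (``two_side_tprt_both`` or ``two_side_tprt``), not nested inside a
    same-family repeat, carried by the family's affecteds. De novo:
    zero supporting reads in both parents, top-confidence call only
    (``two_side_tprt_both``) and absent from population panels. Peak
    overlap uses the insertion point with +/- ``padding`` bp to absorb
    breakpoint uncertainty.
    """
    warned_nested = False
    out = []
    for te in tes:
        point = te.pos - 1
        hit = peakset.assign(te.contig, point - padding, point + 1 + padding)
        if hit is None:
            continue
        _, interval_id = hit
        if te.in_same_family_repeat is None and not warned_nested:
            warnings.warn("TE records carry no same-family-repeat annotation; "
                          "nested-insertion removal skipped")
            warned_nested = True
        for ped in pedigrees:
            if ped.solved:
                continue
            support = {m.id: te.carrier_support.get(m.id, 0) for m in ped.members}
            affected = ped.affected_members()
            denovo_emitted = False
            # de novo track
            for child in ped.children_with_parents():
                if (child.affected
                        and support[child.id] > 0
                        and support[child.father_id] == 0
                        and support[child.mother_id] == 0
                        and te.confidence == "two_side_tprt_both"
                        and te.pop_af == 0.0):
                    out.append({"te_id": te.te_id, "contig": te.contig,
                                "pos": te.pos, "te_family": te.te_family,
                                "family_id": ped.family_id, "mode": MODE_DE_NOVO,
                                "carriers": [child.id], "peak_id": interval_id})
                    denovo_emitted = True
            # rare-inherited track
            if (not denovo_emitted
                    and affected
                    and te.pop_af < pop_af_max
                    and te.confidence in TE_HIGH_CONFIDENCE
                    and te.in_same_family_repeat is not True
                    and all(support[m.id] > 0 for m in affected)):
                out.append({"te_id": te.te_id, "contig": te.contig,
                            "pos": te.pos, "te_family": te.te_family,
                            "family_id": ped.family_id, "mode": MODE_DOMINANT,
                            "carriers": [m.id for m in affected],
                            "peak_id": interval_id})
    return out
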