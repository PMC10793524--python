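"""End-to-end orchestration: split, filter, inherit, overlay, aggregate.

:func:`run_nomination` realizes the full nomination pass over a cohort:
multi-allelic splitting and annotation, hard filtering, per-pedigree
inheritance searches (with the disease peak set supplied so the
compound-het search can use the peak as its unit of heredity), overlay on
the cell-type search space, cohort-level exclusion, outlier detection,
multi-hit aggregation and (optionally) permutation enrichment. Every
stage's candidate count is recorded so the search-space reduction can be
audited, and all randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import (
    DEFAULT_PHENOTYPE_MAP,
    DiseasePeakSet,
    assign_to_peaks,
    build_disease_search_space,
)
from .filters import DOMINANT, FilterPolicy, passes_genotype_filters, \
    passes_site_filters, split_multiallelic
from .genome import GenomeLayout
from .inheritance import (
    MODE_COMP_HET,
    CandidateVariant,
    DeNovoPolicy,
    apply_cohort_exclusion,
    detect_outliers,
    search_family,
)
from .multihit import isolated_syndromic_enrichment, tabulate_multihit_peaks
from .pedigree import Pedigree
from .permutation import PermutationResult, permutation_enrichment
from .variants import RawVariant, VariantRecord, annotation_lookup

CANDIDATE_COLUMNS = ["contig", "pos", "ref", "alt", "family_id", "disease_group",
                     "presentation", "mode", "broad_mode", "carriers",
                     "partner", "peak_id"]


@dataclass
class NominationResult:
    candidates: pd.DataFrame
    pre_overlay: list[CandidateVariant]
    multihit_peaks: list
    stage_counts: dict[str, int]
    flagged_individuals: set[str]
    flagged_families: set[str]
    enrichment: dict[str, PermutationResult] = field(default_factory=dict)
    isolated_or: float = float("nan")
    isolated_p: float = float("nan")


def candidates_to_frame(cands: list[CandidateVariant],
                        pedigrees: list[Pedigree]) -> pd.DataFrame:
    meta = {p.family_id: p for p in pedigrees}
    rows = []
    for c in cands:
        ped = meta[c.family_id]
        rows.append((c.key[0], c.key[1], c.key[2], c.key[3], c.family_id,
                     ped.disease_group, ped.presentation, c.mode, c.broad_mode,
                     ",".join(c.carriers),
                     "" if c.partner_key is None else
                     f"{c.partner_key[0]}:{c.partner_key[1]}:{c.partner_key[2]}>"
                     f"{c.partner_key[3]}",
                     c.peak_id or ""))
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["contig", "pos", "family_id", "mode"],
                          kind="stable").reset_index(drop=True)


def write_candidates(df: pd.DataFrame, path) -> None:
    """Deterministic candidate TSV (columns in fixed order, no NA magic)."""
    df.to_csv(path, sep="\t", index=False, columns=CANDIDATE_COLUMNS)


def read_candidates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["pos"] = df["pos"].astype(np.int64)
    return df[CANDIDATE_COLUMNS]


def split_and_annotate(raws: list[RawVariant],
                       annotations: pd.DataFrame) -> list[VariantRecord]:
    lookup = annotation_lookup(annotations)
    records: list[VariantRecord] = []
    for raw in raws:
        records.extend(split_multiallelic(raw, lookup))
    return records


def run_nomination(
    pedigrees: list[Pedigree],
    raws: list[RawVariant],
    annotations: pd.DataFrame,
    atlas: pd.DataFrame,
    layout: GenomeLayout,
    ctmap: dict | None = None,
    policy: FilterPolicy | None = None,
    denovo_policy: DeNovoPolicy | None = None,
    incomplete_penetrance: bool = False,
    run_enrichment: bool = False,
    n_iter: int = 5000,
    seed: int = 0,
) -> NominationResult:
    """Run the cell-type-aware nomination pipeline over one cohort."""
    ctmap = ctmap or DEFAULT_PHENOTYPE_MAP
    policy = policy or FilterPolicy()
    stage: dict[str, int] = {}

    records = split_and_annotate(raws, annotations)
    stage["biallelic_records"] = len(records)
    by_key = {r.key: r for r in records}

    peaksets: dict[str, DiseasePeakSet] = {}
    for ped in pedigrees:
        if ped.disease_group not in peaksets:
            peaksets[ped.disease_group] = build_disease_search_space(
                atlas, ped.disease_group, ctmap)

    pre_overlay: list[CandidateVariant] = []
    for ped in pedigrees:
        pre_overlay.extend(search_family(
            ped, records, peakset=peaksets[ped.disease_group],
            filter_policy=policy, denovo_policy=denovo_policy,
            incomplete_penetrance=incomplete_penetrance))
    stage["post_inheritance"] = len(pre_overlay)

    ped_by_id = {p.family_id: p for p in pedigrees}
    overlaid: list[CandidateVariant] = []
    for c in pre_overlay:
        ped = ped_by_id[c.family_id]
        kept = assign_to_peaks([c], by_key, peaksets[ped.disease_group])
        overlaid.extend(kept)
    stage["post_overlay"] = len(overlaid)

    surviving = apply_cohort_exclusion(overlaid, by_key, pedigrees, policy)
    stage["post_cohort_exclusion"] = len(surviving)

    flagged_ind, flagged_fam = detect_outliers(surviving)

    multihit = tabulate_multihit_peaks(surviving)
    stage["multihit_peaks"] = len(multihit)

    mh_dominant_fams = set()
    for mh in multihit:
        if mh.broad_mode == "dominant":
            mh_dominant_fams |= set(mh.families)
    fam_pres = {c.family_id: ped_by_id[c.family_id].presentation
                for c in surviving}
    if fam_pres and mh_dominant_fams:
        orr, pval, _ = isolated_syndromic_enrichment(mh_dominant_fams, fam_pres)
    else:
        # no multi-hit families: no association to test
        orr, pval = float("nan"), float("nan")

    enrichment: dict[str, PermutationResult] = {}
    if run_enrichment:
        rng = np.random.default_rng(seed)
        # genome-wide (pre-overlay) candidates per disease group feed the null
        for group in sorted({p.disease_group for p in pedigrees}):
            cands = [c for c in pre_overlay
                     if ped_by_id[c.family_id].disease_group == group
                     and not (set(c.carriers) & flagged_ind)]
            if not cands:
                continue
            spans = pd.DataFrame(
                [(c.key[0], *by_key[c.key].span) for c in cands],
                columns=["contig", "start", "end"]).drop_duplicates()
            peaks = peaksets[group].intervals[["contig", "start", "end"]]
            enrichment[group] = permutation_enrichment(
                spans, peaks, layout, n_iter=n_iter, rng=rng)

    return NominationResult(
        candidates=candidates_to_frame(surviving, pedigrees),
        pre_overlay=pre_overlay,
        multihit_peaks=multihit,
        stage_counts=stage,
        flagged_individuals=flagged_ind,
        flagged_families=flagged_fam,
        enrichment=enrichment,
        isolated_or=orr,
        isolated_p=pval,
    )


# ---------------------------------------------------------------------------
# Planted-truth auditing
# ---------------------------------------------------------------------------

def audit_planted_truth(
    truth: pd.DataFrame,
    result: NominationResult,
    pedigrees: list[Pedigree],
    records: list[VariantRecord],
    atlas: pd.DataFrame,
    ctmap: dict | None = None,
    policy: FilterPolicy | None = None,
) -> pd.DataFrame:
    """Score recovery of plants and rejection (with reasons) of decoys.

    For every truth row, reports whether it was nominated and -- for
    decoys -- the observed rejection reason, classified into the same
    vocabulary the generator plants (af_high / gerp_low / gq_low / ab_low
    / outside_peak / unaffected_carrier).
    """
    ctmap = ctmap or DEFAULT_PHENOTYPE_MAP
    policy = policy or FilterPolicy()
    by_key = {r.key: r for r in records}
    ped_by_id = {p.family_id: p for p in pedigrees}
    nominated = set(zip(result.candidates["contig"], result.candidates["pos"],
                        result.candidates["ref"], result.candidates["alt"],
                        result.candidates["family_id"]))
    peaksets = {}

    def classify(row) -> str:
        key = (row.contig, int(row.pos), row.ref, row.alt)
        v = by_key.get(key)
        if v is None:
            return "absent"
        ok, reasons = passes_site_filters(v, DOMINANT, policy)
        if not ok:
            for r in reasons:
                if r.startswith("gnomad_af") or r.startswith("topmed_af"):
                    return "af_high"
                if r.startswith("gerp"):
                    return "gerp_low"
            return ";".join(reasons)
        ped = ped_by_id[row.family_id]
        proband = next(m for m in ped.children_with_parents() if m.affected)
        ok, reasons = passes_genotype_filters(v.call(proband.id), policy)
        if not ok:
            for r in reasons:
                if r.startswith("gq"):
                    return "gq_low"
                if r.startswith("allele_balance") or r == "no_depth":
                    return "ab_low"
            return ";".join(reasons)
        group = ped.disease_group
        if group not in peaksets:
            peaksets[group] = build_disease_search_space(atlas, group, ctmap)
        if peaksets[group].assign(v.contig, *v.span) is None:
            return "outside_peak"
        from .filters import effective_genotype

        for other in pedigrees:
            if other.family_id == ped.family_id:
                continue
            for m in other.unaffected_members():
                if effective_genotype(v.call(m.id), policy) in ("het", "hom_alt"):
                    return "unaffected_carrier"
        return "survived"

    rows = []
    for row in truth.itertuples(index=False):
        key5 = (row.contig, int(row.pos), row.ref, row.alt, row.family_id)
        was_nominated = key5 in nominated
        observed = "survived" if was_nominated else classify(row)
        rows.append(dict(kind=row.kind, family_id=row.family_id,
                         contig=row.contig, pos=row.pos, ref=row.ref,
                         alt=row.alt, mode=row.mode,
                         expected_survival=bool(row.expected_survival),
                         planted_reason=row.reason, nominated=was_nominated,
                         observed_reason=observed))
    return pd.DataFrame(rows)
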