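"""Pedigree-aware Mendelian searches over filtered bi-allelic variants.

Five modes are searched: de novo, dominant, dominant with incomplete
penetrance, homozygous recessive, and compound heterozygous. For the
compound-heterozygote search the regulatory peak -- not the gene -- is the
unit of heredity: a qualifying pair is two distinct variants inside the
same merged disease peak, one inherited from an unaffected father and the
other from an unaffected mother.

Genotype semantics: "carried" means het or hom_alt on a call passing the
genotype filters; a missing or failing call is never a carrier and never a
confirmed non-carrier, so an affected member with a missing call
disqualifies dominant/recessive candidacy (conservative), while a missing
unaffected member simply cannot veto.

De novo calling is a deterministic rule (child het passing filters, both
parents hom_ref with at most ``max_parental_alt_reads`` supporting reads,
0 by default) rather than a likelihood-based caller, so it is reproducible
without genotype-likelihood fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import (
    DOMINANT,
    RECESSIVE,
    FilterPolicy,
    effective_genotype,
    passes_site_filters,
)
from .pedigree import Pedigree
from .variants import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    VariantKey,
    VariantRecord,
)

MODE_DE_NOVO = "de_novo"
MODE_DOMINANT = "dominant"
MODE_DOMINANT_INCOMPLETE = "dominant_incomplete"
MODE_HOM_RECESSIVE = "hom_recessive"
MODE_COMP_HET = "comp_het"

DOMINANT_MODES = frozenset({MODE_DE_NOVO, MODE_DOMINANT, MODE_DOMINANT_INCOMPLETE})
RECESSIVE_MODES = frozenset({MODE_HOM_RECESSIVE, MODE_COMP_HET})


def broad_mode(mode: str) -> str:
    return "dominant" if mode in DOMINANT_MODES else "recessive"


@dataclass
class DeNovoPolicy:
    max_parental_alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.max_parental_alt_reads < 0:
            raise ValueError("max_parental_alt_reads must be >= 0")


@dataclass
class CandidateVariant:
    key: VariantKey
    family_id: str
    mode: str
    carriers: list[str] = field(default_factory=list)
    partner_key: VariantKey | None = None
    peak_id: str | None = None

    @property
    def broad_mode(self) -> str:
        return broad_mode(self.mode)


def _is_carrier(gt: str) -> bool:
    return gt in (GT_HET, GT_HOM_ALT)


def find_de_novo(
    family: Pedigree,
    variants: list[VariantRecord],
    policy: DeNovoPolicy | None = None,
    filter_policy: FilterPolicy | None = None,
) -> list[CandidateVariant]:
    """De novo candidates: affected child het, both parents confidently hom_ref."""
    policy = policy or DeNovoPolicy()
    out = []
    probands = [
        m for m in family.children_with_parents() if m.affected
    ]
    if not probands:
        return out
    for v in variants:
        ok, _ = passes_site_filters(v, DOMINANT, filter_policy)
        if not ok:
            continue
        for child in probands:
            c_call = v.call(child.id)
            if effective_genotype(c_call, filter_policy) != GT_HET:
                continue
            parents_ok = True
            for pid in (child.father_id, child.mother_id):
                p_call = v.call(pid)
                if (
                    effective_genotype(p_call, filter_policy) != GT_HOM_REF
                    or p_call.alt_depth > policy.max_parental_alt_reads
                ):
                    parents_ok = False
                    break
            if parents_ok:
                out.append(CandidateVariant(v.key, family.family_id,
                                            MODE_DE_NOVO, carriers=[child.id]))
    return out


def find_dominant(
    family: Pedigree,
    variants: list[VariantRecord],
    incomplete_penetrance: bool = False,
    filter_policy: FilterPolicy | None = None,
) -> list[CandidateVariant]:
    """Variants carried by every affected and (unless the incomplete-
    penetrance relaxation is on) by no unaffected family member."""
    affected = family.affected_members()
    unaffected = family.unaffected_members()
    if not affected or len(family.members) < 2:
        return []
    mode = MODE_DOMINANT_INCOMPLETE if incomplete_penetrance else MODE_DOMINANT
    out = []
    for v in variants:
        ok, _ = passes_site_filters(v, DOMINANT, filter_policy)
        if not ok:
            continue
        gts = {m.id: effective_genotype(v.call(m.id), filter_policy)
               for m in family.members}
        if not all(_is_carrier(gts[m.id]) for m in affected):
            continue
        if not incomplete_penetrance and any(
            _is_carrier(gts[m.id]) for m in unaffected
        ):
            continue
        carriers = [m.id for m in family.members if _is_carrier(gts[m.id])]
        out.append(CandidateVariant(v.key, family.family_id, mode,
                                    carriers=carriers))
    return out


def find_hom_recessive(
    family: Pedigree,
    variants: list[VariantRecord],
    filter_policy: FilterPolicy | None = None,
) -> list[CandidateVariant]:
    """All affecteds hom_alt, each genotyped parent het, no unaffected hom_alt."""
    affected = family.affected_members()
    if not affected:
        return []
    out = []
    for v in variants:
        ok, _ = passes_site_filters(v, RECESSIVE, filter_policy)
        if not ok:
            continue
        gts = {m.id: effective_genotype(v.call(m.id), filter_policy)
               for m in family.members}
        if not all(gts[m.id] == GT_HOM_ALT for m in affected):
            continue
        parents_ok = True
        for m in affected:
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                if gts[pid] != GT_HET:
                    parents_ok = False
        if not parents_ok:
            continue
        if any(gts[m.id] == GT_HOM_ALT for m in family.unaffected_members()):
            continue
        out.append(CandidateVariant(v.key, family.family_id, MODE_HOM_RECESSIVE,
                                    carriers=[m.id for m in affected]))
    return out


def find_compound_het(
    family: Pedigree,
    variants: list[VariantRecord],
    peakset,
    filter_policy: FilterPolicy | None = None,
) -> list[CandidateVariant]:
    """Peak-as-locus compound heterozygotes.

    ``peakset`` is the merged disease search space (an object exposing
    ``assign(contig, start, end) -> (interval_index, peak_id) or None``,
    see :class:`crevar.atlas.DiseasePeakSet`). Both variants must lie in
    the same merged peak, both must pass the recessive regime, the child
    must be het for both, and the pair must consist of one paternally- and
    one maternally-inherited allele from unaffected parents. Pairs are
    emitted as two records with mutual partner keys.
    """
    out: list[CandidateVariant] = []
    probands = [m for m in family.children_with_parents() if m.affected]
    for child in probands:
        father = family.get(child.father_id)
        mother = family.get(child.mother_id)
        if not (father.unaffected and mother.unaffected):
            # an affected parent makes the mode inapplicable for this child
            continue
        by_peak: dict[int, dict[str, list]] = {}
        for v in variants:
            ok, _ = passes_site_filters(v, RECESSIVE, filter_policy)
            if not ok:
                continue
            if effective_genotype(v.call(child.id), filter_policy) != GT_HET:
                continue
            f_gt = effective_genotype(v.call(father.id), filter_policy)
            m_gt = effective_genotype(v.call(mother.id), filter_policy)
            if _is_carrier(f_gt) and m_gt == GT_HOM_REF:
                origin = "paternal"
            elif _is_carrier(m_gt) and f_gt == GT_HOM_REF:
                origin = "maternal"
            else:
                continue
            hit = peakset.assign(v.contig, *v.span)
            if hit is None:
                continue
            interval_idx, peak_id = hit
            slot = by_peak.setdefault(interval_idx, {"paternal": [], "maternal": [],
                                                     "peak_id": peak_id})
            slot[origin].append(v)
        for slot in by_peak.values():
            for v1 in slot["paternal"]:
                for v2 in slot["maternal"]:
                    if v1.key == v2.key:
                        continue
                    out.append(CandidateVariant(
                        v1.key, family.family_id, MODE_COMP_HET,
                        carriers=[child.id], partner_key=v2.key,
                        peak_id=slot["peak_id"]))
                    out.append(CandidateVariant(
                        v2.key, family.family_id, MODE_COMP_HET,
                        carriers=[child.id], partner_key=v1.key,
                        peak_id=slot["peak_id"]))
    return out


def apply_cohort_exclusion(
    candidates: list[CandidateVariant],
    variants_by_key: dict[VariantKey, VariantRecord],
    pedigrees: list[Pedigree],
    filter_policy: FilterPolicy | None = None,
) -> list[CandidateVariant]:
    """Cohort-level exclusion against unaffected individuals.

    Dominant / de novo candidates are removed when any unaffected
    individual outside the candidate's family carries an alt allele;
    recessive candidates (homozygous and compound-het members) are removed
    when any such individual is hom_alt. A compound-het pair is removed
    whenever either member is excluded. Exclusion is restricted to
    individuals outside the family because within-family carriers are
    already handled (or deliberately waived) by the mode searches.
    """
    unaffected: dict[str, list[str]] = {}
    for ped in pedigrees:
        for m in ped.unaffected_members():
            unaffected.setdefault(ped.family_id, []).append(m.id)

    def excluded(cand: CandidateVariant, key: VariantKey) -> bool:
        v = variants_by_key.get(key)
        if v is None:
            return False
        for fam, members in unaffected.items():
            if fam == cand.family_id:
                continue
            for sid in members:
                gt = effective_genotype(v.call(sid), filter_policy)
                if cand.broad_mode == "dominant" and _is_carrier(gt):
                    return True
                if cand.broad_mode == "recessive" and gt == GT_HOM_ALT:
                    return True
        return False

    dead_pairs: set[tuple[str, frozenset]] = set()
    for c in candidates:
        if c.mode == MODE_COMP_HET and excluded(c, c.key):
            dead_pairs.add((c.family_id, frozenset((c.key, c.partner_key))))
    out = []
    for c in candidates:
        if c.mode == MODE_COMP_HET:
            if (c.family_id, frozenset((c.key, c.partner_key))) in dead_pairs:
                continue
            out.append(c)
        elif not excluded(c, c.key):
            out.append(c)
    return out


def detect_outliers(
    candidates: list[CandidateVariant],
    de_novo_threshold: int = 75,
    pedigree_robust_z: float = 5.0,
) -> tuple[set[str], set[str]]:
    """Flag hypermutable-looking individuals and pedigrees.

    Individuals with more than ``de_novo_threshold`` de novo candidates
    (strictly greater) are flagged for removal from enrichment analysis.
    Pedigrees whose total candidate count is a robust-z outlier (modified
    z via median absolute deviation) are flagged as well.
    """
    per_individual: dict[str, int] = {}
    per_family: dict[str, int] = {}
    for c in candidates:
        per_family[c.family_id] = per_family.get(c.family_id, 0) + 1
        if c.mode == MODE_DE_NOVO:
            for s in c.carriers:
                per_individual[s] = per_individual.get(s, 0) + 1
    flagged_individuals = {s for s, n in per_individual.items()
                           if n > de_novo_threshold}
    flagged_families: set[str] = set()
    if len(per_family) >= 3:
        counts = np.array(list(per_family.values()), dtype=float)
        med = float(np.median(counts))
        mad = float(np.median(np.abs(counts - med)))
        if mad > 0:
            for fam, n in per_family.items():
                if (n - med) / (1.4826 * mad) > pedigree_robust_z:
                    flagged_families.add(fam)
    return flagged_individuals, flagged_families


def search_family(
    family: Pedigree,
    variants: list[VariantRecord],
    peakset=None,
    filter_policy: FilterPolicy | None = None,
    denovo_policy: DeNovoPolicy | None = None,
    incomplete_penetrance: bool = False,
) -> list[CandidateVariant]:
    """Run every mode plausible for this family's structure.

    Trios with unaffected parents are searched for de novo, homozygous
    recessive and (when a peak set is supplied) compound-het candidates;
    families with two or more affected members are searched under the
    dominant mode, optionally with the incomplete-penetrance relaxation.
    Solved pedigrees are skipped entirely.
    """
    if family.solved:
        return []
    out: list[CandidateVariant] = []
    out += find_de_novo(family, variants, denovo_policy, filter_policy)
    out += find_hom_recessive(family, variants, filter_policy)
    if peakset is not None:
        out += find_compound_het(family, variants, peakset, filter_policy)
    if len(family.affected_members()) >= 2:
        out += find_dominant(family, variants, False, filter_policy)
        if incomplete_penetrance:
            dom_keys = {c.key for c in out if c.mode == MODE_DOMINANT}
            out += [c for c in find_dominant(family, variants, True, filter_policy)
                    if c.key not in dom_keys]
    return out
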