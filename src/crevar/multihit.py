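"""Peak-centric and gene-centric allelic aggregation across families.

A "multi-hit peak" is a disease-relevant peak hit by qualifying candidate
variants (SNVs/indels and/or SVs) in two or more distinct families, all
obeying the same broad mode of inheritance (dominant vs recessive). The
same variant recurring in two unrelated families counts as two family
hits. SVs longer than 100 kb or with a clear coding etiology are excluded
before counting; solved pedigrees never contribute.

A "multi-hit gene" is a gene whose significant peak-to-gene links include
two or more distinct peaks each containing at least one dominant candidate
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .inheritance import MODE_COMP_HET, CandidateVariant


@dataclass
class MultiHitPeak:
    peak_id: str
    broad_mode: str
    families: frozenset
    variant_keys: frozenset

    @property
    def n_families(self) -> int:
        return len(self.families)


@dataclass
class MultiHitGene:
    gene: str
    peaks: frozenset
    variant_keys: frozenset


def tabulate_multihit_peaks(
    candidates: list[CandidateVariant],
    sv_candidates: list[dict] | None = None,
    sv_max_length: int = 100_000,
    min_families: int = 2,
) -> list[MultiHitPeak]:
    """Aggregate overlay-annotated candidates by (peak, broad mode).

    A compound-het pair contributes a single family hit on its shared
    peak. ``sv_candidates`` rows (from
    :func:`crevar.atlas.filter_sv_candidates`) join the tally after the
    length / coding-etiology exclusions.
    """
    per: dict[tuple[str, str], dict[str, set]] = {}

    def add(peak_id, bmode, family, key):
        slot = per.setdefault((peak_id, bmode), {"families": set(), "keys": set()})
        slot["families"].add(family)
        slot["keys"].add(key)

    for c in candidates:
        if c.peak_id is None:
            continue
        add(c.peak_id, c.broad_mode, c.family_id, c.key)
    for sv in sv_candidates or []:
        if sv["length"] > sv_max_length or sv.get("overlaps_coding"):
            continue
        bmode = "dominant" if sv["mode"] in ("de_novo", "dominant",
                                             "dominant_incomplete") else "recessive"
        add(sv["peak_id"], bmode, sv["family_id"],
            ("SV", sv["contig"], sv["start"], sv["end"]))

    out = []
    for (peak_id, bmode), slot in sorted(per.items()):
        if len(slot["families"]) >= min_families:
            out.append(MultiHitPeak(peak_id, bmode,
                                    frozenset(slot["families"]),
                                    frozenset(slot["keys"])))
    return out


def tabulate_multihit_genes(
    candidates: list[CandidateVariant],
    links: pd.DataFrame,
    min_peaks: int = 2,
) -> list[MultiHitGene]:
    """Genes linked to >= ``min_peaks`` distinct dominant-candidate peaks.

    ``links`` must carry ``peak_id`` and ``gene`` columns (significant
    links only). Peaks, not variants, are counted: two candidates in one
    linked peak do not make a gene multi-hit. Set ``min_peaks=1`` for the
    variant-count reading.
    """
    dom_peaks: dict[str, set] = {}
    for c in candidates:
        if c.broad_mode == "dominant" and c.peak_id is not None:
            dom_peaks.setdefault(c.peak_id, set()).add(c.key)
    out = []
    for gene, sub in links.groupby("gene", sort=True):
        hit_peaks = sorted(set(sub["peak_id"]) & set(dom_peaks))
        if len(hit_peaks) >= min_peaks:
            keys = frozenset().union(*(dom_peaks[p] for p in hit_peaks))
            out.append(MultiHitGene(gene, frozenset(hit_peaks), keys))
    return out


def isolated_syndromic_enrichment(
    multihit_families: set,
    family_presentation: dict[str, str],
) -> tuple[float, float, list[list[int]]]:
    """Fisher test of isolated presentation among multi-hit families.

    Builds the 2x2 table (multi-hit membership x isolated status) over all
    families in ``family_presentation`` (the families contributing
    candidates). Returns the sample cross-product odds ratio (with the
    Haldane 0.5 correction when any cell is zero), the two-sided exact
    p-value by point-probability summation over the hypergeometric
    distribution, and the table ``[[a, b], [c, d]]`` where the first row
    is multi-hit families (isolated, syndromic).
    """
    a = b = c = d = 0
    for fam, pres in family_presentation.items():
        isolated = pres == "isolated"
        if fam in multihit_families:
            a, b = a + isolated, b + (not isolated)
        else:
            c, d = c + isolated, d + (not isolated)
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        import warnings

        warnings.warn("degenerate 2x2 margin; odds ratio undefined")
        return float("nan"), 1.0, table
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(orr), p, table
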