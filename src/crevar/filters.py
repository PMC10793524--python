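"""Bi-allelic normalization and the hard site / genotype filters.

Every search runs on bi-allelic records: multi-allelic sites are split one
record per alternate allele (spanning-deletion ``*`` alleles are not
kept), with the other alternate alleles counting as reference for
zygosity. Site filters are applied per inheritance regime -- the dominant
and de novo searches use a stricter allele-frequency ceiling than the
recessive searches -- and all thresholds are strict inequalities:
AF < 1e-3 (dominant) / < 1e-2 (recessive) in both gnomAD and TOPMed,
GERP > 2, FILTER pass, genotype quality > 20 and heterozygous allele
balance > 0.15.

Missing population AF passes (absence from the reference panels is
evidence of rarity); missing GERP fails unless conservation is explicitly
waived, since conservation is an affirmative requirement here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variants import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GenotypeCall,
    RawVariant,
    VariantRecord,
)

DOMINANT = "dominant"
RECESSIVE = "recessive"


@dataclass
class FilterPolicy:
    af_max_dominant: float = 1e-3
    af_max_recessive: float = 1e-2
    gerp_min: float = 2.0
    gq_min: int = 20
    ab_min_het: float = 0.15
    require_pass: bool = True
    missing_af_passes: bool = True
    require_gerp: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_max_dominant <= self.af_max_recessive <= 1.0):
            raise ValueError("need 0 <= af_max_dominant <= af_max_recessive <= 1")

    def af_max(self, regime: str) -> float:
        if regime == DOMINANT:
            return self.af_max_dominant
        if regime == RECESSIVE:
            return self.af_max_recessive
        raise ValueError(f"unknown regime {regime!r}")


def split_multiallelic(raw: RawVariant, annotations=None) -> list[VariantRecord]:
    """Split a raw record into one bi-allelic :class:`VariantRecord` per alt.

    Spanning-deletion alleles (``*``) are dropped. Genotypes are recoded
    relative to the retained alt: any other allele (reference or another
    alt, including ``*``) counts as reference for zygosity. The alt depth
    is the AD entry of the retained alt; the ref depth is the remainder of
    the total, so allele balance remains alt / total.

    ``annotations`` maps ``(contig, pos, ref, alt)`` to a dict with keys
    ``gnomad_af`` / ``topmed_af`` / ``gerp`` / ``region_class``.
    """
    out = []
    for ai, alt in enumerate(raw.alts):
        if alt == "*":
            continue
        allele_idx = ai + 1
        calls: dict[str, GenotypeCall] = {}
        for sample, rc in raw.calls.items():
            if rc.alleles is None:
                calls[sample] = GenotypeCall(sample, GT_MISSING)
                continue
            dosage = sum(1 for a in rc.alleles if a == allele_idx)
            gt = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[dosage]
            ad = rc.ad or ()
            alt_depth = int(ad[allele_idx]) if allele_idx < len(ad) else 0
            ref_depth = int(sum(ad)) - alt_depth if ad else 0
            calls[sample] = GenotypeCall(
                sample, gt, gq=int(rc.gq or 0),
                ref_depth=ref_depth, alt_depth=alt_depth,
            )
        ann = {}
        if annotations is not None:
            ann = annotations.get((raw.contig, raw.pos, raw.ref, alt), {})
        out.append(
            VariantRecord(
                contig=raw.contig,
                pos=raw.pos,
                ref=raw.ref,
                alt=alt,
                filter_pass=raw.filter_pass,
                gnomad_af=ann.get("gnomad_af"),
                topmed_af=ann.get("topmed_af"),
                gerp=ann.get("gerp"),
                region_class=ann.get("region_class"),
                calls=calls,
            )
        )
    return out


def passes_site_filters(
    variant: VariantRecord, regime: str, policy: FilterPolicy | None = None
) -> tuple[bool, list[str]]:
    """Hard site filters for one bi-allelic variant under one regime.

    Returns ``(passed, reasons)`` where ``reasons`` lists every violated
    filter (useful for auditing why a planted decoy was rejected).
    """
    policy = policy or FilterPolicy()
    af_max = policy.af_max(regime)
    reasons: list[str] = []
    if policy.require_pass and not variant.filter_pass:
        reasons.append("filter_not_pass")
    for name, af in (("gnomad_af", variant.gnomad_af),
                     ("topmed_af", variant.topmed_af)):
        if af is None:
            if not policy.missing_af_passes:
                reasons.append(f"{name}_missing")
        elif not (af < af_max):
            reasons.append(f"{name}>={af_max:g}")
    if variant.gerp is None:
        if policy.require_gerp:
            reasons.append("gerp_missing")
    elif not (variant.gerp > policy.gerp_min):
        reasons.append(f"gerp<={policy.gerp_min:g}")
    return (not reasons), reasons


def passes_genotype_filters(
    call: GenotypeCall, policy: FilterPolicy | None = None
) -> tuple[bool, list[str]]:
    """Genotype quality > gq_min; het calls additionally need AB > ab_min."""
    policy = policy or FilterPolicy()
    reasons: list[str] = []
    if call.gt == GT_MISSING:
        return False, ["missing_call"]
    if not (call.gq > policy.gq_min):
        reasons.append(f"gq<={policy.gq_min}")
    if call.gt == GT_HET:
        ab = call.allele_balance
        if ab is None:
            reasons.append("no_depth")
        elif not (ab > policy.ab_min_het):
            reasons.append(f"allele_balance<={policy.ab_min_het:g}")
    return (not reasons), reasons


def effective_genotype(call: GenotypeCall, policy: FilterPolicy | None = None) -> str:
    """Genotype after quality filtering: failing calls become missing.

    This is the genotype the inheritance searches consume -- a failing call
    is never a carrier and never a confirmed non-carrier.
    """
    ok, _ = passes_genotype_filters(call, policy)
    return call.gt if ok else GT_MISSING
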