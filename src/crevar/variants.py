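"""Variant containers and VCF / annotation-table input-output.

The in-memory model mirrors the two stages of the callset: a
:class:`RawVariant` preserves a site exactly as genotyped (possibly
multi-allelic, spanning-deletion alleles included) while a
:class:`VariantRecord` is the bi-allelic representation every downstream
filter and search operates on. Population annotations (gnomAD / TOPMed
allele frequencies, GERP, region class) are carried per bi-allelic key in
a sidecar TSV; missing annotations are represented as ``None``, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"

VariantKey = tuple[str, int, str, str]


@dataclass
class GenotypeCall:
    sample_id: str
    gt: str
    gq: int = 0
    ref_depth: int = 0
    alt_depth: int = 0

    def __post_init__(self) -> None:
        if self.gq < 0 or self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("negative depth or quality")
        if self.gt not in (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING):
            raise ValueError(f"bad genotype {self.gt!r}")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def allele_balance(self) -> float | None:
        if self.total_depth == 0:
            return None
        return self.alt_depth / self.total_depth

    @property
    def is_carrier(self) -> bool:
        return self.gt in (GT_HET, GT_HOM_ALT)


@dataclass
class RawCall:
    """One sample at a possibly multi-allelic site. ``alleles`` are indices
    into ``[ref] + alts``; ``None`` means an uncalled genotype."""
    alleles: tuple[int, int] | None
    gq: int | None = None
    ad: tuple[int, ...] | None = None


@dataclass
class RawVariant:
    contig: str
    pos: int                      # 1-based
    ref: str
    alts: list[str]
    filter_pass: bool = True
    calls: dict[str, RawCall] = field(default_factory=dict)


@dataclass
class VariantRecord:
    contig: str
    pos: int                      # 1-based
    ref: str
    alt: str
    filter_pass: bool = True
    gnomad_af: float | None = None
    topmed_af: float | None = None
    gerp: float | None = None
    region_class: str | None = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref == alt")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span: [pos-1, pos-1+len(ref))."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def call(self, sample_id: str) -> GenotypeCall:
        c = self.calls.get(sample_id)
        if c is None:
            return GenotypeCall(sample_id, GT_MISSING)
        return c


@dataclass
class SVRecord:
    contig: str
    start: int                    # 0-based half-open
    end: int
    svtype: str                   # DEL / DUP / INV / MEI / CPX
    cohort_af: float = 0.0
    overlaps_coding: bool = False
    sv_id: str = ""
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("SV start >= end")
        if not (0.0 <= self.cohort_af <= 1.0):
            raise ValueError("cohort_af outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TERecord:
    contig: str
    pos: int                      # 1-based insertion point
    te_family: str                # L1 / Alu / SVA
    confidence: str               # xTea feature tag
    pop_af: float = 0.0
    te_id: str = ""
    carrier_support: dict[str, int] = field(default_factory=dict)
    in_same_family_repeat: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pop_af <= 1.0):
            raise ValueError("pop_af outside [0,1]")
        if any(v < 0 for v in self.carrier_support.values()):
            raise ValueError("negative supporting read count")


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

_INT_MISSING = -2147483648  # htslib sentinel surfacing through cyvcf2


def read_vcf(path) -> list[RawVariant]:
    """Stream raw (possibly multi-allelic) records from a VCF.

    Requires GT in FORMAT; a sample whose GQ or AD is absent is marked
    missing rather than dropped, matching how failing genotype calls are
    later treated as missing for inheritance logic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise ValueError(f"{v.CHROM}:{v.POS}: no GT format field")
        gqs = v.format("GQ")
        ads = v.format("AD")
        calls: dict[str, RawCall] = {}
        for si, sample in enumerate(samples):
            g = v.genotypes[si]
            alleles = tuple(int(a) for a in g[:2])
            if len(alleles) < 2 or min(alleles) < 0:
                calls[sample] = RawCall(None)
                continue
            gq = None
            if gqs is not None:
                q = int(np.asarray(gqs[si]).ravel()[0])
                gq = None if q == _INT_MISSING else q
            ad = None
            if ads is not None:
                row = np.asarray(ads[si]).ravel()
                if not np.any(row == _INT_MISSING):
                    ad = tuple(int(x) for x in row)
            if gq is None or ad is None:
                calls[sample] = RawCall(None)
            else:
                calls[sample] = RawCall(alleles, gq=gq, ad=ad)
        out.append(
            RawVariant(
                contig=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alts=list(v.ALT),
                filter_pass=v.FILTER is None,  # cyvcf2: None == PASS
                calls=calls,
            )
        )
    return out


def write_vcf(raws: list[RawVariant], samples: list[str], contigs: dict[str, int],
              path) -> None:
    """Write raw records as a minimal VCF 4.2 with GT:GQ:AD per sample."""
    raws = sorted(raws, key=lambda r: (list(contigs).index(r.contig), r.pos, r.ref))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FILTER=<ID=lowqual,Description="Failed site filters">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in raws:
            n_alleles = 1 + len(r.alts)
            cols = [
                r.contig, str(r.pos), ".", r.ref, ",".join(r.alts), ".",
                "PASS" if r.filter_pass else "lowqual", ".", "GT:GQ:AD",
            ]
            for s in samples:
                c = r.calls.get(s)
                if c is None or c.alleles is None:
                    cols.append("./.:.:" + ",".join("." * n_alleles))
                    continue
                gt = "/".join(str(a) for a in c.alleles)
                ad = ",".join(str(x) for x in (c.ad or (0,) * n_alleles))
                cols.append(f"{gt}:{c.gq}:{ad}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation sidecar
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "contig", "pos", "ref", "alt", "gnomad_af", "topmed_af", "gerp", "region_class",
]


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"contig": str, "pos": np.int64, "ref": str, "alt": str,
               "region_class": str},
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS,
              na_rep="", float_format="%.10g")


def annotation_lookup(df: pd.DataFrame) -> dict[VariantKey, dict]:
    """Key the annotation table by (contig, pos, ref, alt)."""
    out: dict[VariantKey, dict] = {}
    for row in df.itertuples(index=False):
        out[(row.contig, int(row.pos), row.ref, row.alt)] = {
            "gnomad_af": None if pd.isna(row.gnomad_af) else float(row.gnomad_af),
            "topmed_af": None if pd.isna(row.topmed_af) else float(row.topmed_af),
            "gerp": None if pd.isna(row.gerp) else float(row.gerp),
            "region_class": None if (row.region_class is None or
                                     pd.isna(row.region_class) or
                                     row.region_class == "")
            else str(row.region_class),
        }
    return out
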