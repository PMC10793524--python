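"""Synthetic cohorts, atlases and matrices with planted ground truth.

Every pipeline input can be generated here with a known answer key, so
each stage -- and the pipeline end to end -- is testable without any
protected data. The generator emulates:

* a cell-type peak atlas with log-normal peak sizes (median 500 bp,
  sigma 0.5 on the log scale -- plausible ATAC peak sizes) and a
  configurable fraction of peaks shared between cell types;
* a rare-allele-frequency variant spectrum (Beta-distributed population
  AF), Hardy-Weinberg founder genotypes and Mendelian transmission within
  trio / dominant / recessive pedigrees;
* planted candidate variants for every inheritance mode, placed inside
  the appropriate disease group's peaks, plus decoys that each violate
  exactly one filter (AF too high, GERP too low, GQ too low, allele
  balance too low, outside the search space, carried by an unaffected
  cohort member);
* accessibility / expression matrices whose planted (peak, gene) pairs
  share a latent factor with a target correlation, with per-cell fragment
  totals drawn log-normally;
* binomially sampled allele counts and noisy cluster labels for the
  allelic and cluster-metric statistics.

Each sub-generator draws from its own RNG stream derived from the master
seed, so adding one generator never perturbs another. What the generator
does *not* emulate: linkage disequilibrium, recombination, sequence
context (no reads or FASTA), or real ATAC count overdispersion beyond the
log-normal-Poisson mixture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DEFAULT_PHENOTYPE_MAP, build_disease_search_space
from .clustermetrics import ClusterContingency
from .allelic import AlleleCountObservation
from .genome import GenomeLayout, place_nonoverlapping
from .pedigree import DISEASE_GROUPS, Individual, Pedigree
from .variants import RawCall, RawVariant, SVRecord, TERecord

CELL_TYPES = ("cMN3/4", "cMN6", "cMN7", "cMN12", "sMN")
TIMEPOINTS = ("e10.5", "e11.5")

REGION_CLASSES = ("exonic", "intronic", "intergenic", "promoter")
# genome-wide proportions of a human WGS callset by region class
REGION_WEIGHTS = (0.021, 0.342, 0.630, 0.007)

DECOY_KINDS = ("af_high", "gerp_low", "gq_low", "ab_low", "outside_peak",
               "unaffected_carrier")


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass
class PlantSpec:
    mode: str                  # de_novo / dominant / hom_recessive / comp_het
    disease_group: str
    in_peak: bool = True
    #: place this plant in the same merged peak as the previous plant
    #: (a different family), emulating a recurrently mutated enhancer
    share_peak_with_previous: bool = False


def default_plants() -> list[PlantSpec]:
    return [
        PlantSpec("de_novo", "DRS"),
        PlantSpec("de_novo", "CFP"),
        PlantSpec("de_novo", "CFEOM"),
        PlantSpec("dominant", "MBS"),
        PlantSpec("dominant", "DRS"),
        PlantSpec("hom_recessive", "CFP"),
        PlantSpec("hom_recessive", "DRS"),
        PlantSpec("comp_het", "DRS"),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000})
    mask: dict = field(default_factory=dict)
    n_trios: int = 12
    n_dominant_families: int = 4
    n_recessive_families: int = 4
    n_solved: int = 1
    peaks_per_celltype: int = 120
    shared_peak_fraction: float = 0.2
    peak_length_median_bp: float = 500.0
    peak_length_sigma: float = 0.5
    background_variant_rate: float = 2e-4   # variants per bp
    af_beta: tuple[float, float] = (0.3, 60.0)
    gerp_mixture: tuple[float, float, float, float, float] = (0.5, 0.0, 1.5, 3.5, 1.0)
    multiallelic_fraction: float = 0.05
    spanning_fraction: float = 0.3          # of multi-allelic sites, extra "*" allele
    plant_spec: list[PlantSpec] = field(default_factory=default_plants)
    decoy_spec: list[str] = field(default_factory=lambda: list(DECOY_KINDS))

    def __post_init__(self) -> None:
        for n in (self.n_trios, self.n_dominant_families,
                  self.n_recessive_families, self.peaks_per_celltype):
            if n < 0:
                raise ValueError("counts must be >= 0")
        for d in self.decoy_spec:
            if d not in DECOY_KINDS:
                raise ValueError(f"unknown decoy kind {d!r}")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.contigs), dict(self.mask))


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def simulate_atlas(config: SimulationConfig) -> tuple[GenomeLayout, pd.DataFrame]:
    """Non-overlapping peaks per cell type with log-normal lengths.

    A ``shared_peak_fraction`` of each cell type's peaks is drawn from a
    pool common to all cell types (same coordinates, same peak_id), the
    rest are private. Returns the layout and an atlas table with one row
    per (peak, cell type).
    """
    rng = stream(config.seed, "atlas")
    layout = config.layout()
    if config.peaks_per_celltype == 0:
        return layout, pd.DataFrame(
            columns=["contig", "start", "end", "peak_id", "cell_type", "timepoint"])
    n_shared = int(round(config.shared_peak_fraction * config.peaks_per_celltype))
    n_private = config.peaks_per_celltype - n_shared
    total = n_shared + n_private * len(CELL_TYPES)
    lengths = rng.lognormal(np.log(config.peak_length_median_bp),
                            config.peak_length_sigma, size=total)
    lengths = np.maximum(lengths.round().astype(np.int64), 50)
    contigs, starts = place_nonoverlapping(lengths, layout, rng)
    peak_ids = np.array([f"pk{i:05d}" for i in range(total)])
    tps = rng.choice(TIMEPOINTS, size=total)
    rows = []
    for i in range(n_shared):
        for ct in CELL_TYPES:
            rows.append((contigs[i], int(starts[i]), int(starts[i] + lengths[i]),
                         peak_ids[i], ct, tps[i]))
    k = n_shared
    for ct in CELL_TYPES:
        for _ in range(n_private):
            rows.append((contigs[k], int(starts[k]), int(starts[k] + lengths[k]),
                         peak_ids[k], ct, tps[k]))
            k += 1
    atlas = pd.DataFrame(rows, columns=["contig", "start", "end", "peak_id",
                                        "cell_type", "timepoint"])
    atlas = atlas.sort_values(["contig", "start", "cell_type"],
                              kind="stable").reset_index(drop=True)
    return layout, atlas


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    pedigrees: list[Pedigree]
    samples: list[str]
    raws: list[RawVariant]
    annotations: pd.DataFrame
    truth: pd.DataFrame


def _make_pedigrees(config: SimulationConfig, rng: np.random.Generator):
    peds: list[Pedigree] = []
    groups = list(DISEASE_GROUPS)
    gi = 0

    def next_group():
        nonlocal gi
        g = groups[gi % len(groups)]
        gi += 1
        return g

    def presentation():
        return "isolated" if rng.random() < 0.6 else "syndromic"

    for t in range(config.n_trios):
        fam = f"T{t:02d}"
        members = [
            Individual(f"{fam}_fa", fam, sex="male", status="unaffected"),
            Individual(f"{fam}_mo", fam, sex="female", status="unaffected"),
            Individual(f"{fam}_p1", fam, father_id=f"{fam}_fa",
                       mother_id=f"{fam}_mo",
                       sex="male" if rng.random() < 0.5 else "female",
                       status="affected"),
        ]
        peds.append(Pedigree(fam, members, disease_group=next_group(),
                             presentation=presentation(), structure="auto",
                             solved=t >= config.n_trios - config.n_solved))
    for t in range(config.n_dominant_families):
        fam = f"D{t:02d}"
        members = [
            Individual(f"{fam}_fa", fam, sex="male", status="affected"),
            Individual(f"{fam}_mo", fam, sex="female", status="unaffected"),
            Individual(f"{fam}_p1", fam, father_id=f"{fam}_fa",
                       mother_id=f"{fam}_mo", sex="female", status="affected"),
            Individual(f"{fam}_s1", fam, father_id=f"{fam}_fa",
                       mother_id=f"{fam}_mo", sex="male", status="unaffected"),
        ]
        peds.append(Pedigree(fam, members, disease_group=next_group(),
                             presentation=presentation(), structure="auto"))
    for t in range(config.n_recessive_families):
        fam = f"R{t:02d}"
        members = [
            Individual(f"{fam}_fa", fam, sex="male", status="unaffected"),
            Individual(f"{fam}_mo", fam, sex="female", status="unaffected"),
            Individual(f"{fam}_p1", fam, father_id=f"{fam}_fa",
                       mother_id=f"{fam}_mo", sex="male", status="affected"),
        ]
        peds.append(Pedigree(fam, members, disease_group=next_group(),
                             presentation=presentation(), structure="auto"))
    return peds


_BASES = np.array(list("ACGT"))


def _random_snv(rng) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _depth_call(rng, alleles: tuple[int, int], n_alleles: int,
                gq: int | None = None) -> RawCall:
    depth = max(int(rng.poisson(30)), 8)
    ad = [0] * n_alleles
    a1, a2 = alleles
    if a1 == a2:
        ad[a1] = depth
    else:
        r = int(rng.binomial(depth, 0.5))
        r = min(max(r, int(0.25 * depth)), int(0.75 * depth))  # keep het AB sane
        ad[a1] += r
        ad[a2] += depth - r
    if gq is None:
        gq = int(rng.integers(40, 99))
    return RawCall(alleles, gq=gq, ad=tuple(ad))


def _founder_alleles(rng, afs: np.ndarray) -> tuple[int, int]:
    p0 = 1.0 - afs.sum()
    probs = np.concatenate([[p0], afs])
    a = rng.choice(len(probs), size=2, p=probs)
    return int(a[0]), int(a[1])


def _transmit(rng, father: tuple[int, int], mother: tuple[int, int]):
    return (int(father[rng.integers(0, 2)]), int(mother[rng.integers(0, 2)]))


def simulate_cohort(config: SimulationConfig, atlas: pd.DataFrame,
                    layout: GenomeLayout | None = None) -> SimulatedCohort:
    """Variants + pedigrees + answer key for the full nomination pipeline."""
    rng = stream(config.seed, "cohort")
    layout = layout or config.layout()
    peds = _make_pedigrees(config, rng)
    samples = [m.id for p in peds for m in p.members]
    contig_names = list(layout.contigs)
    sizes = np.array([layout.contigs[c] for c in contig_names], dtype=np.int64)
    cum = np.cumsum(sizes)

    used_pos: set[tuple[str, int]] = set()

    def random_site(rng) -> tuple[str, int]:
        while True:
            g = int(rng.integers(0, cum[-1]))
            ci = int(np.searchsorted(cum, g, side="right"))
            pos = g - (int(cum[ci - 1]) if ci else 0) + 1  # 1-based
            site = (contig_names[ci], pos)
            if site not in used_pos:
                used_pos.add(site)
                return site

    peaksets = {g: build_disease_search_space(atlas, g) for g in DISEASE_GROUPS}

    def site_in_disease_peaks(rng, group) -> tuple[str, int, str]:
        ps = peaksets[group]
        if ps.n_intervals == 0:
            raise ValueError(f"no disease peak set for group {group!r}")
        while True:
            row = ps.intervals.iloc[int(rng.integers(0, ps.n_intervals))]
            pos = int(rng.integers(row["start"], row["end"])) + 1
            if (row["contig"], pos) not in used_pos:
                used_pos.add((row["contig"], pos))
                return row["contig"], pos, row["interval_id"]

    def site_outside_all_peaks(rng) -> tuple[str, int]:
        full = {g: peaksets[g] for g in peaksets}
        while True:
            contig, pos = random_site(rng)
            if all(full[g].assign(contig, pos - 1, pos) is None for g in full):
                return contig, pos

    raws: list[RawVariant] = []
    ann_rows: list[tuple] = []
    truth_rows: list[dict] = []

    def hom_ref_backfill(calls: dict, rng, n_alleles=2):
        for s in samples:
            if s not in calls:
                calls[s] = _depth_call(rng, (0, 0), n_alleles)

    def add_plant_annotation(contig, pos, ref, alt, gnomad=None, topmed=None,
                             gerp=4.0):
        ann_rows.append((contig, pos, ref, alt, gnomad, topmed, gerp, "intronic"))

    # ---- planted candidates -------------------------------------------
    trio_pool = [p for p in peds if p.family_id.startswith("T") and not p.solved]
    dom_pool = [p for p in peds if p.family_id.startswith("D")]
    rec_pool = [p for p in peds if p.family_id.startswith("R")]
    pools = {"de_novo": trio_pool, "dominant": dom_pool,
             "hom_recessive": rec_pool, "comp_het": rec_pool}
    used_families: set[str] = set()

    def take_family(mode: str, disease_group: str) -> Pedigree:
        for ped in pools[mode]:
            if ped.family_id in used_families:
                continue
            used_families.add(ped.family_id)
            ped.disease_group = disease_group  # generator owns phenotype assignment
            return ped
        raise ValueError(f"not enough families for mode {mode!r}")

    def het_call(rng):
        return _depth_call(rng, (0, 1), 2, gq=99)

    def hom_alt_call(rng):
        return _depth_call(rng, (1, 1), 2, gq=99)

    def hom_ref_call(rng):
        return _depth_call(rng, (0, 0), 2, gq=99)

    prev_interval: tuple[str, str] | None = None  # (disease_group, interval_id)
    for spec in config.plant_spec:
        ped = take_family(spec.mode, spec.disease_group)
        fam = ped.family_id
        if spec.share_peak_with_previous:
            if prev_interval is None or prev_interval[0] != spec.disease_group:
                raise ValueError("share_peak_with_previous needs a preceding "
                                 "plant in the same disease group")
            ps = peaksets[spec.disease_group]
            row = ps.intervals[ps.intervals["interval_id"]
                               == prev_interval[1]].iloc[0]
            contig, peak_id = row["contig"], row["interval_id"]
            while True:
                pos = int(rng.integers(row["start"], row["end"])) + 1
                if (contig, pos) not in used_pos:
                    used_pos.add((contig, pos))
                    break
        elif spec.in_peak:
            contig, pos, peak_id = site_in_disease_peaks(rng, spec.disease_group)
        else:
            contig, pos = site_outside_all_peaks(rng)
            peak_id = ""
        if spec.in_peak:
            prev_interval = (spec.disease_group, peak_id)
        ref, alt = _random_snv(rng)
        calls: dict[str, RawCall] = {}
        if spec.mode == "de_novo":
            calls[f"{fam}_p1"] = het_call(rng)
            calls[f"{fam}_fa"] = hom_ref_call(rng)
            calls[f"{fam}_mo"] = hom_ref_call(rng)
        elif spec.mode == "dominant":
            for m in ped.members:
                calls[m.id] = het_call(rng) if m.affected else hom_ref_call(rng)
        elif spec.mode == "hom_recessive":
            calls[f"{fam}_p1"] = hom_alt_call(rng)
            calls[f"{fam}_fa"] = het_call(rng)
            calls[f"{fam}_mo"] = het_call(rng)
        elif spec.mode == "comp_het":
            # first variant: paternal
            calls[f"{fam}_p1"] = het_call(rng)
            calls[f"{fam}_fa"] = het_call(rng)
            calls[f"{fam}_mo"] = hom_ref_call(rng)
        else:
            raise ValueError(f"unknown plant mode {spec.mode!r}")
        hom_ref_backfill(calls, rng)
        raws.append(RawVariant(contig, pos, ref, alts=[alt], calls=calls))
        add_plant_annotation(contig, pos, ref, alt)
        truth_rows.append(dict(kind="plant", family_id=fam, contig=contig,
                               pos=pos, ref=ref, alt=alt, mode=spec.mode,
                               peak_id=peak_id, reason="",
                               expected_survival=spec.in_peak))
        if spec.mode == "comp_het":
            # maternal partner inside the same merged peak
            ps = peaksets[spec.disease_group]
            row = ps.intervals[ps.intervals["interval_id"] == peak_id].iloc[0]
            while True:
                pos2 = int(rng.integers(row["start"], row["end"])) + 1
                if (contig, pos2) not in used_pos and pos2 != pos:
                    used_pos.add((contig, pos2))
                    break
            ref2, alt2 = _random_snv(rng)
            calls2 = {
                f"{fam}_p1": het_call(rng),
                f"{fam}_mo": het_call(rng),
                f"{fam}_fa": hom_ref_call(rng),
            }
            hom_ref_backfill(calls2, rng)
            raws.append(RawVariant(contig, pos2, ref2, alts=[alt2], calls=calls2))
            add_plant_annotation(contig, pos2, ref2, alt2)
            truth_rows.append(dict(kind="plant", family_id=fam, contig=contig,
                                   pos=pos2, ref=ref2, alt=alt2, mode="comp_het",
                                   peak_id=peak_id, reason="",
                                   expected_survival=spec.in_peak))

    # ---- decoys: each violates exactly one filter ---------------------
    for kind in config.decoy_spec:
        ped = take_family("de_novo", "DRS")
        fam = ped.family_id
        if kind == "outside_peak":
            contig, pos = site_outside_all_peaks(rng)
            peak_id = ""
        else:
            contig, pos, peak_id = site_in_disease_peaks(rng, ped.disease_group)
        ref, alt = _random_snv(rng)
        gnomad = 5e-3 if kind == "af_high" else None
        gerp = 1.0 if kind == "gerp_low" else 4.0
        child = het_call(rng)
        if kind == "gq_low":
            child = RawCall((0, 1), gq=15, ad=child.ad)
        if kind == "ab_low":
            child = RawCall((0, 1), gq=99, ad=(18, 2))
        calls = {
            f"{fam}_p1": child,
            f"{fam}_fa": hom_ref_call(rng),
            f"{fam}_mo": hom_ref_call(rng),
        }
        if kind == "unaffected_carrier":
            other = next(p for p in peds if p.family_id != fam
                         and p.unaffected_members())
            calls[other.unaffected_members()[0].id] = het_call(rng)
        hom_ref_backfill(calls, rng)
        raws.append(RawVariant(contig, pos, ref, alts=[alt], calls=calls))
        add_plant_annotation(contig, pos, ref, alt, gnomad=gnomad, gerp=gerp)
        truth_rows.append(dict(kind="decoy", family_id=fam, contig=contig,
                               pos=pos, ref=ref, alt=alt, mode="de_novo",
                               peak_id=peak_id, reason=kind,
                               expected_survival=False))

    # ---- background variants ------------------------------------------
    a, b = config.af_beta
    w, mu1, sd1, mu2, sd2 = config.gerp_mixture
    n_bg = int(round(config.background_variant_rate * layout.total_length))
    member_index = {p.family_id: p for p in peds}
    for _ in range(n_bg):
        contig, pos = random_site(rng)
        n_alts = 1
        has_span = False
        if rng.random() < config.multiallelic_fraction:
            n_alts = 2
            has_span = rng.random() < config.spanning_fraction
        ref = str(_BASES[rng.integers(0, 4)])
        alts = []
        for _ in range(n_alts):
            while True:
                cand = str(_BASES[rng.integers(0, 4)])
                if cand != ref and cand not in alts:
                    break
            alts.append(cand)
        if has_span:
            alts.append("*")
        afs = rng.beta(a, b, size=len(alts))
        n_alleles = 1 + len(alts)
        calls: dict[str, RawCall] = {}
        for ped in peds:
            founder_gts: dict[str, tuple[int, int]] = {}
            for m in ped.members:
                if m.father_id is None and m.mother_id is None:
                    founder_gts[m.id] = _founder_alleles(rng, afs)
            for m in ped.members:
                if m.father_id is not None and m.mother_id is not None:
                    alle = _transmit(rng, founder_gts[m.father_id],
                                     founder_gts[m.mother_id])
                else:
                    alle = founder_gts[m.id]
                calls[m.id] = _depth_call(rng, alle, n_alleles)
        raws.append(RawVariant(contig, pos, ref, alts=alts, calls=calls))
        gerps = np.where(rng.random(len(alts)) < w,
                         rng.normal(mu1, sd1, len(alts)),
                         rng.normal(mu2, sd2, len(alts)))
        for ai, alt in enumerate(alts):
            if alt == "*":
                continue
            af = float(afs[ai])
            topmed = None if rng.random() < 0.1 else float(
                min(max(af * rng.lognormal(0, 0.2), 0.0), 1.0))
            region = str(rng.choice(REGION_CLASSES, p=REGION_WEIGHTS))
            ann_rows.append((contig, pos, ref, alt, af, topmed,
                             float(gerps[ai]), region))

    order = {c: i for i, c in enumerate(contig_names)}
    raws.sort(key=lambda r: (order[r.contig], r.pos, r.ref))
    ann = pd.DataFrame(ann_rows, columns=["contig", "pos", "ref", "alt",
                                          "gnomad_af", "topmed_af", "gerp",
                                          "region_class"])
    ann = ann.sort_values(["contig", "pos", "ref", "alt"],
                          key=lambda s: s.map(order) if s.name == "contig" else s,
                          kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    assert member_index  # families built
    return SimulatedCohort(peds, samples, raws, ann, truth)


# ---------------------------------------------------------------------------
# Structural variants and TE insertions
# ---------------------------------------------------------------------------

def simulate_sv_te(config: SimulationConfig, atlas: pd.DataFrame,
                   pedigrees: list[Pedigree]):
    """A small SV/TE callset with planted candidates and filter decoys."""
    from .variants import GenotypeCall

    rng = stream(config.seed, "sv_te")
    peaksets = {p.disease_group: build_disease_search_space(atlas, p.disease_group)
                for p in pedigrees}

    def gt(sample, g):
        return GenotypeCall(sample, g, gq=99, ref_depth=15 if g != "hom_alt" else 0,
                            alt_depth=0 if g == "hom_ref" else 15)

    def peak_anchor(ped):
        ps = peaksets[ped.disease_group]
        row = ps.intervals.iloc[int(rng.integers(0, ps.n_intervals))]
        return row["contig"], int(row["start"]), int(row["end"])

    svs: list[SVRecord] = []
    truth = []
    rec = next(p for p in pedigrees if p.family_id.startswith("R"))
    contig, s, e = peak_anchor(rec)
    fam = rec.family_id
    svs.append(SVRecord(contig, max(0, s - 1500), max(0, s - 1500) + 3600, "DEL",
                        cohort_af=0.001, sv_id="sv_rec_del",
                        calls={f"{fam}_p1": gt(f"{fam}_p1", "hom_alt"),
                               f"{fam}_fa": gt(f"{fam}_fa", "het"),
                               f"{fam}_mo": gt(f"{fam}_mo", "het")}))
    truth.append(dict(record_id="sv_rec_del", expected="hom_recessive",
                      family_id=fam))

    trio = next(p for p in pedigrees if p.structure == "trio" and not p.solved)
    contig, s, e = peak_anchor(trio)
    fam = trio.family_id
    svs.append(SVRecord(contig, s, s + 2000, "DEL", cohort_af=0.0,
                        sv_id="sv_denovo_del",
                        calls={f"{fam}_p1": gt(f"{fam}_p1", "het"),
                               f"{fam}_fa": gt(f"{fam}_fa", "hom_ref"),
                               f"{fam}_mo": gt(f"{fam}_mo", "hom_ref")}))
    truth.append(dict(record_id="sv_denovo_del", expected="de_novo",
                      family_id=fam))

    svs.append(SVRecord(contig, s, s + 1200, "DUP", cohort_af=0.02,
                        sv_id="sv_common_dup",
                        calls={f"{fam}_p1": gt(f"{fam}_p1", "het"),
                               f"{fam}_fa": gt(f"{fam}_fa", "hom_ref"),
                               f"{fam}_mo": gt(f"{fam}_mo", "hom_ref")}))
    truth.append(dict(record_id="sv_common_dup", expected="excluded_af",
                      family_id=fam))

    svs.append(SVRecord(contig, max(0, s - 50_000), max(0, s - 50_000) + 150_000,
                        "DEL", cohort_af=0.0, sv_id="sv_large_del",
                        calls={f"{fam}_p1": gt(f"{fam}_p1", "het"),
                               f"{fam}_fa": gt(f"{fam}_fa", "hom_ref"),
                               f"{fam}_mo": gt(f"{fam}_mo", "hom_ref")}))
    truth.append(dict(record_id="sv_large_del", expected="candidate_not_multihit",
                      family_id=fam))

    tes: list[TERecord] = []
    trio2 = [p for p in pedigrees if p.structure == "trio" and not p.solved][1]
    contig, s, e = peak_anchor(trio2)
    fam = trio2.family_id
    tes.append(TERecord(contig, e + 10, "Alu", "two_side_tprt_both", pop_af=0.0,
                        te_id="te_denovo_alu",
                        carrier_support={f"{fam}_p1": 6, f"{fam}_fa": 0,
                                         f"{fam}_mo": 0},
                        in_same_family_repeat=False))
    truth.append(dict(record_id="te_denovo_alu", expected="de_novo",
                      family_id=fam))
    dom = next(p for p in pedigrees if p.family_id.startswith("D"))
    contig, s, e = peak_anchor(dom)
    fam = dom.family_id
    tes.append(TERecord(contig, s + 5, "L1", "two_side_tprt", pop_af=0.005,
                        te_id="te_rare_l1",
                        carrier_support={m.id: (4 if m.affected else 0)
                                         for m in dom.members},
                        in_same_family_repeat=False))
    truth.append(dict(record_id="te_rare_l1", expected="dominant",
                      family_id=fam))
    tes.append(TERecord(contig, s + 25, "Alu", "two_side_tprt_both", pop_af=0.02,
                        te_id="te_common_alu",
                        carrier_support={m.id: 4 for m in dom.members},
                        in_same_family_repeat=False))
    truth.append(dict(record_id="te_common_alu", expected="excluded_af",
                      family_id=fam))
    fam = trio2.family_id
    tes.append(TERecord(contig, s + 45, "L1", "two_side_tprt_both", pop_af=0.0,
                        te_id="te_parental_read",
                        carrier_support={f"{fam}_p1": 6, f"{fam}_fa": 1,
                                         f"{fam}_mo": 0},
                        in_same_family_repeat=False))
    truth.append(dict(record_id="te_parental_read", expected="excluded_parent_read",
                      family_id=fam))
    return svs, tes, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Linked accessibility / expression matrices
# ---------------------------------------------------------------------------

@dataclass
class LinkedMatrices:
    acc: np.ndarray                 # peaks x cells counts
    expr: np.ndarray                # genes x cells counts
    peaks: pd.DataFrame             # contig/start/end/peak_id
    tss: pd.DataFrame               # gene/contig/tss/strand
    frag_totals: np.ndarray         # per-cell unique fragment totals
    truth_links: pd.DataFrame       # peak_id/gene/r_target
    embedding: np.ndarray           # cells x 2 latent embedding


def simulate_linked_matrices(
    seed: int = 0,
    n_cells: int = 500,
    n_genes: int = 12,
    null_peaks_per_gene: int = 2,
    r_target: float = 0.6,
    mean_acc: float = 300.0,
    mean_expr: float = 200.0,
    signal_sd: float = 0.7,
    frag_log_mean: float = np.log(2e4),
    frag_log_sd: float = 0.4,
    linked_offset: int = 30_000,
    contig: str = "chrQ",
    gene_spacing: int = 1_200_000,
) -> LinkedMatrices:
    """Latent-factor-linked count matrices with one planted link per gene.

    Each gene gets one linked peak (population correlation ``r_target``
    through a shared latent factor on the log-intensity scale) and
    ``null_peaks_per_gene`` independent peaks inside the +/- 500 kb
    window, plus one distant peak outside any window every fourth gene.
    Counts are Poisson draws around log-normal intensities scaled by the
    cell's fragment-total depth factor, so depth normalization is
    exercised.
    """
    if n_cells <= 0:
        raise ValueError("need at least one cell")
    if not (-1.0 < r_target < 1.0):
        raise ValueError("r_target must lie in (-1, 1)")
    rng = stream(seed, "linked_matrices")
    frag = rng.lognormal(frag_log_mean, frag_log_sd, size=n_cells)
    depth = frag / frag.mean()
    # sign goes on the expression side only, so corr(acc, expr) = r_target
    sr_acc = np.sqrt(abs(r_target))
    sr_expr = sr_acc * np.sign(r_target)
    so = np.sqrt(1.0 - abs(r_target))

    peaks_rows, tss_rows, truth_rows = [], [], []
    acc_rows, expr_rows = [], []
    for gi in range(n_genes):
        tss = gene_spacing * (gi + 1)
        gene = f"gene{gi:03d}"
        tss_rows.append((gene, contig, tss, "+"))
        z = rng.normal(size=n_cells)
        g_expr = sr_expr * z + so * rng.normal(size=n_cells)
        expr_rows.append(rng.poisson(
            np.exp(np.log(mean_expr) + signal_sd * g_expr) * depth))
        # linked peak
        g_acc = sr_acc * z + so * rng.normal(size=n_cells)
        start = tss + linked_offset
        peaks_rows.append((contig, start, start + 500, f"peak_g{gi:03d}_linked"))
        acc_rows.append(rng.poisson(
            np.exp(np.log(mean_acc) + signal_sd * g_acc) * depth))
        truth_rows.append((f"peak_g{gi:03d}_linked", gene, r_target))
        for ni in range(null_peaks_per_gene):
            start = tss - 100_000 * (ni + 1)
            peaks_rows.append((contig, start, start + 500,
                               f"peak_g{gi:03d}_null{ni}"))
            acc_rows.append(rng.poisson(
                np.exp(np.log(mean_acc)
                       + signal_sd * rng.normal(size=n_cells)) * depth))
        if gi % 4 == 0:
            start = tss + 550_000
            peaks_rows.append((contig, start, start + 500,
                               f"peak_g{gi:03d}_far"))
            acc_rows.append(rng.poisson(
                np.exp(np.log(mean_acc)
                       + signal_sd * rng.normal(size=n_cells)) * depth))
    embedding = rng.normal(size=(n_cells, 2))
    return LinkedMatrices(
        acc=np.vstack(acc_rows),
        expr=np.vstack(expr_rows),
        peaks=pd.DataFrame(peaks_rows,
                           columns=["contig", "start", "end", "peak_id"]),
        tss=pd.DataFrame(tss_rows, columns=["gene", "contig", "tss", "strand"]),
        frag_totals=frag,
        truth_links=pd.DataFrame(truth_rows,
                                 columns=["peak_id", "gene", "r_target"]),
        embedding=embedding,
    )


# ---------------------------------------------------------------------------
# Allele counts and cluster labels
# ---------------------------------------------------------------------------

def simulate_allele_counts(n_total: int, p_ref: float,
                           seed: int = 0,
                           rng: np.random.Generator | None = None
                           ) -> AlleleCountObservation:
    """Reference count ~ Binomial(n_total, p_ref); mutant is the remainder."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if not (0.0 <= p_ref <= 1.0):
        raise ValueError("p_ref must lie in [0,1]")
    if rng is None:
        rng = stream(seed, "allele_counts")
    k = int(rng.binomial(n_total, p_ref))
    return AlleleCountObservation(k=k, n=n_total)


def simulate_cluster_labels(n_cells: int, n_classes: int, n_clusters: int,
                            fidelity: float, seed: int = 0,
                            rng: np.random.Generator | None = None
                            ) -> ClusterContingency:
    """Cells land in their class's designated cluster with prob ``fidelity``.

    With probability ``1 - fidelity`` the cell is assigned uniformly to
    one of the *other* clusters, so ``fidelity=1`` yields a (padded)
    diagonal table and ``fidelity = 1/n_clusters``-ish yields chance-level
    homogeneity.
    """
    if n_clusters < 1:
        raise ValueError("need >= 1 cluster")
    if not (0.0 <= fidelity <= 1.0):
        raise ValueError("fidelity must lie in [0,1]")
    if rng is None:
        rng = stream(seed, "cluster_labels")
    a = np.zeros((n_classes, n_clusters), dtype=np.int64)
    classes = rng.integers(0, n_classes, size=n_cells)
    for c in classes:
        designated = int(c) % n_clusters
        if n_clusters == 1 or rng.random() < fidelity:
            k = designated
        else:
            k = int(rng.integers(0, n_clusters - 1))
            if k >= designated:
                k += 1
        a[c, k] += 1
    return ClusterContingency(a)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_inputs(cohort: SimulatedCohort, atlas: pd.DataFrame,
                 layout: GenomeLayout, outdir) -> dict[str, str]:
    """Emit the exact file formats the pipeline consumes, plus the truth table."""
    import os

    from .atlas import write_atlas_bed
    from .pedigree import write_pedigree
    from .variants import write_annotations, write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("vcf", "cohort.vcf"), ("ped", "cohort.ped"),
        ("phenotypes", "phenotypes.tsv"), ("annotations", "annotations.tsv"),
        ("atlas", "atlas.bed"), ("truth", "planted_truth.tsv"),
        ("contigs", "contigs.tsv")]}
    write_vcf(cohort.raws, cohort.samples, layout.contigs, paths["vcf"])
    write_pedigree(cohort.pedigrees, paths["ped"], paths["phenotypes"])
    write_annotations(cohort.annotations, paths["annotations"])
    write_atlas_bed(atlas, paths["atlas"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({"contig": list(layout.contigs),
                  "length": list(layout.contigs.values())}
                 ).to_csv(paths["contigs"], sep="\t", index=False)
    return paths
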