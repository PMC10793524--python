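"""Variant-level statistics: exact binomial allelic test and SAD scoring.

The allelic-imbalance ("binomial ATAC") test asks whether accessibility
reads from heterozygous tissue sample the two alleles equally: with ``n``
informative reads of which ``k`` carry the reference allele, the
two-sided exact p-value sums the point probabilities of every outcome no
more probable than the observed one,

    p = sum_{i : Pr(X=i) <= Pr(X=k)} C(n, i) pi0^i (1 - pi0)^(n-i),

under the null reference-allele probability ``pi0`` (0.5 by default).
Point-probability comparisons use a relative tolerance of ``1 + 1e-7`` so
floating-point jitter cannot misclassify symmetric outcomes.

SAD ("SNP accessibility difference") scores summarize a sequence-to-
coverage model's predicted allelic effect: the raw score is the summed
predicted alt-minus-ref coverage over a fixed window (131,072 bp for the
reference model family), standardized per sample group to z-scores using
the SNV-derived null (indels are standardized against the same SNV mean
and SD). Negative z is a predicted loss of accessibility (LoF), positive
a gain (GoF); |z| > 2 is called significant. The predictive model itself
is pluggable: any callable mapping a sequence to a per-bin coverage
vector works, and the tests use small analytic motif scorers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SAD_WINDOW = 131_072
TIE_RTOL = 1e-7


@dataclass
class AlleleCountObservation:
    k: int              # reference / wildtype allele count
    n: int              # total informative reads
    pi0: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if self.n < 1:
            raise ValueError("need n >= 1")
        if not (0.0 < self.pi0 < 1.0):
            raise ValueError("pi0 must be in (0,1)")

    @property
    def m(self) -> int:
        """Mutant allele count."""
        return self.n - self.k


def exact_binomial_two_sided(obs: AlleleCountObservation) -> float:
    """Two-sided exact binomial p: sum of outcomes no likelier than observed."""
    i = np.arange(obs.n + 1)
    pmf = stats.binom.pmf(i, obs.n, obs.pi0)
    pk = pmf[obs.k]
    p = float(pmf[pmf <= pk * (1.0 + TIE_RTOL)].sum())
    return min(p, 1.0)


def allelic_ratio(obs: AlleleCountObservation) -> tuple[float, bool]:
    """Wildtype / mutant count ratio; flagged infinite when no mutant reads."""
    if obs.m == 0:
        return float("inf"), True
    return obs.k / obs.m, False


# ---------------------------------------------------------------------------
# SAD post-processing over a pluggable scorer
# ---------------------------------------------------------------------------

#: Registry of named scorers so configurations can refer to them by name.
SCORER_REGISTRY: dict[str, object] = {}


def register_scorer(name: str, scorer) -> None:
    SCORER_REGISTRY[name] = scorer


def sad_raw(scorer, ref_seq: str, alt_seq: str) -> float:
    """Summed predicted alt-minus-ref coverage difference.

    ``scorer(seq)`` must return equal-length per-bin coverage vectors for
    both alleles (a scorer with a fixed-length convention handles indels).
    """
    pred_ref = np.asarray(scorer(ref_seq), dtype=float)
    pred_alt = np.asarray(scorer(alt_seq), dtype=float)
    if pred_ref.shape != pred_alt.shape:
        raise ValueError("scorer returned different-length coverage vectors "
                         f"({pred_ref.shape} vs {pred_alt.shape})")
    return float((pred_alt - pred_ref).sum())


def sad_zscores(records: pd.DataFrame, group_cols=("sample",)) -> pd.DataFrame:
    """Standardize raw SAD scores to z within each sample group.

    ``records`` needs columns ``raw`` and ``is_indel`` plus the grouping
    columns. Within each group the SNV rows define the null (population
    mean and SD, i.e. divide by sqrt(n)); indels are standardized with the
    same SNV-derived parameters. Groups whose SNV SD is zero (or with < 2
    SNVs) are flagged and left with NaN z.
    """
    out = records.copy()
    out["z"] = np.nan
    out["flagged"] = False
    for _, idx in out.groupby(list(group_cols)).groups.items():
        sub = out.loc[idx]
        snv_raw = sub.loc[~sub["is_indel"], "raw"].to_numpy(dtype=float)
        if len(snv_raw) < 2:
            out.loc[idx, "flagged"] = True
            continue
        mu = float(snv_raw.mean())
        sd = float(snv_raw.std())  # population SD
        if sd == 0:
            out.loc[idx, "flagged"] = True
            continue
        out.loc[idx, "z"] = (sub["raw"].to_numpy(dtype=float) - mu) / sd
    return out


def classify_mechanism(z: float, threshold: float = 2.0) -> tuple[str, bool]:
    """LoF for z < 0, GoF for z > 0, neutral at exactly 0; significant iff |z| > threshold."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z < 0:
        mech = "LoF"
    elif z > 0:
        mech = "GoF"
    else:
        mech = "neutral"
    return mech, bool(abs(z) > threshold)


BASES = ("A", "C", "G", "T")


@dataclass
class SaturationResult:
    """Position x alternate-base x sample delta tensor.

    ``delta[i, j, s]`` is the raw SAD score of substituting position ``i``
    with ``alt_bases[i][j]`` under sample ``s``'s scorer; positions whose
    reference base is not A/C/G/T are flagged in ``skipped`` and hold NaN.
    """

    ref_seq: str
    samples: list[str]
    alt_bases: list[tuple[str, ...]]
    delta: np.ndarray
    skipped: np.ndarray


def saturation_mutagenesis(scorers: dict[str, object], region_seq: str) -> SaturationResult:
    """Score every possible single-base substitution in a region.

    ``scorers`` maps sample id to a scorer callable. Returns the
    length-by-3-by-samples tensor of raw deltas.
    """
    if len(region_seq) < 1:
        raise ValueError("empty region")
    samples = list(scorers)
    L = len(region_seq)
    delta = np.full((L, 3, len(samples)), np.nan)
    skipped = np.zeros(L, dtype=bool)
    alt_bases: list[tuple[str, ...]] = []
    ref_preds = {s: np.asarray(scorers[s](region_seq), dtype=float)
                 for s in samples}
    for i, base in enumerate(region_seq.upper()):
        if base not in BASES:
            skipped[i] = True
            alt_bases.append(())
            continue
        alts = tuple(b for b in BASES if b != base)
        alt_bases.append(alts)
        for j, alt in enumerate(alts):
            mutated = region_seq[:i] + alt + region_seq[i + 1:]
            for si, s in enumerate(samples):
                pred_alt = np.asarray(scorers[s](mutated), dtype=float)
                if pred_alt.shape != ref_preds[s].shape:
                    raise ValueError("scorer returned different-length vectors")
                delta[i, j, si] = float((pred_alt - ref_preds[s]).sum())
    return SaturationResult(region_seq, samples, alt_bases, delta, skipped)


class MotifScorer:
    """Analytic toy scorer: predicted coverage is a motif-occurrence pileup.

    Each occurrence of ``motif`` adds ``weight`` to the bins it covers.
    Output length is fixed to ``len(seq_ref_length)`` bins of one base
    each; sequences of other lengths are right-padded/truncated so indel
    alleles still yield equal-length vectors.
    """

    def __init__(self, motif: str, weight: float = 1.0, n_bins: int | None = None):
        self.motif = motif.upper()
        self.weight = weight
        self.n_bins = n_bins

    def __call__(self, seq: str) -> np.ndarray:
        s = seq.upper()
        n = self.n_bins or len(s)
        cov = np.zeros(n, dtype=float)
        m = len(self.motif)
        for i in range(len(s) - m + 1):
            if s[i:i + m] == self.motif:
                j0, j1 = min(i, n), min(i + m, n)
                cov[j0:j1] += self.weight
        return cov
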