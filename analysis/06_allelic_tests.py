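#!/usr/bin/env python
"""Variant-level statistics: binomial ATAC, SAD z-scores, saturation scan.

Simulates allele counts from heterozygous tissue with a cis effect
(reference allele four times as accessible as the mutant), tests the
imbalance with the two-sided exact binomial test, standardizes toy-scorer
SAD scores to z per sample group with mechanism calls, and runs an
in-silico saturation scan over a motif-bearing region.
"""

import argparse
import os

import numpy as np
import pandas as pd

from crevar.allelic import MotifScorer, allelic_ratio, classify_mechanism, \
    exact_binomial_two_sided, sad_raw, sad_zscores, saturation_mutagenesis
from crevar.simulate import simulate_allele_counts, stream


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    rng = stream(args.seed, "allelic_analysis")

    # --- binomial ATAC ---------------------------------------------------
    rows = []
    for coverage in (60, 151, 400):
        obs = simulate_allele_counts(coverage, 0.8, rng=rng)
        ratio, _ = allelic_ratio(obs)
        p = exact_binomial_two_sided(obs)
        rows.append({"coverage": coverage, "ref": obs.k, "mut": obs.m,
                     "ratio": round(ratio, 2), "p": p})
        print(f"coverage {coverage}: ref/mut = {obs.k}/{obs.m} "
              f"(ratio {ratio:.2f}), two-sided exact p = {p:.3g}")
    binom = pd.DataFrame(rows)

    # --- SAD z-scores over a toy motif scorer ----------------------------
    # one motif in a 200 bp element: most scored variants are null, so the
    # SNV-derived null SD reflects background rather than motif disruption
    region = "".join(rng.choice(list("ACGT"), size=200))
    region = region[:100] + "ACGTAC" + region[106:]   # embed a motif instance
    scorer = MotifScorer("ACGTAC", n_bins=len(region))
    sad_rows = []
    for i in range(60):
        pos = int(rng.integers(0, len(region)))
        alt = str(rng.choice([b for b in "ACGT" if b != region[pos]]))
        mutated = region[:pos] + alt + region[pos + 1:]
        sad_rows.append({"variant": f"v{i:02d}", "sample": "cMN7_e10.5",
                         "raw": sad_raw(scorer, region, mutated),
                         "is_indel": False})
    sad = sad_zscores(pd.DataFrame(sad_rows))
    sad[["mechanism", "significant"]] = [
        classify_mechanism(z) if np.isfinite(z) else ("NA", False)
        for z in sad.z]
    n_sig = int(sad.significant.sum())
    print(f"SAD: {len(sad)} scored variants, {n_sig} with |z| > 2 "
          f"({(sad[sad.significant].mechanism.value_counts().to_dict())})")

    # --- saturation mutagenesis ------------------------------------------
    sat = saturation_mutagenesis({"cMN7_e10.5": scorer}, region)
    worst = np.unravel_index(np.nanargmin(sat.delta), sat.delta.shape)
    print(f"saturation: {sat.delta.shape[0]}x3 substitutions; strongest "
          f"loss at position {worst[0]} "
          f"(delta {np.nanmin(sat.delta):.0f}, motif disruption)")

    os.makedirs(args.outdir, exist_ok=True)
    binom.to_csv(os.path.join(args.outdir, "binomial_atac.tsv"), sep="\t",
                 index=False)
    sad.to_csv(os.path.join(args.outdir, "sad_scores.tsv"), sep="\t",
               index=False)
    print(f"wrote {args.outdir}/binomial_atac.tsv, sad_scores.tsv")


if __name__ == "__main__":
    main()
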