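import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from crevar.filters import FilterPolicy
from crevar.pipeline import run_nomination, split_and_annotate
from crevar.simulate import SimulationConfig, simulate_atlas, simulate_cohort
from crevar.variants import GenotypeCall, VariantRecord


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic cohort, atlas, layout (seeded)."""
    cfg = SimulationConfig(seed=1)
    layout, atlas = simulate_atlas(cfg)
    cohort = simulate_cohort(cfg, atlas, layout)
    return cfg, layout, atlas, cohort


@pytest.fixture(scope="session")
def nomination_default(sim_default):
    cfg, layout, atlas, cohort = sim_default
    result = run_nomination(cohort.pedigrees, cohort.raws, cohort.annotations,
                            atlas, layout)
    records = split_and_annotate(cohort.raws, cohort.annotations)
    return cohort, result, records, atlas


def make_call(sample, gt, gq=99):
    depth = {"hom_ref": (30, 0), "het": (10, 10), "hom_alt": (0, 30),
             "missing": (0, 0)}[gt]
    return GenotypeCall(sample, gt, gq=gq, ref_depth=depth[0], alt_depth=depth[1])


def make_variant(contig="chr1", pos=1000, ref="A", alt="G", gerp=4.0,
                 gnomad_af=None, topmed_af=None, filter_pass=True, calls=None):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                         filter_pass=filter_pass, gnomad_af=gnomad_af,
                         topmed_af=topmed_af, gerp=gerp,
                         calls={c.sample_id: c for c in (calls or [])})
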