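import numpy as np
import pytest

from shortpair import pipeline, simulate
from shortpair.io_formats import SeedAlignment
from shortpair.pipeline import FamilyModel, RunConfig
from shortpair.profile_hmm import build_from_msa, viterbi_score


@pytest.fixture(scope="session", autouse=True)
def _warm_aligner():
    """Compile the numba Viterbi kernel once before any timed test."""
    msa = SeedAlignment("warm", [("a", "ACDEF"), ("b", "ACDEF")], 5)
    viterbi_score(build_from_msa(msa), "ACDEF")


@pytest.fixture()
def tiny_msa():
    return SeedAlignment(
        "F1",
        [("s1", "ACDEFGHIK"), ("s2", "ACDEFGHIK"), ("s3", "ACDEFGHIK")],
        9,
    )


@pytest.fixture()
def tiny_hmm(tiny_msa):
    return build_from_msa(tiny_msa)


def build_models(ds):
    return {fid: FamilyModel(build_from_msa(msa), msa)
            for fid, msa in ds.families.items()}


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard 1000-pair study condition: five families, held-out
    member genes at 10% divergence, 76-bp reads, 0.5% sequencing error."""
    sc = simulate.SimScenario(n_pairs=1000, rng_seed=42)
    ds = simulate.simulate_dataset(sc)
    return ds, build_models(ds)


@pytest.fixture(scope="session")
def standard_run(standard_dataset):
    ds, models = standard_dataset
    cfg = RunConfig(seed=42)
    results, summary = pipeline.run_short_pair(ds.pairs, models, cfg)
    return ds, models, cfg, results, summary


@pytest.fixture(scope="session")
def rescue_scenario():
    """500 pairs where 30% of second mates carry 40% extra divergence:
    the regime where one end anchors the pair and the other needs the
    maximum-sensitivity rescan."""
    sc = simulate.SimScenario(n_pairs=500, diverged_mate_fraction=0.3,
                              diverged_mate_divergence=0.4, rng_seed=7)
    ds = simulate.simulate_dataset(sc)
    models = build_models(ds)
    cfg = RunConfig(seed=7)
    hits1 = pipeline.step1_scan(ds.pairs, models, cfg)
    hits2 = pipeline.step2_rescue(ds.pairs, hits1, models, cfg)
    return ds, models, cfg, hits1, hits2
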