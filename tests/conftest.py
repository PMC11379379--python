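import numpy as np
import pytest

import emsmap as em


@pytest.fixture(scope="session")
def toy_genome():
    return em.make_genome(length=200_000, n_chroms=2, gc_frac=0.36, seed=11)


@pytest.fixture(scope="session")
def toy_tracks(toy_genome):
    return em.make_tracks(toy_genome, n_tracks=4, corr_length=1_000, seed=12)


@pytest.fixture(scope="session")
def toy_truth(toy_genome, toy_tracks):
    # elevated base rate so the 200-kb toy genome carries enough events
    return em.make_truth(toy_genome, toy_tracks, base_rate=2e-5, seed=13)


@pytest.fixture(scope="session")
def toy_genes(toy_genome):
    return em.make_genes(toy_genome, seed=14)


@pytest.fixture(scope="session")
def toy_cohort(toy_truth):
    return em.simulate_cohort(toy_truth, 200, seed=15, batch_label="train")


@pytest.fixture(scope="session")
def toy_pipeline(toy_genome, toy_truth, toy_cohort):
    """P0 table, baseline track and feature matrix for the toy cohort."""
    table = em.compute_p0(toy_genome, toy_cohort)
    baseline = em.p0_track(toy_genome, table)
    smoothed = [em.smooth_track(t, 100) for t in toy_truth.tracks]
    matrix = em.build_features(toy_genome, smoothed, baseline, toy_cohort)
    return table, baseline, matrix
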