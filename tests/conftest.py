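"""Shared fixtures: small hand-built datasets and cached simulations."""

import numpy as np
import pytest

import fusemap as fm


@pytest.fixture
def toy_map():
    return fm.MarkerMap.from_arrays(
        ["m1", "m2", "m3"],
        ["1", "1", "2"],
        [100, 5000, 250],
        allele_a=["A", "C", "G"],
        allele_b=["G", "T", "A"],
    )


@pytest.fixture
def toy_genotypes(toy_map):
    calls = np.array([[0, 1, 2], [1, -1, 0]], dtype=np.int8)
    return fm.GenotypeMatrix(["s1", "s2"], toy_map, calls)


def small_sim(seed=0, **overrides):
    """A fast, small simulation for unit tests (not the default conditions)."""
    kw = dict(
        n_samples=60,
        ne=60,
        n_generations=80,
        fusions=[
            fm.FusionSpec("2", 8_000_000, "1", 20_000_000, fusion_time=80)
        ],
        decoy_chroms={"3": 10_000_000},
        n_markers=500,
        seed=seed,
    )
    kw.update(overrides)
    cfg = fm.SimConfig(**kw)
    return fm.simulate_fused_population(cfg)


@pytest.fixture(scope="session")
def small_sim_result():
    return small_sim(seed=7)
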