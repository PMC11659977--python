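"""Shared fixtures: small random genomes and session-scoped simulations.

All randomness is seeded; simulation scales are chosen so the whole suite
stays well inside a single-CPU budget while keeping per-bin counts large
enough for the stochastic assertions.
"""

from __future__ import annotations

import numpy as np
import pytest

import cfgc


def random_genome(seed: int, length: int = 100_000, n_chroms: int = 1) -> cfgc.GenomeSequence:
    rng = np.random.default_rng(seed)
    return cfgc.GenomeSequence(
        {
            f"chr{i + 1}": "".join(
                rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.25, 0.25])
            )
            for i in range(n_chroms)
        }
    )


@pytest.fixture(scope="session")
def genome_100kb() -> cfgc.GenomeSequence:
    return random_genome(11, length=100_000)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete simulated dataset on disk (BAM/FASTA/BED/truth)."""
    out = tmp_path_factory.mktemp("small_sim")
    config = cfgc.SimulationConfig(
        n_chroms=1,
        chrom_length=300_000,
        n_sites=30,
        min_spacing=1200,
        n_fragments=3000,
        seed=42,
    )
    paths = cfgc.simulate_dataset(config, out)
    return {"config": config, "paths": paths}


def run_pipeline(beta: float, seed: int, n_fragments: int = 200_000) -> dict:
    """Full in-memory estimation/correction/signal pipeline at study scale.

    High-GC sites with a 50% coverage dip, log-linear GC acceptance bias of
    the requested sign, bias model estimated from sampled regions excluding
    the sites, fragments weighted through the model, composite extracted at
    the sites.
    """
    config = cfgc.SimulationConfig(
        seed=seed, beta=beta, site_min_gc=0.52, n_fragments=n_fragments
    )
    genome = cfgc.make_genome(config)
    sites = cfgc.make_sites(genome, config)
    truth = cfgc.draw_fragments(genome, sites, config)
    lengths = cfgc.FragmentLengthRange(config.length_min, config.length_max)
    binning = cfgc.GCBinning(26)
    regions = cfgc.sample_regions(
        genome, n_regions=400, region_length=3000, seed=seed + 1000, exclude=sites
    )
    expected = cfgc.expected_distribution(genome, regions, lengths, binning)
    fragments = [
        cfgc.FragmentRecord(r.chrom, int(r.start), int(r.end), gc=r.gc)
        for r in truth.itertuples(index=False)
    ]
    observed = cfgc.observed_distribution(fragments, regions, lengths, binning)
    model = cfgc.compute_weights(expected, observed, min_count=20)
    w = model.lookup(
        np.array([f.length for f in fragments]),
        np.array([f.gc for f in fragments]),
    )
    for frag, wi in zip(fragments, w):
        frag.weight = float(wi)
    sig = cfgc.normalize_composite(
        cfgc.composite_signal(fragments, sites, genome.chrom_lengths, window=1000)
    )
    return {
        "config": config,
        "genome": genome,
        "sites": sites,
        "truth": truth,
        "fragments": fragments,
        "expected": expected,
        "observed": observed,
        "model": model,
        "signal": sig,
    }


@pytest.fixture(scope="session")
def run_low_gc_bias():
    """Study-scale pipeline with low-GC enrichment (beta = -2)."""
    return run_pipeline(beta=-2.0, seed=3)


@pytest.fixture(scope="session")
def run_high_gc_bias():
    """Study-scale pipeline with high-GC enrichment (beta = +2)."""
    return run_pipeline(beta=2.0, seed=4)
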