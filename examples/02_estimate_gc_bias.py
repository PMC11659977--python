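"""Estimate a sample's (fragment length, GC) correction-weight grid.

Compares the expected fragment distribution (all possible fragments in
regions sampled along the reference) with the observed distribution of the
sample's fragments in the same regions, and prints how well the recovered
bias matches the one injected by the simulator.

Run 01_simulate_dataset.py first.
"""

from pathlib import Path

import cfgc

sim = Path("example_output/sim")
genome = cfgc.GenomeSequence.from_fasta(sim / "genome.fa")
sites = cfgc.read_bed(sim / "sites.bed")

lengths = cfgc.FragmentLengthRange(90, 260)
binning = cfgc.GCBinning(26)
regions = cfgc.sample_regions(
    genome, n_regions=100, region_length=3000, seed=5, exclude=sites
)
expected = cfgc.expected_distribution(genome, regions, lengths, binning)
stream = cfgc.iterate_fragments(
    sim / "fragments.bam", genome, min_mapq=0, min_length=90, max_length=260
)
observed = cfgc.observed_distribution(stream, regions, lengths, binning)
model = cfgc.compute_weights(expected, observed, min_count=10)
model.to_files(Path("example_output") / "sample")

print(f"observed fragments in sampled regions: {int(observed.total)}")
print(f"rescale factor (coverage conservation): {model.rescale_factor:.4f}")
print(f"log-weight slope vs GC: {cfgc.bias_slope(model):.2f} "
      "(the simulator injected beta=+2, so approximately -2 is correct)")
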