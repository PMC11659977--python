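"""Expected/observed fragment distributions and correction-weight derivation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cfgc
from cfgc.errors import ConfigError, DegenerateDistributionError, GridMismatchError

from conftest import random_genome


def brute_force_expected(genome, regions, lengths, binning, max_n_fraction=0.1):
    """Independent oracle: enumerate every substring and count directly."""
    counts = np.zeros((lengths.n_lengths, binning.n_bins), dtype=np.int64)
    for region in regions.regions:
        seq = genome.fetch(region.chrom, region.start, region.end)
        for f in range(lengths.f_min, lengths.f_max + 1):
            for s in range(0, len(seq) - f + 1):
                sub = seq[s : s + f]
                n = sub.count("N")
                if n > max_n_fraction * f:
                    continue
                non_n = f - n
                if non_n == 0:
                    continue
                gc = (sub.count("G") + sub.count("C")) / non_n
                b = min(int(gc * binning.n_bins), binning.n_bins - 1)
                counts[f - lengths.f_min, b] += 1
    return counts


class TestGCBinning:
    def test_mapping_is_total_and_monotone(self):
        binning = cfgc.GCBinning(101)
        gcs = np.linspace(0, 1, 1001)
        bins = binning.bin_of(gcs)
        assert bins.min() == 0 and bins.max() == 100
        assert (np.diff(bins) >= 0).all()
        assert binning.bin_of(1.0) == 100


class TestSampleRegions:
    def test_deterministic_and_in_bounds(self):
        genome = random_genome(1, length=10_000)
        a = cfgc.sample_regions(genome, n_regions=5, region_length=1000, seed=9)
        b = cfgc.sample_regions(genome, n_regions=5, region_length=1000, seed=9)
        assert a.regions == b.regions
        for r in a.regions:
            assert 0 <= r.start and r.end <= 10_000 and len(r) == 1000

    def test_whole_chromosome_when_region_length_matches(self):
        genome = random_genome(2, length=2000)
        got = cfgc.sample_regions(genome, n_regions=1, region_length=2000, seed=0)
        assert got.regions == [cfgc.Region("chr1", 0, 2000)]

    def test_chrom_weighting_follows_length(self):
        """Two chroms 9000/1000: chr1 fraction within 3 binomial SE of 0.9."""
        rng = np.random.default_rng(7)
        genome = cfgc.GenomeSequence(
            {
                "chr1": "".join(rng.choice(list("ACGT"), size=9000)),
                "chr2": "".join(rng.choice(list("ACGT"), size=1000)),
            }
        )
        got = cfgc.sample_regions(
            genome, n_regions=1000, region_length=500, seed=13, allow_overlap=True
        )
        frac = sum(r.chrom == "chr1" for r in got.regions) / 1000
        se = math.sqrt(0.9 * 0.1 / 1000)
        assert abs(frac - 0.9) <= 3 * se

    def test_regions_disjoint_by_default(self):
        genome = random_genome(6, length=30_000)
        got = cfgc.sample_regions(genome, n_regions=15, region_length=1000, seed=2)
        ordered = sorted(got.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start

    def test_infeasible_genome_errors(self):
        genome = cfgc.GenomeSequence({"c": "ACGT" * 10})
        with pytest.raises(cfgc.CfgcError):
            cfgc.sample_regions(genome, n_regions=1, region_length=100)

    def test_exclusion_blacklist_respected(self):
        genome = random_genome(3, length=60_000)
        banned = [cfgc.Region("chr1", 0, 15_000)]
        got = cfgc.sample_regions(
            genome, n_regions=20, region_length=1000, seed=5, exclude=banned
        )
        assert all(r.start >= 15_000 for r in got.regions)


class TestExpectedDistribution:
    def test_single_length_hand_example(self):
        """ACGTACGTAC, f=4: seven substrings, all GC 0.5 -> bin 2 of 4."""
        genome = cfgc.GenomeSequence({"c": "ACGTACGTAC"})
        regions = cfgc.regions_as_sampled([cfgc.Region("c", 0, 10)])
        dist = cfgc.expected_distribution(
            genome, regions, cfgc.FragmentLengthRange(4, 4), cfgc.GCBinning(4)
        )
        assert dist.total == 7
        assert dist.counts[0, 2] == 7
        assert (np.delete(dist.counts, 2, axis=1) == 0).all()

    def test_region_shorter_than_f_min_is_degenerate(self):
        genome = cfgc.GenomeSequence({"c": "ACGTACGTAC"})
        regions = cfgc.regions_as_sampled([cfgc.Region("c", 0, 5)])
        dist = cfgc.expected_distribution(
            genome, regions, cfgc.FragmentLengthRange(8, 9), cfgc.GCBinning(4)
        )
        assert dist.total == 0 and dist.degenerate

    def test_matches_brute_force_on_random_genome(self):
        """Mandatory oracle: exhaustive substring enumeration, exact match."""
        genome = random_genome(17, length=2000)
        regions = cfgc.regions_as_sampled(
            [cfgc.Region("chr1", 0, 1200), cfgc.Region("chr1", 900, 2000)]
        )
        lengths = cfgc.FragmentLengthRange(50, 150)
        binning = cfgc.GCBinning(25)
        dist = cfgc.expected_distribution(genome, regions, lengths, binning)
        oracle = brute_force_expected(genome, regions, lengths, binning)
        assert (dist.counts == oracle).all()

    def test_n_masked_fragments_excluded(self):
        genome = cfgc.GenomeSequence({"c": "ACGT" * 10 + "N" * 40 + "ACGT" * 10})
        regions = cfgc.regions_as_sampled([cfgc.Region("c", 0, 120)])
        lengths = cfgc.FragmentLengthRange(20, 20)
        dist = cfgc.expected_distribution(genome, regions, lengths, cfgc.GCBinning(10))
        oracle = brute_force_expected(genome, regions, lengths, cfgc.GCBinning(10))
        assert (dist.counts == oracle).all()
        assert dist.total < 101  # the N block removed candidates


class TestObservedDistribution:
    def _setup(self):
        genome = random_genome(23, length=5000)
        regions = cfgc.regions_as_sampled([cfgc.Region("chr1", 1000, 2000)])
        lengths = cfgc.FragmentLengthRange(50, 200)
        return genome, regions, lengths, cfgc.GCBinning(20)

    def test_midpoint_inside_counts_once(self):
        genome, regions, lengths, binning = self._setup()
        frag = cfgc.FragmentRecord("chr1", 1400, 1500, gc=0.43)
        dist = cfgc.observed_distribution([frag], regions, lengths, binning)
        assert dist.total == 1
        assert dist.counts[100 - 50, binning.bin_of(0.43)] == 1

    def test_midpoint_one_bp_left_of_region_is_out(self):
        genome, regions, lengths, binning = self._setup()
        # midpoint = (start+end)//2 = 999 < region start 1000
        frag = cfgc.FragmentRecord("chr1", 949, 1049, gc=0.5)
        with pytest.raises(DegenerateDistributionError):
            cfgc.observed_distribution([frag], regions, lengths, binning)

    def test_overlapping_regions_count_once(self):
        genome, _, lengths, binning = self._setup()
        regions = cfgc.regions_as_sampled(
            [cfgc.Region("chr1", 1000, 2000), cfgc.Region("chr1", 1200, 2200)]
        )
        frag = cfgc.FragmentRecord("chr1", 1400, 1500, gc=0.5)
        dist = cfgc.observed_distribution([frag], regions, lengths, binning)
        assert dist.total == 1

    def test_unbiased_simulation_matches_expected_within_3se(self):
        """beta=0, densest possible sampling (the whole chromosome as the
        sampled region): per-bin GC densities match the enumeration once the
        expected grid is reweighted to the observed length law."""
        config = cfgc.SimulationConfig(
            n_chroms=1, chrom_length=600_000, n_sites=0, n_fragments=60_000, seed=21
        )
        genome = cfgc.make_genome(config)
        truth = cfgc.draw_fragments(genome, [], config)
        lengths = cfgc.FragmentLengthRange(config.length_min, config.length_max)
        binning = cfgc.GCBinning(26)
        regions = cfgc.regions_as_sampled([cfgc.Region("chr1", 0, 600_000)])
        expected = cfgc.expected_distribution(genome, regions, lengths, binning)
        frags = [
            cfgc.FragmentRecord(r.chrom, int(r.start), int(r.end), gc=r.gc)
            for r in truth.itertuples(index=False)
        ]
        observed = cfgc.observed_distribution(frags, regions, lengths, binning)
        length_totals = observed.counts.sum(axis=1).astype(float)
        row_densities = expected.counts / expected.counts.sum(axis=1, keepdims=True).clip(min=1)
        exp_marginal = (row_densities * length_totals[:, None]).sum(axis=0) / length_totals.sum()
        obs_marginal = observed.gc_marginal_density()
        se = np.sqrt(exp_marginal * (1 - exp_marginal) / observed.total)
        dev = np.abs(obs_marginal - exp_marginal)
        assert (dev <= np.maximum(3 * se, 1e-4)).all()


class TestComputeWeights:
    def _grids(self, E, O, n_bins):
        lengths = cfgc.FragmentLengthRange(100, 100)
        binning = cfgc.GCBinning(n_bins)
        e = cfgc.FragmentDistribution(np.array([E]), lengths, binning, "expected")
        o = cfgc.FragmentDistribution(np.array([O]), lengths, binning, "observed")
        return e, o

    def test_identity_yields_unit_weights(self):
        e, o = self._grids([5, 9, 3, 1], [5, 9, 3, 1], 4)
        model = cfgc.compute_weights(e, o, min_count=1)
        assert np.allclose(model.weights, 1.0, atol=1e-12)
        assert model.rescale_factor == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_two_cell_example(self):
        """E = {2, 2}, O = {3, 1}: pre-rescale weights {2/3, 2}, rescale 1."""
        e, o = self._grids([2, 2], [3, 1], 2)
        model = cfgc.compute_weights(e, o, min_count=1, clip=(0.01, 100))
        assert model.pre_rescale[0, 0] == pytest.approx(2 / 3)
        assert model.pre_rescale[0, 1] == pytest.approx(2.0)
        assert model.rescale_factor == pytest.approx(1.0)

    @pytest.mark.parametrize("min_count", [1, 3, 50])
    @pytest.mark.parametrize("clip", [(0.1, 10.0), (0.5, 2.0), (0.9, 1.1)])
    def test_conservation_for_any_clip_and_min_count(self, min_count, clip):
        rng = np.random.default_rng(31)
        E = rng.integers(0, 50, size=(5, 10))
        O = rng.integers(0, 50, size=(5, 10))
        O[0, 0] = max(O[0, 0], 1)
        lengths = cfgc.FragmentLengthRange(100, 104)
        binning = cfgc.GCBinning(10)
        e = cfgc.FragmentDistribution(E, lengths, binning, "expected")
        o = cfgc.FragmentDistribution(O, lengths, binning, "observed")
        model = cfgc.compute_weights(e, o, min_count=min_count, clip=clip)
        assert (O * model.weights).sum() == pytest.approx(O.sum(), rel=1e-9)

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 200), st.integers(0, 200)),
            min_size=4,
            max_size=12,
        ),
        min_count=st.integers(0, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, counts, min_count):
        E = np.array([[c[0] for c in counts]])
        O = np.array([[c[1] for c in counts]])
        if E.sum() == 0 or O.sum() == 0:
            return
        lengths = cfgc.FragmentLengthRange(100, 100)
        binning = cfgc.GCBinning(len(counts))
        e = cfgc.FragmentDistribution(E, lengths, binning, "expected")
        o = cfgc.FragmentDistribution(O, lengths, binning, "observed")
        model = cfgc.compute_weights(e, o, min_count=min_count)
        assert (O * model.weights).sum() == pytest.approx(O.sum(), rel=1e-9)

    def test_impossible_cells_get_lower_clip(self):
        e, o = self._grids([0, 10], [5, 5], 2)
        model = cfgc.compute_weights(e, o, min_count=1, clip=(0.1, 10))
        assert model.pre_rescale[0, 0] == pytest.approx(0.1)

    def test_neutral_fallback_keeps_sparse_cells_at_rescale(self):
        e, o = self._grids([10, 10, 10], [40, 2, 30], 3)
        model = cfgc.compute_weights(e, o, min_count=5, fallback="neutral")
        assert model.weights[0, 1] == pytest.approx(model.rescale_factor)

    def test_marginal_fallback_pools_over_lengths(self):
        lengths = cfgc.FragmentLengthRange(100, 101)
        binning = cfgc.GCBinning(2)
        E = np.array([[10, 10], [10, 10]])
        O = np.array([[30, 10], [6, 1]])  # second length sparse
        e = cfgc.FragmentDistribution(E, lengths, binning, "expected")
        o = cfgc.FragmentDistribution(O, lengths, binning, "observed")
        model = cfgc.compute_weights(e, o, min_count=5)
        # the sparse cell of bin 0 inherits the pooled ratio of that bin's
        # sparse pool (E 10 vs O 6 of grid totals 40/47); bin 1's sparse
        # pool is itself below min_count, so it stays neutral
        assert model.pre_rescale[1, 0] == pytest.approx((10 / 40) / (6 / 47))
        assert model.pre_rescale[1, 1] == pytest.approx(1.0)

    def test_monotone_bias_gives_monotone_weights(self, run_high_gc_bias):
        """Increasing acceptance bias in GC -> non-increasing weights along
        GC: strictly at the length-pooled level (where counts resolve the
        trend), and within each length up to Poisson counting noise."""
        model = run_high_gc_bias["model"]
        O = model.observed_counts.astype(float)
        E = model.expected_counts.astype(float)
        # pooled: well-supported bins must decrease monotonically
        Om, Em = O.sum(axis=0), E.sum(axis=0)
        dense = Om >= 500
        pooled = np.log((Em[dense] / Em.sum()) / (Om[dense] / Om.sum()))
        assert (np.diff(pooled) <= 0.02).all()
        # per length: any apparent increase must be within 3 SE of the
        # log-ratio's Poisson noise
        violations = total = 0
        for fi in range(model.pre_rescale.shape[0]):
            ok = O[fi] >= model.min_count
            if ok.sum() < 2:
                continue
            w = model.pre_rescale[fi, ok]
            noise = 3 * np.sqrt(1 / O[fi, ok][:-1] + 1 / O[fi, ok][1:])
            diffs = np.diff(np.log(w))
            total += diffs.size
            violations += (diffs > noise).sum()
        assert total > 100
        assert violations / total < 0.01

    def test_mismatched_grids_rejected(self):
        e, _ = self._grids([1, 2], [1, 2], 2)
        _, o = self._grids([1, 2, 3], [1, 2, 3], 3)
        with pytest.raises(GridMismatchError):
            cfgc.compute_weights(e, o)

    def test_bad_clip_rejected(self):
        e, o = self._grids([1, 2], [1, 2], 2)
        with pytest.raises(ConfigError):
            cfgc.compute_weights(e, o, clip=(2.0, 10.0))


class TestWeightLookup:
    def _identity_model(self):
        e = cfgc.FragmentDistribution(
            np.full((3, 4), 7), cfgc.FragmentLengthRange(100, 102), cfgc.GCBinning(4),
            "expected",
        )
        o = cfgc.FragmentDistribution(
            np.full((3, 4), 7), cfgc.FragmentLengthRange(100, 102), cfgc.GCBinning(4),
            "observed",
        )
        return cfgc.compute_weights(e, o, min_count=1)

    def test_identity_model_returns_one(self):
        model = self._identity_model()
        assert cfgc.weight_lookup(model, 101, 0.37) == pytest.approx(1.0)

    def test_lengths_clamp_to_modeled_range(self, run_low_gc_bias):
        model = run_low_gc_bias["model"]
        f_max = model.lengths.f_max
        assert cfgc.weight_lookup(model, f_max + 50, 0.4) == cfgc.weight_lookup(
            model, f_max, 0.4
        )
        assert cfgc.weight_lookup(model, 1, 0.4) == cfgc.weight_lookup(
            model, model.lengths.f_min, 0.4
        )

    def test_matches_direct_grid_indexing(self, run_low_gc_bias):
        model = run_low_gc_bias["model"]
        rng = np.random.default_rng(3)
        for _ in range(100):
            f = int(rng.integers(model.lengths.f_min, model.lengths.f_max + 1))
            gc = float(rng.random())
            direct = model.weights[f - model.lengths.f_min, int(model.binning.bin_of(gc))]
            assert cfgc.weight_lookup(model, f, gc) == direct

    def test_nan_gc_returns_neutral(self, run_low_gc_bias):
        model = run_low_gc_bias["model"]
        assert cfgc.weight_lookup(model, 150, float("nan")) == pytest.approx(
            model.rescale_factor
        )


class TestSerialization:
    def test_round_trip(self, tmp_path, run_low_gc_bias):
        model = run_low_gc_bias["model"]
        prefix = tmp_path / "sample1"
        model.to_files(prefix)
        back = cfgc.CorrectionModel.from_files(prefix)
        assert np.allclose(back.weights, model.weights)
        assert (back.expected_counts == model.expected_counts).all()
        assert (back.observed_counts == model.observed_counts).all()
        assert back.rescale_factor == pytest.approx(model.rescale_factor)
        assert back.lengths == model.lengths and back.binning == model.binning


class TestMeanWeightConservation:
    def test_mean_weight_over_counted_fragments_is_one(self, run_low_gc_bias):
        """Fragments the model was built on have mean weight 1 (rescale step)."""
        model = run_low_gc_bias["model"]
        O = model.observed_counts
        mean_w = (O * model.weights).sum() / O.sum()
        assert mean_w == pytest.approx(1.0, abs=1e-9)
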