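import numpy as np
import pytest

from mosaikit import synthdata
from mosaikit.sequtil import decode


class TestConfig:
    def test_list_lengths_get_names(self):
        cfg = synthdata.SimulationConfig(chrom_lengths=[100, 200])
        assert list(cfg.chrom_lengths) == ["chr01", "chr02"]

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            synthdata.SimulationConfig(chrom_lengths=[100], div_p=1.5)

    def test_zero_length_chromosome(self):
        with pytest.raises(ValueError):
            synthdata.SimulationConfig(chrom_lengths=[0])

    def test_event_outside_chromosome(self):
        with pytest.raises(ValueError):
            synthdata.SimulationConfig(
                chrom_lengths=[1_000],
                event_specs=[synthdata.EventSpec("crossover", "chr01", start=2_000)],
            )


class TestParentSimulation:
    def test_zero_rates_identical_sequences(self):
        cfg = synthdata.SimulationConfig(
            chrom_lengths=[10_000], div_p=0, div_s=0, het_p=0, het_s=0, seed=0
        )
        anc, parents = synthdata.simulate_parent_haplotypes(cfg)
        for hap in ("P1", "P2", "S1", "S2"):
            assert np.array_equal(parents[hap]["chr01"], anc["chr01"])

    def test_divergence_within_binomial_error(self):
        L, d = 1_000_000, 0.027
        cfg = synthdata.SimulationConfig(
            chrom_lengths=[L], div_p=d, div_s=0.0, het_p=0, het_s=0, seed=1
        )
        anc, parents = synthdata.simulate_parent_haplotypes(cfg)
        frac = np.mean(parents["P1"]["chr01"] != anc["chr01"])
        assert abs(frac - d) < 3 * np.sqrt(d * (1 - d) / L)

    def test_seed_determinism_byte_identical(self, tmp_path):
        from mosaikit import io

        cfg = synthdata.SimulationConfig(chrom_lengths=[20_000], seed=42)
        out = []
        for run in range(2):
            anc, parents = synthdata.simulate_parent_haplotypes(cfg)
            path = tmp_path / f"run{run}.fasta"
            io.write_fasta(path, parents["P1"])
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestHybridEvents:
    def test_no_events_hybrid_equals_founders(self):
        cfg = synthdata.SimulationConfig(chrom_lengths=[50_000], seed=2)
        _, parents = synthdata.simulate_parent_haplotypes(cfg)
        hybrid, truth = synthdata.apply_hybrid_events(parents, cfg)
        assert np.array_equal(hybrid["A"]["chr01"], parents["P1"]["chr01"])
        assert np.array_equal(hybrid["B"]["chr01"], parents["S1"]["chr01"])
        assert truth.parent_intervals[("A", "chr01")] == [(0, 50_000, "P")]

    def test_terminal_loh_suffix_identical(self):
        cfg = synthdata.SimulationConfig(
            chrom_lengths=[200_000],
            seed=3,
            event_specs=[
                synthdata.EventSpec("loh_terminal", "chr01", start=100_000, end=200_000)
            ],
        )
        _, parents = synthdata.simulate_parent_haplotypes(cfg)
        hybrid, truth = synthdata.apply_hybrid_events(parents, cfg)
        a, b = hybrid["A"]["chr01"], hybrid["B"]["chr01"]
        assert np.array_equal(a[100_000:], b[100_000:])
        assert not np.array_equal(a[:100_000], b[:100_000])
        assert truth.loh_tracts == [
            {"chrom": "chr01", "start": 100_000, "end": 200_000, "recipient": "A"}
        ]

    def test_reciprocal_crossover_swaps_truth_labels(self, small_sim):
        truth = small_sim["truth"]
        assert truth.parent_intervals[("A", "chr01")] == [
            (0, 150_000, "P"),
            (150_000, 300_000, "S"),
        ]
        assert truth.parent_intervals[("B", "chr01")] == [
            (0, 150_000, "S"),
            (150_000, 300_000, "P"),
        ]

    def test_truth_intervals_tile_chromosomes(self, small_sim):
        small_sim["truth"].validate(small_sim["config"].chrom_lengths)

    def test_conflicting_loh_rejected(self):
        cfg_kwargs = dict(
            chrom_lengths=[100_000],
            event_specs=[
                synthdata.EventSpec("loh_interstitial", "chr01", start=10_000, end=30_000),
                synthdata.EventSpec("loh_interstitial", "chr01", start=20_000, end=40_000),
            ],
        )
        cfg = synthdata.SimulationConfig(**cfg_kwargs)
        _, parents = synthdata.simulate_parent_haplotypes(cfg)
        with pytest.raises(ValueError):
            synthdata.apply_hybrid_events(parents, cfg)

    def test_loh_inside_tract_sequences_identical(self, small_sim):
        hybrid = small_sim["hybrid"]
        a, b = hybrid["A"]["chr02"], hybrid["B"]["chr02"]
        assert np.array_equal(a[50_000:90_000], b[50_000:90_000])


class TestVariantTable:
    def test_exact_counts_without_noise(self, small_sim):
        hybrid = small_sim["hybrid"]
        table = synthdata.emit_variant_table(hybrid)
        for chrom in ("chr01", "chr02"):
            want = int(np.sum(hybrid["A"][chrom] != hybrid["B"][chrom]))
            assert (table["chrom"] == chrom).sum() == want

    def test_no_variants_inside_planted_tract(self, small_sim):
        table = synthdata.emit_variant_table(small_sim["hybrid"])
        sub = table[(table["chrom"] == "chr02") & (table["pos"] >= 50_000) & (table["pos"] < 90_000)]
        assert len(sub) == 0

    def test_false_negative_rate_binomial(self, small_sim):
        hybrid = small_sim["hybrid"]
        n_true = sum(
            int(np.sum(hybrid["A"][c] != hybrid["B"][c])) for c in ("chr01", "chr02")
        )
        fn = 0.1
        table = synthdata.emit_variant_table(
            hybrid, false_negative_rate=fn, rng=np.random.default_rng(9)
        )
        want = n_true * (1 - fn)
        assert abs(len(table) - want) < 3 * np.sqrt(n_true * fn * (1 - fn))

    def test_false_positives_added(self, small_sim):
        hybrid = small_sim["hybrid"]
        base = len(synthdata.emit_variant_table(hybrid))
        noisy = synthdata.emit_variant_table(
            hybrid, false_positive_rate=0.001, rng=np.random.default_rng(10)
        )
        assert len(noisy) > base

    def test_bad_rate_rejected(self, small_sim):
        with pytest.raises(ValueError):
            synthdata.emit_variant_table(small_sim["hybrid"], false_negative_rate=1.5)


class TestHeterozygosityStructure:
    def test_background_het_matches_config(self):
        """Outside planted events, A-B mismatch density ~ div_p + div_s."""
        cfg = synthdata.SimulationConfig(chrom_lengths=[1_000_000], seed=6)
        _, parents = synthdata.simulate_parent_haplotypes(cfg)
        hybrid, _ = synthdata.apply_hybrid_events(parents, cfg)
        frac = np.mean(hybrid["A"]["chr01"] != hybrid["B"]["chr01"])
        # two independent substitution layers; coincident hits are O(pq)
        assert frac == pytest.approx(cfg.div_p + cfg.div_s, rel=0.05)

    def test_transcript_truth_upstream_atg_constructed(self, tx_dataset):
        """Extended-class genes carry a stop-free in-frame upstream ATG."""
        from mosaikit import txrules

        genome = tx_dataset["genome"]
        models = {t.id: t for t in tx_dataset["transcripts"]}
        n_checked = 0
        for gene in tx_dataset["truth"].genes:
            if gene["class"] != "extended":
                continue
            t = models[gene["primary"]]
            cands = txrules.upstream_start_candidates(t, genome)
            assert gene["true_start_t"] in cands
            n_checked += 1
        assert n_checked > 0
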