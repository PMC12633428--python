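import numpy as np
import pandas as pd
import pytest

from mosaikit import ploidy


def const_windows(chrom, depth, n=10, width=20_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "mean_depth": float(depth),
            "short": False,
        }
    )


class TestWindowedCoverage:
    def test_constant_depth(self):
        win = ploidy.windowed_coverage(np.full(100_000, 50.0), 20_000)
        assert (win["mean_depth"] == 50.0).all()
        assert not win["short"].any()

    def test_zero_depth(self):
        win = ploidy.windowed_coverage(np.zeros(40_000), 20_000)
        assert (win["mean_depth"] == 0.0).all()

    def test_step_at_tile_boundary(self):
        depth = np.concatenate([np.full(20_000, 50.0), np.full(20_000, 100.0)])
        win = ploidy.windowed_coverage(depth, 20_000)
        assert win["mean_depth"].tolist() == [50.0, 100.0]

    def test_short_last_tile_flagged(self):
        win = ploidy.windowed_coverage(np.ones(50_000), 20_000)
        assert win["short"].tolist() == [False, False, True]

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            ploidy.windowed_coverage(np.ones(10), 0)


class TestCopyNumber:
    def genome(self, medians, mode="phased"):
        windows = pd.concat(
            [const_windows(c, d) for c, d in medians.items()], ignore_index=True
        )
        return ploidy.call_chromosome_copy_number(windows, mode=mode)

    def test_phased_duplicated_haplotype(self):
        # a haplotype chromosome at ~2x the genome-wide per-haplotype depth
        medians = {f"c{i}": 272 for i in range(8)}
        medians["c8"] = 528
        calls = {c.chrom: c for c in self.genome(medians)}
        assert calls["c8"].copies == 2
        assert all(calls[f"c{i}"].copies == 1 for i in range(8))

    def test_phased_triplicated(self):
        medians = {f"c{i}": 53 for i in range(8)}
        medians["c8"] = 163
        calls = {c.chrom: c for c in self.genome(medians)}
        assert calls["c8"].copies == 3

    def test_collapsed_trisomy(self):
        medians = {f"c{i}": 54 for i in range(8)}
        medians["c8"] = 76
        calls = {c.chrom: c for c in self.genome(medians, mode="collapsed")}
        assert calls["c8"].copies == 3
        assert all(calls[f"c{i}"].copies == 2 for i in range(8))

    def test_scaling_invariance(self):
        medians = {f"c{i}": 50 for i in range(6)}
        medians["c6"] = 100
        base = {c.chrom: c.copies for c in self.genome(medians)}
        scaled = {c.chrom: c.copies for c in self.genome({k: v * 7.3 for k, v in medians.items()})}
        assert base == scaled

    def test_baseline_pruning_resists_aneuploid_inflation(self):
        # three of seven chromosomes duplicated must not drag the baseline up
        medians = {f"c{i}": 50 for i in range(4)}
        medians.update({f"d{i}": 100 for i in range(3)})
        calls = {c.chrom: c for c in self.genome(medians)}
        assert all(calls[f"c{i}"].copies == 1 for i in range(4))
        assert all(calls[f"d{i}"].copies == 2 for i in range(3))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            ploidy.call_chromosome_copy_number(const_windows("c", 50, n=4))

    def test_confidence_fraction(self):
        win = const_windows("c0", 50, n=10)
        win.loc[0, "mean_depth"] = 100.0  # one window implies a different integer
        windows = pd.concat([win] + [const_windows(f"c{i}", 50) for i in range(1, 6)], ignore_index=True)
        calls = {c.chrom: c for c in ploidy.call_chromosome_copy_number(windows)}
        assert calls["c0"].confidence == pytest.approx(0.9)


class TestRounding:
    @pytest.mark.parametrize("x,want", [(1.5, 2), (2.5, 3), (0.49, 0), (-1.5, -2), (1.49, 1)])
    def test_half_away_from_zero(self, x, want):
        assert ploidy.round_half_away(x) == want


class TestSegmentation:
    def test_flat_single_segment(self):
        win = const_windows("c", 50, n=40)
        segs = ploidy.segment_partial_aneuploidy(win, baseline=50.0)
        assert len(segs) == 1 and segs["copies"].iloc[0] == 1

    def test_single_step_recovered(self):
        rng = np.random.default_rng(0)
        n1, n2 = 105, 45
        vals = np.concatenate(
            [rng.poisson(50 * 20_000, n1) / 20_000, rng.poisson(100 * 20_000, n2) / 20_000]
        )
        win = const_windows("c", 0, n=n1 + n2)
        win["mean_depth"] = vals
        segs = ploidy.segment_partial_aneuploidy(win, baseline=50.0)
        assert len(segs) == 2
        assert segs["copies"].tolist() == [1, 2]
        assert segs["start"].iloc[1] == n1 * 20_000

    def test_two_steps_three_segments(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [
                rng.poisson(50 * 20_000, 40) / 20_000,
                rng.poisson(150 * 20_000, 30) / 20_000,
                rng.poisson(50 * 20_000, 40) / 20_000,
            ]
        )
        win = const_windows("c", 0, n=110)
        win["mean_depth"] = vals
        segs = ploidy.segment_partial_aneuploidy(win, baseline=50.0)
        assert segs["copies"].tolist() == [1, 3, 1]

    def test_best_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        values = rng.normal(50, 2, size=160)
        values[60:] += 25
        k, diff = ploidy._best_split(values, 5)
        gains = []
        for kk in range(5, len(values) - 4):
            l, r = values[:kk], values[kk:]
            gains.append((len(l) * len(r) / len(values)) * (l.mean() - r.mean()) ** 2)
        assert k == int(np.argmax(gains)) + 5
        assert diff == pytest.approx(abs(values[:k].mean() - values[k:].mean()))

    def test_small_effect_not_split(self):
        win = const_windows("c", 50, n=40)
        win.loc[20:, "mean_depth"] = 55.0  # 10% effect < default 25% threshold
        segs = ploidy.segment_partial_aneuploidy(win, baseline=50.0)
        assert len(segs) == 1


class TestSimulatedDepth:
    def test_duplicated_chromosome_doubles_depth(self, small_sim):
        from mosaikit import synthdata

        tracks = synthdata.emit_coverage_track(
            small_sim["truth"], small_sim["config"], mode="phased",
            rng=np.random.default_rng(0),
        )
        assert tracks["chr02_B"].mean() == pytest.approx(2 * tracks["chr01_B"].mean(), rel=0.02)

    def test_poisson_variance_at_zero_dispersion(self):
        from mosaikit import synthdata

        config = synthdata.SimulationConfig(chrom_lengths=[100_000], depth_mean=50, seed=0)
        truth = synthdata.TruthLog()
        truth.copy_numbers[("A", "chr01")] = [(0, 100_000, 1)]
        truth.copy_numbers[("B", "chr01")] = [(0, 100_000, 1)]
        tracks = synthdata.emit_coverage_track(truth, config, rng=config.rng())
        d = tracks["chr01_A"]
        assert d.var() == pytest.approx(d.mean(), rel=0.05)

    def test_overdispersed_variance_exceeds_mean(self):
        from mosaikit import synthdata

        config = synthdata.SimulationConfig(
            chrom_lengths=[100_000], depth_mean=50, depth_dispersion=0.05, seed=0
        )
        truth = synthdata.TruthLog()
        truth.copy_numbers[("A", "chr01")] = [(0, 100_000, 1)]
        truth.copy_numbers[("B", "chr01")] = [(0, 100_000, 1)]
        d = synthdata.emit_coverage_track(truth, config, rng=config.rng())["chr01_A"]
        want_var = 50 + 0.05 * 50**2
        assert d.var() == pytest.approx(want_var, rel=0.1)
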