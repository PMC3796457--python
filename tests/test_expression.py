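import numpy as np
import pytest
from scipy import stats

from kanseek.errors import ConfigError, ValidationError
from kanseek.expression import (
    ProbeTrack,
    RegulationCall,
    TimepointCall,
    call_regulation,
    calls_from_table,
    merge_timepoints,
    pool_replicates,
    read_probe_table,
    write_probe_table,
)
from kanseek.io_formats import RegulationTableRow


def track(ratios, gene_id="g1", timepoint=80):
    return ProbeTrack(gene_id, timepoint, tuple(range(0, 100 * len(ratios), 100)), tuple(ratios))


class TestProbeTrack:
    def test_sorts_by_position(self):
        t = ProbeTrack("g", 80, (300, 100, 200), (3.0, 1.0, 2.0))
        assert t.probe_positions == (100, 200, 300)
        assert t.log_ratios == (1.0, 2.0, 3.0)

    def test_rejects_duplicate_positions(self):
        with pytest.raises(ValidationError):
            ProbeTrack("g", 80, (100, 100), (1.0, 2.0))

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            track([float("inf"), 0.0])


class TestCallRegulation:
    def test_all_probes_down(self):
        call = call_regulation(track([-1.5] * 10))
        assert call.down and not call.up

    def test_half_down_fails_consistency(self):
        call = call_regulation(track([-1.5] * 5 + [0.0] * 5))
        assert not call.down

    def test_all_probes_up(self):
        call = call_regulation(track([1.5] * 10))
        assert call.up and not call.down

    def test_short_track_is_no_call_with_reason(self):
        call = call_regulation(track([-5.0, -5.0]), min_probes=4)
        assert not call.down and not call.up
        assert "min_probes" in call.reason

    def test_threshold_is_inclusive(self):
        assert call_regulation(track([-1.0] * 10), delta=1.0).down

    def test_fraction_boundary(self):
        assert call_regulation(track([-2.0] * 9 + [0.0]), min_fraction=0.9).down
        assert not call_regulation(track([-2.0] * 8 + [0.0] * 2), min_fraction=0.9).down

    def test_bad_params(self):
        for kwargs in ({"delta": 0}, {"min_fraction": 0}, {"min_fraction": 1.5}, {"min_probes": 0}):
            with pytest.raises(ConfigError):
                call_regulation(track([-2.0] * 5), **kwargs)

    def test_shrinking_signal_never_creates_calls(self):
        rng = np.random.default_rng(20240906)
        for _ in range(50):
            ratios = rng.normal(0, 2, size=10)
            full = call_regulation(track(list(ratios)))
            shrunk = call_regulation(track(list(ratios * rng.uniform(0.01, 0.99))))
            assert full.down or not shrunk.down
            assert full.up or not shrunk.up

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(20240907)
        ratios = list(rng.normal(-1.2, 0.5, size=12))
        base = call_regulation(track(ratios))
        order = list(range(12))
        rng.shuffle(order)
        shuffled = ProbeTrack("g1", 80, tuple(100 * i for i in order), tuple(ratios[i] for i in order))
        assert call_regulation(shuffled) == base


class TestPoolReplicates:
    def test_probe_wise_mean(self):
        pooled = pool_replicates([track([1.0, 3.0]), track([3.0, 5.0])])
        assert pooled.log_ratios == (2.0, 4.0)

    def test_rejects_mixed_keys(self):
        with pytest.raises(ValidationError):
            pool_replicates([track([1.0]), track([1.0], gene_id="g2")])


class TestMergeTimepoints:
    def test_down_80_only(self):
        (merged,) = merge_timepoints([TimepointCall("g", 80, True, False)])
        assert (merged.down_80, merged.down_160, merged.up_80, merged.up_160) == (True, False, False, False)

    def test_down_both(self):
        (merged,) = merge_timepoints(
            [TimepointCall("g", 80, True, False), TimepointCall("g", 160, True, False)]
        )
        assert (merged.down_80, merged.down_160) == (True, True)

    def test_duplicate_raises(self):
        with pytest.raises(ValidationError):
            merge_timepoints([TimepointCall("g", 80, True, False), TimepointCall("g", 80, False, False)])

    def test_counting_identity_on_random_call_sets(self):
        rng = np.random.default_rng(20240908)
        for _ in range(20):
            calls = []
            for i in range(100):
                for tp in (80, 160):
                    if rng.random() < 0.8:
                        calls.append(TimepointCall(f"g{i}", tp, bool(rng.random() < 0.4), False))
            merged = merge_timepoints(calls)
            either = sum(1 for c in merged if c.down_80 or c.down_160)
            both = sum(1 for c in merged if c.down_80 and c.down_160)
            only80 = sum(1 for c in merged if c.down_80 and not c.down_160)
            only160 = sum(1 for c in merged if c.down_160 and not c.down_80)
            assert either == both + only80 + only160

    def test_down_and_up_never_both(self):
        with pytest.raises(ValidationError):
            RegulationCall("g", down_80=True, up_80=True)


class TestCallsFromTable:
    def test_adapts_rows(self):
        rows = [RegulationTableRow("g2", True, False), RegulationTableRow("g1", False, True)]
        calls = calls_from_table(rows)
        assert [c.gene_id for c in calls] == ["g1", "g2"]
        assert calls[1].down_80 and not calls[1].down_160


class TestAnalyticRecovery:
    """Empirical call rates at n=1000 tracks match the Gaussian/binomial theory."""

    DELTA, FRACTION, K, SIGMA, SHIFT = 1.0, 0.9, 8, 0.3, 2.0

    def _rate(self, shift, seed):
        rng = np.random.default_rng(seed)
        n_called = 0
        for _ in range(1000):
            ratios = rng.normal(-shift, self.SIGMA, size=self.K)
            call = call_regulation(track(list(ratios)), delta=self.DELTA, min_fraction=self.FRACTION)
            n_called += call.down
        return n_called / 1000

    def _theory(self, shift):
        q = stats.norm.cdf((-self.DELTA + shift) / self.SIGMA)
        m = int(np.ceil(self.FRACTION * self.K))
        return float(stats.binom.sf(m - 1, self.K, q))

    def test_sensitivity_matches_theory(self):
        p = self._theory(self.SHIFT)
        rate = self._rate(self.SHIFT, seed=20240909)
        assert abs(rate - p) <= 4 * np.sqrt(p * (1 - p) / 1000) + 1e-3

    def test_null_false_call_rate_bounded(self):
        p_null = self._theory(0.0)
        rate = self._rate(0.0, seed=20240910)
        assert rate <= p_null + 4 * np.sqrt(max(p_null * (1 - p_null), 1e-9) / 1000) + 1e-3

    def test_sensitivity_approaches_one_as_noise_vanishes(self):
        rng = np.random.default_rng(20240911)
        for sigma, floor in ((0.3, 0.9), (0.1, 0.999), (0.01, 1.0)):
            called = sum(
                call_regulation(track(list(rng.normal(-2.0, sigma, size=8)))).down for _ in range(200)
            )
            assert called / 200 >= floor


class TestProbeTableIO:
    def test_round_trip(self, tmp_path):
        tracks = [track([-1.25, 0.5, 2.0], gene_id="gA", timepoint=80), track([0.0, 1.0, -1.0], gene_id="gB", timepoint=160)]
        p = tmp_path / "probes.tsv"
        write_probe_table(tracks, str(p))
        back = read_probe_table(str(p))
        assert back == sorted(tracks, key=lambda t: (t.gene_id, t.timepoint))

    def test_replicate_rows_averaged(self, tmp_path):
        p = tmp_path / "probes.tsv"
        p.write_text(
            "gene_id\ttimepoint\tposition\tlog_ratio\n"
            "g1\t80\t0\t-1.0\ng1\t80\t0\t-3.0\ng1\t80\t100\t0.0\n"
        )
        (t,) = read_probe_table(str(p))
        assert t.log_ratios == (-2.0, 0.0)
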