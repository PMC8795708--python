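import numpy as np
import pandas as pd
import pytest

from nirslat.blocks import (block_average_frame, epoch_and_average,
                            exclude_few_blocks, mean_window_response,
                            reject_blocks, summarize_behavior)
from nirslat.core import TimeSeriesBundle
from nirslat.design import LANDMARK, PICTURE_NAMING, make_block_design
from nirslat.simulate import simulate_behavior

FS = 17.0


def _hemo(n_s, n_ch=2, value=0.0):
    data = np.full((int(n_s * FS), n_ch, 2), float(value))
    return TimeSeriesBundle(data, FS, list(range(1, n_ch + 1)),
                            kind="hemoglobin")


@pytest.fixture(scope="module")
def design():
    return make_block_design(PICTURE_NAMING, n_blocks=4)


class TestRejectBlocks:
    def test_step_inside_a_block_rejects_it(self, design):
        hemo = _hemo(design.total_duration_s)
        i = int((design.blocks[1].onset_s + 5) * FS)
        hemo.data[i:i + 2, :, 0] += 0.2  # 0.2 mM*mm jump within 0.2 s
        kept, ledger = reject_blocks(hemo, design)
        assert [b.index for b in kept] == [0, 2, 3]
        assert ledger[0]["block"] == 1 and ledger[0]["rule"] == "signal"

    def test_low_accuracy_block_rejected(self):
        d = make_block_design(LANDMARK, n_blocks=2, rest_s=16.0, seed=0)
        hemo = _hemo(d.total_duration_s)
        rows = [{"block_index": b.index, "condition": b.condition,
                 "correct": False, "rt_ms": 500.0} for b in d.blocks[:1]
                for _ in range(10)]
        beh = pd.DataFrame(rows)
        kept, ledger = reject_blocks(hemo, d, beh)
        assert d.blocks[0].index not in [b.index for b in kept]
        assert ledger[0]["rule"] == "accuracy"

    def test_flat_accurate_blocks_kept(self, design):
        hemo = _hemo(design.total_duration_s)
        kept, ledger = reject_blocks(hemo, design)
        assert len(kept) == 4 and ledger == []

    def test_rejection_monotone_in_amplitude_threshold(self, design, rng):
        hemo = _hemo(design.total_duration_s)
        hemo.data += 0.02 * rng.standard_normal(hemo.data.shape)
        counts = [len(reject_blocks(hemo, design, amp_thresh=a)[0])
                  for a in (0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts)

    def test_unknown_behavior_blocks_rejected(self, design):
        hemo = _hemo(design.total_duration_s)
        beh = pd.DataFrame([{"block_index": 99, "correct": True}])
        with pytest.raises(ValueError, match="unknown blocks"):
            reject_blocks(hemo, design, beh)


class TestExcludeFewBlocks:
    @pytest.mark.parametrize("n,excluded", [(2, True), (3, False), (12, False)])
    def test_strict_minimum(self, n, excluded):
        assert exclude_few_blocks(n, min_blocks=3) is excluded


class TestEpochAndAverage:
    def test_epoch_grid_has_expected_sample_count(self, design):
        hemo = _hemo(design.total_duration_s)
        avg = epoch_and_average(hemo, list(design.blocks))
        ca = avg.conditions["LP"]
        # 44 s span at 17 Hz -> 748 samples, from -4 s
        assert ca.mean.shape[0] == 748
        assert ca.times[0] == pytest.approx(-4.0)

    def test_baseline_window_mean_is_zero(self, design, rng):
        hemo = _hemo(design.total_duration_s)
        hemo.data += rng.normal(size=hemo.data.shape)
        blocks = list(design.blocks)[:1]  # single block: average == block
        # align the baseline window with the stored epoch start so the
        # zero-mean property is visible in the output grid
        avg = epoch_and_average(hemo, blocks, baseline_window_s=(-4.0, 0.0))
        ca = avg.conditions["LP"]
        sel = (ca.times >= -4.0) & (ca.times < 0.0)
        assert np.abs(ca.mean[sel].mean(axis=0)).max() < 1e-9

    def test_pure_linear_ramp_removed(self, design):
        hemo = _hemo(design.total_duration_s)
        ramp = np.linspace(-3.0, 3.0, hemo.data.shape[0])
        hemo.data += ramp[:, None, None]
        avg = epoch_and_average(hemo, list(design.blocks))
        assert np.abs(avg.conditions["LP"].mean).max() < 1e-9

    def test_identical_blocks_average_to_single_block(self, design):
        hemo = _hemo(design.total_duration_s)
        # identical deterministic content around every onset
        for b in design.blocks:
            i = int(b.onset_s * FS)
            hemo.data[i:i + 100, :, 0] += np.linspace(0, 1, 100)[:, None] ** 2
        all_avg = epoch_and_average(hemo, list(design.blocks))
        one_avg = epoch_and_average(hemo, [design.blocks[0]])
        assert np.allclose(all_avg.conditions["LP"].mean,
                           one_avg.conditions["LP"].mean, atol=1e-9)

    def test_out_of_bounds_epochs_dropped_with_ledger(self, design):
        hemo = _hemo(design.blocks[-1].onset_s + 10.0)  # truncated recording
        avg = epoch_and_average(hemo, list(design.blocks))
        ca = avg.conditions["LP"]
        assert ca.n_blocks_used == 3
        assert ca.dropped_blocks[0]["rule"] == "epoch_bounds"

    def test_zero_kept_blocks_raises(self, design):
        with pytest.raises(ValueError, match="no kept blocks"):
            epoch_and_average(_hemo(60.0), [])


class TestMeanWindowResponse:
    def test_constant_average_returns_constant(self, design):
        hemo = _hemo(design.total_duration_s)
        avg = epoch_and_average(hemo, list(design.blocks))
        avg.conditions["LP"].mean[:] = 2.5
        resp = mean_window_response(avg)
        assert np.allclose(resp["mean_response"], 2.5)

    def test_window_is_centered_5_to_35(self, design):
        hemo = _hemo(design.total_duration_s)
        avg = epoch_and_average(hemo, list(design.blocks))
        ca = avg.conditions["LP"]
        ca.mean[:] = 0.0
        inside = (ca.times >= 5.0) & (ca.times < 35.0)
        ca.mean[inside, :, 0] = 1.0
        resp = mean_window_response(avg)
        assert np.allclose(resp["mean_response"], 1.0)

    def test_block_average_exports_as_time_by_channel_table(self, design):
        hemo = _hemo(design.total_duration_s)
        avg = epoch_and_average(hemo, list(design.blocks))
        df = block_average_frame(avg, "LP")
        assert list(df.columns) == ["time_s", 1, 2]
        assert len(df) == 748

    def test_window_longer_than_epoch_rejected(self, design):
        hemo = _hemo(design.total_duration_s)
        avg = epoch_and_average(hemo, list(design.blocks))
        with pytest.raises(ValueError, match="exceeds"):
            mean_window_response(avg, window_s=50.0)


class TestSummarizeBehavior:
    def test_all_correct_record_gives_unit_accuracy(self):
        d = make_block_design(LANDMARK, n_blocks=2, rest_s=16.0, seed=0)
        beh = simulate_behavior(d, seed=1)
        beh["correct"] = True
        out = summarize_behavior(beh)
        assert np.allclose(out["by_condition"]["accuracy_mean"], 1.0)
        assert np.allclose(out["by_side_deviation"]["accuracy_mean"], 1.0)

    def test_lm_only_record_summarised_without_crash(self):
        d = make_block_design(LANDMARK, n_blocks=2, rest_s=16.0, seed=0)
        beh = simulate_behavior(d, seed=1)
        out = summarize_behavior(beh[beh.condition == "LM"])
        assert set(out["by_condition"]["condition"]) == {"LM"}

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_behavior(pd.DataFrame())
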