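"""Block rejection, epoching, detrending, baseline correction, averaging
and response-window summarisation.

A block is rejected when (1) any retained channel's HbO swings by more than
0.1 mM·mm inside a 0.2 s sliding window anywhere in the block's epoch, or
(2) the behavioral accuracy of the block is below 0.5 (landmark only —
picture naming has no per-trial accuracy). Participants keeping fewer than
3 blocks of a condition are excluded.

Epochs are cut at −5..+40 s around block onset so that the −5..0 s baseline
window is available, linearly detrended, baseline-corrected, then trimmed
to the stored −4..+40 s grid and averaged per condition and channel. The
scalar response per channel is the mean over the 30 s window centred in the
0..40 s post-onset span (5–35 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CHROMOPHORES, TimeSeriesBundle
from .preprocess import _sliding_range
from .design import Block, BlockDesign

__all__ = ["BlockAverage", "ConditionAverage", "reject_blocks",
           "exclude_few_blocks", "epoch_and_average", "mean_window_response",
           "summarize_behavior"]


@dataclass
class ConditionAverage:
    condition: str
    times: np.ndarray                  # seconds relative to block onset
    mean: np.ndarray                   # (n_times, n_channels, 2)
    n_blocks_used: int
    used_blocks: list[int]
    dropped_blocks: list[dict]


@dataclass
class BlockAverage:
    channel_ids: list[int]
    sfreq: float
    conditions: dict[str, ConditionAverage]

    def trace(self, condition: str, chromophore: str = "HbO") -> np.ndarray:
        k = CHROMOPHORES.index(chromophore)
        return self.conditions[condition].mean[:, :, k]


def reject_blocks(
    hemo: TimeSeriesBundle,
    design: BlockDesign,
    behavior: pd.DataFrame | None = None,
    amp_thresh: float = 0.1,
    window_s: float = 0.2,
    accuracy_min: float = 0.5,
    epoch_window_s: tuple[float, float] = (-4.0, 40.0),
    chromophore: str = "HbO",
) -> tuple[list[Block], list[dict]]:
    """Apply the two block-rejection rules; returns kept blocks + ledger.

    The signal rule scans the block's epoch extent on the given chromophore
    in every retained channel; the behavior rule computes per-block accuracy
    from ``behavior`` (rows joinable on ``block_index``).
    """
    if hemo.kind != "hemoglobin":
        raise ValueError("block rejection runs on hemoglobin series")
    fs = hemo.sfreq
    k = CHROMOPHORES.index(chromophore)
    x = hemo.data[:, :, k]
    w = max(2, int(round(window_s * fs)))
    n = x.shape[0]

    block_acc: dict[int, float] = {}
    if behavior is not None and len(behavior):
        if "block_index" not in behavior or "correct" not in behavior:
            raise ValueError("behavior table needs block_index and correct columns")
        grouped = behavior.groupby("block_index")["correct"].mean()
        unknown = set(grouped.index) - {b.index for b in design.blocks}
        if unknown:
            raise ValueError(f"behavior rows reference unknown blocks: {sorted(unknown)}")
        block_acc = grouped.to_dict()

    kept, ledger = [], []
    for block in design.blocks:
        i0 = int(round((block.onset_s + epoch_window_s[0]) * fs))
        i1 = int(round((block.onset_s + epoch_window_s[1]) * fs))
        lo, hi = max(0, i0), min(n, i1)
        seg = x[lo:hi]
        excursion = 0.0
        if seg.shape[0] >= w:
            excursion = float(_sliding_range(seg, w).max())
        acc = block_acc.get(block.index)
        if excursion > amp_thresh:
            ledger.append({"block": block.index, "condition": block.condition,
                           "rule": "signal",
                           "detail": f"max-min {excursion:.4g} mM*mm > "
                                     f"{amp_thresh} within {window_s} s"})
        elif acc is not None and acc < accuracy_min:
            ledger.append({"block": block.index, "condition": block.condition,
                           "rule": "accuracy",
                           "detail": f"accuracy {acc:.3g} < {accuracy_min}"})
        else:
            kept.append(block)
    return kept, ledger


def exclude_few_blocks(n_kept: int, min_blocks: int = 3) -> bool:
    """Participant verdict: True = excluded (strictly fewer kept blocks)."""
    return n_kept < min_blocks


def epoch_and_average(
    hemo: TimeSeriesBundle,
    kept_blocks: list[Block],
    epoch_window_s: tuple[float, float] = (-4.0, 40.0),
    baseline_window_s: tuple[float, float] = (-5.0, 0.0),
) -> BlockAverage:
    """Detrend, baseline-correct and average kept blocks per condition.

    Epochs are cut from ``min(baseline start, epoch start)`` so the baseline
    window is always inside the cut, then trimmed to the epoch window for
    output. Blocks whose epoch leaves the recording are dropped with a
    ledger entry rather than raising.
    """
    if not kept_blocks:
        raise ValueError("no kept blocks to average")
    fs = hemo.sfreq
    pre = min(baseline_window_s[0], epoch_window_s[0])
    n_cut = int(round((epoch_window_s[1] - pre) * fs))
    b0 = int(round((baseline_window_s[0] - pre) * fs))
    b1 = int(round((baseline_window_s[1] - pre) * fs))
    o0 = int(round((epoch_window_s[0] - pre) * fs))
    n = hemo.data.shape[0]
    ramp = np.arange(n_cut, dtype=float)
    ramp = (ramp - ramp.mean()) / np.sqrt(((ramp - ramp.mean()) ** 2).sum())

    starts: dict[str, list[int]] = {}
    used: dict[str, list[int]] = {}
    dropped: dict[str, list[dict]] = {}
    for block in kept_blocks:
        start = int(round((block.onset_s + pre) * fs))
        starts.setdefault(block.condition, [])
        used.setdefault(block.condition, [])
        d = dropped.setdefault(block.condition, [])
        if start < 0 or start + n_cut > n:
            d.append({"block": block.index, "rule": "epoch_bounds",
                      "detail": "epoch exceeds recording bounds"})
            continue
        starts[block.condition].append(start)
        used[block.condition].append(block.index)

    conditions = {}
    times = (np.arange(n_cut - o0) + int(round(epoch_window_s[0] * fs))) / fs
    for cond, s0 in starts.items():
        if s0:
            idx = np.asarray(s0)[:, None] + np.arange(n_cut)[None, :]
            eps = hemo.data[idx].reshape(len(s0), n_cut, -1)  # (B, t, ch*2)
            # least-squares linear detrend per block over the cut epoch
            eps -= ramp[None, :, None] * np.einsum("t,btk->bk", ramp, eps)[:, None, :]
            eps -= eps.mean(axis=1, keepdims=True)
            # baseline correction on the pre-onset window
            eps -= eps[:, b0:b1].mean(axis=1, keepdims=True)
            mean = eps.mean(axis=0)[o0:].reshape(n_cut - o0, hemo.n_channels, 2)
        else:
            mean = np.full((n_cut - o0, hemo.n_channels, 2), np.nan)
        conditions[cond] = ConditionAverage(
            cond, times, mean, len(s0), used[cond], dropped[cond])
    return BlockAverage(list(hemo.channel_ids), fs, conditions)


def mean_window_response(
    average: BlockAverage,
    window_s: float = 30.0,
    chromophore: str = "HbO",
) -> pd.DataFrame:
    """Scalar mean response per channel and condition (mM·mm).

    The window of ``window_s`` seconds is centred in the post-onset span of
    the epoch (0 s to the epoch end), i.e. 5–35 s for a 40 s epoch and the
    default 30 s window.
    """
    rows = []
    for cond, ca in average.conditions.items():
        post_end = ca.times[-1] + 1.0 / average.sfreq
        if window_s > post_end:
            raise ValueError(
                f"response window {window_s} s exceeds the {post_end:.3g} s "
                "post-onset span"
            )
        start = (post_end - window_s) / 2.0
        sel = (ca.times >= start) & (ca.times < start + window_s)
        k = CHROMOPHORES.index(chromophore)
        vals = ca.mean[sel, :, k].mean(axis=0)
        for cid, v in zip(average.channel_ids, vals):
            rows.append({"condition": cond, "channel_id": cid,
                         "mean_response": float(v),
                         "n_blocks": ca.n_blocks_used})
    return pd.DataFrame(rows)


def block_average_frame(
    average: BlockAverage,
    condition: str,
    chromophore: str = "HbO",
) -> pd.DataFrame:
    """Block-averaged trace as a tidy table (time × channel), ready for
    ``DataFrame.to_csv(..., sep='\\t')`` export."""
    ca = average.conditions[condition]
    k = CHROMOPHORES.index(chromophore)
    df = pd.DataFrame(ca.mean[:, :, k], columns=average.channel_ids)
    df.insert(0, "time_s", ca.times)
    return df


def summarize_behavior(behavior: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Accuracy and RT summaries per condition and per side × deviation."""
    if behavior is None or not len(behavior):
        raise ValueError("empty behavioral record")
    df = behavior.copy()
    df["correct"] = df["correct"].astype(float)
    by_condition = df.groupby("condition").agg(
        accuracy_mean=("correct", "mean"), accuracy_sd=("correct", "std"),
        rt_mean_ms=("rt_ms", "mean"), rt_sd_ms=("rt_ms", "std"),
        n_trials=("correct", "size"),
    ).reset_index()
    lm = df[(df["condition"] == "LM") & (df["deviation_side"] != "center")]
    by_cell = lm.groupby(["deviation_side", "deviation_pct"]).agg(
        accuracy_mean=("correct", "mean"), accuracy_sd=("correct", "std"),
        rt_mean_ms=("rt_ms", "mean"), rt_sd_ms=("rt_ms", "std"),
        n_trials=("correct", "size"),
    ).reset_index()
    return {"by_condition": by_condition, "by_side_deviation": by_cell}
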