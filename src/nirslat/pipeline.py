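"""End-to-end orchestration: QC → preprocessing → block analysis →
laterality → group statistics, with an auditable exclusion ledger.

Per task run the stages execute in their canonical order: channel QC on the
raw intensity (participant excluded above 20 % bad channels), optical
density, spline-SG motion correction, 0.008–0.5 Hz band-pass, modified
Beer–Lambert conversion, projection of the resting-state principal
components, block rejection (signal excursion / behavioral accuracy),
participant exclusion below 3 kept blocks, detrended baseline-corrected
block averaging, the middle-30 s mean response, ROI means and the
laterality index. Every exclusion cites exactly one configured rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blk
from . import stats as st
from .config import PipelineConfig
from .core import TimeSeriesBundle
from .design import BlockDesign, LANDMARK, PICTURE_NAMING
from .montage import Montage
from .preprocess import (BandpassFilter, BeerLambertTransformer, MBLLParams,
                         ODConverter, RestingPCADenoiser, SplineSGCorrector)
from .qc import ChannelQualityFlagger, QCReport
from .simulate import SubjectData

__all__ = ["TaskResult", "SubjectResult", "process_subject", "group_statistics",
           "run_pipeline", "TASK_ROI", "MAIN_CONDITION"]

#: target ROI and analysed condition per task
TASK_ROI = {PICTURE_NAMING: "language", LANDMARK: "attention"}
MAIN_CONDITION = {PICTURE_NAMING: "LP", LANDMARK: "LM"}


@dataclass
class TaskResult:
    task: str
    qc: QCReport
    excluded: bool
    exclusion_rule: str | None
    n_blocks_kept: int
    rejection_ledger: list[dict]
    mean_responses: pd.DataFrame | None  # channel_id x condition scalars
    L: float | None
    R: float | None
    li: float | None
    block_average: blk.BlockAverage | None = None


@dataclass
class SubjectResult:
    subject_id: int
    tasks: dict[str, TaskResult]
    behavior_summary: dict[str, pd.DataFrame] | None = None

    def li(self, task: str) -> float | None:
        tr = self.tasks.get(task)
        return None if tr is None or tr.excluded else tr.li


def _preprocess_run(bundle: TimeSeriesBundle, cfg: PipelineConfig) -> TimeSeriesBundle:
    od = ODConverter().transform(bundle.data)
    od = SplineSGCorrector(
        bundle.sfreq, frame_s=cfg.frame_s, spline_p=cfg.spline_p,
        t_motion_s=cfg.motion_t_s, amp_thresh=cfg.motion_amp_od,
        std_thresh=cfg.motion_std, mask_s=cfg.motion_mask_s,
    ).transform(od)
    od = BandpassFilter(bundle.sfreq, cfg.low_hz, cfg.high_hz,
                        cfg.filter_order).transform(od)
    hemo = BeerLambertTransformer(MBLLParams.from_config(cfg)).transform(od)
    return bundle.copy_with(data=hemo, kind="hemoglobin")


def process_subject(
    subject: SubjectData,
    config: PipelineConfig | None = None,
) -> SubjectResult:
    """Run the full per-subject analysis on simulated (or loaded) runs."""
    cfg = config or PipelineConfig()
    montage = subject.montage
    results: dict[str, TaskResult] = {}

    for task, raw in sorted(subject.task_bundles.items()):
        design = subject.designs[task]
        if cfg.qc_enabled:
            flagger = ChannelQualityFlagger(cfg).fit(raw)
            qc = flagger.report_
            if qc.participant_excluded:
                results[task] = TaskResult(
                    task, qc, True, "bad_channel_fraction", 0, [], None,
                    None, None, None)
                continue
            pruned = flagger.transform(raw)
        else:
            qc = QCReport(channels=[], bad_fraction=0.0,
                          participant_excluded=False,
                          rules={"qc": "disabled by config"})
            pruned = raw
        resting = subject.resting.pick(pruned.channel_ids)
        hemo_task = _preprocess_run(pruned, cfg)
        hemo_rest = _preprocess_run(resting, cfg)
        if cfg.n_components > 0 and cfg.n_components < hemo_task.n_channels:
            den = RestingPCADenoiser(cfg.n_components).fit(hemo_rest.data)
            hemo_task = hemo_task.copy_with(data=den.transform(hemo_task.data))

        behavior = subject.behavior if task == LANDMARK else None
        kept, ledger = blk.reject_blocks(
            hemo_task, design, behavior,
            amp_thresh=cfg.reject_amp, window_s=cfg.reject_window_s,
            accuracy_min=cfg.accuracy_min,
            epoch_window_s=tuple(cfg.epoch_window_s),
        )
        main = MAIN_CONDITION.get(task, design.conditions[0])
        n_main = sum(1 for b in kept if b.condition == main)
        if blk.exclude_few_blocks(n_main, cfg.min_blocks):
            results[task] = TaskResult(
                task, qc, True, "min_blocks", n_main, ledger, None,
                None, None, None)
            continue

        average = blk.epoch_and_average(
            hemo_task, kept, tuple(cfg.epoch_window_s),
            tuple(cfg.baseline_window_s))
        responses = blk.mean_window_response(average, cfg.response_window_s)
        roi = TASK_ROI.get(task)
        L = R = li = None
        rule = None
        excluded = False
        if roi is not None:
            retained = set(pruned.channel_ids)
            for side in ("left", "right"):
                missing = [c for c in montage.roi_channels(roi, side)
                           if c not in retained]
                if missing:
                    ledger = ledger + [{
                        "rule": "roi_channel_pruned",
                        "detail": f"{roi}/{side} ROI mean computed without "
                                  f"pruned channels {missing}",
                    }]
            resp_main = responses[responses["condition"] == main]
            series = resp_main.set_index("channel_id")["mean_response"]
            try:
                L = st.roi_mean(series, montage.roi_channels(roi, "left"))
                R = st.roi_mean(series, montage.roi_channels(roi, "right"))
                li = st.laterality_index(L, R)
            except ValueError as err:
                excluded, rule = True, "undefined_li"
                ledger = ledger + [{"rule": "undefined_li", "detail": str(err)}]
        results[task] = TaskResult(task, qc, excluded, rule, n_main, ledger,
                                   responses, L, R, li, average)

    behavior_summary = None
    if subject.behavior is not None and len(subject.behavior):
        behavior_summary = blk.summarize_behavior(subject.behavior)
    return SubjectResult(subject.subject_id, results, behavior_summary)


# ---------------------------------------------------------------------------
# group level

def li_table(results: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for task, tr in sorted(res.tasks.items()):
            rows.append({
                "subject": res.subject_id, "task": task,
                "excluded": tr.excluded, "exclusion_rule": tr.exclusion_rule,
                "n_blocks": tr.n_blocks_kept,
                "L": tr.L, "R": tr.R, "li": tr.li,
            })
    return pd.DataFrame(rows)


def group_statistics(results: list[SubjectResult], q: float = 0.05) -> dict:
    """Group inference across subjects: per-task LI t-tests and sign counts,
    L-vs-R paired t-tests, channelwise activation maps with BH-FDR, the
    cross-task LI Pearson correlation (raw and outlier-excluded) and the
    KS comparison of the two LI distributions."""
    table = li_table(results)
    out: dict = {"n_subjects": len(results), "per_task": {}}

    li_by_task: dict[str, pd.Series] = {}
    for task in sorted({t for r in results for t in r.tasks}):
        sub = table[(table["task"] == task) & (~table["excluded"])]
        li = sub.dropna(subset=["li"]).set_index("subject")["li"]
        li_by_task[task] = li
        entry: dict = {"n": int(len(li)),
                       "n_positive": int((li > 0).sum()),
                       "n_negative": int((li < 0).sum()),
                       "mean_li": float(li.mean()) if len(li) else None}
        if len(li) >= 3 and li.std(ddof=1) > 0:
            entry["li_t_test"] = st.t_test(li.to_numpy()).to_dict()
        Ls = sub.dropna(subset=["L", "R"])
        if len(Ls) >= 3:
            try:
                entry["l_vs_r_paired_t"] = st.t_test(
                    Ls["L"].to_numpy(), Ls["R"].to_numpy(), paired=True
                ).to_dict()
            except ValueError as err:
                entry["l_vs_r_paired_t"] = {"error": str(err)}
        resp = _response_matrix(results, task)
        if resp is not None and len(resp) >= 3:
            amap = st.channel_t_map(resp, q=q)
            entry["activation_map"] = amap.table.to_dict(orient="records")
            entry["significant_channels"] = amap.significant_channels
        out["per_task"][task] = entry

    if len(li_by_task) == 2:
        t1, t2 = sorted(li_by_task)
        joined = pd.concat(
            [li_by_task[t1].rename("a"), li_by_task[t2].rename("b")],
            axis=1).dropna()
        out["n_both_tasks"] = int(len(joined))
        if len(joined) >= 4:
            try:
                out["li_correlation"] = st.pearson_li_correlation(
                    joined["a"].to_numpy(), joined["b"].to_numpy(),
                    exclude_outliers=True).to_dict()
            except ValueError as err:
                out["li_correlation"] = {"error": str(err)}
            out["li_ks_test"] = st.ks_two_sample(
                li_by_task[t1].to_numpy(), li_by_task[t2].to_numpy()).to_dict()
    return out


def _response_matrix(results: list[SubjectResult], task: str) -> pd.DataFrame | None:
    rows = {}
    for res in results:
        tr = res.tasks.get(task)
        if tr is None or tr.excluded or tr.mean_responses is None:
            continue
        main = MAIN_CONDITION.get(task)
        sub = tr.mean_responses[tr.mean_responses["condition"] == main]
        rows[res.subject_id] = sub.set_index("channel_id")["mean_response"]
    if not rows:
        return None
    return pd.DataFrame(rows).T  # subjects x channels, NaN where pruned


def behavioral_anova(subjects_behavior: list[pd.DataFrame]) -> dict | None:
    """Hemifield × deviation repeated-measures ANOVA on LM accuracy."""
    rows = []
    for sid, beh in enumerate(subjects_behavior):
        if beh is None or not len(beh):
            continue
        lm = beh[(beh["condition"] == "LM") & (beh["deviation_side"] != "center")]
        for (side, pct), grp in lm.groupby(["deviation_side", "deviation_pct"]):
            rows.append({"subject": sid, "side": side, "deviation": pct,
                         "accuracy": grp["correct"].mean()})
    if not rows:
        return None
    df = pd.DataFrame(rows)
    counts = df.groupby("subject").size()
    full = counts[counts == counts.max()].index
    df = df[df["subject"].isin(full)]
    if df["subject"].nunique() < 3:
        return None
    res = st.rm_anova2(df, "accuracy", ("side", "deviation"), "subject")
    return {k: v.to_dict() for k, v in res.items()}


# ---------------------------------------------------------------------------
# result-directory driver

def run_pipeline(
    subjects,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Process an iterable of :class:`SubjectData`, compute group statistics
    and (optionally) write the result directory:

    ``li_table.tsv`` — subject, task, L, R, LI, exclusion verdicts;
    ``group_stats.json`` — group inference; ``qc_reports.json`` — per
    subject/task channel QC; ``exclusions.json`` — every exclusion with its
    triggering rule. Raises when QC and block rejection leave no analyzable
    subject.
    """
    cfg = config or PipelineConfig()
    results: list[SubjectResult] = []
    behaviors: list[pd.DataFrame] = []
    qc_reports: dict = {}
    exclusions: list[dict] = []
    n_any = 0
    for subject in subjects:
        res = process_subject(subject, cfg)
        results.append(res)
        behaviors.append(subject.behavior)
        for task, tr in res.tasks.items():
            qc_reports[f"subject{res.subject_id}/{task}"] = tr.qc.to_dict()
            if tr.excluded:
                exclusions.append({
                    "subject": res.subject_id, "task": task, "stage": "subject",
                    "rule": tr.exclusion_rule,
                })
            else:
                n_any += 1
            for entry in tr.rejection_ledger:
                exclusions.append({"subject": res.subject_id, "task": task,
                                   "stage": "block", **entry})
    if n_any == 0:
        raise RuntimeError("no analyzable subjects: QC/block rejection "
                           "excluded every run")

    table = li_table(results)
    group = group_statistics(results)
    anova = behavioral_anova(behaviors)
    if anova is not None:
        group["behavior_rm_anova"] = anova

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "li_table.tsv", sep="\t", index=False,
                     float_format="%.10g")
        (out / "group_stats.json").write_text(
            json.dumps(group, indent=2, default=_json_default))
        (out / "qc_reports.json").write_text(
            json.dumps(qc_reports, indent=2, default=_json_default))
        (out / "exclusions.json").write_text(
            json.dumps(exclusions, indent=2, default=_json_default))
    return {"results": results, "li_table": table, "group": group,
            "exclusions": exclusions}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
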