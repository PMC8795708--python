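"""Synthetic block-design fNIRS sessions with exported ground truth.

The generator inverts the analysis pipeline's forward model. Hemoglobin
series are composed in mM·mm — lateralized HRF-shaped task responses in the
ROI channel pairs, plus cardiac / respiratory / Mayer-wave / low-frequency
physiological components that share a global spatial loading pattern across
channels — then mapped to optical density with the modified Beer–Lambert
law, contaminated with motion spikes and baseline shifts, and exponentiated
into raw dual-wavelength intensity (I = I0 · 10^-OD).

Per-subject ground truth (true L, R, LI per task, planted bad channels,
artifact times, loading vectors) is exported next to every dataset. With
all noise amplitudes at zero the full pipeline recovers each subject's true
laterality index to numerical precision, which is the generator's central
design constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeSeriesBundle
from .design import BlockDesign, LANDMARK, PICTURE_NAMING, make_block_design
from .montage import Montage, default_montage
from .preprocess import MBLLParams, mbll_forward

__all__ = [
    "EffectSpec", "TaskEffect", "NoiseSpec", "GroundTruth", "SubjectData",
    "canonical_hrf", "simulate_subject", "simulate_cohort",
    "simulate_behavior", "CohortSpec", "CohortSimulation",
]

#: HbR task response as a fraction of the HbO response (typical inversion)
HBR_RATIO = -1.0 / 3.0


# ---------------------------------------------------------------------------
# canonical HRF

def canonical_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma hemodynamic response on time grid ``t`` (seconds).

    Zero at t = 0, peak normalized to 1. ``peak_s`` / ``undershoot_s`` are
    the modes of the positive and undershoot gamma lobes; ``ratio`` scales
    the undershoot.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0 or t.min() < 0:
        raise ValueError("time grid must start at 0 (no negative times)")
    if peak_s <= 0 or undershoot_s <= 0 or ratio < 0:
        raise ValueError("HRF shape parameters must be positive")
    from scipy.stats import gamma as gamma_dist
    # gamma pdf with scale 1 peaks at (a - 1): choose a = mode + 1
    h = gamma_dist.pdf(t, peak_s + 1.0) - ratio * gamma_dist.pdf(t, undershoot_s + 1.0)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return h / peak


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class TaskEffect:
    """Hemisphere-specific HRF peak amplitudes for one task's target ROI."""

    roi: str
    amp_left: float      # mM*mm, peak HbO response, left-ROI channels
    amp_right: float
    control_amp: float = 0.0  # symmetric amplitude of the control condition

    @property
    def true_li(self) -> float:
        return (self.amp_left - self.amp_right) / (self.amp_left + self.amp_right)

    @classmethod
    def from_li(cls, roi: str, li: float, total_amp: float = 0.03,
                control_ratio: float = 0.0) -> "TaskEffect":
        """Split ``total_amp`` = L + R so that (L−R)/(L+R) = ``li``."""
        if not -1.0 <= li <= 1.0:
            raise ValueError("laterality index must lie in [-1, 1]")
        left = 0.5 * (1.0 + li) * total_amp
        right = 0.5 * (1.0 - li) * total_amp
        return cls(roi, left, right, control_ratio * total_amp / 2.0)


@dataclass(frozen=True)
class EffectSpec:
    """Per-subject activation truth: one :class:`TaskEffect` per task."""

    effects: dict[str, TaskEffect] = field(default_factory=dict)
    hbr_ratio: float = HBR_RATIO
    hbr_lag_s: float = 0.8  # HbR response lags HbO (venous washout delay)

    @classmethod
    def from_li(cls, li_language: float, li_attention: float,
                total_amp: float = 0.03, control_ratio: float = 0.3) -> "EffectSpec":
        return cls({
            PICTURE_NAMING: TaskEffect.from_li("language", li_language, total_amp),
            LANDMARK: TaskEffect.from_li("attention", li_attention, total_amp,
                                         control_ratio),
        })

    def true_li(self, task: str) -> float:
        return self.effects[task].true_li


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (mM·mm unless noted) of the simulated nuisance structure."""

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.008
    resp_hz: float = 0.25
    resp_amp: float = 0.004
    mayer_hz: float = 0.1
    mayer_amp: float = 0.005
    drift_amp: float = 0.01
    drift_exponent: float = 1.0
    loading_jitter: float = 0.3    # per-component spatial loading perturbation
    white_sd: float = 0.002
    hbr_coupling: float = -0.2     # HbR mirror of the HbO physiological noise
    hbr_drift_ratio: float = 0.3   # independent HbR drift vs HbO drift amp
    spike_rate_per_min: float = 0.5
    spike_amp_od: float = 0.03
    spike_decay_s: float = 0.4
    shift_rate_per_min: float = 0.1
    shift_amp_od: float = 0.008
    intensity_noise: float = 0.0005  # relative white noise on raw intensity

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "resp_amp", "mayer_amp", "drift_amp",
                     "white_sd", "spike_amp_od", "shift_amp_od",
                     "spike_rate_per_min", "shift_rate_per_min",
                     "intensity_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0,
                   white_sd=0.0, spike_rate_per_min=0.0, shift_rate_per_min=0.0,
                   intensity_noise=0.0)

    def validate_against(self, sfreq: float) -> None:
        if self.cardiac_hz >= sfreq / 2.0:
            raise ValueError(
                f"cardiac frequency {self.cardiac_hz} Hz at or above Nyquist "
                f"({sfreq / 2.0} Hz)"
            )


@dataclass
class GroundTruth:
    """Immutable record of what was planted in one simulated subject."""

    li: dict[str, float]
    amplitudes: dict[str, tuple[float, float]]  # task -> (L, R)
    bad_channels: dict[int, str]
    artifact_times_s: dict[str, np.ndarray]
    loading: np.ndarray


@dataclass
class SubjectData:
    subject_id: int
    montage: Montage
    task_bundles: dict[str, TimeSeriesBundle]
    designs: dict[str, BlockDesign]
    resting: TimeSeriesBundle
    behavior: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# noise synthesis helpers

def _one_over_f(rng: np.random.Generator, n: int, exponent: float,
                n_series: int = 1) -> np.ndarray:
    """Unit-variance 1/f^exponent (power) noise via spectral shaping.

    Returns shape (n,) for a single series, else (n, n_series)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros((len(freqs), n_series))
    amp[1:] = freqs[1:, None] ** (-exponent / 2.0)
    phases = (rng.standard_normal(amp.shape)
              + 1j * rng.standard_normal(amp.shape))
    x = np.fft.irfft(amp * phases, n=n, axis=0)
    sd = x.std(axis=0, keepdims=True)
    x = np.divide(x, sd, out=x, where=sd > 0)
    return x[:, 0] if n_series == 1 else x


def _physio_components(rng: np.random.Generator, n: int, sfreq: float,
                       noise: NoiseSpec) -> np.ndarray:
    """Stack of unit-peak physiological time courses scaled by amplitude."""
    t = np.arange(n) / sfreq
    comps = []
    for hz, amp in ((noise.cardiac_hz, noise.cardiac_amp),
                    (noise.resp_hz, noise.resp_amp),
                    (noise.mayer_hz, noise.mayer_amp)):
        phase = rng.uniform(0, 2 * np.pi)
        comps.append(amp * np.sin(2 * np.pi * hz * t + phase))
    comps.append(noise.drift_amp * _one_over_f(rng, n, noise.drift_exponent))
    return np.stack(comps, axis=1)  # (n, 4)


def _task_waveforms(design: BlockDesign, n: int, sfreq: float) -> dict[str, np.ndarray]:
    """Per-condition boxcar ⊗ HRF, normalized to unit peak."""
    kernel_t = np.arange(0, 40.0, 1.0 / sfreq)
    kernel = canonical_hrf(kernel_t)
    out = {}
    for cond in design.conditions:
        box = np.zeros(n)
        for b in design.blocks_of(cond):
            i0 = int(round(b.onset_s * sfreq))
            i1 = int(round(b.end_s * sfreq))
            box[i0:min(i1, n)] = 1.0
        resp = np.convolve(box, kernel)[:n]
        peak = np.abs(resp).max()
        out[cond] = resp / peak if peak > 0 else resp
    return out


def _roi_indicator(montage: Montage, roi: str, side: str,
                   channel_ids: list[int]) -> np.ndarray:
    members = set(montage.roi_defs[roi][side])
    return np.array([1.0 if c in members else 0.0 for c in channel_ids])


# ---------------------------------------------------------------------------
# single-recording forward model

def _simulate_recording(
    rng: np.random.Generator,
    montage: Montage,
    sfreq: float,
    duration_s: float,
    design: BlockDesign | None,
    effect: TaskEffect | None,
    hbr_ratio: float,
    hbr_lag_s: float,
    noise: NoiseSpec,
    loading: np.ndarray,
    bad_channels: dict[int, str],
    mbll_params: MBLLParams,
) -> tuple[TimeSeriesBundle, np.ndarray]:
    n = int(round(duration_s * sfreq))
    ids = montage.channel_ids
    n_ch = len(ids)
    hbo = np.zeros((n, n_ch))
    hbr = np.zeros((n, n_ch))

    # task signal
    if design is not None and effect is not None:
        waves = _task_waveforms(design, n, sfreq)
        main_cond = "LP" if design.task == PICTURE_NAMING else "LM"
        left = _roi_indicator(montage, effect.roi, "left", ids)
        right = _roi_indicator(montage, effect.roi, "right", ids)
        sig = waves[main_cond][:, None] * (
            effect.amp_left * left + effect.amp_right * right
        )
        if design.task == LANDMARK and effect.control_amp != 0.0:
            sig = sig + waves["LMC"][:, None] * effect.control_amp * (left + right)
        hbo += sig
        # HbR mirrors HbO at reduced amplitude with a small physiological
        # lag; the lag keeps the HbO/HbR correlation away from exactly -1.
        shift = int(round(hbr_lag_s * sfreq))
        sig_lag = np.zeros_like(sig)
        if shift < sig.shape[0]:
            sig_lag[shift:] = sig[: sig.shape[0] - shift]
        hbr += hbr_ratio * sig_lag

    # shared physiological structure
    comps = _physio_components(rng, n, sfreq, noise)  # (n, 4)
    k = comps.shape[1]
    jitter = 1.0 + noise.loading_jitter * rng.standard_normal((k, n_ch))
    loadings = np.abs(loading[None, :] * jitter)     # (4, n_ch)
    physio = comps @ loadings
    hbo += physio
    hbr += noise.hbr_coupling * physio
    if noise.drift_amp > 0 and noise.hbr_drift_ratio > 0:
        hbr += (noise.hbr_drift_ratio * noise.drift_amp
                * _one_over_f(rng, n, noise.drift_exponent, n_ch))

    # white measurement-level noise (hemoglobin scale)
    if noise.white_sd > 0:
        hbo += noise.white_sd * rng.standard_normal((n, n_ch))
        hbr += noise.white_sd * rng.standard_normal((n, n_ch))

    # planted bad channels, stage 1: poor coupling -> white noise only
    for cid, mode in bad_channels.items():
        j = ids.index(cid)
        if mode == "no_cardiac":
            sd = max(noise.white_sd, 1e-4)
            hbo[:, j] = sd * rng.standard_normal(n)
            hbr[:, j] = sd * rng.standard_normal(n)
        elif mode not in ("coupled", "anticorrelated"):
            raise ValueError(f"unknown bad-channel mode {mode!r}")

    od = mbll_forward(np.stack([hbo, hbr], axis=2), mbll_params)

    # motion artifacts, applied in OD space across all channels; the event
    # time courses and channel scales are accumulated with one matmul
    minutes = duration_s / 60.0
    t = np.arange(n) / sfreq
    events: list[float] = []
    shapes: list[np.ndarray] = []
    ch_scales: list[np.ndarray] = []
    n_spikes = rng.poisson(noise.spike_rate_per_min * minutes)
    for _ in range(n_spikes):
        t0 = rng.uniform(5.0, duration_s - 5.0)
        scale = noise.spike_amp_od * rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
        shapes.append(scale * np.exp(-np.abs(t - t0) / noise.spike_decay_s))
        ch_scales.append(rng.uniform(0.5, 1.5, n_ch))
        events.append(t0)
    n_shifts = rng.poisson(noise.shift_rate_per_min * minutes)
    for _ in range(n_shifts):
        t0 = rng.uniform(5.0, duration_s - 5.0)
        scale = noise.shift_amp_od * rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
        shapes.append(scale * (t >= t0).astype(float))
        ch_scales.append(rng.uniform(0.5, 1.5, n_ch))
        events.append(t0)
    if shapes:
        motion = np.stack(shapes, axis=1) @ np.stack(ch_scales, axis=0)
        od += motion[:, :, None]

    # planted bad channels, stage 2: deterministic cross-wavelength faults.
    # Choosing OD_l2 = a * OD_l1 with eps(1, -1) or eps(1, 1) proportional to
    # (1, a) makes the converted HbR an exact negative (or positive) copy of
    # HbO, the degenerate dependence the correlation rule is meant to catch.
    e = mbll_params.extinction
    d1, d2 = mbll_params.dpf
    for cid, mode in bad_channels.items():
        if mode in ("coupled", "anticorrelated"):
            j = ids.index(cid)
            sign = 1.0 if mode == "coupled" else -1.0
            v = e @ np.array([1.0, sign])
            od[:, j, 1] = od[:, j, 0] * (v[1] / v[0]) * (d2 / d1)

    # OD -> raw intensity
    i0 = np.exp(rng.normal(0.0, 0.2, (1, n_ch, 2)))
    intensity = i0 * np.exp(-np.log(10.0) * od)
    if noise.intensity_noise > 0:
        mult = 1.0 + noise.intensity_noise * rng.standard_normal(intensity.shape)
        # deterministic channel faults stay exact: no measurement dither there
        for cid, mode in bad_channels.items():
            if mode in ("coupled", "anticorrelated"):
                mult[:, ids.index(cid), :] = 1.0
        intensity *= mult
        np.clip(intensity, 1e-12, None, out=intensity)

    bundle = TimeSeriesBundle(intensity, sfreq, ids, kind="intensity",
                              wavelengths_nm=tuple(mbll_params.wavelengths_nm))
    return bundle, np.sort(np.array(events))


# ---------------------------------------------------------------------------
# subject- and cohort-level generation

def simulate_subject(
    montage: Montage | None = None,
    designs: dict[str, BlockDesign] | None = None,
    effects: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    mbll_params: MBLLParams | None = None,
    *,
    sfreq: float = 17.0,
    rest_duration_s: float = 300.0,
    bad_channels: dict[int, str] | None = None,
    subject_id: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> SubjectData:
    """Simulate one subject: both task runs, a resting run and behavior.

    ``bad_channels`` maps channel id → planting mode (``"no_cardiac"``,
    ``"coupled"``, ``"anticorrelated"``).
    """
    montage = montage or default_montage()
    effects = effects or EffectSpec.from_li(0.3, -0.3)
    noise = noise or NoiseSpec()
    noise.validate_against(sfreq)
    mbll_params = mbll_params or MBLLParams()
    bad_channels = dict(bad_channels or {})
    missing = [c for c in bad_channels if c not in montage.channel_ids]
    if missing:
        raise ValueError(f"bad channels not in montage: {missing}")
    for task, eff in effects.effects.items():
        if eff.roi not in montage.roi_defs:
            raise ValueError(f"ROI {eff.roi!r} not defined in montage")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    if designs is None:
        designs = {
            PICTURE_NAMING: make_block_design(PICTURE_NAMING),
            LANDMARK: make_block_design(
                LANDMARK, seed=int(rngs[4].integers(2**31))),
        }

    loading = np.abs(rngs[0].uniform(0.5, 1.5, montage.n_channels))

    task_bundles, artifact_times = {}, {}
    for i, (task, design) in enumerate(sorted(designs.items())):
        bundle, events = _simulate_recording(
            rngs[1 + i], montage, sfreq, design.total_duration_s, design,
            effects.effects.get(task), effects.hbr_ratio, effects.hbr_lag_s,
            noise, loading, bad_channels, mbll_params,
        )
        task_bundles[task] = bundle
        artifact_times[task] = events

    resting, rest_events = _simulate_recording(
        rngs[3], montage, sfreq, rest_duration_s, None, None,
        effects.hbr_ratio, effects.hbr_lag_s, noise, loading, bad_channels,
        mbll_params,
    )
    artifact_times["resting"] = rest_events

    behavior = pd.DataFrame()
    if LANDMARK in designs:
        behavior = simulate_behavior(
            designs[LANDMARK], seed=int(rngs[4].integers(2**31)))

    truth = GroundTruth(
        li={task: eff.true_li for task, eff in effects.effects.items()},
        amplitudes={task: (eff.amp_left, eff.amp_right)
                    for task, eff in effects.effects.items()},
        bad_channels=bad_channels,
        artifact_times_s=artifact_times,
        loading=loading,
    )
    return SubjectData(subject_id, montage, task_bundles, designs, resting,
                       behavior, truth)


@dataclass(frozen=True)
class CohortSpec:
    """Population distribution of the per-subject true laterality indices."""

    li_mean: tuple[float, float] = (0.3, -0.3)   # (language, attention)
    li_sd: tuple[float, float] = (0.25, 0.25)
    rho: float = 0.0
    total_amp: float = 0.03
    control_ratio: float = 0.3
    li_clip: float = 0.95

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if any(sd < 0 for sd in self.li_sd):
            raise ValueError("li_sd must be non-negative")


@dataclass
class CohortSimulation:
    """Lazily realised cohort: truth table plus a subject generator."""

    truth: pd.DataFrame
    spec: CohortSpec
    montage: Montage
    noise: NoiseSpec
    sfreq: float
    rest_duration_s: float
    _seeds: list[np.random.SeedSequence]

    def subjects(self):
        for row, seed in zip(self.truth.itertuples(), self._seeds):
            effects = EffectSpec.from_li(
                row.true_li_language, row.true_li_attention,
                total_amp=self.spec.total_amp,
                control_ratio=self.spec.control_ratio,
            )
            yield simulate_subject(
                self.montage, None, effects, self.noise,
                sfreq=self.sfreq, rest_duration_s=self.rest_duration_s,
                subject_id=int(row.subject), seed=seed,
            )


def simulate_cohort(
    n_subjects: int,
    spec: CohortSpec | None = None,
    noise: NoiseSpec | None = None,
    montage: Montage | None = None,
    *,
    sfreq: float = 17.0,
    rest_duration_s: float = 300.0,
    seed: int = 0,
) -> CohortSimulation:
    """Draw per-subject true (LI_language, LI_attention) from a bivariate
    normal with the configured means, SDs and correlation ``rho`` (clipped
    to ±``li_clip`` to keep L and R non-negative), and return a lazily
    evaluated cohort simulation.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    spec = spec or CohortSpec()
    noise = noise or NoiseSpec()
    montage = montage or default_montage()
    ss = np.random.SeedSequence(seed)
    truth_ss, *subject_ss = ss.spawn(n_subjects + 1)
    rng = np.random.default_rng(truth_ss)
    s1, s2 = spec.li_sd
    cov = [[s1 ** 2, spec.rho * s1 * s2], [spec.rho * s1 * s2, s2 ** 2]]
    li = rng.multivariate_normal(spec.li_mean, cov, size=n_subjects)
    li = np.clip(li, -spec.li_clip, spec.li_clip)
    truth = pd.DataFrame({
        "subject": np.arange(n_subjects),
        "true_li_language": li[:, 0],
        "true_li_attention": li[:, 1],
    })
    truth["empirical_rho"] = np.corrcoef(li[:, 0], li[:, 1])[0, 1]
    return CohortSimulation(truth, spec, montage, noise, sfreq,
                            rest_duration_s, subject_ss)


# ---------------------------------------------------------------------------
# behavior

DEFAULT_ACCURACY = {2.5: 0.43, 5.0: 0.85, 7.5: 0.95}


def simulate_behavior(
    design: BlockDesign,
    *,
    accuracy_by_deviation: dict[float, float] | None = None,
    center_accuracy: float = 0.80,
    control_accuracy: float = 0.93,
    left_bias: float = 0.06,
    rt_median_ms: float = 850.0,
    rt_sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial landmark behavior.

    Half the LM trials are precisely bisected; the rest deviate left or
    right (balanced) by 2.5, 5.0 or 7.5 % of the line length. Accuracy is
    monotone non-decreasing in the deviation distance; ``left_bias`` adds
    half its value to left-deviation accuracy and subtracts half from the
    right, emulating the leftward attentional bias (pseudoneglect).
    """
    if design.task != LANDMARK:
        raise ValueError("behavior is defined for the landmark task")
    acc = dict(accuracy_by_deviation or DEFAULT_ACCURACY)
    probs = list(acc.values()) + [center_accuracy, control_accuracy]
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError("accuracy parameters must lie in [0, 1]")
    pcts = sorted(acc)
    if any(acc[a] > acc[b] for a, b in zip(pcts, pcts[1:])):
        raise ValueError("accuracy must be monotone non-decreasing in deviation")

    rng = np.random.default_rng(seed)
    rows = []
    for block in design.blocks:
        trials = list(block.trials)
        n = len(trials)
        if block.condition == "LM":
            n_dev = n // 2
            sides = ["left"] * (n_dev // 2) + ["right"] * (n_dev - n_dev // 2)
            devs = [float(rng.choice(pcts)) for _ in sides]
            stim = [("center", 0.0)] * (n - n_dev) + list(zip(sides, devs))
            order = rng.permutation(n)
            stim = [stim[i] for i in order]
        else:
            stim = [("center", 0.0)] * n
        for trial, (side, pct) in zip(trials, stim):
            if block.condition != "LM":
                p = control_accuracy
            elif side == "center":
                p = center_accuracy
            else:
                p = acc[pct] + (0.5 if side == "left" else -0.5) * left_bias
                p = min(1.0, max(0.0, p))
            correct = bool(rng.random() < p)
            rt = float(rt_median_ms * np.exp(rng.normal(0.0, rt_sigma)))
            rows.append({
                "block_index": block.index,
                "condition": block.condition,
                "deviation_side": side,
                "deviation_pct": pct,
                "correct": correct,
                "rt_ms": rt,
            })
    return pd.DataFrame(rows)
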