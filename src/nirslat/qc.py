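"""Initial channel pruning and participant exclusion.

Two rules mark a channel bad before any preprocessing:

1. **HbO/HbR correlation.** During cognitive tasks HbO and HbR are
   negatively correlated; motion pushes the correlation positive. A channel
   whose whole-recording Pearson correlation is (numerically) −1 or above
   0.5 is bad. The correlation is computed on a *provisional* Beer–Lambert
   conversion of the raw data — no motion correction or filtering — since
   the criterion is defined on hemoglobin but pruning precedes processing.
2. **Cardiac component.** A channel whose power spectrum shows no ~1 Hz
   cardiac peak (default band 0.8–1.5 Hz, peak ≥ 5× the local median
   background, on either wavelength's optical density) has poor
   optode–scalp coupling and is bad.

A participant (task run) with strictly more than 20 % bad channels is
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .core import TimeSeriesBundle
from .montage import Montage
from .preprocess import BeerLambertTransformer, MBLLParams, ODConverter

__all__ = ["QCReport", "ChannelQualityFlagger", "correlation_flag",
           "cardiac_flag", "apply_qc"]


@dataclass
class ChannelQC:
    channel_id: int
    corr_hbo_hbr: float | None
    corr_flag: bool
    cardiac_flag: bool  # True = cardiac component absent (bad)

    @property
    def bad(self) -> bool:
        return self.corr_flag or self.cardiac_flag


@dataclass
class QCReport:
    channels: list[ChannelQC]
    bad_fraction: float
    participant_excluded: bool
    rules: dict[str, str] = field(default_factory=dict)

    @property
    def bad_channels(self) -> list[int]:
        return [c.channel_id for c in self.channels if c.bad]

    @property
    def good_channels(self) -> list[int]:
        return [c.channel_id for c in self.channels if not c.bad]

    def to_dict(self) -> dict:
        return {
            "channels": [
                {
                    "channel_id": c.channel_id,
                    "corr_hbo_hbr": c.corr_hbo_hbr,
                    "corr_flag": c.corr_flag,
                    "cardiac_flag": c.cardiac_flag,
                    "bad": c.bad,
                }
                for c in self.channels
            ],
            "bad_fraction": self.bad_fraction,
            "participant_excluded": self.participant_excluded,
            "rules": self.rules,
        }


def correlation_flag(
    hbo: np.ndarray,
    hbr: np.ndarray,
    lower: float = -1.0,
    upper: float = 0.5,
    eps: float = 1e-6,
) -> tuple[float | None, bool]:
    """Pearson correlation of HbO vs HbR and the bad flag.

    Flag is true iff corr <= lower + eps or corr > upper. A zero-variance
    series leaves the correlation undefined (None) and flags the channel.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape or hbo.ndim != 1:
        raise ValueError("hbo and hbr must be equal-length 1-D series")
    if len(hbo) < 10:
        raise ValueError("series too short for a meaningful correlation")
    if not (np.isfinite(hbo).all() and np.isfinite(hbr).all()):
        raise ValueError("series contain non-finite values")
    if hbo.std() == 0 or hbr.std() == 0:
        return None, True
    r = float(np.corrcoef(hbo, hbr)[0, 1])
    return r, bool(r <= lower + eps or r > upper)


def _cardiac_absent(
    x: np.ndarray,
    sfreq: float,
    band: tuple[float, float],
    prominence: float,
) -> np.ndarray:
    """Vectorized cardiac-peak check on the columns of a 2-D array.

    Returns a boolean per column: True when the peak is absent (bad)."""
    lo, hi = band
    if sfreq / 2.0 <= hi:
        raise ValueError(
            f"cardiac band {band} exceeds Nyquist at {sfreq} Hz sampling"
        )
    nperseg = int(min(x.shape[0], round(60 * sfreq)))
    freqs, psd = sp_signal.welch(x, fs=sfreq, nperseg=nperseg,
                                 detrend="constant", axis=0)
    in_band = (freqs >= lo) & (freqs <= hi)
    bg_lo, bg_hi = 0.5, min(sfreq / 2.0, hi + 1.0)
    bg = (freqs >= bg_lo) & (freqs <= bg_hi) & ~in_band
    if not in_band.any() or not bg.any():
        return np.ones(x.shape[1], dtype=bool)
    background = np.median(psd[bg], axis=0)
    peak = psd[in_band].max(axis=0)
    absent = np.where(background > 0, peak < prominence * background, peak <= 0)
    return absent.astype(bool)


def cardiac_flag(
    series: np.ndarray,
    sfreq: float,
    band: tuple[float, float] = (0.8, 1.5),
    prominence: float = 5.0,
) -> bool:
    """True when the cardiac spectral peak is *absent* (channel is bad).

    A Welch periodogram is compared inside ``band`` against the local median
    background (0.5 Hz up to 1 Hz above the band, excluding the band
    itself); the peak must exceed ``prominence`` times that background.
    """
    x = np.asarray(series, dtype=float).reshape(-1, 1)
    return bool(_cardiac_absent(x, sfreq, band, prominence)[0])


class ChannelQualityFlagger(BaseEstimator):
    """Fit on a raw intensity bundle; exposes the QC verdict as attributes.

    Fitted attributes: ``report_`` (:class:`QCReport`), ``bad_channels_``,
    ``good_channels_``, ``excluded_``.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def fit(self, bundle: TimeSeriesBundle, y=None):
        cfg = self.config or PipelineConfig()
        if bundle.kind != "intensity":
            raise ValueError("QC runs on the raw intensity recording")
        od = ODConverter().transform(bundle.data)
        hemo = BeerLambertTransformer(MBLLParams.from_config(cfg)).transform(od)
        n_ch = bundle.n_channels
        band = tuple(cfg.cardiac_band)
        # cardiac presence at either wavelength suffices; test the second
        # wavelength (stronger HbO weighting) first, recheck only misses
        absent_by_ch = _cardiac_absent(od[:, :, 1], bundle.sfreq, band,
                                       cfg.cardiac_prominence)
        if absent_by_ch.any():
            recheck = np.flatnonzero(absent_by_ch)
            absent_by_ch[recheck] &= _cardiac_absent(
                od[:, recheck, 0], bundle.sfreq, band, cfg.cardiac_prominence)

        # vectorized HbO/HbR Pearson correlation per channel
        hb = hemo - hemo.mean(axis=0, keepdims=True)
        sd = hb.std(axis=0)
        cov = np.einsum("tc,tc->c", hb[:, :, 0], hb[:, :, 1]) / hb.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_all = cov / (sd[:, 0] * sd[:, 1])
        channels = []
        for j, cid in enumerate(bundle.channel_ids):
            if sd[j, 0] == 0 or sd[j, 1] == 0:
                corr, cflag = None, True
            else:
                corr = float(np.clip(corr_all[j], -1.0, 1.0))
                cflag = bool(corr <= cfg.corr_lower + cfg.corr_eps
                             or corr > cfg.corr_upper)
            channels.append(ChannelQC(cid, corr, cflag, bool(absent_by_ch[j])))
        n_bad = sum(c.bad for c in channels)
        frac = n_bad / len(channels) if channels else 0.0
        self.report_ = QCReport(
            channels=channels,
            bad_fraction=frac,
            participant_excluded=bool(frac > cfg.bad_channel_fraction),
            rules={
                "corr": f"corr <= {cfg.corr_lower} + {cfg.corr_eps} or "
                        f"corr > {cfg.corr_upper}",
                "cardiac": f"no PSD peak in {tuple(cfg.cardiac_band)} Hz "
                           f">= {cfg.cardiac_prominence}x local median",
                "participant": f"bad fraction > {cfg.bad_channel_fraction}",
            },
        )
        self.bad_channels_ = self.report_.bad_channels
        self.good_channels_ = self.report_.good_channels
        self.excluded_ = self.report_.participant_excluded
        return self

    def transform(self, bundle: TimeSeriesBundle) -> TimeSeriesBundle:
        if not hasattr(self, "report_"):
            raise RuntimeError("fit the flagger before pruning")
        return bundle.pick(self.good_channels_)


def apply_qc(
    bundle: TimeSeriesBundle,
    montage: Montage,
    config: PipelineConfig | None = None,
) -> tuple[TimeSeriesBundle, QCReport]:
    """Prune bad channels from ``bundle`` and return the verdict."""
    flagger = ChannelQualityFlagger(config).fit(bundle)
    return flagger.transform(bundle), flagger.report_
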