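"""Pipeline configuration.

Every numeric constant of the processing chain lives here with its default:
17 Hz sampling, the HbO/HbR correlation bounds (−1, 0.5) and the 20 %
bad-channel participant cutoff, the spline-SG parameters (frame 6 s,
p = 0.99), the 0.008–0.5 Hz band, the two resting-state PCA components, the
block-rejection rules (0.1 mM·mm over 0.2 s; accuracy < 0.5; < 3 blocks),
the −5..0 s baseline, the −4..+40 s epoch and the middle 30 s response
window. A YAML config file may override any subset of keys; omitted keys
keep these defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Base-10 molar extinction coefficients, mm^-1 per mM, rows = wavelengths
#: (740, 850 nm), columns = (HbO, HbR). Compiled hemoglobin spectra (Prahl),
#: converted from cm^-1 M^-1.
EXTINCTION_740_850 = (
    (0.0446, 0.111588),
    (0.1058, 0.069132),
)


class ConfigError(ValueError):
    """A configuration value is out of range or unknown."""


@dataclass
class PipelineConfig:
    # acquisition
    sampling_rate: float = 17.0

    # channel QC (qc_enabled=False passes all channels through; the corr
    # and cardiac rules presume stochastic physiological recordings and
    # degenerate on idealized noiseless data)
    qc_enabled: bool = True
    corr_lower: float = -1.0
    corr_upper: float = 0.5
    corr_eps: float = 1e-6
    bad_channel_fraction: float = 0.2
    cardiac_band: tuple[float, float] = (0.8, 1.5)
    cardiac_prominence: float = 5.0

    # motion detection + spline-SG correction (on optical density)
    motion_t_s: float = 0.5
    motion_amp_od: float = 0.2
    motion_std: float = 4.0
    motion_mask_s: float = 1.0
    frame_s: float = 6.0
    spline_p: float = 0.99

    # band-pass filter
    low_hz: float = 0.008
    high_hz: float = 0.5
    filter_order: int = 3

    # modified Beer-Lambert law
    wavelengths_nm: tuple[float, float] = (740.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = EXTINCTION_740_850
    dpf: tuple[float, float] = (6.0, 6.0)

    # resting-state PCA denoising
    n_components: int = 2

    # block analysis
    reject_amp: float = 0.1  # mM*mm
    reject_window_s: float = 0.2
    accuracy_min: float = 0.5
    min_blocks: int = 3
    epoch_window_s: tuple[float, float] = (-4.0, 40.0)
    baseline_window_s: tuple[float, float] = (-5.0, 0.0)
    response_window_s: float = 30.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fs = self.sampling_rate
        _require(fs > 0, "sampling_rate", "must be positive")
        _require(
            0 < self.low_hz < self.high_hz < fs / 2,
            "low_hz/high_hz",
            "need 0 < low_hz < high_hz < sampling_rate/2",
        )
        _require(self.cardiac_band[1] < fs / 2, "cardiac_band", "above Nyquist")
        _require(self.cardiac_band[0] < self.cardiac_band[1], "cardiac_band", "empty band")
        _require(self.corr_lower < self.corr_upper, "corr_lower/corr_upper", "empty range")
        _require(0 <= self.bad_channel_fraction <= 1, "bad_channel_fraction", "not in [0,1]")
        _require(self.cardiac_prominence > 0, "cardiac_prominence", "must be positive")
        _require(0 < self.spline_p <= 1, "spline_p", "must be in (0, 1]")
        for key in ("motion_t_s", "motion_mask_s", "frame_s", "reject_window_s",
                    "response_window_s"):
            _require(getattr(self, key) > 0, key, "window must be positive")
        _require(self.n_components >= 0, "n_components", "must be >= 0")
        _require(self.min_blocks >= 1, "min_blocks", "must be >= 1")
        _require(0 <= self.accuracy_min <= 1, "accuracy_min", "not in [0,1]")
        _require(self.epoch_window_s[0] < self.epoch_window_s[1], "epoch_window_s", "empty")
        _require(
            self.baseline_window_s[0] < self.baseline_window_s[1],
            "baseline_window_s", "empty",
        )
        _require(all(d > 0 for d in self.dpf), "dpf", "must be positive")
        e = self.extinction
        det = e[0][0] * e[1][1] - e[0][1] * e[1][0]
        _require(abs(det) > 1e-12, "extinction", "matrix is singular")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        d["extinction"] = [list(r) for r in self.extinction]
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            kwargs[key] = value
        return cls(**kwargs)


def _require(ok: bool, key: str, msg: str) -> None:
    if not ok:
        raise ConfigError(f"{key}: {msg}")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; omitted keys fall back to the printed defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    mapping = yaml.safe_load(text) or {}
    if not isinstance(mapping, dict):
        raise ConfigError("config file must contain a mapping")
    return PipelineConfig.from_dict(mapping)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
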