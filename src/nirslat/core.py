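"""Core in-memory containers shared across the pipeline.

The pipeline moves a single array shape through its stages: ``(n_times,
n_channels, 2)``, where the trailing axis holds the two wavelengths for raw
intensity / optical density, or the two chromophores (HbO, HbR) once the
modified Beer–Lambert conversion has run. :class:`TimeSeriesBundle` carries
that array together with the sampling rate and channel labels so that
channel pruning stays consistent downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: admissible values for :attr:`TimeSeriesBundle.kind`
KINDS = ("intensity", "od", "hemoglobin")

CHROMOPHORES = ("HbO", "HbR")


@dataclass
class TimeSeriesBundle:
    """A dual-wavelength (or dual-chromophore) multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_times, n_channels, 2)
        Raw intensity (arbitrary units), optical density (dimensionless) or
        hemoglobin concentration change times pathlength (mM·mm), depending
        on ``kind``.
    sfreq : float
        Sampling rate in Hz.
    channel_ids : sequence of int
        Channel labels, aligned with axis 1 of ``data``.
    kind : {"intensity", "od", "hemoglobin"}
    """

    data: np.ndarray
    sfreq: float
    channel_ids: Sequence[int]
    kind: str = "intensity"
    wavelengths_nm: tuple[float, float] = (740.0, 850.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ValueError(
                f"data must have shape (n_times, n_channels, 2), got {self.data.shape}"
            )
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[1]} channels"
            )
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sfreq

    @property
    def duration_s(self) -> float:
        return self.n_times / self.sfreq

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "TimeSeriesBundle":
        """Return a copy, optionally replacing the data array and metadata."""
        out = replace(self, **kw)
        if data is not None:
            out.data = np.asarray(data, dtype=float)
            if out.data.shape[1] != len(out.channel_ids):
                raise ValueError("replacement data does not match channel ids")
        else:
            out.data = self.data.copy()
        return out

    def pick(self, channel_ids: Sequence[int]) -> "TimeSeriesBundle":
        """Return a new bundle restricted to ``channel_ids`` (given order)."""
        index = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in channel_ids if c not in index]
        if missing:
            raise ValueError(f"channels not in bundle: {missing}")
        cols = [index[c] for c in channel_ids]
        return TimeSeriesBundle(
            data=self.data[:, cols, :].copy(),
            sfreq=self.sfreq,
            channel_ids=list(channel_ids),
            kind=self.kind,
            wavelengths_nm=self.wavelengths_nm,
        )

    def channel(self, channel_id: int) -> np.ndarray:
        """Series of one channel, shape (n_times, 2)."""
        return self.data[:, list(self.channel_ids).index(channel_id), :]
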