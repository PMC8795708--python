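"""Intensity → optical density → motion correction → band-pass → modified
Beer–Lambert → resting-state PCA denoising.

Each stage is a scikit-learn style transformer operating on arrays shaped
``(n_times, n_channels)`` or ``(n_times, n_channels, 2)`` (trailing axis:
wavelength before the Beer–Lambert step, chromophore after). Module-level
functions are thin wrappers for one-shot use on
:class:`~nirslat.core.TimeSeriesBundle` objects.

Numerical conventions
---------------------
* Optical density uses the base-10 log against the channel's temporal mean
  intensity, so OD is zero-mean up to the log nonlinearity.
* The Beer–Lambert solve returns concentration change × pathlength in
  mM·mm: the 2×2 extinction system ``eps @ [HbO·L, HbR·L] = dOD / DPF`` is
  inverted per sample; the geometric separation is folded into the
  pathlength rather than divided out.
* The band-pass is a 3rd-order Butterworth applied forward–backward
  (zero phase), so block averages are not delayed.
* PCA denoising learns *spatial* eigenvectors of the channel covariance of
  a resting recording and projects them out of the task data, separately
  per chromophore. Eigenvectors with negligible eigenvalue (relative to the
  covariance trace) are skipped, so a silent resting recording removes
  nothing instead of removing arbitrary directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .config import PipelineConfig
from .core import TimeSeriesBundle

__all__ = [
    "MBLLParams",
    "ODConverter",
    "SplineSGCorrector",
    "BandpassFilter",
    "BeerLambertTransformer",
    "RestingPCADenoiser",
    "intensity_to_od",
    "detect_motion",
    "spline_sg_correct",
    "bandpass",
    "mbll",
    "mbll_forward",
    "pca_remove",
]


# ---------------------------------------------------------------------------
# helpers

def _as_2d(X: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Flatten trailing axes into columns; return (2-D view, original shape)."""
    X = np.asarray(X, dtype=float)
    shape = X.shape
    return X.reshape(shape[0], -1), shape


def _sliding_range(x: np.ndarray, w: int) -> np.ndarray:
    """Max−min inside every length-``w`` window, per column (O(n) filters)."""
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    hi = maximum_filter1d(x, w, axis=0, mode="nearest", origin=-(w // 2))
    lo = minimum_filter1d(x, w, axis=0, mode="nearest", origin=-(w // 2))
    return (hi - lo)[: x.shape[0] - w + 1]


def _whittaker(y: np.ndarray, lam: float) -> np.ndarray:
    """Discrete cubic smoothing spline on the sample grid: solve
    (I + lam DᵀD) f = y with D the second-difference operator (banded)."""
    from scipy.linalg import solveh_banded
    n = len(y)
    if n < 4:
        return np.full(n, y.mean())
    # upper bands of I + lam * D2.T @ D2 (pentadiagonal, symmetric)
    main = np.ones(n)
    main[0] = main[-1] = 1 + lam
    main[1] = main[-2] = 1 + 5 * lam
    main[2:-2] += 6 * lam
    off1 = np.full(n - 1, -4.0 * lam)
    off1[0] = off1[-1] = -2.0 * lam
    off2 = np.full(n - 2, lam)
    ab = np.zeros((3, n))
    ab[0, 2:] = off2
    ab[1, 1:] = off1
    ab[2, :] = main
    return solveh_banded(ab, y, lower=False)


@dataclass
class MBLLParams:
    """Parameters of the modified Beer–Lambert conversion.

    extinction : (2, 2) array — rows = wavelengths, columns = (HbO, HbR),
        base-10, in mm^-1 per mM.
    dpf : (2,) array — differential pathlength factor per wavelength.
    """

    wavelengths_nm: tuple[float, float] = (740.0, 850.0)
    extinction: np.ndarray | None = None
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        if self.extinction is None:
            from .config import EXTINCTION_740_850
            self.extinction = np.array(EXTINCTION_740_850)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be positive")

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "MBLLParams":
        return cls(
            wavelengths_nm=tuple(config.wavelengths_nm),
            extinction=np.array(config.extinction),
            dpf=tuple(config.dpf),
        )


# ---------------------------------------------------------------------------
# optical density

class ODConverter(TransformerMixin, BaseEstimator):
    """Convert raw intensity to optical density.

    OD(t) = -log10( I(t) / mean_t I ), per channel and wavelength.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X2, shape = _as_2d(X)
        bad = ~(X2 > 0)
        if bad.any():
            t, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive intensity at time index {t}, column {c}"
            )
        od = -np.log10(X2 / X2.mean(axis=0, keepdims=True))
        return od.reshape(shape)


# ---------------------------------------------------------------------------
# motion detection + spline-SG correction

def detect_motion(
    od: np.ndarray,
    sfreq: float,
    t_motion_s: float = 0.5,
    amp_thresh: float = 0.2,
    std_thresh: float = 4.0,
    mask_s: float = 1.0,
) -> list[list[tuple[int, int]]]:
    """Detect motion-artifact segments per column of a 2-D OD array.

    A sample is artifactual when the max−min excursion of its channel inside
    a sliding window of ``t_motion_s`` exceeds ``amp_thresh`` (absolute OD)
    or ``std_thresh`` times the channel's *median* moving excursion — a
    robust scale proxy that is insensitive to the artifacts themselves, to
    the channel's overall scale and to ever-present rhythms (cardiac), so
    only excursions far outside the channel's typical short-time variation
    fire. Flagged samples are dilated by ``mask_s`` and merged into
    half-open index segments ``(start, stop)``.
    """
    od2, _ = _as_2d(od)
    n, c = od2.shape
    # localization runs on a 2x-decimated stream (the +-mask_s dilation far
    # exceeds the localization granularity this costs)
    dec = 2
    xd = od2[::dec]
    w = max(2, int(round(t_motion_s * sfreq / dec)))
    if xd.shape[0] < w:
        return [[] for _ in range(c)]
    rng = _sliding_range(xd, w)
    scale = np.median(rng[::2], axis=0)  # subsampled median: robust + fast
    thresh = np.minimum(amp_thresh, std_thresh * scale)
    hit = rng > np.maximum(thresh, np.finfo(float).tiny)  # strict: flat -> clean
    pad = int(round(mask_s * sfreq))
    wlen = w * dec
    segments: list[list[tuple[int, int]]] = []
    for j in range(c):
        idx = np.flatnonzero(hit[:, j]) * dec
        segs: list[tuple[int, int]] = []
        for i in idx:
            lo, hi = max(0, int(i) - pad), min(n, int(i) + wlen + pad)
            if segs and lo <= segs[-1][1]:
                segs[-1] = (segs[-1][0], hi)
            else:
                segs.append((lo, hi))
        segments.append(segs)
    return segments


def _spline_correct_1d(x: np.ndarray, segs, sfreq: float, spline_p: float,
                       anchor_s: float = 2.0) -> np.ndarray:
    lam = (1.0 - spline_p) / spline_p
    out = x.copy()
    n = len(x)
    n_anchor = max(1, int(round(anchor_s * sfreq)))
    for s, e in segs:
        resid = out[s:e] - _whittaker(out[s:e], lam)
        if s > 0:
            anchor = out[max(0, s - n_anchor):s].mean()
        elif e < n:
            anchor = out[e:min(n, e + n_anchor)].mean()
        else:
            anchor = 0.0
        out[s:e] = resid + anchor
    return out


class SplineSGCorrector(TransformerMixin, BaseEstimator):
    """Spline-SG motion correction on optical density.

    Within each detected artifact segment a smoothing spline — the discrete
    second-difference-penalized form on the sample grid, with penalty
    ``lam = (1 − spline_p)/spline_p`` following the csaps ``p`` convention —
    is subtracted and the segment is re-anchored to the neighbouring
    baseline level; a Savitzky–Golay filter (window = ``frame_s`` seconds
    forced to an odd sample count, polynomial order 3) then smooths the
    full series.
    """

    def __init__(self, sfreq: float, frame_s: float = 6.0, spline_p: float = 0.99,
                 t_motion_s: float = 0.5, amp_thresh: float = 0.2,
                 std_thresh: float = 4.0, mask_s: float = 1.0, sg_order: int = 3):
        self.sfreq = sfreq
        self.frame_s = frame_s
        self.spline_p = spline_p
        self.t_motion_s = t_motion_s
        self.amp_thresh = amp_thresh
        self.std_thresh = std_thresh
        self.mask_s = mask_s
        self.sg_order = sg_order

    def fit(self, X, y=None):
        return self

    def _window(self, n: int) -> int:
        w = int(round(self.frame_s * self.sfreq))
        if w % 2 == 0:
            w += 1
        if w <= self.sg_order or w < 5:
            raise ValueError(
                f"frame_s={self.frame_s} too short at {self.sfreq} Hz for "
                f"order-{self.sg_order} Savitzky-Golay smoothing"
            )
        if n < w:
            raise ValueError("series shorter than the Savitzky-Golay window")
        return w

    def transform(self, X, segments=None) -> np.ndarray:
        X2, shape = _as_2d(X)
        w = self._window(X2.shape[0])
        if segments is None:
            segments = detect_motion(
                X2, self.sfreq, self.t_motion_s, self.amp_thresh,
                self.std_thresh, self.mask_s,
            )
        out = np.empty_like(X2)
        for j in range(X2.shape[1]):
            segs = segments[j] if j < len(segments) else []
            out[:, j] = _spline_correct_1d(
                X2[:, j], segs, self.sfreq, self.spline_p
            )
        out = signal.savgol_filter(out, w, self.sg_order, axis=0)
        return out.reshape(shape)


# ---------------------------------------------------------------------------
# band-pass

class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth band-pass (default 0.008–0.5 Hz, order 3)."""

    def __init__(self, sfreq: float, low_hz: float = 0.008, high_hz: float = 0.5,
                 order: int = 3):
        self.sfreq = sfreq
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        nyq = self.sfreq / 2.0
        if not 0 < self.low_hz < self.high_hz < nyq:
            raise ValueError(
                f"infeasible band [{self.low_hz}, {self.high_hz}] Hz at "
                f"{self.sfreq} Hz sampling"
            )
        X2, shape = _as_2d(X)
        sos = signal.butter(
            self.order, [self.low_hz / nyq, self.high_hz / nyq],
            btype="bandpass", output="sos",
        )
        out = signal.sosfiltfilt(sos, X2, axis=0)
        return out.reshape(shape)


# ---------------------------------------------------------------------------
# modified Beer-Lambert law

class BeerLambertTransformer(TransformerMixin, BaseEstimator):
    """Solve the 2×2 extinction system per sample: OD → (HbO·L, HbR·L)."""

    def __init__(self, params: MBLLParams | None = None):
        self.params = params

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        p = self.params or MBLLParams()
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected OD with shape (n_times, n_channels, 2)")
        scaled = X / np.asarray(p.dpf)  # broadcast over wavelength axis
        inv = np.linalg.inv(p.extinction)
        out = scaled.reshape(-1, 2) @ inv.T  # (t*c, wl) @ (wl -> chrom)
        return out.reshape(X.shape)


def mbll_forward(hemo: np.ndarray, params: MBLLParams | None = None) -> np.ndarray:
    """Inverse of :class:`BeerLambertTransformer`: (HbO·L, HbR·L) → OD."""
    p = params or MBLLParams()
    hemo = np.asarray(hemo, dtype=float)
    out = hemo.reshape(-1, 2) @ p.extinction.T
    return out.reshape(hemo.shape) * np.asarray(p.dpf)


# ---------------------------------------------------------------------------
# resting-state PCA denoising

class RestingPCADenoiser(TransformerMixin, BaseEstimator):
    """Remove globally covarying physiology learned from a resting recording.

    fit(X_rest) computes, separately for each trailing slice (chromophore),
    the leading ``n_components`` spatial eigenvectors of the channel
    covariance of the resting data; transform(X_task) projects those
    directions out of the task data: ``X − X U Uᵀ``.
    """

    def __init__(self, n_components: int = 2, eig_rtol: float = 1e-10,
                 var_floor: float = 1e-30):
        self.n_components = n_components
        self.eig_rtol = eig_rtol
        self.var_floor = var_floor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        n_ch = X.shape[1]
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        if self.n_components >= n_ch and self.n_components > 0:
            raise ValueError(
                f"n_components={self.n_components} must be < n_channels={n_ch}"
            )
        comps = []
        for k in range(X.shape[2]):
            Xc = X[:, :, k] - X[:, :, k].mean(axis=0, keepdims=True)
            cov = Xc.T @ Xc / max(1, Xc.shape[0] - 1)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            trace = max(evals.sum(), np.finfo(float).tiny)
            # both relative (degenerate directions) and absolute (numerical
            # dust from a silent recording) floors must be cleared
            keep = (evals > self.eig_rtol * trace) & (evals > self.var_floor)
            U = evecs[:, : self.n_components]
            U = U[:, keep[: self.n_components]]
            comps.append(U)
        self.components_ = comps
        self.n_channels_ = n_ch
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise RuntimeError("RestingPCADenoiser must be fit on resting data first")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[:, :, None]
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"task data has {X.shape[1]} channels, resting fit had "
                f"{self.n_channels_}"
            )
        out = np.empty_like(X)
        for k in range(X.shape[2]):
            U = self.components_[min(k, len(self.components_) - 1)]
            Xk = X[:, :, k]
            out[:, :, k] = Xk - (Xk @ U) @ U.T
        return out[:, :, 0] if squeeze else out


# ---------------------------------------------------------------------------
# functional wrappers

def intensity_to_od(bundle: TimeSeriesBundle) -> TimeSeriesBundle:
    if bundle.kind != "intensity":
        raise ValueError(f"expected an intensity bundle, got {bundle.kind!r}")
    od = ODConverter().fit_transform(bundle.data)
    return bundle.copy_with(data=od, kind="od")


def spline_sg_correct(od: TimeSeriesBundle, segments=None, *, frame_s: float = 6.0,
                      spline_p: float = 0.99, **detect_kw) -> TimeSeriesBundle:
    corr = SplineSGCorrector(od.sfreq, frame_s=frame_s, spline_p=spline_p,
                             **detect_kw)
    n_wl = od.data.shape[2]
    flat_segments = segments
    if segments is not None and len(segments) == od.n_channels and n_wl > 1:
        # per-channel segments apply to every wavelength column of that
        # channel (2-D column order is (c0,wl0), (c0,wl1), (c1,wl0), ...)
        flat_segments = [segments[j // n_wl] for j in range(od.n_channels * n_wl)]
    out = corr.transform(od.data, segments=flat_segments)
    return od.copy_with(data=out)


def bandpass(bundle: TimeSeriesBundle, low_hz: float = 0.008, high_hz: float = 0.5,
             order: int = 3) -> TimeSeriesBundle:
    out = BandpassFilter(bundle.sfreq, low_hz, high_hz, order).transform(bundle.data)
    return bundle.copy_with(data=out)


def mbll(od: TimeSeriesBundle, params: MBLLParams | None = None) -> TimeSeriesBundle:
    hemo = BeerLambertTransformer(params).transform(od.data)
    return od.copy_with(data=hemo, kind="hemoglobin")


def pca_remove(task: TimeSeriesBundle, resting: TimeSeriesBundle,
               n_components: int = 2) -> TimeSeriesBundle:
    if list(task.channel_ids) != list(resting.channel_ids):
        raise ValueError("task and resting bundles must share the channel set")
    den = RestingPCADenoiser(n_components).fit(resting.data)
    return task.copy_with(data=den.transform(task.data))
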