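"""Heart-rate-variability features for AF RR-interval windows.

Per 30-minute window this module computes the nine short-window metrics
(meanNN, SDNN, RMSSD, NN50, pNN50, LF, HF, LF/HF, TP) and, over the whole
recording, the long-term RR and heart-rate summaries (minRR/maxRR/avgRR,
minHR/maxHR/avgHR, meanRMSSD).

In persistent AF the beat-to-beat series is irregularly irregular, so the
short-window metrics are used as aggregate surrogates of autonomic burden
rather than as sinus-rhythm HRV. Degenerate windows (fewer than two valid
intervals) carry the sentinel value -1 in every metric and are flagged
invalid; frequency metrics additionally fall back to the sentinel when the
window does not hold enough interpolable tachogram for spectral estimation.

Frequency-domain defaults follow standard HRV practice (none are dictated
by the device): tachogram resampled at 4 Hz by linear interpolation, Welch
PSD with 5-min Hann segments at 50% overlap and linear detrending, band
edges LF 0.04-0.15 Hz, HF 0.15-0.40 Hz, TP 0.0033-0.40 Hz. Powers are in
ms^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .errors import InsufficientDataError
from .preprocessing import RRSeries, Window

__all__ = [
    "SENTINEL",
    "HRV_SEQUENCE_FEATURES",
    "SpectralConfig",
    "HRVWindowFeatures",
    "LongTermSummary",
    "time_domain",
    "frequency_domain",
    "window_features",
    "long_term_summary",
]

SENTINEL = -1.0

HRV_SEQUENCE_FEATURES = (
    "meanNN",
    "SDNN",
    "RMSSD",
    "NN50",
    "pNN50",
    "LF",
    "HF",
    "LF_HF",
    "TP",
)

_TIME_KEYS = ("meanNN", "SDNN", "RMSSD", "NN50", "pNN50")
_FREQ_KEYS = ("LF", "HF", "LF_HF", "TP")


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimator settings for the frequency-domain metrics."""

    resample_hz: float = 4.0
    segment_s: float = 300.0
    overlap: float = 0.5
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    tp_band: tuple[float, float] = (0.0033, 0.40)
    #: minimum tachogram coverage (s) for spectral estimation
    min_coverage_s: float = 300.0


@dataclass(frozen=True)
class HRVWindowFeatures:
    """The nine per-window metrics plus validity bookkeeping."""

    window_index: int
    start_ms: int
    valid: bool
    meanNN: float
    SDNN: float
    RMSSD: float
    NN50: float
    pNN50: float
    LF: float
    HF: float
    LF_HF: float
    TP: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in HRV_SEQUENCE_FEATURES}


@dataclass(frozen=True)
class LongTermSummary:
    """Whole-recording RR and heart-rate summaries.

    HR values are instantaneous-rate transforms of the RR summaries
    (HR = 60000 / RR in bpm), so minHR pairs with maxRR and vice versa.
    ``meanRMSSD`` averages RMSSD over valid windows only and is -1 when no
    window is valid (``all_windows_invalid`` flags that case).
    """

    minRR: float
    maxRR: float
    avgRR: float
    minHR: float
    maxHR: float
    avgHR: float
    meanRMSSD: float
    all_windows_invalid: bool = False


def time_domain(rr: RRSeries | np.ndarray) -> dict[str, float]:
    """Time-domain metrics of one window; sentinel block if <2 intervals.

    meanNN/SDNN in ms (SDNN is the n-1 sample standard deviation), RMSSD
    the root mean square of successive differences, NN50 the count of
    absolute successive differences strictly greater than 50 ms, pNN50 that
    count as a percentage of the n-1 differences.
    """
    x = rr.rr_ms if isinstance(rr, RRSeries) else np.asarray(rr, dtype=np.float64)
    if x.size < 2:
        return {k: SENTINEL for k in _TIME_KEYS}
    d = np.diff(x)
    nn50 = float(np.sum(np.abs(d) > 50.0))
    return {
        "meanNN": float(np.mean(x)),
        "SDNN": float(np.std(x, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "NN50": nn50,
        "pNN50": 100.0 * nn50 / d.size,
    }


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    # half-open [lo, hi) so adjacent bands (LF/HF at 0.15 Hz) never double count
    sel = (freqs >= band[0]) & (freqs < band[1])
    if np.count_nonzero(sel) < 2:
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def frequency_domain(
    rr: RRSeries, config: SpectralConfig = SpectralConfig()
) -> dict[str, float]:
    """Frequency-domain metrics of one window; sentinel block when the
    window has insufficient data for spectral estimation.

    The RR tachogram (interval value against onset time) is linearly
    interpolated onto an even grid, detrended, and its Welch PSD integrated
    over the LF/HF/TP bands. "Insufficient" means fewer than two intervals
    or less than ``min_coverage_s`` of interpolable tachogram. An HF power
    of exactly zero makes LF/HF undefined; the sentinel is emitted for the
    ratio (with a warning) to keep feature matrices finite.
    """
    if len(rr) < 2:
        return {k: SENTINEL for k in _FREQ_KEYS}
    t = rr.onsets_ms / 1000.0
    coverage = t[-1] - t[0]
    if coverage < config.min_coverage_s:
        return {k: SENTINEL for k in _FREQ_KEYS}
    fs = config.resample_hz
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = np.interp(grid, t, rr.rr_ms)
    x = x - np.mean(x)
    nperseg = min(x.size, int(config.segment_s * fs))
    freqs, psd = welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * config.overlap),
        detrend="linear",
    )
    lf = _band_power(freqs, psd, config.lf_band)
    hf = _band_power(freqs, psd, config.hf_band)
    tp = _band_power(freqs, psd, config.tp_band)
    if hf == 0.0:
        warnings.warn("HF power is zero; LF/HF set to sentinel", stacklevel=2)
        lf_hf = SENTINEL
    else:
        lf_hf = lf / hf
    return {"LF": lf, "HF": hf, "LF_HF": lf_hf, "TP": tp}


def window_features(
    window: Window, config: SpectralConfig = SpectralConfig()
) -> HRVWindowFeatures:
    """All nine metrics for one window.

    ``valid`` is False iff the window has fewer than two intervals, in
    which case every metric is the sentinel.
    """
    td = time_domain(window.rr)
    fd = frequency_domain(window.rr, config)
    valid = len(window.rr) >= 2
    return HRVWindowFeatures(
        window_index=window.index,
        start_ms=window.start_ms,
        valid=valid,
        **td,
        **fd,
    )


def long_term_summary(
    full: RRSeries, windows: list[HRVWindowFeatures]
) -> LongTermSummary:
    """Whole-recording RR/HR summaries plus meanRMSSD over valid windows."""
    if full.is_empty:
        raise InsufficientDataError("cannot summarise an empty RR series")
    rr = full.rr_ms
    min_rr, max_rr, avg_rr = float(np.min(rr)), float(np.max(rr)), float(np.mean(rr))
    valid_rmssd = [w.RMSSD for w in windows if w.valid]
    all_invalid = len(valid_rmssd) == 0
    return LongTermSummary(
        minRR=min_rr,
        maxRR=max_rr,
        avgRR=avg_rr,
        minHR=60000.0 / max_rr,
        maxHR=60000.0 / min_rr,
        avgHR=60000.0 / avg_rr,
        meanRMSSD=SENTINEL if all_invalid else float(np.mean(valid_rmssd)),
        all_windows_invalid=all_invalid,
    )
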