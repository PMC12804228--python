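"""Acoustic-emission feature extraction: spectra, band percentiles, RMS.

Two feature families are computed from the raw AE voltage waveform:

* frequency domain — a one-sided amplitude spectrum of the whole record,
  optionally cleaned of singular reversal-noise peaks, summarized by the
  90th-percentile magnitude in the 120-160 kHz band of interest;
* time domain — a windowed RMS envelope (0.01 s non-overlapping windows,
  20,000 samples at 2 MSa/s), segmented into strokes and summarized with
  the same static (95th percentile) / dynamic (median) statistics as the
  friction coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    NotSegmentableError,
    ParameterError,
    ValidationError,
)
from .friction import (
    Stroke,
    StrokeFeatures,
    percentile,
    split_static_dynamic,
)

logger = logging.getLogger(__name__)

DEFAULT_BAND = (120_000.0, 160_000.0)
DEFAULT_BAND_PERCENTILE = 90.0
DEFAULT_WINDOW_SAMPLES = 20_000

# Spectral smoothing defaults.  Prominence/height thresholds apply on the
# peak-normalized scale (spectrum maximum = 1).  The separation distance is
# stored in Hz — 50,000 bins of a 30 s record at 2 MSa/s correspond to
# about 1.67 kHz — and converted to bins per record, so the same physical
# criterion applies to records of any length.
DEFAULT_PROMINENCE_RANGE = (0.01, 0.1)
DEFAULT_MIN_HEIGHT = 0.015
DEFAULT_MIN_DISTANCE_HZ = 1_670.0

# Self-mode stroke segmentation of RMS profiles.
DEFAULT_VALLEY_FRACTION = 0.2   # of the profile's 95th percentile
DEFAULT_SMOOTH_WINDOWS = 5       # moving-average span before valley search
DEFAULT_MIN_STROKE_WINDOWS = 4


@dataclass
class AERecording:
    """Single-channel AE voltage waveform."""

    samples: np.ndarray
    rate: float = 2e6
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("AE waveform must be a non-empty 1-D array")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")

    def __len__(self):
        return len(self.samples)


@dataclass
class SpectralProfile:
    """One-sided amplitude spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    normalization: str = "amplitude"
    smoothed: bool = False
    removed_peaks: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.freqs) != len(self.magnitudes):
            raise ValidationError("freqs and magnitudes must have equal length")

    @property
    def df(self) -> float:
        """Bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def normalized(self) -> "SpectralProfile":
        """Copy rescaled to a maximum magnitude of 1."""
        peak = self.magnitudes.max()
        mags = self.magnitudes / peak if peak > 0 else self.magnitudes.copy()
        return SpectralProfile(self.freqs, mags, "peak-normalized", self.smoothed,
                               list(self.removed_peaks))


@dataclass
class RMSProfile:
    """Windowed RMS envelope: one value per non-overlapping window."""

    values: np.ndarray
    time: np.ndarray
    window_samples: int
    rate: float
    meta: dict = field(default_factory=dict)

    @property
    def window_seconds(self) -> float:
        return self.window_samples / self.rate

    def __len__(self):
        return len(self.values)


def compute_fft_spectrum(rec: AERecording) -> SpectralProfile:
    """One-sided amplitude spectrum of the full record.

    Magnitudes are scaled so a unit-amplitude sinusoid at a bin frequency
    yields magnitude 1 at that bin (``2 |X_k| / n``, halved at DC and
    Nyquist).  Deterministic; raises for records of fewer than 2 samples.
    """
    n = len(rec)
    if n < 2:
        raise ParameterError("need at least 2 samples for a spectrum")
    spec = np.fft.rfft(rec.samples)
    mags = np.abs(spec) * 2.0 / n
    mags[0] /= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / rec.rate)
    return SpectralProfile(freqs=freqs, magnitudes=mags)


def spectral_energy(sp: SpectralProfile, n_samples: int) -> float:
    """Time-domain-equivalent energy ``sum(x^2)`` from an amplitude spectrum.

    Parseval's identity for the one-sided amplitude scaling used by
    :func:`compute_fft_spectrum`.
    """
    a = sp.magnitudes.astype(float)
    n = n_samples
    e = a[0] ** 2
    if n % 2 == 0:
        e += a[-1] ** 2
        interior = a[1:-1]
    else:
        interior = a[1:]
    e += 0.5 * np.sum(interior**2)
    return float(n * e)


def smooth_spectrum(
    sp: SpectralProfile,
    prominence_range: tuple[float, float] = DEFAULT_PROMINENCE_RANGE,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_distance_hz: float = DEFAULT_MIN_DISTANCE_HZ,
    min_distance_bins: int | None = None,
) -> SpectralProfile:
    """Remove singular (reversal-noise) peaks from a spectrum.

    Peaks are detected on the peak-normalized scale with all three
    criteria of the cleaning rule: prominence inside ``prominence_range``,
    height above ``min_height`` and separation of at least the distance
    parameter from the nearest retained peak.  Detected peaks are replaced
    by linear interpolation between their prominence bases, never above
    the original magnitude; all other bins are returned bit-unchanged.

    ``min_distance_bins`` overrides the Hz-based distance for literal
    bin-count fidelity.
    """
    n = len(sp.magnitudes)
    if min_distance_bins is None:
        min_distance_bins = max(1, int(round(min_distance_hz / sp.df)))
    if min_distance_bins >= n:
        raise ParameterError(
            f"min distance of {min_distance_bins} bins >= spectrum length {n}"
        )
    peak_mag = sp.magnitudes.max()
    if peak_mag <= 0:
        return SpectralProfile(sp.freqs, sp.magnitudes.copy(), sp.normalization, True)
    norm = sp.magnitudes / peak_mag
    idx, props = find_peaks(
        norm,
        height=min_height,
        prominence=prominence_range,
        distance=min_distance_bins,
    )
    out = sp.magnitudes.copy()
    removed = []
    for i, lb, rb in zip(idx, props["left_bases"], props["right_bases"]):
        # prominence bases can stretch far along a flat baseline; clamp the
        # fill span so bins beyond the distance parameter stay untouched
        lb = max(int(lb), int(i) - min_distance_bins)
        rb = min(int(rb), int(i) + min_distance_bins)
        span = np.arange(lb + 1, rb)
        if span.size == 0:
            continue
        fill = np.interp(span, [lb, rb], [out[lb], out[rb]])
        out[span] = np.minimum(out[span], fill)
        removed.append(int(i))
    logger.debug("smooth_spectrum removed %d peak(s)", len(removed))
    return SpectralProfile(sp.freqs, out, sp.normalization, smoothed=True,
                           removed_peaks=removed)


def band_percentile(
    sp: SpectralProfile,
    band: tuple[float, float] = DEFAULT_BAND,
    pct: float = DEFAULT_BAND_PERCENTILE,
) -> float:
    """Percentile of spectral magnitude inside a closed frequency band."""
    lo, hi = band
    nyquist = float(sp.freqs[-1])
    if not (0 < lo < hi <= nyquist):
        raise ParameterError(f"band {band} outside (0, {nyquist:g}] Hz")
    sel = (sp.freqs >= lo) & (sp.freqs <= hi)
    if sel.sum() < 10:
        raise ParameterError(
            f"band {band} contains only {int(sel.sum())} bins (need >= 10)"
        )
    return percentile(sp.magnitudes[sel], pct)


def compute_rms_profile(
    rec: AERecording, window_samples: int = DEFAULT_WINDOW_SAMPLES
) -> RMSProfile:
    """Windowed RMS envelope: ``sqrt(sum(x^2)/n)`` per window.

    Windows are non-overlapping, aligned to sample 0; a trailing partial
    window is dropped (logged).
    """
    if window_samples < 1:
        raise ParameterError("window_samples must be >= 1")
    n_win = len(rec) // window_samples
    if n_win < 1:
        raise ParameterError(
            f"record of {len(rec)} samples shorter than one window "
            f"({window_samples})"
        )
    dropped = len(rec) - n_win * window_samples
    if dropped:
        logger.debug("dropping trailing partial window of %d samples", dropped)
    x = rec.samples[: n_win * window_samples].reshape(n_win, window_samples)
    values = np.sqrt(np.mean(x**2, axis=1))
    time = (np.arange(n_win) + 0.5) * window_samples / rec.rate
    return RMSProfile(values=values, time=time, window_samples=window_samples,
                      rate=rec.rate, meta=dict(rec.meta))


def _rms_cofseries(profile: RMSProfile):
    """Adapter: present an RMS profile as a COF-like series for the
    shared static/dynamic split."""
    from .friction import COFSeries

    n = len(profile)
    return COFSeries(
        time=profile.time,
        cof=profile.values.astype(float),
        valid=np.ones(n, dtype=bool),
        mask_reason=np.full(n, "valid"),
    )


def segment_rms_strokes(
    profile: RMSProfile,
    mode: str = "self",
    strokes: list[Stroke] | None = None,
    force_rate: float | None = None,
    valley_fraction: float = DEFAULT_VALLEY_FRACTION,
    smooth_windows: int = DEFAULT_SMOOTH_WINDOWS,
    min_stroke_windows: int = DEFAULT_MIN_STROKE_WINDOWS,
    trim_fraction: float = 0.05,
) -> list[Stroke]:
    """Segment an RMS profile into strokes.

    mode="self"
        Stroke boundaries are local minima of the moving-average-smoothed
        envelope lying below ``valley_fraction`` of the profile's 95th
        percentile.  Profiles without such valley structure — the
        behaviour of smooth planar substrates, whose sliding movements
        cannot be separated this way — raise :class:`NotSegmentableError`.
    mode="transfer"
        Stroke boundaries from the synchronized force recording are
        rescaled from force-sample indices to RMS-window indices
        (``force_rate`` required); directions carry over.

    In both modes the static/dynamic split is applied to the RMS values
    with the same first-peak rule as for the friction coefficient.
    """
    series = _rms_cofseries(profile)
    if mode == "transfer":
        if strokes is None or force_rate is None:
            raise ParameterError("transfer mode needs force strokes and force_rate")
        scale = 1.0 / (force_rate * profile.window_seconds)
        out = []
        n = len(profile)
        for st in strokes:
            a = int(round(st.start * scale))
            b = int(round(st.end * scale))
            a, b = max(0, a), min(n, b)
            if b - a < min_stroke_windows:
                logger.debug("transfer stroke [%d,%d) too short, dropped", a, b)
                continue
            out.append(Stroke(a, b, st.direction))
    elif mode == "self":
        if len(profile) < 2 * min_stroke_windows:
            raise NotSegmentableError("profile shorter than two strokes")
        kernel = np.ones(smooth_windows) / smooth_windows
        smoothed = np.convolve(profile.values, kernel, mode="same")
        threshold = valley_fraction * percentile(profile.values, 95.0)
        below = smoothed < threshold
        if not below.any():
            raise NotSegmentableError(
                "no valley below threshold: RMS profile is not friction-like "
                "(sliding movements cannot be separated)"
            )
        # one boundary per contiguous below-threshold region: its minimum
        boundaries = [0]
        i = 0
        n = len(profile)
        while i < n:
            if below[i]:
                j = i
                while j < n and below[j]:
                    j += 1
                boundaries.append(i + int(np.argmin(smoothed[i:j])))
                i = j
            else:
                i += 1
        boundaries.append(n)
        boundaries = sorted(set(boundaries))
        out = []
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a >= min_stroke_windows:
                out.append(Stroke(a, b, direction=0))
        if len(out) < 2:
            raise NotSegmentableError(
                "fewer than two envelope cycles found in RMS profile"
            )
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    for st in out:
        split_static_dynamic(st, series, trim_fraction)
    return out


def extract_stroke_rms(stroke: Stroke, profile: RMSProfile, stroke_id: int = 0) -> StrokeFeatures | None:
    """Static (95th-percentile) / dynamic (median) RMS of one stroke.

    Same statistics as the friction-coefficient extraction, applied to the
    RMS envelope.  Returns ``None`` for unusable strokes.
    """
    if not stroke.usable or stroke.static_span is None or stroke.dynamic_span is None:
        return None
    static_vals = profile.values[stroke.static_span[0]:stroke.static_span[1]]
    dynamic_vals = profile.values[stroke.dynamic_span[0]:stroke.dynamic_span[1]]
    if static_vals.size == 0 or dynamic_vals.size == 0:
        return None
    return StrokeFeatures(
        stroke_id=stroke_id,
        direction=stroke.direction,
        static_cof=percentile(static_vals, 95.0),
        dynamic_cof=percentile(dynamic_vals, 50.0),
    )


def analyze_ae_recording(
    rec: AERecording,
    window_samples: int | None = None,
    mode: str = "self",
    force_strokes: list[Stroke] | None = None,
    force_rate: float | None = None,
) -> pd.DataFrame:
    """RMS stroke-feature pipeline on one AE recording.

    Returns one row per usable stroke with ``static_rms`` / ``dynamic_rms``
    columns and the recording metadata attached.
    """
    if window_samples is None:
        window_samples = int(round(rec.rate * 0.01))  # 0.01 s windows
    profile = compute_rms_profile(rec, window_samples)
    strokes = segment_rms_strokes(
        profile, mode=mode, strokes=force_strokes, force_rate=force_rate
    )
    rows = []
    for k, st in enumerate(strokes):
        feat = extract_stroke_rms(st, profile, stroke_id=k)
        if feat is None:
            continue
        row = dict(rec.meta)
        row.update(
            stroke_id=k,
            direction=feat.direction,
            static_rms=feat.static_cof,
            dynamic_rms=feat.dynamic_cof,
        )
        rows.append(row)
    return pd.DataFrame(rows)
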