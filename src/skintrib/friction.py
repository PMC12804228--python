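"""Per-stroke static/dynamic coefficient-of-friction extraction.

The coefficient of friction (COF) is the ratio of the absolute lateral
(friction) force to the normal force, computed per sample.  A reciprocating
trial is segmented into strokes — maximal runs of consistent lateral-force
sign after hysteresis debouncing — and each stroke is split at its first
COF maximum into a static region (initial rise to the static peak) and a
dynamic region (kinetic plateau, with a trailing trim before reversal).
The stroke summary statistics are the 95th percentile of the static region
(static COF) and the median of the dynamic region (dynamic COF).

Index convention: 0-based, half-open spans ``[start, end)`` throughout.
The percentile convention is linear interpolation between closest order
statistics, applied identically everywhere a percentile is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, NoStrokesError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Default low-normal-force mask threshold (N): prevents COF blow-up when
#: the finger lifts off between strokes.
DEFAULT_MIN_NORMAL = 0.2

#: Hysteresis half-band (N) for the sign-based stroke segmentation.
DEFAULT_HYSTERESIS = 0.05

#: Minimum accepted stroke duration (s): 10 samples at 40 Hz.
DEFAULT_MIN_STROKE_DURATION = 0.25

#: Fraction of each stroke trimmed from the tail of the dynamic region
#: (deceleration into the direction reversal).
DEFAULT_TRIM_FRACTION = 0.05

STATIC_PERCENTILE = 95.0


def percentile(values, q):
    """Percentile with the package-wide linear-interpolation convention."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


@dataclass
class ForceRecording:
    """Synchronized normal/lateral force channels of one trial."""

    time: np.ndarray
    normal_force: np.ndarray
    lateral_force: np.ndarray
    rate: float = 40.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.normal_force = np.asarray(self.normal_force, dtype=float)
        self.lateral_force = np.asarray(self.lateral_force, dtype=float)
        n = len(self.time)
        if n < 2:
            raise ValidationError("force recording needs at least 2 samples")
        if len(self.normal_force) != n or len(self.lateral_force) != n:
            raise ValidationError("force channels must have equal length")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")

    def __len__(self):
        return len(self.time)


@dataclass
class COFSeries:
    """Per-sample COF with a validity mask.

    ``cof`` is NaN wherever ``valid`` is False; ``mask_reason`` is
    ``"valid"`` or ``"low-normal-force"`` per sample.
    """

    time: np.ndarray
    cof: np.ndarray
    valid: np.ndarray
    mask_reason: np.ndarray


@dataclass
class Stroke:
    """One sliding movement: ``[start, end)`` sample span and sub-spans."""

    start: int
    end: int
    direction: int
    static_span: tuple[int, int] | None = None
    dynamic_span: tuple[int, int] | None = None
    usable: bool = True
    note: str = ""

    def __len__(self):
        return self.end - self.start


@dataclass
class StrokeFeatures:
    """Summary statistics of one stroke."""

    stroke_id: int
    direction: int
    static_cof: float
    dynamic_cof: float
    meta: dict = field(default_factory=dict)


def compute_cof_series(rec: ForceRecording, min_normal: float = DEFAULT_MIN_NORMAL) -> COFSeries:
    """Per-sample COF = |lateral| / normal, masked at low normal force.

    Samples with ``normal < min_normal`` are masked (reason
    ``low-normal-force``) rather than producing unstable ratios.

    Raises
    ------
    EmptySeriesError
        If every sample is masked.
    """
    if min_normal <= 0:
        raise ParameterError("min_normal must be > 0")
    valid = rec.normal_force >= min_normal
    if not valid.any():
        raise EmptySeriesError(
            f"all {len(rec)} samples have normal force below {min_normal} N"
        )
    cof = np.full(len(rec), np.nan)
    cof[valid] = np.abs(rec.lateral_force[valid]) / rec.normal_force[valid]
    reason = np.where(valid, "valid", "low-normal-force")
    return COFSeries(time=rec.time, cof=cof, valid=valid, mask_reason=reason)


def segment_strokes(
    rec: ForceRecording,
    hysteresis: float = DEFAULT_HYSTERESIS,
    min_duration: float = DEFAULT_MIN_STROKE_DURATION,
) -> list[Stroke]:
    """Segment a recording into strokes by lateral-force sign.

    A Schmitt-trigger state machine debounces the sign: the direction
    flips only when the lateral force crosses ``+hysteresis`` or
    ``-hysteresis``, suppressing zero-crossing chatter at reversals.
    Runs shorter than ``min_duration`` are dropped (logged) and adjacent
    same-direction runs are merged.

    Raises
    ------
    NoStrokesError
        If no run of at least ``min_duration`` remains.
    """
    lat = rec.lateral_force
    state = 0
    states = np.empty(len(lat), dtype=np.int8)
    for i, v in enumerate(lat):
        if v > hysteresis:
            state = 1
        elif v < -hysteresis:
            state = -1
        states[i] = state

    # maximal runs of nonzero state
    runs: list[Stroke] = []
    start = None
    for i in range(len(states)):
        s = states[i]
        if start is None:
            if s != 0:
                start = i
        elif s != states[start]:
            runs.append(Stroke(start, i, int(states[start])))
            start = i if s != 0 else None
    if start is not None:
        runs.append(Stroke(start, len(states), int(states[start])))

    min_samples = max(1, int(round(min_duration * rec.rate)))
    kept: list[Stroke] = []
    for r in runs:
        if len(r) < min_samples:
            logger.debug("dropping %d-sample run at %d (min %d)", len(r), r.start, min_samples)
            continue
        if kept and kept[-1].direction == r.direction:
            kept[-1] = Stroke(kept[-1].start, r.end, r.direction)
        else:
            kept.append(r)
    if not kept:
        raise NoStrokesError(
            f"no stroke of at least {min_duration} s found in recording"
        )
    return kept


def split_static_dynamic(
    stroke: Stroke,
    series: COFSeries,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> Stroke:
    """Fill the static/dynamic sub-spans of a stroke.

    The static region runs from the stroke start to the first sample
    attaining the stroke's maximum COF (inclusive); the dynamic region is
    the remainder minus a trailing ``trim_fraction`` of the stroke.
    Strokes with fewer than 4 valid samples, or whose dynamic region would
    be empty, are flagged unusable instead of raising.
    """
    vals = series.cof[stroke.start:stroke.end]
    valid = series.valid[stroke.start:stroke.end]
    if valid.sum() < 4:
        stroke.usable = False
        stroke.note = "fewer than 4 valid samples"
        logger.debug("stroke at %d unusable: %s", stroke.start, stroke.note)
        return stroke
    masked = np.where(valid, vals, -np.inf)
    peak = int(np.argmax(masked))  # first index attaining the maximum
    trim = int(trim_fraction * len(stroke))
    dyn_end = stroke.end - trim
    dyn_start = stroke.start + peak + 1
    if dyn_start >= dyn_end or not series.valid[dyn_start:dyn_end].any():
        stroke.usable = False
        stroke.note = "empty dynamic region after peak/trim"
        logger.debug("stroke at %d unusable: %s", stroke.start, stroke.note)
        return stroke
    stroke.static_span = (stroke.start, stroke.start + peak + 1)
    stroke.dynamic_span = (dyn_start, dyn_end)
    return stroke


def extract_stroke_cof(stroke: Stroke, series: COFSeries, stroke_id: int = 0) -> StrokeFeatures | None:
    """Static (95th-percentile) and dynamic (median) COF of one stroke.

    Returns ``None`` for strokes flagged unusable or with no valid samples
    in either region.
    """
    if not stroke.usable or stroke.static_span is None or stroke.dynamic_span is None:
        return None
    s0, s1 = stroke.static_span
    d0, d1 = stroke.dynamic_span
    static_vals = series.cof[s0:s1][series.valid[s0:s1]]
    dynamic_vals = series.cof[d0:d1][series.valid[d0:d1]]
    if static_vals.size == 0 or dynamic_vals.size == 0:
        stroke.usable = False
        stroke.note = "no valid samples in a region"
        return None
    return StrokeFeatures(
        stroke_id=stroke_id,
        direction=stroke.direction,
        static_cof=percentile(static_vals, STATIC_PERCENTILE),
        dynamic_cof=percentile(dynamic_vals, 50.0),
    )


def analyze_force_recording(
    rec: ForceRecording,
    min_normal: float = DEFAULT_MIN_NORMAL,
    hysteresis: float = DEFAULT_HYSTERESIS,
    min_duration: float = DEFAULT_MIN_STROKE_DURATION,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
):
    """Full friction pipeline on one recording.

    Returns ``(features_df, strokes, series)`` where ``features_df`` has
    one row per usable stroke with the recording metadata attached.
    """
    series = compute_cof_series(rec, min_normal)
    strokes = segment_strokes(rec, hysteresis, min_duration)
    rows = []
    for k, st in enumerate(strokes):
        split_static_dynamic(st, series, trim_fraction)
        feat = extract_stroke_cof(st, series, stroke_id=k)
        if feat is None:
            continue
        row = dict(rec.meta)
        row.update(
            stroke_id=k,
            direction=feat.direction,
            static_cof=feat.static_cof,
            dynamic_cof=feat.dynamic_cof,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df, strokes, series


def summarize_features(features: pd.DataFrame, group_by, value: str = "dynamic_cof") -> pd.DataFrame:
    """Box-plot statistics of stroke features per group.

    For each group: n, median, quartiles, whiskers by the 1.5 x IQR rule
    (most extreme data point inside the fences) and the list of outliers
    beyond them.  No values are discarded — outliers are reported, not
    removed.  Empty groups are omitted with a warning.
    """
    if features.empty:
        raise EmptySeriesError("no usable stroke features to summarize")
    if isinstance(group_by, str):
        group_by = [group_by]
    rows = []
    for key, grp in features.groupby(list(group_by), sort=True):
        vals = grp[value].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("empty group %r omitted", key)
            continue
        q1 = percentile(vals, 25.0)
        q3 = percentile(vals, 75.0)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        row = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=int(vals.size),
            median=percentile(vals, 50.0),
            q1=q1,
            q3=q3,
            whisker_low=float(inside.min()) if inside.size else float("nan"),
            whisker_high=float(inside.max()) if inside.size else float("nan"),
            n_outliers=int(outliers.size),
            outliers=outliers.tolist(),
        )
        rows.append(row)
    return pd.DataFrame(rows)
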