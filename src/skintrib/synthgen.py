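"""Synthetic force, acoustic-emission and questionnaire data with planted truth.

This module emulates a finger-friction experiment in which a finger slides
reciprocally over a substrate at a controlled normal load while a force
plate records normal/lateral forces (40 Hz) and a piezoelectric sensor
records the acoustic emission (AE) released by the sliding contact at MHz
rates.  Every generated quantity has a known ground truth (planted friction
coefficients, stroke schedule, spectral band levels, sensory profiles) so
that the downstream extraction stages can be tested by parameter recovery
instead of against unreleased human-subject recordings.

The friction trace of one stroke follows the classic static-peak /
kinetic-plateau morphology: the lateral force ramps linearly to the static
peak ``mu_static * load`` over the first 20 % of the stroke, drops to the
kinetic plateau ``mu_dynamic * load``, and decays back to zero over the
final 5 % as the finger decelerates into the direction reversal.  Smooth
planar substrates optionally superimpose an 8 Hz stick-slip oscillation on
the plateau.  The AE waveform is white noise band-limited to 120-160 kHz
whose instantaneous amplitude follows the same stroke envelope, on top of
an unmodulated broadband noise floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidPlanError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical sensory attribute vocabulary, in fixed reporting order.
ATTRIBUTES = ("slippery", "soft", "rough", "thick", "greasy", "pleasant")

#: Aliases from descriptive prose names to the canonical attribute labels.
ATTRIBUTE_ALIASES = {
    "stickiness": "slippery",
    "softness": "soft",
    "roughness": "rough",
    "thickness": "thick",
    "greasiness": "greasy",
    "overall feeling": "pleasant",
    "pleasantness": "pleasant",
}

#: Shortest physically plausible stroke (s); also the segmentation floor.
MIN_STROKE_DURATION = 0.25

#: Stroke envelope geometry: ramp fraction to the static peak, terminal
#: decay fraction before direction reversal.
RAMP_FRACTION = 0.20
DECAY_FRACTION = 0.05

#: Stick-slip modulation frequency (Hz) on the kinetic plateau.
STICK_SLIP_FREQ = 8.0

#: Normal-load tracking error: Gaussian sd and sinusoidal drift, both as
#: fractions of the target load; drift frequency in Hz.
LOAD_NOISE_REL = 0.05
LOAD_DRIFT_REL = 0.05
LOAD_DRIFT_FREQ = 0.1

#: Additive lateral-force sensor noise (N); kept below the 0.05 N
#: segmentation hysteresis band.
LATERAL_NOISE_N = 0.02

#: AE band of interest (Hz).
AE_BAND = (120_000.0, 160_000.0)


@dataclass(frozen=True)
class MaterialSpec:
    """Physical and sensory ground truth for one substrate.

    Parameters
    ----------
    name : str
        Material label.
    mu_static, mu_dynamic : float
        Planted static / dynamic coefficients of friction
        (``mu_static >= mu_dynamic >= 0``).
    stick_slip : bool
        Whether the kinetic plateau carries a stick-slip oscillation.
    stick_slip_amplitude : float
        Oscillation amplitude as a fraction of the plateau force.
    ae_band_level : float
        Amplitude (arbitrary units) of the stroke-modulated AE noise in the
        120-160 kHz band.
    ae_out_of_band_level : float
        Amplitude of the unmodulated broadband noise floor.
    sensory_profile : dict
        Mean rating per attribute on the 1-10 interval scale.
    """

    name: str
    mu_static: float
    mu_dynamic: float
    ae_band_level: float
    ae_out_of_band_level: float
    sensory_profile: dict = field(default_factory=dict)
    stick_slip: bool = False
    stick_slip_amplitude: float = 0.0

    def __post_init__(self):
        if self.mu_static < 0 or self.mu_dynamic < 0:
            raise ValidationError("friction coefficients must be >= 0")
        if self.mu_static < self.mu_dynamic:
            raise ValidationError(
                f"{self.name}: mu_static ({self.mu_static}) < mu_dynamic "
                f"({self.mu_dynamic})"
            )
        if self.ae_band_level < 0 or self.ae_out_of_band_level < 0:
            raise ValidationError("AE levels must be >= 0")
        if self.stick_slip_amplitude < 0:
            raise ValidationError("stick_slip_amplitude must be >= 0")
        for attr, mean in self.sensory_profile.items():
            if attr not in ATTRIBUTES:
                raise ValidationError(f"unknown sensory attribute {attr!r}")
            if not 1.0 <= mean <= 10.0:
                raise ValidationError(
                    f"{self.name}: sensory mean for {attr!r} outside [1, 10]"
                )


def _profile(slippery, soft, rough, thick, greasy, pleasant):
    return dict(zip(ATTRIBUTES, (slippery, soft, rough, thick, greasy, pleasant)))


#: Default presets for the six study substrates: three fabrics (cotton
#: terry, polycotton knit, cotton woven) and three planar anchors (PET
#: film, glazed enamel, PTFE tape).  Friction medians are ordered
#: PET > enamel > PTFE ~ terry > knit ~ woven with all fabrics below 0.5,
#: AE band levels inversely; knit and woven share mu_dynamic exactly so
#: that friction alone cannot distinguish them while their AE levels can.
#: The exact numbers are fixture choices, not measured values.
PRESETS: dict[str, MaterialSpec] = {
    "cotton_terry": MaterialSpec(
        "cotton_terry", mu_static=0.62, mu_dynamic=0.46,
        ae_band_level=0.40, ae_out_of_band_level=0.02,
        sensory_profile=_profile(4.5, 5.0, 8.0, 7.0, 2.0, 6.5),
    ),
    "polycotton_knit": MaterialSpec(
        "polycotton_knit", mu_static=0.50, mu_dynamic=0.35,
        ae_band_level=0.80, ae_out_of_band_level=0.02,
        sensory_profile=_profile(4.0, 7.0, 4.0, 5.0, 3.0, 6.0),
    ),
    "cotton_woven": MaterialSpec(
        "cotton_woven", mu_static=0.48, mu_dynamic=0.35,
        ae_band_level=1.20, ae_out_of_band_level=0.02,
        sensory_profile=_profile(3.5, 7.5, 3.0, 4.0, 3.0, 5.0),
    ),
    "pet_film": MaterialSpec(
        "pet_film", mu_static=1.50, mu_dynamic=0.90,
        stick_slip=True, stick_slip_amplitude=0.25,
        ae_band_level=0.05, ae_out_of_band_level=0.10,
        sensory_profile=_profile(8.0, 2.0, 2.0, 2.0, 6.0, 4.0),
    ),
    "enamel": MaterialSpec(
        "enamel", mu_static=1.10, mu_dynamic=0.75,
        stick_slip=True, stick_slip_amplitude=0.20,
        ae_band_level=0.10, ae_out_of_band_level=0.12,
        sensory_profile=_profile(8.5, 1.5, 1.5, 3.0, 5.0, 5.0),
    ),
    "ptfe": MaterialSpec(
        "ptfe", mu_static=0.70, mu_dynamic=0.50,
        stick_slip=True, stick_slip_amplitude=0.15,
        ae_band_level=0.20, ae_out_of_band_level=0.15,
        sensory_profile=_profile(9.0, 3.0, 2.0, 2.0, 7.0, 5.5),
    ),
}

FABRICS = ("cotton_terry", "polycotton_knit", "cotton_woven")


@dataclass(frozen=True)
class TrialPlan:
    """Parameters of one simulated trial.

    Defaults reproduce the study conditions: a 30 s recording at a target
    load of 2, 3 or 4 N, force channels at 40 Hz and AE at 2 MSa/s.
    """

    target_load: float = 2.0
    duration: float = 30.0
    n_strokes: int = 10
    force_rate: float = 40.0
    ae_rate: float = 2e6
    seed: int = 0

    def __post_init__(self):
        if self.target_load not in (2.0, 3.0, 4.0):
            raise InvalidPlanError(
                f"target_load must be one of 2, 3, 4 N; got {self.target_load}"
            )
        if self.duration <= 0:
            raise InvalidPlanError("duration must be > 0")
        if self.n_strokes < 1:
            raise InvalidPlanError("n_strokes must be >= 1")
        if self.force_rate <= 0 or self.ae_rate <= 0:
            raise InvalidPlanError("sampling rates must be > 0")
        if self.n_strokes * MIN_STROKE_DURATION > self.duration:
            raise InvalidPlanError(
                f"{self.n_strokes} strokes of at least {MIN_STROKE_DURATION} s "
                f"do not fit in {self.duration} s"
            )


@dataclass(frozen=True)
class ScheduledStroke:
    """Ground-truth span of one sliding movement."""

    start_time: float
    end_time: float
    direction: int  # +1 left-to-right, -1 right-to-left

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def generate_stroke_schedule(plan: TrialPlan) -> list[ScheduledStroke]:
    """Tile the trial duration with alternating-direction strokes.

    Strokes partition ``[0, duration]`` uniformly; the first stroke moves
    left-to-right (+1).  Deterministic: the schedule depends only on the
    plan, so identical plans give identical schedules.
    """
    edges = np.linspace(0.0, plan.duration, plan.n_strokes + 1)
    return [
        ScheduledStroke(float(edges[k]), float(edges[k + 1]), 1 if k % 2 == 0 else -1)
        for k in range(plan.n_strokes)
    ]


def _stroke_envelope(m: int, mu_static: float, mu_dynamic: float) -> np.ndarray:
    """Friction envelope over the ``m`` samples of one stroke.

    Linear ramp 0 -> mu_static over the first RAMP_FRACTION of the stroke
    (the static peak is attained exactly at the last ramp sample), kinetic
    plateau mu_dynamic, then linear decay to 0 over the terminal
    DECAY_FRACTION as the finger decelerates into the reversal.
    """
    ramp_len = max(1, int(round(RAMP_FRACTION * m)))
    decay_len = max(1, int(round(DECAY_FRACTION * m)))
    if ramp_len + decay_len > m:  # degenerate, very short stroke
        ramp_len = max(1, m - 1)
        decay_len = m - ramp_len
    env = np.full(m, mu_dynamic, dtype=float)
    env[:ramp_len] = mu_static * np.arange(1, ramp_len + 1) / ramp_len
    env[m - decay_len:] = mu_dynamic * np.arange(decay_len - 1, -1, -1) / decay_len
    return env


def _envelope_trace(
    times: np.ndarray, strokes: list[ScheduledStroke], material: MaterialSpec,
    signed: bool,
) -> np.ndarray:
    """Dimensionless friction envelope (units of COF) sampled at ``times``.

    ``times`` must be ascending (sample grid); strokes are located with
    binary search so the cost stays linear in the trace length.
    """
    out = np.zeros_like(times)
    for s in strokes:
        a = int(np.searchsorted(times, s.start_time, side="left"))
        b = int(np.searchsorted(times, s.end_time, side="left"))
        if b <= a:
            continue
        m = b - a
        env = _stroke_envelope(m, material.mu_static, material.mu_dynamic)
        if material.stick_slip and material.stick_slip_amplitude > 0:
            ramp_len = max(1, int(round(RAMP_FRACTION * m)))
            decay_len = max(1, int(round(DECAY_FRACTION * m)))
            plateau = np.zeros(m, dtype=bool)
            plateau[ramp_len:m - decay_len] = True
            mod = 1.0 + material.stick_slip_amplitude * np.sin(
                2 * np.pi * STICK_SLIP_FREQ * times[a:b]
            )
            env = np.where(plateau, env * mod, env)
        out[a:b] = env * (s.direction if signed else 1)
    return out


def synthesize_force_recording(
    material: MaterialSpec,
    plan: TrialPlan,
    *,
    load_noise_rel: float = LOAD_NOISE_REL,
    drift_rel: float = LOAD_DRIFT_REL,
    lateral_noise_sd: float = LATERAL_NOISE_N,
    meta: dict | None = None,
):
    """Simulate one force-plate trial.

    Returns
    -------
    rec : ForceRecording
        Synchronized normal/lateral channels at ``plan.force_rate``.
    strokes : list of ScheduledStroke
        The planted stroke schedule (ground truth for recovery tests).

    Notes
    -----
    The normal channel tracks the target load with per-sample Gaussian
    error (sd ``load_noise_rel`` of the load) plus a slow sinusoidal drift
    (amplitude ``drift_rel`` of the load at 0.1 Hz), emulating imperfect
    manual load control.  Setting all three noise arguments to zero yields
    a noise-free trace whose plateau equals ``mu_dynamic * load`` exactly.
    """
    from .friction import ForceRecording  # local import avoids a cycle

    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration * plan.force_rate))
    t = np.arange(n) / plan.force_rate
    strokes = generate_stroke_schedule(plan)

    drift_phase = rng.uniform(0, 2 * np.pi)
    normal = plan.target_load * (
        1.0
        + load_noise_rel * rng.standard_normal(n)
        + drift_rel * np.sin(2 * np.pi * LOAD_DRIFT_FREQ * t + drift_phase)
    )
    lateral = _envelope_trace(t, strokes, material, signed=True) * plan.target_load
    if lateral_noise_sd > 0:
        lateral = lateral + lateral_noise_sd * rng.standard_normal(n)

    md = {"material": material.name, "target_load": plan.target_load}
    if meta:
        md.update(meta)
    rec = ForceRecording(
        time=t, normal_force=normal, lateral_force=lateral,
        rate=plan.force_rate, meta=md,
    )
    return rec, strokes


def _band_limited_noise(n: int, rate: float, band: tuple, rng) -> np.ndarray:
    """Unit-variance white Gaussian noise restricted to ``band``.

    Constructed in the frequency domain: the masked spectrum of white
    noise has independent complex-Gaussian coefficients on the in-band
    bins and zero elsewhere, so those coefficients are drawn directly and
    inverse-transformed — identical in distribution to filtering a
    time-domain white-noise draw, at a fraction of the cost.
    """
    f = np.fft.rfftfreq(n, 1.0 / rate)
    sel = (f >= band[0]) & (f <= band[1])
    spec = np.zeros(len(f), dtype=complex)
    m = int(sel.sum())
    spec[sel] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    y = np.fft.irfft(spec, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def synthesize_ae_recording(
    material: MaterialSpec,
    plan: TrialPlan,
    strokes: list[ScheduledStroke],
    *,
    meta: dict | None = None,
):
    """Simulate the AE waveform paired with a force trial.

    The in-band (120-160 kHz) component is white noise filtered in the
    frequency domain, amplitude-modulated by the stroke friction envelope
    normalized to peak 1, and scaled by ``material.ae_band_level``.  An
    unmodulated broadband floor of amplitude ``ae_out_of_band_level`` is
    added on top, so smooth substrates with a high floor produce an RMS
    profile without inter-stroke valleys.

    Raises
    ------
    ParameterError
        If ``plan.ae_rate`` is below 400 kHz (the 120-160 kHz band would
        violate the Nyquist limit).
    """
    from .acoustic import AERecording  # local import avoids a cycle

    if plan.ae_rate < 2 * AE_BAND[1]:
        raise ParameterError(
            f"ae_rate {plan.ae_rate:g} Hz cannot represent the "
            f"{AE_BAND[0]:g}-{AE_BAND[1]:g} Hz band (Nyquist)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0xAE]))
    n = int(round(plan.duration * plan.ae_rate))
    samples = np.zeros(n)
    if material.ae_band_level > 0:
        t = np.arange(n) / plan.ae_rate
        env = _envelope_trace(t, strokes, material, signed=False)
        peak = env.max()
        if peak > 0:
            env = env / peak
        samples += material.ae_band_level * env * _band_limited_noise(
            n, plan.ae_rate, AE_BAND, rng
        )
    if material.ae_out_of_band_level > 0:
        samples += material.ae_out_of_band_level * rng.standard_normal(n)

    md = {"material": material.name, "target_load": plan.target_load}
    if meta:
        md.update(meta)
    return AERecording(samples=samples, rate=plan.ae_rate, meta=md)


def generate_sensory_responses(
    materials: list[MaterialSpec],
    n_panellists: int = 8,
    noise_sd: float = 0.8,
    seed: int = 0,
):
    """Simulate a sensory questionnaire session.

    Each panellist rates every material on the six attributes: the planted
    material mean plus Gaussian panellist noise, then rescaled affinely
    (hence monotonically) per panellist and attribute so that the extreme
    grades 1 and 10 are each used at least once — the anchoring instruction
    given to real panellists — and clipped to [1, 10].

    Returns a :class:`~skintrib.sensory.SensoryTable`.
    """
    from .sensory import SensoryTable

    if n_panellists < 1:
        raise ParameterError("n_panellists must be >= 1")
    if len(materials) < 2:
        raise ParameterError("need at least 2 materials to anchor the scale")

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_panellists):
        panellist = f"P{p + 1:02d}"
        for attr in ATTRIBUTES:
            raw = np.array(
                [m.sensory_profile.get(attr, 5.0) for m in materials], float
            )
            raw = raw + noise_sd * rng.standard_normal(len(materials))
            lo, hi = raw.min(), raw.max()
            if hi > lo:
                ratings = np.clip(1.0 + 9.0 * (raw - lo) / (hi - lo), 1.0, 10.0)
            else:  # identical perceived level: scale cannot be anchored
                ratings = np.clip(raw, 1.0, 10.0)
            for m, r in zip(materials, ratings):
                rows.append((panellist, m.name, attr, float(r)))
    df = pd.DataFrame(rows, columns=["panellist", "material", "attribute", "rating"])
    return SensoryTable(df)


def preset(name: str, **overrides) -> MaterialSpec:
    """Fetch a default material preset, optionally overriding fields."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown material preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(spec, **overrides) if overrides else spec
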