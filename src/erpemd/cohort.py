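"""Synthetic infant visual-ERP cohort generator.

Emulates a face/gaze ERP study in 6–10-month-old infants: three groups
(low-risk controls, high-risk infants without a later ASD diagnosis, and
high-risk infants with one), six visual stimulus conditions, high-density
EEG epoched around stimulus onset, and the stereotyped infant
face-processing components P100, N290 and P400 over occipital channels.

Group differences are expressed the way the developmental-ERP literature
describes them: added peak latency on N290/P400 for the high-risk family
groups, a multiplicative amplitude scaling per group, and group-specific
power of stimulus-locked beta/gamma oscillatory bursts.  Trial-level
variability is 1/f-shaped background plus white noise.  No artifacts
(blinks, muscle, line noise, bridging) are modelled: the generator stands
in for data that has already been cleaned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "GROUPS",
    "GROUP_CONTROL",
    "GROUP_HR_NOASD",
    "GROUP_HR_ASD",
    "GROUP_HR_UNKNOWN",
    "ComponentSpec",
    "BandSpec",
    "EffectSpec",
    "CohortSpec",
    "EpochedRecording",
    "Cohort",
    "generate_trial",
    "generate_cohort",
]

#: Canonical stimulus conditions, in fixed order (dynamic gaze shifts,
#: static gaze photographs, a scrambled-face "face" contrast and a visual
#: noise control image).
CONDITIONS: tuple[str, ...] = (
    "direct_gaze",
    "averted_gaze",
    "static_direct",
    "static_averted",
    "face",
    "noise",
)

GROUP_CONTROL = "control"
GROUP_HR_NOASD = "HR-noASD"
GROUP_HR_ASD = "HR-ASD"
#: High-risk subject whose diagnostic outcome was never ascertained; such
#: subjects are dropped before the outcome analysis.
GROUP_HR_UNKNOWN = "HR-unknown"

GROUPS: tuple[str, ...] = (GROUP_CONTROL, GROUP_HR_NOASD, GROUP_HR_ASD)

#: Groups at high familial risk (an older diagnosed sibling).
HR_FAMILY_GROUPS = frozenset({GROUP_HR_NOASD, GROUP_HR_ASD, GROUP_HR_UNKNOWN})

# Mild deterministic per-condition gain so conditions are not copies of
# one another; the face-absent "noise" condition is handled separately.
_CONDITION_GAIN = {
    "direct_gaze": 1.05,
    "averted_gaze": 1.00,
    "static_direct": 0.95,
    "static_averted": 0.90,
    "face": 1.00,
    "noise": 0.0,
}


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a Gaussian bump in time.

    Polarity is carried by the sign of ``amplitude_uv``; ``width_ms`` is the
    Gaussian standard deviation.
    """

    latency_ms: float
    amplitude_uv: float
    width_ms: float
    #: Relative position (0..1) of the topography peak along the channel
    #: axis; occipital channels sit near the end of the index range here.
    topo_center: float = 0.85

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"width_ms must be > 0, got {self.width_ms}")


@dataclass(frozen=True)
class BandSpec:
    """A stimulus-locked band-limited oscillatory burst.

    ``amplitude_uv`` maps group name -> burst amplitude (µV, >= 0).  The
    burst is a Gabor packet: carrier at the band centre, Gaussian envelope
    whose spectral width stays inside [f_lo, f_hi].
    """

    f_lo: float
    f_hi: float
    amplitude_uv: Mapping[str, float]
    center_ms: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        for g, a in self.amplitude_uv.items():
            if a < 0:
                raise ValueError(f"band amplitude for {g!r} must be >= 0")

    def amplitude_for(self, group: str) -> float:
        key = group
        if key not in self.amplitude_uv and key in HR_FAMILY_GROUPS:
            # unknown-outcome HR subjects behave like generic HR
            key = GROUP_HR_NOASD
        return float(self.amplitude_uv.get(key, 0.0))


def _default_components() -> dict[str, ComponentSpec]:
    # Canonical infant face-processing morphology: positive P100,
    # negative N290, broad positive P400, all occipitally weighted.
    return {
        "P100": ComponentSpec(100.0, 4.0, 25.0, topo_center=0.88),
        "N290": ComponentSpec(290.0, -6.0, 45.0, topo_center=0.82),
        "P400": ComponentSpec(400.0, 5.0, 70.0, topo_center=0.78),
    }


def _uniform_scale() -> dict[str, float]:
    return {GROUP_CONTROL: 1.0, GROUP_HR_NOASD: 1.0, GROUP_HR_ASD: 1.0}


@dataclass(frozen=True)
class EffectSpec:
    """Group-effect model for the generator.

    Parameters
    ----------
    components
        Name -> ComponentSpec for the face-evoked bumps.
    group_latency_shift_ms
        Milliseconds added to the N290 and P400 peak latency for
        high-risk-family subjects (slowed face processing).
    group_amplitude_scale
        Multiplicative factor applied to all components, per group.
    osc_bands
        Name -> BandSpec for beta/gamma bursts with per-group power.
    topo_width
        Width (fraction of the channel axis) of each component's Gaussian
        channel-weight profile; weights lie in [0, 1].
    """

    components: Mapping[str, ComponentSpec] = field(default_factory=_default_components)
    group_latency_shift_ms: float = 0.0
    group_amplitude_scale: Mapping[str, float] = field(default_factory=_uniform_scale)
    osc_bands: Mapping[str, BandSpec] = field(
        default_factory=lambda: {
            "beta": BandSpec(13.0, 30.0, {g: 0.5 for g in GROUPS}),
            "gamma": BandSpec(30.0, 60.0, {g: 0.5 for g in GROUPS}, center_ms=150.0),
        }
    )
    topo_width: float = 0.12
    #: Components whose latency is shifted for HR-family subjects.
    shifted_components: tuple[str, ...] = ("N290", "P400")

    def __post_init__(self) -> None:
        if self.topo_width <= 0:
            raise ValueError("topo_width must be > 0")
        for g, s in self.group_amplitude_scale.items():
            if s < 0:
                raise ValueError(f"amplitude scale for {g!r} must be >= 0")

    def amplitude_scale_for(self, group: str) -> float:
        key = group
        if key not in self.group_amplitude_scale and key in HR_FAMILY_GROUPS:
            key = GROUP_HR_NOASD
        return float(self.group_amplitude_scale.get(key, 1.0))

    # ------------------------------------------------------------------
    # presets
    # ------------------------------------------------------------------
    @staticmethod
    def null() -> "EffectSpec":
        """No group differences at all: every group draws the same signal."""
        return EffectSpec()

    @staticmethod
    def strong() -> "EffectSpec":
        """Large, cleanly separable group effects.

        High-risk groups respond later (40 ms on N290/P400) and weaker,
        with elevated beta/gamma burst power; the two high-risk outcome
        groups differ from each other in burst power and amplitude scale.
        """
        return EffectSpec(
            group_latency_shift_ms=40.0,
            group_amplitude_scale={
                GROUP_CONTROL: 1.0,
                GROUP_HR_NOASD: 0.75,
                GROUP_HR_ASD: 0.55,
            },
            osc_bands={
                "beta": BandSpec(
                    13.0,
                    30.0,
                    {GROUP_CONTROL: 0.4, GROUP_HR_NOASD: 1.2, GROUP_HR_ASD: 2.0},
                ),
                "gamma": BandSpec(
                    30.0,
                    60.0,
                    {GROUP_CONTROL: 0.3, GROUP_HR_NOASD: 1.5, GROUP_HR_ASD: 2.6},
                    center_ms=150.0,
                ),
            },
        )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    Counts are per final analysis group; ``n_hr_unknown`` adds high-risk
    subjects with no ascertained outcome and ``n_forced_low_trials``
    deterministically forces that many subjects to draw fewer than 10
    trials in one condition, so the exclusion rule has something to do.
    """

    n_control: int = 44
    n_hr_noasd: int = 33
    n_hr_asd: int = 17
    n_channels: int = 128
    fs: float = 500.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    conditions: tuple[str, ...] = CONDITIONS
    trials_mean: float = 25.0
    p_low_trials: float = 0.0
    effect: EffectSpec = field(default_factory=EffectSpec.strong)
    noise_sd: float = 1.0
    seed: int = 0
    n_hr_unknown: int = 0
    n_forced_low_trials: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_hr_noasd", "n_hr_asd", "n_hr_unknown",
                     "n_forced_low_trials"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        lo, hi = self.epoch_window_ms
        if hi <= lo:
            raise ValueError("epoch_window_ms must satisfy lo < hi")
        span_samples = (hi - lo) * self.fs / 1000.0
        if abs(span_samples - round(span_samples)) > 1e-9:
            raise ValueError(
                "epoch_window_ms span must be an integer number of samples at fs"
            )
        if len(self.conditions) != 6 or len(set(self.conditions)) != 6:
            raise ValueError("conditions must contain exactly 6 unique names")
        if not 0.0 <= self.p_low_trials <= 1.0:
            raise ValueError("p_low_trials must be in [0, 1]")
        if self.trials_mean <= 0:
            raise ValueError("trials_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window_ms
        return int(round((hi - lo) * self.fs / 1000.0))

    @property
    def t0(self) -> int:
        """Sample index of stimulus onset."""
        return int(round(-self.epoch_window_ms[0] * self.fs / 1000.0))

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_hr_noasd + self.n_hr_asd + self.n_hr_unknown


@dataclass
class EpochedRecording:
    """Epoched trials for one subject in one stimulus condition."""

    subject_id: str
    condition: str
    data: np.ndarray  # (n_trials, n_channels, n_samples), µV
    fs: float
    t0: int  # sample index of stimulus onset

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class Cohort:
    """A generated cohort: recordings plus the subject -> group map."""

    spec: CohortSpec
    recordings: dict[tuple[str, str], EpochedRecording]
    labels: dict[str, str]

    @property
    def subjects(self) -> list[str]:
        return list(self.labels)

    def recording(self, subject_id: str, condition: str) -> EpochedRecording:
        return self.recordings[(subject_id, condition)]

    def subject_conditions(self, subject_id: str) -> dict[str, EpochedRecording]:
        return {
            c: self.recordings[(subject_id, c)]
            for c in self.spec.conditions
        }


# ----------------------------------------------------------------------
# waveform construction
# ----------------------------------------------------------------------

def _time_axis_ms(n_samples: int, fs: float, t0: int) -> np.ndarray:
    return (np.arange(n_samples) - t0) * 1000.0 / fs


def _topography(n_channels: int, center: float, width: float) -> np.ndarray:
    if n_channels == 1:
        return np.ones(1)
    pos = np.linspace(0.0, 1.0, n_channels)
    return np.exp(-0.5 * ((pos - center) / width) ** 2)


def deterministic_trial(
    effect: EffectSpec,
    group: str,
    condition: str,
    *,
    n_channels: int = 128,
    fs: float = 500.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0),
) -> np.ndarray:
    """Noise-free evoked part of a trial: components + oscillatory bursts.

    Shape (n_channels, n_samples).  The "noise" condition omits the face
    components but keeps the stimulus-locked bursts.
    """
    if condition not in _CONDITION_GAIN:
        raise ValueError(f"unknown condition {condition!r}")
    lo, hi = epoch_window_ms
    n_samples = int(round((hi - lo) * fs / 1000.0))
    t0 = int(round(-lo * fs / 1000.0))
    t_ms = _time_axis_ms(n_samples, fs, t0)
    out = np.zeros((n_channels, n_samples))

    gain = _CONDITION_GAIN[condition]
    if gain > 0:
        amp_scale = effect.amplitude_scale_for(group)
        is_hr = group in HR_FAMILY_GROUPS
        for name, comp in effect.components.items():
            lat = comp.latency_ms
            if is_hr and name in effect.shifted_components:
                lat = lat + effect.group_latency_shift_ms
            bump = np.exp(-0.5 * ((t_ms - lat) / comp.width_ms) ** 2)
            bump[t_ms < 0] = 0.0  # evoked activity is post-stimulus
            topo = _topography(n_channels, comp.topo_center, effect.topo_width)
            out += (
                gain * amp_scale * comp.amplitude_uv * topo[:, None] * bump[None, :]
            )

    for band in effect.osc_bands.values():
        amp = band.amplitude_for(group)
        if amp == 0.0:
            continue
        f_c = 0.5 * (band.f_lo + band.f_hi)
        # Gabor envelope: spectral sd = quarter of the band width keeps the
        # packet's energy inside [f_lo, f_hi].
        sd_f = (band.f_hi - band.f_lo) / 4.0
        sd_t_ms = 1000.0 / (2.0 * np.pi * sd_f)
        env = np.exp(-0.5 * ((t_ms - band.center_ms) / sd_t_ms) ** 2)
        env[t_ms < 0] = 0.0
        carrier = np.cos(2.0 * np.pi * f_c * (t_ms - band.center_ms) / 1000.0)
        topo = _topography(n_channels, 0.85, effect.topo_width)
        out += amp * topo[:, None] * (env * carrier)[None, :]

    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f-power-shaped Gaussian noise, unit standard deviation per channel."""
    n_ch, n_s = shape
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_s, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale[None, :], n=n_s, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_trial(
    effect: EffectSpec,
    group: str,
    condition: str,
    rng: np.random.Generator,
    *,
    n_channels: int = 128,
    fs: float = 500.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0),
    noise_sd: float = 1.0,
) -> np.ndarray:
    """One trial: deterministic evoked part + 1/f background + white noise."""
    det = deterministic_trial(
        effect, group, condition,
        n_channels=n_channels, fs=fs, epoch_window_ms=epoch_window_ms,
    )
    if noise_sd > 0:
        n_ch, n_s = det.shape
        det = (
            det
            + noise_sd * _pink_noise(rng, (n_ch, n_s), fs)
            + 0.5 * noise_sd * rng.standard_normal((n_ch, n_s))
        )
    return det


# ----------------------------------------------------------------------
# cohort assembly
# ----------------------------------------------------------------------

def _subject_groups(spec: CohortSpec) -> list[str]:
    return (
        [GROUP_CONTROL] * spec.n_control
        + [GROUP_HR_NOASD] * spec.n_hr_noasd
        + [GROUP_HR_ASD] * spec.n_hr_asd
        + [GROUP_HR_UNKNOWN] * spec.n_hr_unknown
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate every subject × condition recording for ``spec``.

    Bit-identical for identical specs (per-subject RNG streams are derived
    from ``spec.seed`` and the subject index, independent of iteration
    order).
    """
    groups = _subject_groups(spec)
    n_sub = len(groups)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_sub)]
    labels = dict(zip(subject_ids, groups))

    master = np.random.default_rng(spec.seed)
    # subjects forced to violate the 10-trial rule are drawn from the
    # control group, so trial-count exclusions never overlap the
    # missing-outcome ones and the per-group arithmetic stays exact
    controls = [i for i, g in enumerate(groups) if g == GROUP_CONTROL]
    if spec.n_forced_low_trials > len(controls):
        raise ValueError("n_forced_low_trials exceeds n_control")
    forced = set(
        master.choice(controls, size=spec.n_forced_low_trials, replace=False).tolist()
    )

    recordings: dict[tuple[str, str], EpochedRecording] = {}
    for i, (sid, group) in enumerate(zip(subject_ids, groups)):
        rng = np.random.default_rng((spec.seed, 7919, i))
        forced_cond = (
            int(rng.integers(len(spec.conditions))) if i in forced else -1
        )
        for j, cond in enumerate(spec.conditions):
            low = j == forced_cond or (
                spec.p_low_trials > 0 and rng.random() < spec.p_low_trials
            )
            if low:
                n_trials = int(rng.integers(1, 10))
            else:
                n_trials = max(10, int(rng.poisson(spec.trials_mean)))
            trials = np.stack(
                [
                    generate_trial(
                        spec.effect, group, cond, rng,
                        n_channels=spec.n_channels,
                        fs=spec.fs,
                        epoch_window_ms=spec.epoch_window_ms,
                        noise_sd=spec.noise_sd,
                    )
                    for _ in range(n_trials)
                ]
            )
            recordings[(sid, cond)] = EpochedRecording(
                subject_id=sid,
                condition=cond,
                data=trials,
                fs=spec.fs,
                t0=spec.t0,
            )
    return Cohort(spec=spec, recordings=recordings, labels=labels)


def with_effect(spec: CohortSpec, effect: EffectSpec) -> CohortSpec:
    """Copy of ``spec`` with a different effect model."""
    return replace(spec, effect=effect)
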