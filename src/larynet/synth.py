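"""Seeded synthesis of multichannel laryngeal recordings.

Emulates what a skin-mounted throat patch measures: a triaxial accelerometer
(ax, ay, az in units of g) plus one surface-EMG channel (arbitrary units),
sampled at a nominal 333 Hz.  The z axis (normal to the skin) carries cardiac
micro-vibrations and laryngeal events (speech, swallowing, drinking,
coughing); the y axis (neck-to-head) carries respiratory modulation and
locomotion; all axes pick up motion artifacts.

Every generator takes an explicit integer seed and is bit-deterministic:
equal inputs and equal seed give identical sample vectors.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_FS = 333.0
"""Nominal sampling rate of the patch, Hz."""

#: The ten surrogate acoustic classes plus the three laryngeal behaviors:
#: together the 13 classifier classes.
ACOUSTIC_KINDS = tuple(f"pinyin{i}" for i in range(1, 6)) + tuple(
    f"vowel{i}" for i in range(1, 6)
)
BEHAVIOR_KINDS = ("swallow", "drink", "cough")
CLASSIFIER_KINDS = ACOUSTIC_KINDS + BEHAVIOR_KINDS
LOCOMOTION_KINDS = ("walk", "jump")
ARTIFACT_KINDS = ("chew", "nod", "choke")
EVENT_KINDS = CLASSIFIER_KINDS + LOCOMOTION_KINDS + ARTIFACT_KINDS + ("rest",)

#: sEMG baseline (electrode/thermal) noise RMS in a.u., present even at rest.
SEMG_BASELINE_RMS = 0.05


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject scaling of the signal model.

    Parameters
    ----------
    cardiac_amp : float
        Peak amplitude of the cardiac R lobe on az, in g.
    resp_amp : float
        Amplitude of the respiratory oscillation on ay, in g.
    semg_gain : float
        Dimensionless multiplier on muscle-activation sEMG amplitude.
    spectral_jitter : float
        Fractional perturbation (0..0.5) of the acoustic-class center
        frequencies for this subject; the perturbation direction is a fixed,
        reproducible function of ``subject_id`` so a subject is internally
        consistent but shifted relative to the population templates.
    baseline_noise_sd : float
        White accelerometer noise standard deviation, in g.
    """

    subject_id: str
    cardiac_amp: float = 0.015
    resp_amp: float = 0.05
    semg_gain: float = 1.0
    spectral_jitter: float = 0.0
    baseline_noise_sd: float = 0.003

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "resp_amp", "semg_gain", "baseline_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SubjectProfile.{name} must be > 0")
        if not 0.0 <= self.spectral_jitter <= 0.5:
            raise ValueError("spectral_jitter must lie in [0, 0.5]")


@dataclass(frozen=True)
class EventSpec:
    """One scheduled event: kind, onset (s), duration (s), intensity (0..1]."""

    kind: str
    onset: float
    duration: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; valid: {EVENT_KINDS}")
        if self.onset < 0:
            raise ValueError("event onset must be >= 0 s")
        if self.duration <= 0:
            raise ValueError("event duration must be > 0 s")


@dataclass
class Recording:
    """A multichannel labeled recording.

    Channels are equal-length 1-D float arrays: ``ax, ay, az`` in g and
    ``semg`` in a.u.  ``annotations`` keeps the event schedule verbatim.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    semg: np.ndarray
    annotations: list[EventSpec] = field(default_factory=list)
    subject: SubjectProfile | None = None
    seed: int | None = None

    CHANNEL_NAMES = ("ax", "ay", "az", "semg")

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        n = len(self.ax)
        for name in self.CHANNEL_NAMES:
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")
        dur = n / self.fs
        for ev in self.annotations:
            if ev.onset > dur:
                raise ValueError(
                    f"annotation {ev.kind!r} onset {ev.onset} s outside recording "
                    f"of {dur:.3f} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_matrix(self) -> np.ndarray:
        """Stack channels as a (4, n) array in the fixed (ax, ay, az, semg) order."""
        return np.stack([self.ax, self.ay, self.az, self.semg])


# --------------------------------------------------------------------------
# component generators
# --------------------------------------------------------------------------

def _gauss_lobe(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def synthesize_cardiac(
    hr_bpm: float,
    fs: float,
    duration: float,
    profile: SubjectProfile,
    seed: int,
) -> np.ndarray:
    """Quasi-periodic train of triphasic cardiac wavelets on the z axis.

    Each beat is the sum of three Gaussian-windowed lobes mimicking the
    R (sharp, up), S (sharp, down) and T (broad, small, up) deflections that
    laryngeal-bone accelerometry resolves, plus a broad diastolic trough
    spanning the late cycle which anchors the spectral fundamental at the
    beat rate.  Beat-to-beat intervals carry at most 2 % Gaussian jitter.
    """
    if not 30.0 <= hr_bpm <= 220.0:
        raise ValueError(
            f"heart rate {hr_bpm} bpm outside the physiological range [30, 220]"
        )
    if duration * hr_bpm / 60.0 < 2:
        raise ValueError("duration too short: need at least 2 cardiac cycles")
    rng = np.random.default_rng(seed)
    period = 60.0 / hr_bpm
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    beat = 0.5 * period  # first beat away from the edge
    a = profile.cardiac_amp
    while beat < duration:
        # R up, S down, T small up, then a slow diastolic trough
        out += a * _gauss_lobe(t, beat, 0.018)
        out -= 0.45 * a * _gauss_lobe(t, beat + 0.045, 0.014)
        out += 0.22 * a * _gauss_lobe(t, beat + 0.18 * period, 0.055)
        out -= 0.25 * a * _gauss_lobe(t, beat + 0.55 * period, 0.20 * period)
        beat += period * (1.0 + 0.02 * np.clip(rng.standard_normal(), -1, 1))
    return out


def synthesize_respiration(
    rr_bpm: float,
    fs: float,
    duration: float,
    profile: SubjectProfile,
    seed: int,
) -> np.ndarray:
    """Slow respiratory oscillation on the y axis: fundamental + 2 weak harmonics."""
    if not 5.0 <= rr_bpm <= 60.0:
        raise ValueError(
            f"respiration rate {rr_bpm} bpm outside the plausible range [5, 60]"
        )
    rng = np.random.default_rng(seed)
    f0 = rr_bpm / 60.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    x = (
        np.sin(2 * np.pi * f0 * t + phase)
        + 0.22 * np.sin(4 * np.pi * f0 * t + 2 * phase)
        + 0.07 * np.sin(6 * np.pi * f0 * t + 3 * phase)
    )
    return profile.resp_amp * x


# Acoustic class templates: two "formant" band centers per class on a fixed
# grid, plus a class-specific syllabic AM rate.  The grid spans 80-165 Hz so
# every template sits below the 166.5 Hz Nyquist limit of 333 Hz sampling
# while preserving the <=200 Hz laryngeal band.  Pinyin surrogates get a
# plosive-like fast attack, vowel surrogates a smooth one.
def _acoustic_template(kind: str) -> dict:
    idx = CLASSIFIER_KINDS.index(kind)
    fc = 85.0 + 8.0 * idx  # 85 .. 157 Hz over the ten acoustic classes
    return {
        "formants": (fc - 8.0, fc + 8.0),
        "am_rate": 2.0 + 0.6 * idx,
        "attack": 0.05 if kind.startswith("pinyin") else 0.25,
        "amp": 0.18,
        "semg_level": 0.8,
    }


def acoustic_spectral_centroid(kind: str) -> float:
    """Design-time spectral centroid (Hz) of an acoustic class template."""
    f1, f2 = _acoustic_template(kind)["formants"]
    return 0.5 * (f1 + f2)


def _subject_formant_factor(profile: SubjectProfile, kind: str) -> np.ndarray:
    """Fixed per-(subject, class) fractional frequency shift in [-jitter, +jitter]."""
    if profile.spectral_jitter == 0.0:
        return np.ones(2)
    key = zlib.crc32(f"{profile.subject_id}/{kind}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(key)
    return 1.0 + profile.spectral_jitter * rng.uniform(-1.0, 1.0, size=2)


def _burst(t: np.ndarray, onset: float, dur: float, attack: float) -> np.ndarray:
    """Smooth attack/sustain/release envelope in [0, 1] supported on [onset, onset+dur]."""
    release = min(0.3 * dur, 0.4)
    attack = min(attack, 0.5 * dur)
    env = np.clip((t - onset) / max(attack, 1e-6), 0.0, 1.0)
    env *= np.clip((onset + dur - t) / max(release, 1e-6), 0.0, 1.0)
    return np.clip(env, 0.0, 1.0)


def synthesize_event(
    kind: str,
    fs: float,
    duration: float,
    intensity: float,
    profile: SubjectProfile,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Acceleration deltas and sEMG activation envelope for one event.

    Returns
    -------
    accel : (3, n) array
        Additive (ax, ay, az) contribution in g over the event's support.
    semg_env : (n,) array
        Non-negative muscle-activation envelope (pre-gain), co-timed with the
        mechanical event for swallow/drink/cough and speech.

    Laryngeal events put their energy on az below 200 Hz with peak |az| < 0.4 g
    at intensity <= 1; locomotion sits on ay below 5 Hz with larger amplitude.
    """
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}")
    if fs <= 0:
        raise ValueError("sampling rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    accel = np.zeros((3, n))
    semg_env = np.zeros(n)
    amp = float(intensity)

    if kind in ACOUSTIC_KINDS:
        tpl = _acoustic_template(kind)
        f1, f2 = np.asarray(tpl["formants"]) * _subject_formant_factor(profile, kind)
        env = _burst(t, 0.1 * duration, 0.8 * duration, tpl["attack"])
        # syllabic amplitude modulation at the class AM rate
        env = env * (0.65 + 0.35 * np.cos(2 * np.pi * tpl["am_rate"] * t))
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        carrier = np.sin(2 * np.pi * f1 * t + ph1) + 0.7 * np.sin(
            2 * np.pi * f2 * t + ph2
        )
        accel[2] = amp * tpl["amp"] * env * carrier / 1.7
        accel[0] = 0.15 * accel[2]
        semg_env = amp * tpl["semg_level"] * np.abs(env)
    elif kind == "swallow":
        # two laryngeal-elevation bursts: hyoid rise then bolus transit
        for rel, f, w in ((0.25, 38.0, 0.30), (0.6, 62.0, 0.22)):
            env = _gauss_lobe(t, rel * duration, w * 0.45)
            accel[2] += amp * 0.24 * env * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
            )
            semg_env += amp * 1.0 * env
        accel[0] = 0.2 * accel[2]
    elif kind == "drink":
        # rhythmic gulps
        n_gulps = 3
        for j in range(n_gulps):
            c = (0.2 + 0.3 * j) * duration
            env = _gauss_lobe(t, c, 0.09 * duration)
            accel[2] += amp * 0.2 * env * np.sin(
                2 * np.pi * 28.0 * t + rng.uniform(0, 2 * np.pi)
            )
            semg_env += amp * 0.9 * env
        accel[0] = 0.2 * accel[2]
    elif kind == "cough":
        # sharp broadband expulsions; fundamental content above 100 Hz
        noise = rng.standard_normal(n)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [90.0, min(150.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
        broadband = sosfiltfilt(sos, noise)
        broadband /= max(np.abs(broadband).max(), 1e-12)
        for rel, scale in ((0.3, 1.0), (0.55, 0.6)):
            env = _burst(t, rel * duration, 0.18 * duration, 0.02)
            accel[2] += amp * 0.3 * scale * env * broadband
            semg_env += amp * 0.7 * scale * env
        accel[0] = 0.15 * accel[2]
    elif kind == "walk":
        f_step = 2.0 * (1.0 + 0.05 * rng.uniform(-1, 1))
        env = _burst(t, 0.05 * duration, 0.9 * duration, 0.4)
        ph = rng.uniform(0, 2 * np.pi)
        accel[1] = amp * env * (
            0.65 * np.sin(2 * np.pi * f_step * t + ph)
            + 0.2 * np.sin(4 * np.pi * f_step * t + 2 * ph)
        )
        accel[0] = 0.12 * accel[1]
        accel[2] = 0.1 * accel[1]
    elif kind == "jump":
        # landing impulses
        n_jumps = max(2, int(duration))
        for j in range(n_jumps):
            c = (0.2 + 0.7 * j / max(n_jumps - 1, 1)) * duration
            accel[1] += amp * 1.3 * _gauss_lobe(t, c, 0.04)
            accel[2] += amp * 0.25 * _gauss_lobe(t, c, 0.05)
        accel[0] = 0.1 * accel[1]
    elif kind == "chew":
        env = _burst(t, 0.1 * duration, 0.8 * duration, 0.3)
        osc = np.sin(2 * np.pi * 1.6 * t + rng.uniform(0, 2 * np.pi))
        for i, c in enumerate((0.05, 0.04, 0.06)):
            accel[i] = amp * c * env * osc
    elif kind == "nod":
        env = _burst(t, 0.1 * duration, 0.8 * duration, 0.4)
        osc = np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
        accel[0] = amp * 0.12 * env * osc
        accel[2] = amp * 0.08 * env * osc
    elif kind == "choke":
        # irregular low-frequency spasms on all axes with sEMG co-activation
        n_spasms = 4
        centers = np.sort(rng.uniform(0.15, 0.85, n_spasms)) * duration
        for c in centers:
            env = _gauss_lobe(t, c, 0.08 * duration)
            osc = np.sin(2 * np.pi * rng.uniform(4, 15) * t + rng.uniform(0, 2 * np.pi))
            for i, s in enumerate((0.08, 0.06, 0.12)):
                accel[i] += amp * s * env * osc
            semg_env += amp * 0.5 * env
    # "rest": all zeros
    return accel, semg_env


def synthesize_semg(
    activation_envelope: np.ndarray,
    fs: float,
    profile: SubjectProfile,
    seed: int,
) -> np.ndarray:
    """sEMG channel: 20-150 Hz stochastic carrier modulated by the envelope.

    The carrier is band-limited Gaussian noise normalized to unit RMS; output
    amplitude is ``SEMG_BASELINE_RMS + envelope * semg_gain``, so an all-zero
    envelope leaves pure baseline noise.
    """
    env = np.asarray(activation_envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("sEMG activation envelope must be non-negative")
    if fs <= 0:
        raise ValueError("sampling rate must be > 0")
    rng = np.random.default_rng(seed)
    n = env.size
    noise = rng.standard_normal(n)
    from scipy.signal import butter, sosfiltfilt

    hi = min(150.0, 0.45 * fs)
    sos = butter(4, [20.0, hi], btype="band", fs=fs, output="sos")
    carrier = sosfiltfilt(sos, noise)
    carrier /= max(np.sqrt(np.mean(carrier**2)), 1e-12)
    return (SEMG_BASELINE_RMS + env * profile.semg_gain) * carrier


def synthesize_recording(
    schedule: list[EventSpec],
    vitals: tuple[float, float],
    fs: float,
    duration: float,
    profile: SubjectProfile,
    seed: int,
) -> Recording:
    """Compose a full recording: cardiac + respiration + events + sEMG + noise.

    Components mix additively: cardiac on az, respiration on ay, event deltas
    on their native axes, white accelerometer noise everywhere, and one sEMG
    channel driven by the summed activation envelope.  Annotations pass
    through verbatim.  The same (inputs, seed) reproduce the samples bitwise.
    """
    hr_bpm, rr_bpm = vitals
    n = int(round(duration * fs))
    seen: set[tuple[str, float]] = set()
    for ev in schedule:
        if ev.onset + ev.duration > duration + 1e-9:
            raise ValueError(
                f"event {ev.kind!r} at {ev.onset} s extends past the recording end"
            )
        key = (ev.kind, ev.onset)
        if key in seen:
            warnings.warn(
                f"overlapping identical events: {ev.kind!r} at onset {ev.onset} s",
                stacklevel=2,
            )
        seen.add(key)

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4 + len(schedule))
    accel = np.zeros((3, n))
    semg_env = np.zeros(n)
    accel[2] += synthesize_cardiac(hr_bpm, fs, duration, profile, int(sub_seeds[0]))
    accel[1] += synthesize_respiration(rr_bpm, fs, duration, profile, int(sub_seeds[1]))
    for k, ev in enumerate(schedule):
        d_accel, d_env = synthesize_event(
            ev.kind, fs, ev.duration, ev.intensity, profile, int(sub_seeds[2 + k])
        )
        i0 = int(round(ev.onset * fs))
        i1 = min(i0 + d_accel.shape[1], n)
        accel[:, i0:i1] += d_accel[:, : i1 - i0]
        semg_env[i0:i1] += d_env[: i1 - i0]
    accel += profile.baseline_noise_sd * np.random.default_rng(
        int(sub_seeds[-2])
    ).standard_normal((3, n))
    semg = synthesize_semg(semg_env, fs, profile, int(sub_seeds[-1]))
    return Recording(
        fs=fs,
        ax=accel[0],
        ay=accel[1],
        az=accel[2],
        semg=semg,
        annotations=list(schedule),
        subject=profile,
        seed=seed,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def draw_profile(subject_id: str, rng: np.random.Generator,
                 jitter_range: tuple[float, float] = (0.0, 0.03)) -> SubjectProfile:
    """Draw one subject's profile from the population distributions."""
    return SubjectProfile(
        subject_id=subject_id,
        cardiac_amp=rng.uniform(0.010, 0.020),
        resp_amp=rng.uniform(0.035, 0.07),
        semg_gain=rng.uniform(0.8, 1.2),
        spectral_jitter=rng.uniform(*jitter_range),
        baseline_noise_sd=rng.uniform(0.002, 0.004),
    )


def synthesize_subject_recordings(
    profile: SubjectProfile,
    classes: tuple[str, ...] = CLASSIFIER_KINDS,
    reps_per_class: int = 2,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    duration: float = 4.5,
) -> list[Recording]:
    """All single-event recordings for one subject (one event per recording)."""
    for c in classes:
        if c not in EVENT_KINDS:
            raise ValueError(f"unknown class kind {c!r}")
    rng = np.random.default_rng(seed)
    ev_duration = max(duration - 1.7, 1.0)
    recs: list[Recording] = []
    for kind in classes:
        for _ in range(reps_per_class):
            hr = rng.uniform(55.0, 90.0)
            rr = rng.uniform(10.0, 20.0)
            intensity = rng.uniform(0.7, 1.0)
            rec_seed = int(rng.integers(0, 2**31 - 1))
            schedule = [EventSpec(kind, onset=0.8, duration=ev_duration,
                                  intensity=intensity)]
            recs.append(
                synthesize_recording(schedule, (hr, rr), fs, duration, profile,
                                     rec_seed)
            )
    return recs


def synthesize_cohort(
    n_subjects: int,
    classes: tuple[str, ...] = CLASSIFIER_KINDS,
    reps_per_class: int = 2,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    duration: float = 4.5,
    jitter_range: tuple[float, float] = (0.0, 0.03),
) -> dict[str, list[Recording]]:
    """Generate a labeled multi-subject cohort, grouped by subject.

    Each subject receives an independently drawn :class:`SubjectProfile` and
    ``reps_per_class`` single-event recordings per class (event onset 0.8 s,
    event duration ``duration - 1.7`` s), enabling subject-disjoint train/test
    splits downstream.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects to allow a held-out split")
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[Recording]] = {}
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        profile = draw_profile(sid, rng, jitter_range)
        cohort[sid] = synthesize_subject_recordings(
            profile, classes, reps_per_class, fs,
            seed=int(rng.integers(0, 2**31 - 1)), duration=duration,
        )
    return cohort


def recording_label(rec: Recording) -> str:
    """The class kind of a single-event recording (its first annotation)."""
    if not rec.annotations:
        return "rest"
    return rec.annotations[0].kind
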