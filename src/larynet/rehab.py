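"""Rehabilitation scoring: S/D/T behavior flags, the eight-level scale, and
swallow-timing safety rules.

Swallowing (S), drinking water (D) and talking (T) are each flagged normal or
abnormal from classifier confidence and, for S and D, from swallow-timing
rules taken from clinical swallowing screens: the bolus must reach the
circumpharyngeal opening in under 3 s (safety) and the complete ingestion
must finish in under 15 s (effectiveness) — both strict inequalities, so a
16 s ingestion and an exactly-15 s ingestion both fail.  The three flags
combine bijectively into an ordinal level I (all normal) .. VIII (all
abnormal); the scale is a monitoring convention, not a validated clinical
instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SAFETY_LIMIT_S = 3.0
EFFECTIVENESS_LIMIT_S = 15.0
DEFAULT_CONFIDENCE_THRESHOLD = 0.5

NORMAL = "normal"
ABNORMAL = "abnormal"
NOT_ASSESSABLE = "not_assessable"

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass(frozen=True)
class SwallowTiming:
    """Timing of one swallowing/ingestion episode.

    ``onset_to_opening`` is the interval from event onset to the first burst
    peak (the accelerometric proxy for the circumpharyngeal opening);
    ``total_duration`` runs from onset to the offset of the last burst.
    """

    onset_to_opening: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.onset_to_opening < 0 or self.total_duration < 0:
            raise ValueError("durations must be >= 0")

    @property
    def safety_ok(self) -> bool:
        return self.onset_to_opening < SAFETY_LIMIT_S

    @property
    def effectiveness_ok(self) -> bool:
        return self.total_duration < EFFECTIVENESS_LIMIT_S


@dataclass(frozen=True)
class BehaviorFlags:
    swallowing: str
    drinking: str
    talking: str

    def __post_init__(self) -> None:
        for v in (self.swallowing, self.drinking, self.talking):
            if v not in (NORMAL, ABNORMAL, NOT_ASSESSABLE):
                raise ValueError(f"invalid flag {v!r}")


@dataclass(frozen=True)
class RehabLevel:
    level: int  # 1..8
    flags: BehaviorFlags

    @property
    def roman(self) -> str:
        return ROMAN[self.level - 1]


def swallow_timing(
    signal: np.ndarray,
    fs: float,
    onset: float = 0.0,
    smooth_s: float = 0.05,
    min_burst_s: float = 0.08,
) -> SwallowTiming | None:
    """Extract swallow timing from a segmented event trace (az or sEMG).

    A moving-RMS envelope is thresholded at baseline-median plus 30 % of the
    dynamic range; contiguous supra-threshold runs of at least
    ``min_burst_s`` form bursts.  Returns None (not assessable) when no burst
    is found.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return None
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win
    env = np.sqrt(np.convolve(x**2, kernel, mode="same"))
    med = float(np.median(env))
    thr = med + 0.3 * (float(env.max()) - med)
    above = env > thr
    if not above.any():
        return None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= int(round(min_burst_s * fs))
    if not keep.any():
        return None
    starts, ends = starts[keep], ends[keep]
    first_peak = int(starts[0] + np.argmax(env[starts[0]: ends[0]]))
    return SwallowTiming(
        onset_to_opening=first_peak / fs - onset,
        total_duration=ends[-1] / fs - onset,
    )


def behavior_flags(
    confidences: dict[str, float],
    timings: dict[str, SwallowTiming | None] | None = None,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> BehaviorFlags:
    """Flag swallowing/drinking/talking as normal or abnormal.

    A behavior is abnormal when its mean classifier confidence over the
    session falls below ``confidence_threshold`` OR (for swallowing and
    drinking) its timing rule fails.  A behavior absent from ``confidences``
    is flagged not-assessable, which is distinct from abnormal.
    """
    timings = timings or {}
    out = {}
    for behavior in ("swallow", "drink", "talk"):
        if behavior not in confidences:
            out[behavior] = NOT_ASSESSABLE
            continue
        ok = confidences[behavior] >= confidence_threshold
        if behavior in ("swallow", "drink"):
            t = timings.get(behavior)
            if t is not None:
                ok = ok and t.safety_ok and t.effectiveness_ok
        out[behavior] = NORMAL if ok else ABNORMAL
    return BehaviorFlags(
        swallowing=out["swallow"], drinking=out["drink"], talking=out["talk"]
    )


#: Severity order of the 8 flag combinations: level rises with the abnormal
#: count; within a count, abnormal swallowing outranks drinking outranks
#: talking (S > D > T).  Tuples are (S, D, T) with True = abnormal.
_LEVEL_ORDER = (
    (False, False, False),  # I
    (True, False, False),   # II
    (False, True, False),   # III
    (False, False, True),   # IV
    (True, True, False),    # V
    (True, False, True),    # VI
    (False, True, True),    # VII
    (True, True, True),     # VIII
)


def rehab_level(flags: BehaviorFlags) -> RehabLevel:
    """Bijective ordinal mapping of the S/D/T flags to levels I..VIII."""
    for v in (flags.swallowing, flags.drinking, flags.talking):
        if v == NOT_ASSESSABLE:
            raise ValueError(
                "cannot assign a rehabilitation level with not-assessable behaviors"
            )
    key = (
        flags.swallowing == ABNORMAL,
        flags.drinking == ABNORMAL,
        flags.talking == ABNORMAL,
    )
    return RehabLevel(level=_LEVEL_ORDER.index(key) + 1, flags=flags)


def render_session_report(
    flags: BehaviorFlags,
    level: RehabLevel | None,
    timings: dict[str, SwallowTiming | None] | None = None,
    protocol: str = "",
) -> str:
    """Human-readable session report (the local stand-in for a cloud view).

    ``level`` may be None when some behavior was not assessable in the
    session; the report then states that instead of an ordinal level.
    """
    timings = timings or {}
    lines = [
        "Laryngeal rehabilitation session report",
        "=" * 40,
        f"protocol: {protocol or 'n/a'}",
        f"swallowing: {flags.swallowing}",
        f"drinking:   {flags.drinking}",
        f"talking:    {flags.talking}",
        (
            f"rehabilitation level: {level.roman} ({level.level}/8)"
            if level is not None
            else "rehabilitation level: not assessable (incomplete session)"
        ),
    ]
    for name, t in sorted(timings.items()):
        if t is None:
            lines.append(f"{name} timing: not assessable")
        else:
            lines.append(
                f"{name} timing: opening at {t.onset_to_opening:.2f} s "
                f"(safety {'ok' if t.safety_ok else 'FAIL'}), total "
                f"{t.total_duration:.2f} s "
                f"(effectiveness {'ok' if t.effectiveness_ok else 'FAIL'})"
            )
    return "\n".join(lines) + "\n"
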