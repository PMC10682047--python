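"""Spectral characterization and vital-sign decoupling.

Heart rate is read from the z-axis acceleration (cardiac micro-vibrations of
the laryngeal bones) and respiration rate from the y axis, each by zero-phase
band-pass filtering followed by refractory peak detection.  Spectral tools
(Welch PSD, band SNR, STFT) wrap scipy.signal with the containers the rest of
the pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .synth import Recording

#: Default analysis bands (Hz).  The cardiac band isolates the sharp R/S
#: complex (a 5-25 Hz transient) ahead of energy-envelope detection; the
#: respiratory band brackets physiological breathing rates.
HR_BAND = (5.0, 25.0)
RR_BAND = (0.1, 0.7)
HR_REFRACTORY_S = 0.25
RR_REFRACTORY_S = 1.5
HR_ENVELOPE_S = 0.08


class Quality(str, Enum):
    OK = "ok"
    LOW_CONFIDENCE = "low_confidence"
    UNDEFINED = "undefined"


@dataclass
class SpectralResult:
    freqs: np.ndarray
    power: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if np.any(self.freqs < 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be non-negative and increasing")

    def peak_frequency(self) -> float:
        return float(self.freqs[int(np.argmax(self.power))])

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Integrated power in [f_lo, f_hi] (trapezoidal over the density)."""
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if m.sum() < 2:
            raise ValueError("band too narrow for the spectral resolution")
        return float(np.trapezoid(self.power[m], self.freqs[m]))


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    magnitude: np.ndarray  # |freqs| x |times|

    def __post_init__(self) -> None:
        if self.magnitude.shape != (self.freqs.size, self.times.size):
            raise ValueError("magnitude must be |freqs| x |times|")

    def ridge(self) -> np.ndarray:
        """Dominant frequency per frame."""
        return self.freqs[np.argmax(self.magnitude, axis=0)]

    def to_text(self) -> str:
        """Columnar (time, freq, magnitude) export for plotting tools."""
        lines = ["time\tfreq\tmagnitude"]
        for j, tt in enumerate(self.times):
            for i, ff in enumerate(self.freqs):
                lines.append(f"{tt:.6g}\t{ff:.6g}\t{self.magnitude[i, j]:.6g}")
        return "\n".join(lines) + "\n"


@dataclass
class VitalsEstimate:
    hr_bpm: float
    rr_bpm: float
    hr_peak_times: np.ndarray
    rr_peak_times: np.ndarray
    quality_flag: Quality


def bandpass(
    x: np.ndarray, fs: float, f_lo: float, f_hi: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward), same length out."""
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi >= fs / 2:
        raise ValueError(f"upper cutoff {f_hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    if f_lo == 0:
        sos = sps.butter(order, f_hi, btype="low", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [f_lo, f_hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def welch_psd(
    x: np.ndarray, fs: float, segment_len: int | None = None, overlap: float = 0.5
) -> SpectralResult:
    """Welch average-periodogram PSD (Hann window, density scaling)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate a spectrum from an empty signal")
    if segment_len is None:
        segment_len = min(x.size, 1024)
    if segment_len > x.size:
        raise ValueError("segment_len exceeds the signal length")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    f, p = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=segment_len,
        noverlap=int(overlap * segment_len),
        detrend="constant",
    )
    return SpectralResult(freqs=f, power=p, method="welch")


def periodogram(x: np.ndarray, fs: float) -> SpectralResult:
    f, p = sps.periodogram(np.asarray(x, dtype=float), fs=fs, window="hann",
                           detrend="constant")
    return SpectralResult(freqs=f, power=p, method="periodogram")


def snr_db(
    x: np.ndarray,
    fs: float,
    signal_band: tuple[float, float],
    noise_band: tuple[float, float],
    segment_len: int | None = None,
) -> float:
    """10 log10 of the band-integrated signal/noise power ratio.

    Returns ``inf`` (flagged distinctly to the caller) when the noise band
    carries zero power.
    """
    for lo, hi in (signal_band, noise_band):
        if not 0 <= lo < hi or hi > fs / 2:
            raise ValueError(f"band ({lo}, {hi}) must lie within [0, Nyquist]")
    spec = welch_psd(x, fs, segment_len=segment_len)
    p_sig = spec.band_power(*signal_band)
    p_noise = spec.band_power(*noise_band)
    if p_noise == 0.0:
        return float("inf")
    return float(10.0 * np.log10(p_sig / p_noise))


def stft_spectrogram(
    x: np.ndarray, fs: float, win_len: int = 256, hop: int = 128
) -> Spectrogram:
    """Hann-windowed magnitude STFT."""
    x = np.asarray(x, dtype=float)
    if not 0 < hop <= win_len:
        raise ValueError("need 0 < hop <= win_len")
    if win_len > x.size:
        raise ValueError("win_len exceeds the signal length")
    stft = sps.ShortTimeFFT(
        sps.windows.hann(win_len, sym=False), hop=hop, fs=fs, scale_to="magnitude"
    )
    z = stft.stft(x)
    t = stft.t(x.size)
    return Spectrogram(times=t, freqs=stft.f, magnitude=np.abs(z))


def _detect_peaks(
    x: np.ndarray, fs: float, refractory_s: float
) -> np.ndarray:
    """Local maxima above mean + 0.5 sd with a refractory interval; sample indices."""
    thr = float(np.mean(x) + 0.5 * np.std(x))
    distance = max(int(round(refractory_s * fs)), 1)
    peaks, _ = sps.find_peaks(x, height=thr, distance=distance)
    return peaks


def _rate_from_peaks(peak_times: np.ndarray) -> float | None:
    """Rate (per minute) from the mean inter-peak interval; None if < 2 peaks.

    Intervals outside 0.5-1.5x the median are dropped before averaging: they
    are missed-beat or double-detection artifacts, not rate information.
    """
    if peak_times.size < 2:
        return None
    d = np.diff(peak_times)
    med = float(np.median(d))
    keep = d[(d > 0.5 * med) & (d < 1.5 * med)]
    if keep.size == 0:
        return None
    return 60.0 / float(np.mean(keep))


def _cardiac_envelope(x: np.ndarray, fs: float, band: tuple[float, float]
                      ) -> np.ndarray:
    """Squared-energy envelope of the band-passed cardiac transient train."""
    y = bandpass(x, fs, *band)
    w = max(int(round(HR_ENVELOPE_S * fs)), 1)
    return np.convolve(y * y, np.ones(w) / w, mode="same")


def estimate_vitals(
    recording: Recording,
    hr_band: tuple[float, float] = HR_BAND,
    rr_band: tuple[float, float] = RR_BAND,
) -> VitalsEstimate:
    """Decouple heart and respiration rate from the az / ay channels.

    The cardiac path band-passes az around the R/S transient, squares and
    smooths it into an energy envelope, and detects envelope peaks with a
    0.25 s refractory interval; the respiratory path band-passes ay and
    detects peaks directly with a 1.5 s refractory interval.  Both rates come
    from the trimmed mean inter-peak interval.  Degenerate inputs (flat
    channels, fewer than two peaks) yield the ``undefined`` quality flag
    instead of raising.
    """
    if recording.duration < 10.0:
        raise ValueError("vitals estimation needs at least 10 s of signal")
    fs = recording.fs
    out: dict[str, np.ndarray] = {}
    rates: dict[str, float | None] = {}
    for name, chan, band, refr in (
        ("hr", recording.az, hr_band, HR_REFRACTORY_S),
        ("rr", recording.ay, rr_band, RR_REFRACTORY_S),
    ):
        if np.ptp(chan) == 0:
            out[name] = np.empty(0)
            rates[name] = None
            continue
        filt = _cardiac_envelope(chan, fs, band) if name == "hr" else \
            bandpass(chan, fs, *band)
        idx = _detect_peaks(filt, fs, refr)
        out[name] = idx / fs
        rates[name] = _rate_from_peaks(out[name])
    if rates["hr"] is None or rates["rr"] is None:
        return VitalsEstimate(0.0, 0.0, out["hr"], out["rr"], Quality.UNDEFINED)
    flag = Quality.OK
    if out["hr"].size < 5 or out["rr"].size < 3:
        flag = Quality.LOW_CONFIDENCE
    return VitalsEstimate(
        float(rates["hr"]), float(rates["rr"]), out["hr"], out["rr"], flag
    )


def fundamental_frequency(
    x: np.ndarray, fs: float, noise_floor_ratio: float = 5.0
) -> float | None:
    """Dominant spectral peak above the noise floor; None for flat spectra.

    The floor is ``noise_floor_ratio`` times the median Welch power; a
    white-noise spectrum has no such dominant peak and returns None.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 0.5 * fs:
        raise ValueError("need at least 0.5 s of signal")
    spec = welch_psd(x, fs, segment_len=min(x.size, 512))
    power = spec.power[1:]  # skip DC
    freqs = spec.freqs[1:]
    floor = noise_floor_ratio * float(np.median(power))
    i = int(np.argmax(power))
    if power[i] <= floor or power[i] == 0:
        return None
    return float(freqs[i])
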