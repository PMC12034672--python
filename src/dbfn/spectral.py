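"""Complex Morlet band decomposition and inter-band difference signals.

Each trial is decomposed into four EEG rhythms — theta (4-8 Hz), alpha
(8-12 Hz), beta (12-32 Hz) and gamma (32-42 Hz) — by convolution with one
complex Morlet wavelet per band.  The wavelet is centred at the band midpoint
with a Gaussian spectral standard deviation of (high - low)/4, so ~95% of its
energy lies inside the band.  From the four analytic signals, the 6 unordered
band pairs yield 12 per-channel difference series per trial: 6 amplitude
differences (envelope of the higher band minus envelope of the lower) and 6
phase differences (wrapped to (-pi, pi]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core_data import TrialRecording

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BAND_PAIRS",
    "BandAnalytic",
    "DifferenceSignal",
    "morlet_decompose",
    "band_differences",
    "segment_windows",
    "trial_difference_signals",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def sigma_f(self) -> float:
        """Gaussian spectral SD: quarter of the bandwidth."""
        return (self.high - self.low) / 4.0


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 32.0),
    BandDefinition("gamma", 32.0, 42.0),
)

#: The 6 unordered band pairs, named higher-frequency band first
#: (e.g. "alpha_theta", "gamma_beta").
BAND_PAIRS: tuple[tuple[str, str], ...] = (
    ("alpha", "theta"),
    ("beta", "theta"),
    ("beta", "alpha"),
    ("gamma", "theta"),
    ("gamma", "alpha"),
    ("gamma", "beta"),
)


@dataclass(frozen=True)
class BandAnalytic:
    """Amplitude envelope and instantaneous phase of one rhythm."""

    band: BandDefinition
    amplitude: np.ndarray  # (n_channels, n_samples), >= 0
    phase: np.ndarray  # (n_channels, n_samples), in (-pi, pi]


@dataclass(frozen=True)
class DifferenceSignal:
    """Per-channel difference series for one (band pair, mode) combination."""

    pair: tuple[str, str]  # (higher band, lower band)
    mode: str  # "amplitude" or "phase"
    values: np.ndarray  # (n_channels, n_samples)

    @property
    def name(self) -> str:
        return f"{self.pair[0]}_{self.pair[1]}:{self.mode}"


def _morlet_kernel(band: BandDefinition, fs: float) -> np.ndarray:
    """Complex Morlet kernel for one band, normalized to unit passband gain.

    The envelope is a Gaussian with time-domain SD sigma_t = 1/(2 pi sigma_f),
    truncated at 4 sigma_t; the carrier is the band-centre complex exponential.
    The envelope is scaled so that a unit-amplitude real sinusoid at the centre
    frequency comes out with amplitude envelope 1.
    """
    sigma_t = 1.0 / (2.0 * np.pi * band.sigma_f)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-0.5 * (t / sigma_t) ** 2)
    env *= 2.0 / env.sum()  # real sinusoid splits power between +/- frequencies
    return env * np.exp(2j * np.pi * band.center * t)


def morlet_decompose(
    tr: TrialRecording, band: BandDefinition, cycles: float | None = None
) -> BandAnalytic:
    """Band-pass a trial with a complex Morlet wavelet; return envelope + phase.

    Parameters
    ----------
    tr
        The recording (channels x samples).
    band
        Frequency band; ``band.high`` must be below the Nyquist frequency.
    cycles
        Optional override of the wavelet width, in carrier cycles per
        time-domain SD (``cycles = center / sigma_f`` by default, i.e. the
        quarter-bandwidth rule).

    Notes
    -----
    Edges are handled by reflect-padding the signal with one wavelet half-length
    so the output is the same length as the input and fully deterministic.
    Zero-amplitude samples get phase 0 by convention.
    """
    if band.high >= tr.fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {tr.fs / 2} Hz"
        )
    if cycles is not None:
        sigma_f = band.center / cycles
        band = BandDefinition(band.name, band.center - 2 * sigma_f,
                              band.center + 2 * sigma_f)
    kernel = _morlet_kernel(band, tr.fs)
    half = (len(kernel) - 1) // 2
    pad = min(half, tr.n_samples - 1)
    x = np.pad(tr.data, ((0, 0), (pad, pad)), mode="reflect")
    analytic = fftconvolve(x, kernel[np.newaxis, :], mode="same")
    analytic = analytic[:, pad:pad + tr.n_samples]
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    phase[amplitude == 0.0] = 0.0
    return BandAnalytic(band, amplitude, phase)


def _wrap_phase(values: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    wrapped = np.mod(-values + np.pi, 2.0 * np.pi)
    return np.pi - wrapped


def band_differences(
    analytics: dict[str, BandAnalytic] | list[BandAnalytic],
    wrap_phases: bool = True,
) -> list[DifferenceSignal]:
    """Build the 12 inter-band difference signals from the 4 rhythm analytics.

    For every unordered band pair the amplitude difference is
    ``A_higher - A_lower`` and the phase difference is
    ``phi_higher - phi_lower`` wrapped to (-pi, pi] (set ``wrap_phases=False``
    for raw subtraction).  Returns 6 amplitude signals followed by 6 phase
    signals, in ``BAND_PAIRS`` order within each mode.
    """
    if not isinstance(analytics, dict):
        analytics = {a.band.name: a for a in analytics}
    missing = {b for pair in BAND_PAIRS for b in pair} - set(analytics)
    if missing:
        raise ValueError(f"missing band analytics: {sorted(missing)}")
    shapes = {a.amplitude.shape for a in analytics.values()}
    if len(shapes) != 1:
        raise ValueError(f"band analytics have mismatched shapes: {shapes}")

    out: list[DifferenceSignal] = []
    for hi, lo in BAND_PAIRS:
        out.append(DifferenceSignal(
            (hi, lo), "amplitude",
            analytics[hi].amplitude - analytics[lo].amplitude,
        ))
    for hi, lo in BAND_PAIRS:
        dphi = analytics[hi].phase - analytics[lo].phase
        if wrap_phases:
            dphi = _wrap_phase(dphi)
        out.append(DifferenceSignal((hi, lo), "phase", dphi))
    return out


def segment_windows(values: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Split a channels x samples array into contiguous non-overlapping windows.

    Returns an array of shape ``(n_windows, n_channels, window_s * fs)``;
    a 60 s signal with 6 s windows yields 10 windows.  Partial windows are an
    error: the duration must be an integer multiple of the window length.
    """
    values = np.asarray(values)
    win = window_s * fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError(f"window_s * fs = {win} is not an integer sample count")
    win = int(round(win))
    n = values.shape[-1]
    if n % win != 0:
        raise ValueError(
            f"{n} samples not divisible by the {win}-sample window "
            f"({window_s} s at {fs} Hz); partial windows are not allowed"
        )
    n_win = n // win
    return values.reshape(*values.shape[:-1], n_win, win).swapaxes(-3, -2) \
        if values.ndim > 1 else values.reshape(n_win, win)


def trial_difference_signals(
    tr: TrialRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    wrap_phases: bool = True,
) -> list[DifferenceSignal]:
    """Decompose one trial into all bands and return its 12 difference signals."""
    analytics = {b.name: morlet_decompose(tr, b) for b in bands}
    return band_differences(analytics, wrap_phases=wrap_phases)
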