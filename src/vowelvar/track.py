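"""LPC formant tracking with dynamic-programming candidate selection.

The tracker follows the classical offline recipe used by speech-analysis
formant trackers (Praat and kin): the audio is decimated to an analysis
rate that places the highest formant of interest below Nyquist, pre-emphasized,
cut into short overlapping windowed frames, and fit with an all-pole (LPC)
model per frame.  Complex pole pairs of the prediction polynomial yield
formant frequency/bandwidth candidates; a dynamic program assigns candidates
to formant slots F1..F4 by trading off deviation from nominal formant values,
candidate bandwidth, and inter-frame continuity.

Frequencies are in Hz throughout; :func:`hz_to_mel` / :func:`mel_to_hz`
implement the O'Shaughnessy (HTK) Mel scale used by the downstream
variability metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.signal


class DegenerateFrameError(ValueError):
    """Raised when a frame carries no signal an LPC fit could model."""


class TrackingError(ValueError):
    """Raised when a waveform cannot be tracked at all (e.g. too short)."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio: dimensionless samples in [-1, 1] at sampling rate ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class TrackerConfig:
    """Parameters of the LPC analysis and the candidate-selection DP.

    ``lpc_order`` defaults to 17, the male-speaker order used for offline
    formant calculation (15 is the female-speaker counterpart).  The default
    frame length/hop (25 ms / 5 ms), Hamming window and 11,025 Hz analysis
    rate are conventional values for 4-formant tracking; the 5-ms hop puts
    ~10 frames inside a 50-ms analysis window.  The mild default
    pre-emphasis (0.85) keeps low first formants unbiased for sources
    without a steep glottal spectral roll-off.

    ``dp_weights`` is ``(continuity, bandwidth, nominal)``: the weights of the
    squared inter-frame log-frequency jump, the relative-bandwidth penalty
    B/F, and the squared log deviation from ``nominal_formants``.
    """

    lpc_order: int = 17
    preemphasis: float = 0.85
    frame_length: float = 0.025
    frame_hop: float = 0.005
    window: str = "hamming"
    n_formants_out: int = 4
    dp_weights: tuple[float, float, float] = (2.0, 0.5, 1.0)
    nominal_formants: tuple[float, ...] = (500.0, 1500.0, 2500.0, 3500.0)
    analysis_fs: float = 11025.0

    def __post_init__(self) -> None:
        if self.lpc_order < 2 * self.n_formants_out:
            raise ValueError("lpc_order must be at least 2 * n_formants_out")
        if not 0 <= self.preemphasis < 1:
            raise ValueError("preemphasis must lie in [0, 1)")
        if not 0 < self.frame_hop <= self.frame_length:
            raise ValueError("require 0 < frame_hop <= frame_length")
        if len(self.nominal_formants) < self.n_formants_out:
            raise ValueError("need a nominal frequency per output formant")


@dataclass
class FormantTrack:
    """Per-frame formant frequencies/bandwidths (Hz) at frame-center times (s).

    ``F`` and ``B`` have shape (n_formants, n_frames).  ``flags`` marks frames
    where the LPC fit was degenerate or offered fewer candidates than slots
    (those slots hold nominal values).  ``candidates`` retains the per-frame
    (frequency, bandwidth) candidate lists for diagnostics.
    """

    frame_times: np.ndarray
    F: np.ndarray
    B: np.ndarray
    flags: np.ndarray
    candidates: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def select(self, mask: np.ndarray) -> "FormantTrack":
        """Return the sub-track at frames where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        cands = [c for c, m in zip(self.candidates, mask) if m] if self.candidates else []
        return FormantTrack(self.frame_times[mask], self.F[:, mask],
                            self.B[:, mask], self.flags[mask], cands)


# ---------------------------------------------------------------------------
# Mel scale

_MEL_K = 2595.0
_MEL_F0 = 700.0


def hz_to_mel(f):
    """Convert frequency in Hz to Mel: ``2595 * log10(1 + f/700)``."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = _MEL_K * np.log10(1.0 + f / _MEL_F0)
    return out if out.ndim else float(out)


def mel_to_hz(m):
    """Inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("mel value must be non-negative")
    out = _MEL_F0 * (10.0 ** (m / _MEL_K) - 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# LPC core

def preemphasize(w: Waveform, a: float) -> Waveform:
    """First-order high-pass ``y[n] = x[n] - a*x[n-1]`` (y[0] = x[0])."""
    if not 0 <= a < 1:
        raise ValueError("preemphasis coefficient must lie in [0, 1)")
    x = w.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - a * x[:-1]
    return Waveform(y, w.fs)


def lpc_coefficients(frame: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Autocorrelation-method LPC via Levinson-Durbin.

    Returns ``(a, gain)`` where ``a = [1, a_1, ..., a_p]`` are the prediction
    polynomial coefficients (A(z) = 1 + sum a_k z^-k solving the Toeplitz
    normal equations) and ``gain`` is the residual standard deviation.  The
    autocorrelation method guarantees a minimum-phase synthesis filter.

    Raises :class:`DegenerateFrameError` on an (essentially) all-zero frame.
    """
    frame = np.asarray(frame, dtype=float)
    n = len(frame)
    if n <= order:
        raise ValueError("frame must be longer than the LPC order")
    r = np.correlate(frame, frame, mode="full")[n - 1 : n + order]
    if r[0] <= 0 or r[0] < 1e-18:
        raise DegenerateFrameError("frame energy is zero")
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[i - 1 : 0 : -1]
        k = -acc / err
        # reflection update: a_new[j] = a[j] + k * a[i-j], a_new[i] = k
        prev = a[1:i].copy()
        a[1:i] = prev + k * prev[::-1]
        a[i] = k
        err *= 1.0 - k * k
        if err <= 0:
            raise DegenerateFrameError("Levinson-Durbin recursion collapsed")
    return a, float(np.sqrt(err))


def roots_to_candidates(a: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Map complex roots of the LPC polynomial to (frequency, bandwidth) pairs.

    A root ``m * exp(i*theta)`` with ``theta`` in (0, pi) yields frequency
    ``theta*fs/(2*pi)`` and bandwidth ``-(fs/pi)*ln(m)``.  Candidates below
    50 Hz or above fs/2 - 50 Hz are discarded; the list is sorted by
    frequency and may be empty.
    """
    roots = np.roots(np.asarray(a, dtype=float))
    cands = []
    for r in roots:
        if r.imag <= 0:
            continue
        theta = np.angle(r)
        if not 0 < theta < np.pi:
            continue
        freq = theta * fs / (2.0 * np.pi)
        if freq < 50.0 or freq > fs / 2.0 - 50.0:
            continue
        modulus = abs(r)
        if modulus <= 0:
            continue
        bw = -(fs / np.pi) * np.log(modulus)
        cands.append((float(freq), float(bw)))
    cands.sort(key=lambda c: c[0])
    return cands


# ---------------------------------------------------------------------------
# Dynamic-programming slot assignment

def _frame_states(cands, nominal, n_out, max_candidates=12):
    """Enumerate increasing-frequency assignments of candidates to slots.

    Returns (freqs, bws, flagged): arrays of shape (n_states, n_out).  When a
    frame offers fewer candidates than slots, the single emitted state holds
    nominal frequencies in the unfilled slots and is flagged.
    """
    if len(cands) > max_candidates:
        cands = sorted(cands, key=lambda c: c[1])[:max_candidates]
        cands.sort(key=lambda c: c[0])
    if len(cands) >= n_out:
        combos = list(itertools.combinations(range(len(cands)), n_out))
        freqs = np.array([[cands[i][0] for i in c] for c in combos])
        bws = np.array([[cands[i][1] for i in c] for c in combos])
        return freqs, bws, False
    # too few candidates: place what we have by nearest nominal slot
    freqs = np.array(nominal[:n_out], dtype=float)
    bws = np.full(n_out, 300.0)
    for f, b in cands:
        slot = int(np.argmin(np.abs(np.log(f / np.asarray(nominal[:n_out])))))
        freqs[slot] = f
        bws[slot] = b
    order = np.argsort(freqs)
    return freqs[order][None, :], bws[order][None, :], True


def track_formants(w: Waveform, cfg: TrackerConfig | None = None) -> FormantTrack:
    """Track formants F1..n through a waveform.

    The waveform is resampled to ``cfg.analysis_fs``, pre-emphasized and
    windowed; per frame, LPC-root candidates are computed and the globally
    cheapest assignment of candidates to formant slots across frames is found
    by dynamic programming (Viterbi over per-frame assignment states).  Frame
    times refer to frame centers in the original waveform's time axis.
    """
    cfg = cfg or TrackerConfig()
    if w.duration < cfg.frame_length:
        raise TrackingError("waveform shorter than one analysis frame")

    x, fs = w.samples, w.fs
    if fs != cfg.analysis_fs:
        if fs % cfg.analysis_fs == 0:
            x = scipy.signal.decimate(x, int(fs // cfg.analysis_fs), ftype="fir",
                                      zero_phase=True)
        else:
            up = int(round(cfg.analysis_fs))
            down = int(round(fs))
            x = scipy.signal.resample_poly(x, up, down)
        fs = cfg.analysis_fs

    y = preemphasize(Waveform(x, fs), cfg.preemphasis).samples
    L = int(round(cfg.frame_length * fs))
    hop = int(round(cfg.frame_hop * fs))
    win = scipy.signal.get_window(cfg.window, L, fftbins=False)
    n_frames = 1 + (len(y) - L) // hop
    if n_frames < 1:
        raise TrackingError("waveform shorter than one analysis frame")

    n_out = cfg.n_formants_out
    nominal = np.asarray(cfg.nominal_formants[:n_out], dtype=float)
    w_cont, w_bw, w_nom = cfg.dp_weights

    states_f, states_b, flagged, all_cands = [], [], [], []
    for i in range(n_frames):
        frame = y[i * hop : i * hop + L] * win
        try:
            a, _ = lpc_coefficients(frame, cfg.lpc_order)
            cands = roots_to_candidates(a, fs)
        except DegenerateFrameError:
            cands = []
        all_cands.append(cands)
        f, b, flag = _frame_states(cands, nominal, n_out)
        states_f.append(f)
        states_b.append(b)
        flagged.append(flag)

    # local cost per state
    log_nom = np.log(nominal)
    local = []
    for f, b in zip(states_f, states_b):
        cost = (w_nom * np.sum((np.log(f) - log_nom) ** 2, axis=1)
                + w_bw * np.sum(b / f, axis=1))
        local.append(cost)

    # Viterbi over frames
    back = []
    acc = local[0].copy()
    for t in range(1, n_frames):
        lf_prev = np.log(states_f[t - 1])          # (S_prev, n)
        lf_cur = np.log(states_f[t])               # (S_cur, n)
        jump = lf_prev[:, None, :] - lf_cur[None, :, :]
        trans = w_cont * np.sum(jump * jump, axis=2)
        total = acc[:, None] + trans
        idx = np.argmin(total, axis=0)
        back.append(idx)
        acc = total[idx, np.arange(len(states_f[t]))] + local[t]

    best = int(np.argmin(acc))
    path = [best]
    for idx in reversed(back):
        path.append(int(idx[path[-1]]))
    path.reverse()

    F = np.column_stack([states_f[t][s] for t, s in enumerate(path)])
    B = np.column_stack([states_b[t][s] for t, s in enumerate(path)])
    times = (np.arange(n_frames) * hop + L / 2.0) / fs
    return FormantTrack(times, F, B, np.asarray(flagged, dtype=bool), all_cands)


# ---------------------------------------------------------------------------
# Track CSV round-trip (also an accepted pipeline input, bypassing audio)

_TRACK_COLS = ("frame_time_s", "F1_hz", "F2_hz", "F3_hz", "F4_hz",
               "B1_hz", "B2_hz", "B3_hz", "B4_hz", "flagged")


def track_to_frame(track: FormantTrack):
    """Formant track as a tidy DataFrame (one row per frame)."""
    import pandas as pd

    data = {"frame_time_s": track.frame_times}
    for k in range(track.F.shape[0]):
        data[f"F{k + 1}_hz"] = track.F[k]
        data[f"B{k + 1}_hz"] = track.B[k]
    data["flagged"] = track.flags.astype(int)
    return pd.DataFrame(data)


def frame_to_track(df) -> FormantTrack:
    """Rebuild a :class:`FormantTrack` from :func:`track_to_frame` output."""
    ks = sorted(int(c[1:-3]) for c in df.columns if c.startswith("F") and c.endswith("_hz"))
    F = np.vstack([df[f"F{k}_hz"].to_numpy(float) for k in ks])
    B = np.vstack([df[f"B{k}_hz"].to_numpy(float) for k in ks])
    flags = df["flagged"].to_numpy() if "flagged" in df else np.zeros(len(df))
    return FormantTrack(df["frame_time_s"].to_numpy(float), F, B, flags.astype(bool))
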