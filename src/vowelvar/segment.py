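"""Vowel span selection and per-trial duration/intensity measures.

The analysis pipeline normally takes vowel onsets/offsets from the
annotation table (hand-labelled spans in the experiment the generator
emulates); :func:`detect_vowel_bounds` is an energy-threshold fallback for
un-annotated audio and is flagged as such in its output.  The feedforward
analysis window is the first 50 ms of the vowel — early enough that auditory
feedback of the ongoing production cannot yet have influenced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track import FormantTrack, Waveform


class DetectionError(ValueError):
    """Vowel bounds could not be determined (silent or too-short signal)."""


class InsufficientFramesError(ValueError):
    """The analysis window contains too few formant frames."""


@dataclass(frozen=True)
class VowelSpan:
    """Analyzed vowel interval in seconds; ``source`` is annotation or auto."""

    onset: float
    offset: float
    source: str = "annotation"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")
        if self.offset - self.onset < 0.05:
            raise ValueError("span must be at least 50 ms for windowing")


def short_time_rms(w: Waveform, frame_s: float = 0.010, hop_s: float = 0.005):
    """(times, rms) of sliding-window RMS; times are window centers."""
    L = max(1, int(round(frame_s * w.fs)))
    hop = max(1, int(round(hop_s * w.fs)))
    n = 1 + max(0, (len(w.samples) - L)) // hop
    sq = w.samples ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    starts = np.arange(n) * hop
    rms = np.sqrt((csum[starts + L] - csum[starts]) / L)
    times = (starts + L / 2.0) / w.fs
    return times, rms


def detect_vowel_bounds(w: Waveform, threshold: float = 0.2,
                        frame_s: float = 0.010, hop_s: float = 0.005,
                        min_sustain_s: float = 0.030) -> VowelSpan:
    """Energy-threshold vowel bounds: first/last sustained supra-threshold RMS.

    Onset is the first time the short-time RMS exceeds ``threshold`` x max
    RMS for at least ``min_sustain_s``; offset is the end of the last such
    run.  Raises :class:`DetectionError` for silent input or a detected span
    shorter than 50 ms.
    """
    times, rms = short_time_rms(w, frame_s, hop_s)
    peak = rms.max(initial=0.0)
    if peak <= 1e-8:
        raise DetectionError("silent input: no vowel detected")
    above = rms >= threshold * peak
    min_run = max(1, int(round(min_sustain_s / hop_s)))
    # runs of consecutive supra-threshold frames
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    long_enough = (ends - starts) >= min_run
    if not np.any(long_enough):
        raise DetectionError("no sustained voiced region found")
    onset = times[starts[long_enough][0]] - frame_s / 2.0
    offset = times[ends[long_enough][-1] - 1] + frame_s / 2.0
    if offset - onset < 0.05:
        raise DetectionError("detected vowel span is shorter than 50 ms")
    return VowelSpan(max(0.0, onset), offset, source="auto")


def extract_window(track: FormantTrack, span: VowelSpan,
                   window_s: float = 0.050) -> FormantTrack:
    """Frames of ``track`` whose centers lie in ``[onset, onset + window_s)``.

    The half-open convention makes the frame count depend only on the onset,
    hop and window length — never on the vowel offset.  Raises
    :class:`InsufficientFramesError` with fewer than 3 frames.
    """
    mask = (track.frame_times >= span.onset) & (track.frame_times < span.onset + window_s)
    if int(mask.sum()) < 3:
        raise InsufficientFramesError(
            f"only {int(mask.sum())} frames in [{span.onset:.3f}, "
            f"{span.onset + window_s:.3f}); need at least 3")
    return track.select(mask)


def vowel_duration(span: VowelSpan) -> float:
    """Vowel duration in milliseconds."""
    return (span.offset - span.onset) * 1000.0


def vowel_intensity(w: Waveform, span: VowelSpan) -> float:
    """RMS intensity over the span in dB re full scale (dBFS).

    Only differences between conditions are meaningful (no SPL calibration).
    """
    lo = int(round(span.onset * w.fs))
    hi = int(round(span.offset * w.fs))
    seg = w.samples[lo:hi]
    if len(seg) == 0:
        raise ValueError("span contains no samples")
    rms = float(np.sqrt(np.mean(seg ** 2)))
    if rms <= 0:
        raise ValueError("silent span: intensity undefined")
    return 20.0 * np.log10(rms)
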