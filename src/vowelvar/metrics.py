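"""Formant-variability metrics: trial-to-trial and within-trial dispersion.

All dispersion measures operate on Mel-scaled F1/F2 values from the 50-ms
feedforward window of each trial:

* **Trial-to-trial variability (TTV)** of one participant x vowel x
  condition cell — the RMS of per-trial Euclidean deviations of the
  window-mean (F1, F2) point from the cell's grand-average point:
  ``sqrt(mean_i(d1_i^2 + d2_i^2))``.  TTV indexes the dispersion of the
  planned (feedforward) formant target across repeated productions.
* **Within-trial variability (WTV)** — the RMS of the per-trial F1/F2
  trajectory standard deviations pooled over both formants:
  ``sqrt(sum_i(s1_i^2 + s2_i^2) / (2n))``.
* **Inter-vowel distance** — the mean of the 6 pairwise Euclidean distances
  among the four vowel centroids of a participant x condition, a measure of
  vowel-space distinctness.

Because the variability measures are bounded below by zero, the analysis
table carries their natural logarithms for the linear mixed model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import VowelSpan, extract_window, vowel_duration, vowel_intensity
from .track import FormantTrack, Waveform, hz_to_mel

logger = logging.getLogger(__name__)

CELL_KEYS = ["participant", "group", "condition", "vowel"]

ANALYSIS_COLUMNS = ("participant", "group", "condition", "vowel", "n_trials",
                    "ttv_mel", "wtv_mel", "log_ttv", "log_wtv",
                    "mean_duration_ms", "mean_intensity_db",
                    "centroid_f1_mel", "centroid_f2_mel")


class InsufficientDataError(ValueError):
    """Too few trials (or degenerate values) to compute a cell statistic."""


@dataclass(frozen=True)
class TrialMeasures:
    """Per-trial measures entering the variability analysis.

    ``m1``/``m2``: window-mean Mel F1/F2; ``s1``/``s2``: within-window SDs
    of the Mel F1/F2 trajectories; duration in ms, intensity in dBFS.
    """

    participant: str
    group: str
    condition: str
    vowel: str
    m1: float
    m2: float
    s1: float
    s2: float
    duration_ms: float
    intensity_db: float
    trial_id: int = -1

    def __post_init__(self) -> None:
        if not self.m1 < self.m2:
            raise ValueError("window-mean Mel F1 must lie below F2")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("within-trial SDs must be non-negative")


def measure_trial(track: FormantTrack, span: VowelSpan, waveform: Waveform,
                  meta: dict, window_s: float = 0.050) -> TrialMeasures:
    """Window a formant track and reduce one trial to its analysis measures.

    Mel conversion happens before averaging, so ``m1``/``m2`` are means of
    Mel-scaled trajectories (not Mel of the mean).  SDs use ddof=1.
    """
    win = extract_window(track, span, window_s)
    mel1 = hz_to_mel(win.F[0])
    mel2 = hz_to_mel(win.F[1])
    return TrialMeasures(
        participant=meta.get("participant", ""), group=meta.get("group", ""),
        condition=meta.get("condition", ""), vowel=meta.get("vowel", ""),
        m1=float(np.mean(mel1)), m2=float(np.mean(mel2)),
        s1=float(np.std(mel1, ddof=1)), s2=float(np.std(mel2, ddof=1)),
        duration_ms=vowel_duration(span),
        intensity_db=vowel_intensity(waveform, span),
        trial_id=int(meta.get("trial_id", -1)),
    )


def trials_to_frame(trials) -> pd.DataFrame:
    """Stack :class:`TrialMeasures` into a tidy per-trial DataFrame."""
    return pd.DataFrame([t.__dict__ for t in trials])


# ---------------------------------------------------------------------------
# Cell statistics

def _center(x: np.ndarray, centering: str) -> np.ndarray:
    if centering == "mean":
        return x - x.mean()
    if centering == "median":
        return x - np.median(x)
    raise ValueError(f"unknown centering {centering!r}")


def trial_to_trial_variability(m1, m2, centering: str = "mean",
                               combination: str = "euclidean") -> float:
    """TTV of one cell from per-trial window-mean Mel F1/F2 values.

    ``euclidean`` (default): ``sqrt(mean_i(d1_i^2 + d2_i^2))`` — RMS of the
    per-trial Euclidean deviation from the cell's grand-average (F1, F2)
    point.  ``pooled`` divides by 2n instead of n (the RMS over the pooled
    set of per-formant deviations), smaller by a factor sqrt(2).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("m1 and m2 must be equal-length 1-D arrays")
    n = len(m1)
    if n < 2:
        raise InsufficientDataError("TTV needs at least 2 trials")
    d1 = _center(m1, centering)
    d2 = _center(m2, centering)
    ss = float(np.sum(d1 ** 2 + d2 ** 2))
    if combination == "euclidean":
        return float(np.sqrt(ss / n))
    if combination == "pooled":
        return float(np.sqrt(ss / (2 * n)))
    raise ValueError(f"unknown combination {combination!r}")


def within_trial_variability(s1, s2) -> float:
    """WTV of one cell: RMS of the pooled per-trial F1/F2 trajectory SDs."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1 or len(s1) < 1:
        raise InsufficientDataError("WTV needs at least 1 trial")
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("trajectory SDs must be non-negative")
    return float(np.sqrt(np.sum(s1 ** 2 + s2 ** 2) / (2 * len(s1))))


def inter_vowel_distance(centroids: dict) -> float:
    """Mean pairwise Euclidean distance among the four vowel centroids.

    ``centroids`` maps vowel label to an (F1, F2) pair (Mel by default in
    the pipeline).  Exactly four vowels are required.
    """
    if len(centroids) != 4:
        raise ValueError(f"need 4 vowel centroids, got {sorted(centroids)}")
    pts = {v: np.asarray(c, dtype=float) for v, c in centroids.items()}
    dists = [float(np.linalg.norm(pts[a] - pts[b]))
             for a, b in itertools.combinations(sorted(pts), 2)]
    return float(np.mean(dists))


def build_analysis_table(trials: pd.DataFrame, centering: str = "mean",
                         combination: str = "euclidean") -> pd.DataFrame:
    """Aggregate per-trial measures into the per-cell analysis table.

    One row per participant x vowel x condition cell with TTV/WTV (raw and
    natural-log), mean duration/intensity and the cell centroid.  Cells with
    zero variability (log undefined) are dropped with a logged warning.  The
    default design yields 24 x 4 x 2 = 192 rows.
    """
    if len(trials) == 0:
        raise ValueError("no trials to aggregate")
    rows = []
    for keys, cell in trials.groupby(CELL_KEYS, sort=True, observed=True):
        m1 = cell["m1"].to_numpy(float)
        m2 = cell["m2"].to_numpy(float)
        if len(cell) < 2:
            logger.warning("cell %s: only %d trial(s), skipped", keys, len(cell))
            continue
        ttv = trial_to_trial_variability(m1, m2, centering, combination)
        wtv = within_trial_variability(cell["s1"].to_numpy(float),
                                       cell["s2"].to_numpy(float))
        if ttv <= 0 or wtv <= 0:
            logger.warning("cell %s: zero variability, excluded from log table", keys)
            continue
        rows.append(dict(zip(CELL_KEYS, keys)) | {
            "n_trials": len(cell),
            "ttv_mel": ttv, "wtv_mel": wtv,
            "log_ttv": float(np.log(ttv)), "log_wtv": float(np.log(wtv)),
            "mean_duration_ms": float(cell["duration_ms"].mean()),
            "mean_intensity_db": float(cell["intensity_db"].mean()),
            "centroid_f1_mel": float(m1.mean()), "centroid_f2_mel": float(m2.mean()),
        })
    if not rows:
        raise ValueError("every cell was degenerate; no analysis table")
    return pd.DataFrame(rows, columns=list(ANALYSIS_COLUMNS))


def inter_vowel_distance_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition mean pairwise vowel-centroid distance (Mel)."""
    rows = []
    for (pid, grp, cond), sub in cells.groupby(["participant", "group", "condition"],
                                               sort=True, observed=True):
        cents = {r.vowel: (r.centroid_f1_mel, r.centroid_f2_mel)
                 for r in sub.itertuples()}
        rows.append({"participant": pid, "group": grp, "condition": cond,
                     "inter_vowel_distance_mel": inter_vowel_distance(cents)})
    return pd.DataFrame(rows)
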