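"""Synthetic vowel audio and cohort simulation with known ground truth.

The generator stands in for a speech-production experiment in which adults
who stutter (AWS) and matched adults who do not stutter (ANS) each produce
front vowels under normal (NAF) and 100-ms delayed (DAF) auditory feedback.
It emulates the experiment's *measurable consequences* rather than the
feedback loop itself:

* trial-to-trial dispersion of the produced (F1, F2) target, controlled per
  group x condition in Mel (``sigma_trial``) — higher at baseline in the AWS
  group, increased by DAF in ANS but decreased by DAF in AWS;
* smooth within-trial formant drift (``sigma_within``, Mel);
* DAF lengthening vowels (``daf_duration_factor``) and raising intensity
  (``daf_intensity_shift_db``);
* vowel-dependent baselines: /i/ (ARPAbet ``iy``) is the least variable and
  quietest vowel, /ae/ the longest and most variable within trials.

Audio is a Klatt-style source-filter synthesis: an impulse-train glottal
source at f0 through a cascade of second-order resonators at the (offset and
drifting) formant frequencies, so the exact instantaneous formants of every
trial are known and recorded as a ground-truth track.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.signal
from scipy.io import wavfile

from .track import FormantTrack, Waveform, hz_to_mel, mel_to_hz

GROUPS = ("ANS", "AWS")
CONDITIONS = ("NAF", "DAF")
ANNOTATION_COLUMNS = ("trial_id", "participant", "group", "condition", "vowel",
                      "wav_path", "onset_s", "offset_s", "excluded")


@dataclass(frozen=True)
class VowelTarget:
    """Acoustic target of one vowel: formants/bandwidths (Hz), f0, duration.

    ``base_intensity_db`` is a per-vowel dB offset applied on top of the
    -6 dBFS peak normalization (/i/ is produced slightly quieter than the
    open vowels).
    """

    label: str
    formants_hz: tuple[float, float, float, float]
    bandwidths_hz: tuple[float, float, float, float]
    f0: float = 120.0
    base_duration: float = 0.25
    base_intensity_db: float = 0.0

    def __post_init__(self) -> None:
        f = self.formants_hz
        if len(f) != 4 or len(self.bandwidths_hz) != 4:
            raise ValueError("exactly four formants/bandwidths are required")
        if any(x <= 0 for x in f) or any(b <= 0 for b in self.bandwidths_hz):
            raise ValueError("formant frequencies and bandwidths must be positive")
        if any(f[i] >= f[i + 1] for i in range(3)):
            raise ValueError("formants must be strictly increasing")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.base_duration < 0.1:
            raise ValueError("base_duration must be at least 0.1 s")


#: Canonical American-English adult-male front-vowel targets (ARPAbet keys;
#: /i/, /ɪ/, /ɛ/, /æ/).  F1/F2 from standard reference values; shared
#: F3/F4 and bandwidths; durations give /ae/ the longest vowel.
DEFAULT_VOWEL_TARGETS: tuple[VowelTarget, ...] = (
    VowelTarget("iy", (270.0, 2290.0, 2500.0, 3500.0), (80.0, 120.0, 160.0, 200.0),
                base_duration=0.24, base_intensity_db=-2.0),
    VowelTarget("ih", (390.0, 1990.0, 2500.0, 3500.0), (80.0, 120.0, 160.0, 200.0),
                base_duration=0.20, base_intensity_db=-0.5),
    VowelTarget("eh", (530.0, 1840.0, 2500.0, 3500.0), (80.0, 120.0, 160.0, 200.0),
                base_duration=0.23),
    VowelTarget("ae", (660.0, 1720.0, 2500.0, 3500.0), (80.0, 120.0, 160.0, 200.0),
                base_duration=0.30),
)

# Injected study conditions on the log scale:  log sigma_trial =
# log(20 Mel) - 0.125 + 0.5*[AWS] +/- 0.125 crossover (DAF raises ANS
# dispersion, lowers AWS dispersion; AWS baseline higher by 0.5 log units).
_SIGMA_TRIAL_DEFAULT = {
    ("ANS", "NAF"): 20.0 * float(np.exp(-0.125)),   # 17.65
    ("ANS", "DAF"): 20.0 * float(np.exp(+0.125)),   # 22.66
    ("AWS", "NAF"): 20.0 * float(np.exp(+0.625)),   # 37.38
    ("AWS", "DAF"): 20.0 * float(np.exp(+0.375)),   # 29.10
}

#: Multiplier on sigma_trial per vowel — /i/ the least variable target.
VOWEL_SIGMA_SCALE = {"iy": 0.74, "ih": 1.0, "eh": 1.05, "ae": 1.11}
#: Multiplier on sigma_within per vowel — /ae/ the most variable within trials.
VOWEL_WITHIN_SCALE = {"iy": 0.85, "ih": 1.0, "eh": 1.05, "ae": 1.3}


@dataclass(frozen=True)
class CohortConfig:
    """Design and effect sizes of a simulated cohort.

    Defaults mirror the target experiment: 12 participants per group, 2
    conditions, 4 front vowels with 24 trials each (96 trials per condition),
    44,100 Hz audio.  ``sigma_trial`` maps (group, condition) to the Mel SD
    of per-trial F1/F2 target offsets; ``participant_sigma_log`` is the SD of
    a lognormal participant-level multiplier on that dispersion (the source
    of the participant random intercept on the log-variability scale).
    """

    n_per_group: int = 12
    trials_per_vowel_per_condition: int = 24
    fs: float = 44100.0
    sigma_trial: dict = field(default_factory=lambda: dict(_SIGMA_TRIAL_DEFAULT))
    sigma_within: float = 8.0
    participant_sigma_log: float = 0.3
    daf_duration_factor: float = 1.2
    daf_intensity_shift_db: float = 2.0
    vowel_targets: tuple[VowelTarget, ...] = DEFAULT_VOWEL_TARGETS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.trials_per_vowel_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if any(v < 0 for v in self.sigma_trial.values()) or self.sigma_within < 0:
            raise ValueError("sigma values must be non-negative")
        if self.daf_duration_factor <= 0:
            raise ValueError("daf_duration_factor must be positive")
        missing = {(g, c) for g in GROUPS for c in CONDITIONS} - set(self.sigma_trial)
        if missing:
            raise ValueError(f"sigma_trial missing cells: {sorted(missing)}")
        labels = [t.label for t in self.vowel_targets]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate vowel labels")

    @property
    def n_trials(self) -> int:
        return (2 * self.n_per_group * len(CONDITIONS)
                * len(self.vowel_targets) * self.trials_per_vowel_per_condition)


@dataclass
class SynthTrial:
    """One synthesized production with its ground-truth formant track."""

    waveform: Waveform
    truth_track: FormantTrack
    onset: float
    offset: float
    meta: dict

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset <= self.waveform.duration + 1e-9:
            raise ValueError("onset/offset must lie within the waveform")


# ---------------------------------------------------------------------------
# Single-vowel synthesis

def _drift_polynomial(sigma: float, rng: np.random.Generator):
    """Smooth zero-mean drift on [0, 1] with expected SD ``sigma``.

    Uses the first two shifted-Legendre polynomials (orthonormal under the
    uniform measure), so the drift averages ~0 over the vowel and its
    variance over the window is sigma**2 in expectation.
    """
    c = rng.normal(0.0, sigma / np.sqrt(2.0), size=2)

    def drift(u):
        return (c[0] * np.sqrt(3.0) * (2.0 * u - 1.0)
                + c[1] * np.sqrt(5.0) * (6.0 * u * u - 6.0 * u + 1.0))

    return drift


def synthesize_vowel(target: VowelTarget,
                     trial_offset_mel: Iterable[float] = (0.0, 0.0, 0.0, 0.0),
                     sigma_within_mel: Iterable[float] | float = 0.0,
                     fs: float = 44100.0,
                     seed: int | np.random.Generator = 0,
                     duration: float | None = None,
                     intensity_shift_db: float = 0.0,
                     pre_silence: float = 0.1,
                     post_silence: float = 0.1,
                     truth_hop: float = 0.005,
                     f0_jitter: float = 0.01,
                     meta: dict | None = None) -> SynthTrial:
    """Synthesize one vowel token and its exact formant ground truth.

    The instantaneous Mel frequency of formant k is ``mel(F_k) + offset_k +
    drift_k(t)`` where drift is a smooth random polynomial with SD
    ``sigma_within_mel[k]``.  Formants are held piecewise-constant over
    ``truth_hop`` blocks; ``truth_track`` records the exact block values at
    block centers.  The source is an impulse train at ``target.f0`` passed
    through a cascade of unity-DC-gain second-order resonators, with 15-ms
    raised-cosine onset/offset ramps, peak-normalized to -6 dBFS before
    ``intensity_shift_db`` and the vowel's own intensity offset are applied.
    ``f0_jitter`` is the relative SD of cycle-to-cycle period perturbation
    (~1% in natural voices); it spreads the harmonic comb, avoiding the
    formant-at-harmonic degeneracy a perfectly periodic source would have.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = np.asarray(list(trial_offset_mel), dtype=float)
    if len(offsets) != 4 or not np.all(np.isfinite(offsets)):
        raise ValueError("trial_offset_mel must be four finite Mel offsets")
    sig_w = np.asarray(sigma_within_mel, dtype=float)
    if sig_w.ndim == 0:
        sig_w = np.array([float(sig_w), float(sig_w), 0.0, 0.0])
    dur = float(duration if duration is not None else target.base_duration)
    if dur < 0.1:
        raise ValueError("vowel duration must be at least 0.1 s")

    base_mel = hz_to_mel(np.asarray(target.formants_hz))
    drifts = [_drift_polynomial(s, rng) for s in sig_w]

    n_blocks = max(1, int(round(dur / truth_hop)))
    u = (np.arange(n_blocks) + 0.5) / n_blocks           # block centers in [0,1]
    mel_tracks = np.empty((4, n_blocks))
    for k in range(4):
        mel_tracks[k] = base_mel[k] + offsets[k] + drifts[k](u)
    if np.any(mel_tracks <= 0):
        raise ValueError("formant offset pushes a formant to or below 0 Hz")
    hz_tracks = np.vstack([mel_to_hz(mel_tracks[k]) for k in range(4)])
    if np.any(hz_tracks >= fs / 2.0):
        raise ValueError("formant offset pushes a formant above Nyquist")

    # impulse-train source over the vowel, with natural cycle-to-cycle jitter
    n_voiced = int(round(dur * fs))
    src = np.zeros(n_voiced)
    t = 0.0
    while t < n_voiced:
        src[int(t)] = 1.0
        t += (fs / target.f0) * (1.0 + f0_jitter * rng.standard_normal())

    # cascade resonators, piecewise-constant coefficients per block
    T = 1.0 / fs
    block_len = int(np.ceil(n_voiced / n_blocks))
    y = src
    for k in range(4):
        out = np.empty_like(y)
        zi = np.zeros(2)
        for b in range(n_blocks):
            lo, hi = b * block_len, min((b + 1) * block_len, n_voiced)
            if lo >= hi:
                break
            F, Bw = hz_tracks[k, b], target.bandwidths_hz[k]
            r = np.exp(-np.pi * Bw * T)
            a1, a2 = 2.0 * r * np.cos(2.0 * np.pi * F * T), -r * r
            g = 1.0 - a1 - a2
            out[lo:hi], zi = scipy.signal.lfilter([g], [1.0, -a1, -a2],
                                                  y[lo:hi], zi=zi)
        y = out

    # onset/offset ramps
    n_ramp = min(int(0.015 * fs), n_voiced // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        y[:n_ramp] *= ramp
        y[-n_ramp:] *= ramp[::-1]

    peak = np.max(np.abs(y))
    if peak > 0:
        y = y * (0.5 / peak)                              # -6 dBFS peak
    y = y * 10.0 ** ((intensity_shift_db + target.base_intensity_db) / 20.0)

    n_pre, n_post = int(round(pre_silence * fs)), int(round(post_silence * fs))
    samples = np.concatenate([np.zeros(n_pre), y, np.zeros(n_post)])
    onset = n_pre / fs
    offset = onset + n_voiced / fs

    block_dur = dur / n_blocks
    times = onset + (np.arange(n_blocks) + 0.5) * block_dur
    truth = FormantTrack(times, hz_tracks,
                         np.tile(np.asarray(target.bandwidths_hz)[:, None], n_blocks),
                         np.zeros(n_blocks, dtype=bool))
    return SynthTrial(Waveform(samples, fs), truth, onset, offset, meta or {})


# ---------------------------------------------------------------------------
# Cohort simulation

def participant_ids(config: CohortConfig) -> list[tuple[str, str]]:
    """(participant, group) pairs: ANS01..ANSn then AWS01..AWSn."""
    return [(f"{g}{i + 1:02d}", g) for g in GROUPS for i in range(config.n_per_group)]


def simulate_trial_params(config: CohortConfig) -> pd.DataFrame:
    """Deterministic per-trial parameter table for a cohort.

    One row per trial with the drawn Mel offsets for F1/F2, the effective
    within-trial drift SD, duration and intensity shift, and a per-trial
    child seed.  Audio generation (:func:`simulate_cohort`) consumes this
    table, so analysis-level simulations can reuse it without synthesizing
    audio.
    """
    root = np.random.SeedSequence(config.seed)
    part_ss, trial_ss = root.spawn(2)
    parts = participant_ids(config)
    part_mult = {}
    part_rng = np.random.default_rng(part_ss)
    for pid, _ in parts:
        part_mult[pid] = float(np.exp(part_rng.normal(0.0, config.participant_sigma_log)))

    rng = np.random.default_rng(trial_ss)
    rows = []
    trial_id = 0
    for pid, group in parts:
        for cond in CONDITIONS:
            for target in config.vowel_targets:
                sigma = (config.sigma_trial[(group, cond)]
                         * VOWEL_SIGMA_SCALE.get(target.label, 1.0)
                         * part_mult[pid])
                sig_w = config.sigma_within * VOWEL_WITHIN_SCALE.get(target.label, 1.0)
                dur = target.base_duration
                shift = 0.0
                if cond == "DAF":
                    dur *= config.daf_duration_factor
                    shift = config.daf_intensity_shift_db
                for j in range(config.trials_per_vowel_per_condition):
                    off1, off2 = rng.normal(0.0, sigma, size=2)
                    rows.append({
                        "trial_id": trial_id, "participant": pid, "group": group,
                        "condition": cond, "vowel": target.label, "trial_index": j,
                        "offset_f1_mel": off1, "offset_f2_mel": off2,
                        "sigma_within_mel": sig_w, "duration_s": dur,
                        "intensity_shift_db": shift,
                        "synth_seed": int(rng.integers(0, 2**31 - 1)),
                    })
                    trial_id += 1
    return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig,
                    params: pd.DataFrame | None = None) -> Iterator[SynthTrial]:
    """Yield every trial of the cohort as synthesized audio plus ground truth.

    Lazily generated (a full default cohort is 4,608 trials of audio), fully
    determined by ``config.seed``.
    """
    if params is None:
        params = simulate_trial_params(config)
    targets = {t.label: t for t in config.vowel_targets}
    for row in params.itertuples(index=False):
        target = targets[row.vowel]
        yield synthesize_vowel(
            target,
            trial_offset_mel=(row.offset_f1_mel, row.offset_f2_mel, 0.0, 0.0),
            sigma_within_mel=row.sigma_within_mel,
            fs=config.fs,
            seed=int(row.synth_seed),
            duration=row.duration_s,
            intensity_shift_db=row.intensity_shift_db,
            meta={"trial_id": int(row.trial_id), "participant": row.participant,
                  "group": row.group, "condition": row.condition,
                  "vowel": row.vowel, "trial_index": int(row.trial_index)},
        )


# ---------------------------------------------------------------------------
# Dataset I/O

def write_wav(path: str, w: Waveform) -> None:
    """Write a waveform as mono 16-bit PCM WAV."""
    x = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, int(round(w.fs)), np.round(x * 32767.0).astype(np.int16))


def read_wav(path: str) -> Waveform:
    """Read a mono 16-bit PCM WAV back to a float waveform in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    else:
        samples = data.astype(float)
    return Waveform(samples, float(fs))


def write_dataset(trials: Iterable[SynthTrial], directory: str) -> pd.DataFrame:
    """Write one WAV per trial plus the annotation CSV; return the table.

    The annotation schema is ``trial_id, participant, group, condition,
    vowel, wav_path, onset_s, offset_s, excluded`` with times in seconds and
    ``excluded`` 0/1 (always 0 for synthetic trials).  ``wav_path`` is
    relative to ``directory``.
    """
    os.makedirs(os.path.join(directory, "wav"), exist_ok=True)
    rows = []
    for i, trial in enumerate(trials):
        tid = trial.meta.get("trial_id", i)
        rel = os.path.join("wav", f"trial_{tid:05d}.wav")
        try:
            write_wav(os.path.join(directory, rel), trial.waveform)
        except OSError as exc:
            raise OSError(f"failed to write {os.path.join(directory, rel)}: {exc}") from exc
        rows.append({
            "trial_id": tid,
            "participant": trial.meta.get("participant", ""),
            "group": trial.meta.get("group", ""),
            "condition": trial.meta.get("condition", ""),
            "vowel": trial.meta.get("vowel", ""),
            "wav_path": rel,
            "onset_s": trial.onset,
            "offset_s": trial.offset,
            "excluded": 0,
        })
    table = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    table.to_csv(os.path.join(directory, "annotations.csv"), index=False)
    return table


# ---------------------------------------------------------------------------
# Analysis-table-level simulation (no audio)

def simulate_log_ttv_table(n_per_group: int = 12,
                           group_shift: float = 0.5,
                           daf_shift: float = 0.25,
                           participant_sd: float = 0.3,
                           residual_sd: float = 0.2,
                           vowel_effects: dict | None = None,
                           baseline: float = 3.0,
                           rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Simulate a balanced per-cell log trial-to-trial-variability table.

    Model on the log scale: ``baseline + group_shift*[AWS] + vowel effect +
    condition effect + participant intercept + noise`` where the condition
    effect is the crossover centered within each group — DAF minus NAF
    equals ``+daf_shift`` for ANS and ``-daf_shift`` for AWS, so
    ``group_shift`` is exactly the marginal (condition-averaged) group
    difference.  The participant intercept has SD ``participant_sd`` and the
    residual SD ``residual_sd``.  Setting the shifts to zero gives a null
    cohort.  Returns one row per participant x vowel x condition with a
    ``log_ttv`` column — the direct input of the mixed ANOVA, bypassing
    audio synthesis and tracking.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if vowel_effects is None:
        vowel_effects = {"iy": -0.3, "ih": 0.0, "eh": 0.05, "ae": 0.1}
    vowels = list(vowel_effects)
    rows = []
    for g, group in enumerate(GROUPS):
        for i in range(n_per_group):
            pid = f"{group}{i + 1:02d}"
            b = rng.normal(0.0, participant_sd)
            for cond in CONDITIONS:
                sign = 1.0 if group == "ANS" else -1.0
                cond_eff = sign * (daf_shift / 2.0 if cond == "DAF"
                                   else -daf_shift / 2.0)
                for v in vowels:
                    y = (baseline + group_shift * g + vowel_effects[v]
                         + cond_eff + b + rng.normal(0.0, residual_sd))
                    rows.append({"participant": pid, "group": group,
                                 "condition": cond, "vowel": v, "log_ttv": y})
    return pd.DataFrame(rows)
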