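"""Split-plot mixed-model ANOVA, Tukey post-hocs, and WTV-TTV correlations.

The design is the classic split-plot: a between-subject factor (group:
AWS vs ANS) crossed with two within-subject factors (condition: NAF vs DAF;
vowel: 4 levels), one observation per participant x vowel x condition cell,
and a participant random intercept.  For this balanced design the
REML/Satterthwaite machinery of a general mixed-model fit reduces exactly to
the classical expected-mean-squares strata, which are computed here in
closed form:

* the between-subject stratum (participants within groups) tests the group
  main effect with denominator df ``n_subj - n_groups`` (22 for 24
  participants);
* the within-subject residual stratum tests condition, vowel and every
  interaction with denominator df ``n_subj*(w - 1) - df_within`` where
  ``w`` is the number of within cells per participant (154 for the default
  24 x 4 x 2 design).

Unbalanced input is refused rather than approximated.  Post-hoc pairwise
contrasts of marginal means are Tukey-adjusted via the studentized-range
distribution with the df of the error stratum the contrast is tested
against (the participant stratum whenever a contrast spans groups).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

FACTORS = ("group", "condition", "vowel")

EFFECTS = ("group", "condition", "vowel", "group:condition", "group:vowel",
           "condition:vowel", "group:condition:vowel")


class UnbalancedDesignError(ValueError):
    """The table is not a complete balanced design.

    Fit requires exactly one row per participant x vowel x condition and the
    same number of participants per group; subset or impute to balance
    before fitting (no unbalanced approximation is provided).
    """


class DegenerateDataError(ValueError):
    """Response carries no variance; every F is undefined."""


@dataclass(frozen=True)
class EffectTest:
    name: str
    ss: float
    df_num: int
    ms: float
    F: float
    df_den: int
    p: float


@dataclass
class AnovaTable:
    """Result of the balanced split-plot fit.

    ``effects`` maps effect name (e.g. ``"group:condition"``) to its
    :class:`EffectTest`.  ``sigma2_participant``/``sigma2_residual`` are the
    expected-mean-squares variance components (participant variance truncated
    at zero when the subject mean square falls below the residual one).
    Internal design summaries (cell means, strata mean squares) are retained
    for the post-hoc procedures.
    """

    effects: dict
    sigma2_participant: float
    sigma2_residual: float
    ms_subject: float
    df_subject: int
    ms_residual: float
    df_residual: int
    n_per_group: int
    n_levels: dict
    marginal_means: dict = field(repr=False, default_factory=dict)
    response: str = ""
    degenerate: bool = False
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.effects.values()])


@dataclass(frozen=True)
class PosthocResult:
    contrast: str
    estimate: float
    se: float
    t: float
    df: int
    p_unadjusted: float
    p_adjusted: float


def _check_balanced(table: pd.DataFrame, response: str) -> None:
    required = {"participant", *FACTORS, response}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    counts = table.groupby(["participant", "condition", "vowel"], observed=True).size()
    if not (counts == 1).all():
        raise UnbalancedDesignError(
            "need exactly one observation per participant x condition x vowel")
    per_part = table.groupby("participant", observed=True).size()
    if per_part.nunique() != 1:
        raise UnbalancedDesignError("participants differ in cell counts")
    gsizes = table.groupby("group", observed=True)["participant"].nunique()
    if gsizes.nunique() != 1:
        raise UnbalancedDesignError("groups differ in participant counts")
    pg = table.groupby("participant", observed=True)["group"].nunique()
    if (pg != 1).any():
        raise UnbalancedDesignError("a participant appears in more than one group")


def _marginal_ss(y: np.ndarray, codes: dict, factors: tuple) -> tuple[float, np.ndarray]:
    """Inclusion-exclusion SS of an interaction and its per-row effect values."""
    grand = y.mean()
    effect = np.zeros_like(y)
    for r in range(1, len(factors) + 1):
        sign = (-1.0) ** (len(factors) - r)
        for subset in itertools.combinations(factors, r):
            idx = np.zeros(len(y), dtype=np.int64)
            size = 1
            for f in subset:
                idx = idx * codes[f][1] + codes[f][0]
                size *= codes[f][1]
            sums = np.bincount(idx, weights=y, minlength=size)
            cnts = np.bincount(idx, minlength=size)
            effect += sign * (sums[idx] / cnts[idx])
    effect += ((-1.0) ** len(factors)) * grand
    # with full inclusion-exclusion: effect_row = sum over subsets +/- means
    return float(np.sum(effect ** 2)), effect


def fit_mixed_anova(table: pd.DataFrame, response: str = "log_ttv") -> AnovaTable:
    """Fit the three-factor split-plot mixed ANOVA on a balanced cell table.

    Returns F, numerator/denominator df and p for the three main effects,
    three two-way interactions and the three-way interaction, plus the
    participant-intercept and residual variance components.  Equivalent, on
    this balanced design, to a REML linear mixed model with participant
    random intercept and Satterthwaite denominator df.
    """
    _check_balanced(table, response)
    y = table[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    N = len(y)

    codes = {}
    for f in ("participant", *FACTORS):
        cats, inv = np.unique(table[f].to_numpy(), return_inverse=True)
        codes[f] = (inv, len(cats))
    n_subj = codes["participant"][1]
    n_groups = codes["group"][1]
    w = N // n_subj                              # within cells per participant

    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total <= 0:
        raise DegenerateDataError("constant response: F ratios undefined")

    # between-subject stratum
    s_idx, _ = codes["participant"]
    subj_means = np.bincount(s_idx, weights=y) / np.bincount(s_idx)
    ss_subj_total = float(w * np.sum((subj_means - grand) ** 2))
    ss = {}
    for r in range(1, 4):
        for subset in itertools.combinations(FACTORS, r):
            name = ":".join(subset)
            ss[name], _ = _marginal_ss(y, codes, subset)
    ss_subj_within = ss_subj_total - ss["group"]
    df_subj = n_subj - n_groups

    within_names = [e for e in EFFECTS if e != "group"]
    ss_resid = ss_total - ss_subj_total - sum(ss[e] for e in within_names)
    ss_resid = max(ss_resid, 0.0)

    df_num = {
        "group": n_groups - 1,
        "condition": codes["condition"][1] - 1,
        "vowel": codes["vowel"][1] - 1,
    }
    df_num["group:condition"] = df_num["group"] * df_num["condition"]
    df_num["group:vowel"] = df_num["group"] * df_num["vowel"]
    df_num["condition:vowel"] = df_num["condition"] * df_num["vowel"]
    df_num["group:condition:vowel"] = (df_num["group"] * df_num["condition"]
                                       * df_num["vowel"])
    df_resid = n_subj * (w - 1) - sum(df_num[e] for e in within_names)
    if df_subj <= 0 or df_resid <= 0:
        raise UnbalancedDesignError("design too small for the split-plot strata")

    ms_subj = ss_subj_within / df_subj
    ms_resid = ss_resid / df_resid
    sigma2_resid = ms_resid
    sigma2_part = (ms_subj - ms_resid) / w
    truncated = sigma2_part < 0
    sigma2_part = max(sigma2_part, 0.0)

    effects = {}
    for name in EFFECTS:
        if name == "group":
            ms_err, df_err = ms_subj, df_subj
        else:
            ms_err, df_err = ms_resid, df_resid
        msq = ss[name] / df_num[name]
        if ms_err <= 0:
            F, p = np.nan, np.nan
        else:
            F = msq / ms_err
            p = float(sps.f.sf(F, df_num[name], df_err))
        effects[name] = EffectTest(name, ss[name], df_num[name], msq,
                                   float(F), df_err, p)

    marg = {}
    for fac in (("group",), ("condition",), ("vowel",), ("group", "condition")):
        name = ":".join(fac)
        means = table.groupby(list(fac), observed=True)[response].mean()
        marg[name] = {k if isinstance(k, tuple) else (k,): float(v)
                      for k, v in means.items()}

    return AnovaTable(effects=effects, sigma2_participant=float(sigma2_part),
                      sigma2_residual=float(sigma2_resid),
                      ms_subject=float(ms_subj), df_subject=int(df_subj),
                      ms_residual=float(ms_resid), df_residual=int(df_resid),
                      n_per_group=n_subj // n_groups,
                      n_levels={f: codes[f][1] for f in FACTORS},
                      marginal_means=marg, response=response,
                      truncated=truncated)


# ---------------------------------------------------------------------------
# Post-hoc contrasts

def _tukey_p(t: float, k: int, df: int) -> float:
    return float(np.clip(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df),
                         0.0, 1.0))


def posthoc_pairwise(fit: AnovaTable, factor: str) -> list[PosthocResult]:
    """All pairwise contrasts of marginal means of one factor, Tukey-adjusted.

    ``factor`` is ``"vowel"``, ``"group"``, ``"condition"`` or
    ``"group:condition"`` (the 4 group x condition cell means).  Standard
    errors come from the exact balanced-design variance of a difference of
    marginal means expressed in stratum mean squares; the Tukey studentized
    range uses the df of that stratum (participant stratum for contrasts
    spanning groups, residual stratum otherwise).
    """
    if factor not in fit.marginal_means:
        raise ValueError(f"unknown posthoc factor {factor!r}")
    means = fit.marginal_means[factor]
    levels = sorted(means)
    if len(levels) < 2:
        raise ValueError("factor has a single level; no contrasts")
    n_g = fit.n_per_group
    n_cond, n_vow = fit.n_levels["condition"], fit.n_levels["vowel"]
    w = n_cond * n_vow
    k = len(levels)

    results = []
    for a, b in itertools.combinations(levels, 2):
        if factor == "group":
            # group mean over n_g participants x w cells; participant stratum
            var = 2.0 * fit.ms_subject / (n_g * w)
            df = fit.df_subject
        elif factor == "condition":
            var = 2.0 * fit.ms_residual / (2 * n_g * n_vow)
            df = fit.df_residual
        elif factor == "vowel":
            var = 2.0 * fit.ms_residual / (2 * n_g * n_cond)
            df = fit.df_residual
        else:  # group:condition cells, n = n_g participants x n_vow vowels
            same_group = a[0] == b[0]
            if same_group:
                var = 2.0 * fit.ms_residual / (n_g * n_vow)
                df = fit.df_residual
            else:
                var = (fit.ms_subject + fit.ms_residual) / (n_g * n_vow)
                df = fit.df_subject
        est = means[a] - means[b]
        se = float(np.sqrt(var))
        t = est / se
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        p_adj = max(_tukey_p(t, k, df), p_un)
        label = f"{' '.join(a)} - {' '.join(b)}"
        results.append(PosthocResult(label, float(est), se, float(t), int(df),
                                     p_un, p_adj))
    return results


def simple_effects_condition_within_group(fit: AnovaTable) -> list[PosthocResult]:
    """DAF - NAF condition contrast within each group (Sidak-adjusted pair).

    Both contrasts difference two condition means of the *same* participants,
    so the participant intercept cancels and they are tested against the
    residual stratum.  The two-contrast family is Sidak-adjusted.
    """
    if "group:condition" not in fit.marginal_means:
        raise ValueError("fit lacks group x condition cell means")
    cells = fit.marginal_means["group:condition"]
    n_vow = fit.n_levels["vowel"]
    var = 2.0 * fit.ms_residual / (fit.n_per_group * n_vow)
    se = float(np.sqrt(var))
    results = []
    for grp in sorted({g for g, _ in cells}):
        est = cells[(grp, "DAF")] - cells[(grp, "NAF")]
        t = est / se
        p_un = float(2.0 * sps.t.sf(abs(t), fit.df_residual))
        p_adj = float(min(1.0, 1.0 - (1.0 - p_un) ** 2))
        results.append(PosthocResult(f"{grp}: DAF - NAF", float(est), se,
                                     float(t), fit.df_residual, p_un,
                                     max(p_adj, p_un)))
    return results


# ---------------------------------------------------------------------------
# WTV-TTV correlation

def correlate_wtv_ttv(cells: pd.DataFrame, group: str, condition: str,
                      wtv_col: str = "log_wtv",
                      ttv_col: str = "log_ttv") -> tuple[float, float]:
    """Pearson correlation of participant-mean log WTV vs log TTV in one
    group x condition, with its two-sided t-test p-value."""
    sub = cells[(cells["group"] == group) & (cells["condition"] == condition)]
    by_part = sub.groupby("participant", observed=True)[[wtv_col, ttv_col]].mean()
    if len(by_part) < 3:
        raise ValueError("need at least 3 participants for a correlation")
    x = by_part[wtv_col].to_numpy(float)
    y = by_part[ttv_col].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Report assembly

def anova_report(table: pd.DataFrame, responses: tuple[str, ...] = ("log_ttv", "log_wtv")
                 ) -> dict:
    """Fit each response; return a JSON-ready dict of ANOVA tables,
    group x condition post-hocs, simple effects and WTV-TTV correlations."""
    report: dict = {"responses": {}}
    for resp in responses:
        fit = fit_mixed_anova(table, resp)
        entry = {
            "anova": {n: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den,
                          "p": e.p} for n, e in fit.effects.items()},
            "variance_components": {"participant": fit.sigma2_participant,
                                    "residual": fit.sigma2_residual},
            "posthoc_vowel": [r.__dict__ for r in posthoc_pairwise(fit, "vowel")],
            "posthoc_group_condition": [r.__dict__ for r in
                                        posthoc_pairwise(fit, "group:condition")],
            "simple_effects": [r.__dict__ for r in
                               simple_effects_condition_within_group(fit)],
        }
        report["responses"][resp] = entry
    corr = {}
    for grp in sorted(table["group"].unique()):
        for cond in sorted(table["condition"].unique()):
            try:
                r, p = correlate_wtv_ttv(table, grp, cond)
                corr[f"{grp}:{cond}"] = {"r": r, "p": p}
            except ValueError:
                corr[f"{grp}:{cond}"] = None
    report["wtv_ttv_correlations"] = corr
    return report
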