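"""Antisaccade trial classification, subject summaries and group stats.

In the antisaccade task the participant must look away from a lateral
target. A *directional error* is a first saccade toward the target — the
failed-inhibition event of interest. Trials with first-saccade latency
below the anticipatory cutoff (90 ms) are guesses launched before the
stimulus could be processed and are removed entirely; trials without a
detected saccade are invalid. Hence:

    error rate   = errors / (errors + correct)   over valid trials,
    mean latency = mean over correct trials only.

Change scores are DBS-on minus DBS-off, so a negative change means the
measure decreased when stimulation was switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANTICIPATORY_CUTOFF_MS",
    "classify_trial",
    "classify_trials",
    "summarize_subject",
    "summarize_trials",
    "change_scores",
    "paired_t",
    "paired_t_from_summary",
    "latency_distribution",
    "PairedTResult",
    "SubjectSummary",
    "UndefinedSummaryError",
]

ANTICIPATORY_CUTOFF_MS = 90.0

TRIAL_COLUMNS = ["subject", "condition", "target_side", "first_saccade_direction", "latency_ms"]


class UndefinedSummaryError(ValueError):
    """No valid trials: error rate and latency are undefined."""


def classify_trial(
    target_side: str,
    first_saccade_direction: str,
    latency_ms: float,
    anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS,
) -> str:
    """Classify one trial as error / correct / anticipatory / invalid.

    A trial with no detected saccade is invalid; a latency below the
    anticipatory cutoff removes the trial; otherwise the trial is an
    error iff the first saccade went toward the target.
    """
    if first_saccade_direction == "none":
        return "invalid"
    if pd.isna(latency_ms) or latency_ms < 0:
        return "invalid"
    if latency_ms < anticipatory_ms:
        return "anticipatory"
    return "error" if first_saccade_direction == target_side else "correct"


def classify_trials(
    trials: pd.DataFrame, anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS
) -> pd.Series:
    """Vectorized classification; returns a Series aligned to ``trials``."""
    lat = trials["latency_ms"]
    out = pd.Series("invalid", index=trials.index, dtype=object)
    detected = (trials["first_saccade_direction"] != "none") & lat.notna() & (lat >= 0)
    out[detected & (lat < anticipatory_ms)] = "anticipatory"
    valid = detected & (lat >= anticipatory_ms)
    toward = trials["first_saccade_direction"] == trials["target_side"]
    out[valid & toward] = "error"
    out[valid & ~toward] = "correct"
    return out


@dataclass(frozen=True)
class SubjectSummary:
    error_rate: float
    mean_latency_correct: float
    n_valid: int
    n_error: int
    n_correct: int
    n_anticipatory: int
    n_invalid: int


def summarize_subject(
    trials: pd.DataFrame, anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS
) -> SubjectSummary:
    """Error rate and mean correct latency for one subject x condition.

    Anticipatory and invalid trials are excluded from numerator and
    denominator alike.
    """
    outcome = classify_trials(trials, anticipatory_ms)
    n_err = int((outcome == "error").sum())
    n_cor = int((outcome == "correct").sum())
    n_valid = n_err + n_cor
    if n_valid == 0:
        raise UndefinedSummaryError("no valid trials: summary undefined")
    if n_cor:
        mean_lat = float(trials.loc[outcome == "correct", "latency_ms"].mean())
    else:
        mean_lat = float("nan")
    return SubjectSummary(
        error_rate=n_err / n_valid,
        mean_latency_correct=mean_lat,
        n_valid=n_valid,
        n_error=n_err,
        n_correct=n_cor,
        n_anticipatory=int((outcome == "anticipatory").sum()),
        n_invalid=int((outcome == "invalid").sum()),
    )


def summarize_trials(
    trials: pd.DataFrame, anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS
) -> pd.DataFrame:
    """Per (subject, condition) summaries as a DataFrame."""
    rows = []
    for (subject, condition), g in trials.groupby(["subject", "condition"], sort=True):
        s = summarize_subject(g, anticipatory_ms)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "error_rate": s.error_rate,
                "mean_latency_correct": s.mean_latency_correct,
                "n_valid": s.n_valid,
            }
        )
    return pd.DataFrame(rows).set_index(["subject", "condition"])


def change_scores(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Δ(on − off) for error rate and mean correct latency.

    Subjects lacking either condition are dropped with a warning.
    """
    wide = summaries[["error_rate", "mean_latency_correct"]].unstack("condition")
    keep = wide.notna().all(axis=1)
    dropped = wide.index[~keep]
    if len(dropped):
        warnings.warn(f"dropping subjects missing a condition: {list(dropped)}")
    wide = wide[keep]
    return pd.DataFrame(
        {
            "delta_error_rate": wide[("error_rate", "on")] - wide[("error_rate", "off")],
            "delta_latency_ms": wide[("mean_latency_correct", "on")]
            - wide[("mean_latency_correct", "off")],
        }
    )


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    mean_diff: float
    sd_diff: float
    n: int


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTResult:
    """Paired t-test from the summary statistics of the differences:
    t = mean / (sd/sqrt(n)), df = n − 1, CI = mean ± t_{0.975,df}·sd/√n."""
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    se = sd_diff / np.sqrt(n)
    df = n - 1
    if se == 0:
        t = 0.0 if mean_diff == 0 else float(np.sign(mean_diff) * np.inf)
    else:
        t = mean_diff / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    half = stats.t.ppf(0.975, df) * se
    return PairedTResult(
        t=float(t),
        df=df,
        p=min(max(p, np.finfo(float).tiny), 1.0),
        ci95=(float(mean_diff - half), float(mean_diff + half)),
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        n=int(n),
    )


def paired_t(values_on: np.ndarray, values_off: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test on (on − off) differences."""
    on = np.asarray(values_on, dtype=float)
    off = np.asarray(values_off, dtype=float)
    if on.shape != off.shape:
        raise ValueError("paired samples must have equal length")
    d = on - off
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    return paired_t_from_summary(float(d.mean()), float(d.std(ddof=1)), n)


def latency_distribution(
    trials: pd.DataFrame,
    condition: str | None = None,
    outcome: str | None = None,
    anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS,
) -> pd.DataFrame:
    """Cumulative latency distribution with probit-scaled proportions.

    Rows: sorted latencies with cumulative proportion k/N and its probit
    (inverse-normal) transform; proportions are clipped to
    [1/(2N), 1 − 1/(2N)] before the transform so it stays finite. Used
    for the classic cumulative-frequency latency plots.
    """
    sel = trials
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    if outcome is not None:
        cls = classify_trials(sel, anticipatory_ms)
        sel = sel[cls == outcome]
    lat = np.sort(sel["latency_ms"].dropna().to_numpy(dtype=float))
    n = len(lat)
    if n == 0:
        return pd.DataFrame(columns=["latency_ms", "cum_prop", "probit"])
    cum = np.arange(1, n + 1) / n
    clipped = np.clip(cum, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return pd.DataFrame(
        {"latency_ms": lat, "cum_prop": cum, "probit": stats.norm.ppf(clipped)}
    )
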