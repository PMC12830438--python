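"""Trial-level scoring: response classification, DI / guess rates, AB scores,
RT preprocessing, and participant-level exclusion flags.

Conventions (applied consistently and documented once):

* Filter boundaries are read literally as strict inequalities: RT trials are
  dropped only when strictly faster than 150 ms or strictly slower than
  1000 ms; guess-rate flagging fires only strictly above the threshold.
* Trial-level filters run before any participant-level statistic; 3-SD trims
  are single-pass, never iterated.
* Participant outlier flags use mean/SD computed over the full sample
  including the candidate, and are per-measure: exclusion applies only to
  analyses involving that measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidTrialError, UndefinedResultError

CATEGORIES = ("correct", "intrusion", "other")


def classify_response(target_id, posttarget_id, response_id) -> str:
    """Classify a single report: the target is 'correct', the post-target
    distractor is an 'intrusion', anything else is 'other' (a guess)."""
    if target_id == posttarget_id:
        raise InvalidTrialError(
            f"target and post-target identical ({target_id}); trial is invalid"
        )
    if response_id == target_id:
        return "correct"
    if response_id == posttarget_id:
        return "intrusion"
    return "other"


def classify_frame(trials: pd.DataFrame) -> pd.Series:
    """Vectorized classify_response over a DI trial table."""
    if (trials["target_id"] == trials["posttarget_id"]).any():
        bad = trials.index[trials["target_id"] == trials["posttarget_id"]].tolist()
        raise InvalidTrialError(f"target == post-target on rows {bad[:10]}")
    cat = np.where(
        trials["response_id"] == trials["target_id"], "correct",
        np.where(trials["response_id"] == trials["posttarget_id"], "intrusion", "other"),
    )
    return pd.Series(cat, index=trials.index, name="category")


def di_rate(categories) -> tuple[float, float]:
    """(DI rate, guess rate) for one participant-session's scored trials."""
    cats = pd.Series(categories)
    n = len(cats)
    if n == 0:
        raise UndefinedResultError("DI rate undefined with zero trials")
    return float((cats == "intrusion").sum() / n), float((cats == "other").sum() / n)


def score_di_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session DI scores from a DI trial table."""
    df = trials.copy()
    cat = classify_frame(df)
    df["_intr"] = (cat == "intrusion").astype(float)
    df["_other"] = (cat == "other").astype(float)
    grouped = df.groupby(["participant_id", "session"], sort=True)
    out = grouped.agg(di_rate=("_intr", "mean"), guess_rate=("_other", "mean"),
                      n_di_trials=("_intr", "size")).reset_index()
    return out


def flag_high_guess(scores: pd.DataFrame, threshold: float = 0.25) -> pd.Series:
    """Flag participants whose guess rate is strictly over the threshold.

    High guess rates indicate participants who could not perform the task,
    whose low intrusion rates are uninformative about attention speed."""
    return scores["guess_rate"] > threshold


def ab_scores(trials: pd.DataFrame, condition_on_t1: bool = False) -> pd.DataFrame:
    """Per participant x session AB scores: T1 accuracy, T2 accuracy by lag,
    and AB magnitude = lag-7 minus lag-3 T2 accuracy.

    T2 accuracies are computed over all two-target trials of each lag by
    default; set ``condition_on_t1`` to restrict to T1-correct trials.  A lag
    with zero (usable) trials leaves the AB undefined (NaN), never zero.
    """
    dual = trials[trials["trial_type"] == "dual"].copy()
    if dual.empty:
        raise UndefinedResultError("no two-target trials present")
    dual["t1_ok"] = (dual["t1_response"] == dual["t1_id"]).astype(float)
    dual["t2_ok"] = (dual["t2_response"] == dual["t2_id"]).astype(float)

    keys = ["participant_id", "session"]
    t1 = dual.groupby(keys, sort=True)["t1_ok"].mean().rename("t1_acc")
    usable = dual[dual["t1_ok"] == 1.0] if condition_on_t1 else dual
    t2 = (usable.groupby(keys + ["lag"], sort=True)["t2_ok"].mean()
          .unstack("lag").reindex(columns=[3.0, 7.0]))
    t2.columns = ["t2_acc_lag3", "t2_acc_lag7"]
    out = pd.concat([t1, t2], axis=1).reset_index()
    out["ab_magnitude"] = out["t2_acc_lag7"] - out["t2_acc_lag3"]
    out["ab_undefined"] = ~np.isfinite(out["ab_magnitude"])
    return out


_EFFECTS = {
    # effect name -> (minuend condition, subtrahend condition)
    "cueing": ("cueing_effect_ms", "different", "same"),
    "simon": ("simon_effect_ms", "incompatible", "compatible"),
}


def rt_preprocess(trials: pd.DataFrame, rt_min: float = 150.0, rt_max: float = 1000.0,
                  sd_k: float = 3.0) -> dict:
    """RT cleaning and per-condition scoring for one task's trial table.

    Applies, in order: correct-trials-only filter (RT analyses only), strict
    absolute window (drop rt < ``rt_min`` or rt > ``rt_max``), then a
    single-pass per-participant per-condition ``sd_k``-SD trim.  Returns the
    cleaned trials, per-participant condition means, the task's RT effect,
    per-participant accuracy (from all trials), and an exclusion ledger.
    """
    task_values = trials["task"].unique()
    if len(task_values) != 1:
        raise InvalidTrialError(f"rt_preprocess expects a single task, got {sorted(task_values)}")
    task = task_values[0]
    if task not in _EFFECTS:
        raise InvalidTrialError(f"unknown task {task!r}")
    effect_name, minuend, subtrahend = _EFFECTS[task]
    known = {"cueing": {"absent", "different", "same"}, "simon": {"compatible", "incompatible"}}[task]
    bad_cond = set(trials["condition"].unique()) - known
    if bad_cond:
        raise InvalidTrialError(f"unknown condition label(s) {sorted(bad_cond)} for task {task!r}")

    n_input = len(trials)
    acc = trials.groupby("participant_id", sort=True)["correct"].mean().rename("accuracy")

    correct = trials[trials["correct"] == 1]
    n_incorrect = n_input - len(correct)
    in_window = correct[(correct["rt_ms"] >= rt_min) & (correct["rt_ms"] <= rt_max)]
    n_window = len(correct) - len(in_window)

    grp = in_window.groupby(["participant_id", "condition"], sort=True)["rt_ms"]
    mu = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (in_window["rt_ms"] - mu).abs() <= sd_k * sd
    cleaned = in_window[keep]
    n_trimmed = len(in_window) - len(cleaned)

    cond_means = (cleaned.groupby(["participant_id", "condition"], sort=True)["rt_ms"]
                  .mean().unstack("condition"))
    cond_means.columns = [f"mean_rt_{c}" for c in cond_means.columns]
    cond_means["mean_rt_overall"] = cleaned.groupby("participant_id", sort=True)["rt_ms"].mean()
    minu = cond_means.get(f"mean_rt_{minuend}")
    subt = cond_means.get(f"mean_rt_{subtrahend}")
    # a condition absent from the table leaves the effect undefined, not zero
    cond_means[effect_name] = (minu - subt) if minu is not None and subt is not None else np.nan
    scores = cond_means.join(acc).reset_index()
    scores.insert(1, "task", task)

    ledger = pd.DataFrame([
        {"stage": "incorrect_response", "n_excluded": n_incorrect},
        {"stage": f"outside_[{rt_min:g},{rt_max:g}]ms", "n_excluded": n_window},
        {"stage": f"{sd_k:g}_sd_condition_trim", "n_excluded": n_trimmed},
    ])
    ledger["n_input"] = n_input
    return {"cleaned": cleaned, "scores": scores, "ledger": ledger, "effect_name": effect_name}


def flag_outlier_participants(scores: pd.DataFrame, measure: str, sd_k: float = 3.0) -> pd.Series:
    """Per-measure participant outlier flags: |x - mean| strictly greater than
    ``sd_k`` SDs, with mean/SD over the full sample including the candidate."""
    x = scores[measure].astype(float)
    m, s = x.mean(), x.std(ddof=1)
    if not np.isfinite(s) or s == 0.0:
        return pd.Series(False, index=scores.index, name=f"{measure}_outlier")
    return ((x - m).abs() > sd_k * s).fillna(False).rename(f"{measure}_outlier")
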