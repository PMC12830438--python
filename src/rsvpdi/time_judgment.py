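"""Circular time-judgment error pipeline.

Participants report the angle of a clock hand (one rotation per second) at
cue onset.  The signed angular difference between the reported time t_p and
the cued time t_c, wrapped to (-180, 180], is the time error; positive
errors are clockwise-late reports.  At one rotation per second a degree is
1000/360 ms, so the mean error converts linearly to milliseconds.

Filtering follows the task's curation rules: errors at or beyond +/-160 deg
are discarded (at 180 deg a +500 ms and a -500 ms latency are
indistinguishable), then a single-pass per-participant 3-SD trim is applied
to the remainder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedResultError

MS_PER_DEGREE = 1000.0 / 360.0


def wrap_angle(deg):
    """Wrap an angle (degrees) to the signed interval (-180, 180].

    The boundary maps to +180 so every error has a unique representative,
    which keeps the +/-160 deg filter well defined at exactly 180.
    """
    out = 180.0 - ((180.0 - np.asarray(deg, dtype=float)) % 360.0)
    return float(out) if np.isscalar(deg) else out


def circular_error(t_c, t_p):
    """Signed circular time error in degrees: (t_p - t_c) wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(t_p, dtype=float) - np.asarray(t_c, dtype=float))


def degrees_to_ms(deg):
    """Convert a time error in degrees to milliseconds at one rotation / second."""
    return np.asarray(deg, dtype=float) * MS_PER_DEGREE if not np.isscalar(deg) else float(deg) * MS_PER_DEGREE


def filter_time_errors(errors, wild_cutoff_deg: float = 160.0, sd_k: float = 3.0) -> dict:
    """Two-stage discard for one participant's signed errors.

    Stage 1 removes |e| >= ``wild_cutoff_deg`` (inclusive); stage 2 is a
    single-pass ``sd_k``-SD trim around the participant's post-stage-1 mean.
    Returns retained errors and a ledger; when nothing survives the
    participant's mean error is undefined, never zero.
    """
    e = np.asarray(errors, dtype=float)
    n_input = e.size
    stage1 = e[np.abs(e) < wild_cutoff_deg]
    n_wild = n_input - stage1.size
    if stage1.size == 0:
        return {"retained": stage1, "n_input": n_input, "n_wild_discarded": n_wild,
                "n_sd_trimmed": 0, "undefined": True}
    m = stage1.mean()
    s = stage1.std(ddof=1) if stage1.size > 1 else 0.0
    retained = stage1[np.abs(stage1 - m) <= sd_k * s] if s > 0 else stage1
    return {
        "retained": retained,
        "n_input": n_input,
        "n_wild_discarded": n_wild,
        "n_sd_trimmed": int(stage1.size - retained.size),
        "undefined": retained.size == 0,
    }


def mean_time_error(retained_errors) -> dict:
    """Arithmetic mean of retained signed errors, in degrees and milliseconds."""
    e = np.asarray(retained_errors, dtype=float)
    if e.size == 0:
        raise UndefinedResultError("mean time error undefined: no retained trials")
    m = float(e.mean())
    return {"mean_error_deg": m, "mean_error_ms": m * MS_PER_DEGREE, "n_trials": int(e.size)}


def score_time_trials(trials: pd.DataFrame, wild_cutoff_deg: float = 160.0,
                      sd_k: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw angles -> per-participant mean time error (degrees and ms).

    Returns (scores, ledger); participants whose trials are all discarded get
    NaN means and an ``undefined`` flag.
    """
    bad = trials[(trials["cue_angle_deg"] < 0) | (trials["cue_angle_deg"] >= 360)
                 | (trials["response_angle_deg"] < 0) | (trials["response_angle_deg"] >= 360)]
    if len(bad):
        raise UndefinedResultError(
            f"angles outside [0,360) on rows {bad.index.tolist()[:10]}"
        )
    err = circular_error(trials["cue_angle_deg"].to_numpy(), trials["response_angle_deg"].to_numpy())
    df = trials.assign(error_deg=err)
    n_input = df.groupby("participant_id", sort=True).size().rename("n_input")

    # stage 1: inclusive wild-error discard, then single-pass per-participant trim
    s1 = df[np.abs(df["error_deg"]) < wild_cutoff_deg]
    grp = s1.groupby("participant_id", sort=True)["error_deg"]
    mu, sd = grp.transform("mean"), grp.transform("std").fillna(0.0)
    keep = ((s1["error_deg"] - mu).abs() <= sd_k * sd) | (sd == 0.0)
    retained = s1[keep]

    rg = retained.groupby("participant_id", sort=True)["error_deg"]
    scores = pd.DataFrame({"mean_time_error_deg": rg.mean(), "n_time_trials": rg.size()})
    scores = scores.reindex(n_input.index)
    scores["mean_time_error_ms"] = scores["mean_time_error_deg"] * MS_PER_DEGREE
    scores["n_time_trials"] = scores["n_time_trials"].fillna(0).astype(int)
    scores["time_error_undefined"] = ~np.isfinite(scores["mean_time_error_deg"])
    scores = scores.reset_index()[["participant_id", "mean_time_error_deg",
                                   "mean_time_error_ms", "n_time_trials",
                                   "time_error_undefined"]]

    n_s1 = s1.groupby("participant_id", sort=True).size().reindex(n_input.index).fillna(0).astype(int)
    n_ret = retained.groupby("participant_id", sort=True).size().reindex(n_input.index).fillna(0).astype(int)
    ledger = pd.DataFrame({
        "participant_id": n_input.index,
        "n_input": n_input.to_numpy(),
        "n_wild_discarded": (n_input - n_s1).to_numpy(),
        "n_sd_trimmed": (n_s1 - n_ret).to_numpy(),
        "n_retained": n_ret.to_numpy(),
    })
    return scores, ledger
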