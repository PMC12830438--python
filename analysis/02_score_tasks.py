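"""Score all four task families into per-participant measures.

Applies the trial classification (correct / intrusion / other), the
guess-rate exclusion rule (> 25%), AB magnitudes (lag-7 minus lag-3 T2
accuracy), RT cleaning (correct trials, 150-1000 ms window, per-condition
3-SD trim) and the circular time-error pipeline; writes scores.csv and the
exclusion ledgers under results/.
"""

from pathlib import Path

import pandas as pd

from rsvpdi import cohort, io, scoring, time_judgment

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    di = io.read_validate(DATA / "di_trials.csv", "di_trials")
    ab = io.read_validate(DATA / "ab_trials.csv", "ab_trials")
    tt = io.read_validate(DATA / "time_trials.csv", "time_trials")
    rt = io.read_validate(DATA / "rt_trials.csv", "rt_trials")
    cov = io.read_validate(DATA / "covariates.csv", "covariates")

    di_scores = scoring.score_di_trials(di)
    di_scores["high_guess"] = scoring.flag_high_guess(di_scores)
    s1 = di_scores[di_scores["session"] == 1].reset_index(drop=True)
    s1 = s1.join(scoring.flag_outlier_participants(s1, "di_rate"))
    print(f"DI: {len(s1)} participants, session-1 rate "
          f"M={s1['di_rate'].mean():.3f} SD={s1['di_rate'].std():.3f}; "
          f"{int(s1['high_guess'].sum())} high-guess, "
          f"{int(s1['di_rate_outlier'].sum())} 3-SD outlier(s)")

    ab_s = scoring.ab_scores(ab)
    print(f"AB: T1 M={ab_s['t1_acc'].mean():.3f}, magnitude "
          f"M={ab_s['ab_magnitude'].mean():.3f} SD={ab_s['ab_magnitude'].std():.3f}")

    tt_s, tt_ledger = time_judgment.score_time_trials(tt)
    discarded = tt_ledger["n_wild_discarded"].sum() / tt_ledger["n_input"].sum()
    print(f"time judgment: mean error M={tt_s['mean_time_error_deg'].mean():.2f} deg "
          f"({tt_s['mean_time_error_ms'].mean():.1f} ms); "
          f"{discarded:.1%} of trials discarded at +/-160 deg")

    frames = [s1.drop(columns=["session"]).rename(columns={"di_rate": "di_rate_s1",
                                                           "guess_rate": "guess_rate_s1"}),
              ab_s.drop(columns=["session"]), tt_s]
    rt_ledgers = []
    for task in cohort.RT_TASKS:
        res = scoring.rt_preprocess(rt[rt["task"] == task])
        sc = res["scores"].drop(columns=["task"])
        sc.columns = ["participant_id"] + [f"{task}_{c}" for c in sc.columns[1:]]
        frames.append(sc)
        rt_ledgers.append(res["ledger"].assign(task=task))
        eff = res["effect_name"]
        print(f"{task}: overall RT M={sc[f'{task}_mean_rt_overall'].mean():.0f} ms, "
              f"{eff.replace('_ms','')} M={sc[f'{task}_{eff}'].mean():.0f} ms")

    scores = frames[0]
    for f in frames[1:]:
        scores = scores.merge(f, on="participant_id", how="left")
    scores = scores.merge(cov, on="participant_id", how="left")
    io.write_table(scores, OUT / "scores.csv")
    io.write_table(tt_ledger, OUT / "time_discard_ledger.csv")
    io.write_table(pd.concat(rt_ledgers, ignore_index=True), OUT / "rt_exclusion_ledger.csv")
    print(f"wrote scores.csv with {len(scores)} rows, {scores.shape[1]} columns")


if __name__ == "__main__":
    main()
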