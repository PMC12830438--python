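"""Reliability of the intrusion measure, and the iterative down-sampling map.

Computes full-sample split-half reliability (Spearman-Brown corrected),
Cronbach's alpha, and between-session test-retest stability, then runs the
down-sampling procedure over participants n = 10..100 and trials
t = 20..80, both in steps of 2, with 100 iterations per cell, to find the
smallest design that keeps average reliability above .80.
"""

import json
import sys
from pathlib import Path

from rsvpdi import cohort, io, reliability, scoring

DATA = Path("results/data")
OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    di = io.read_validate(DATA / "di_trials.csv", "di_trials")
    mat, _ = cohort.di_trial_matrix(di, session=1)

    full = reliability.split_half_reliability(mat)
    print(f"full sample ({full.n_participants} x {full.n_trials}): "
          f"r'={full.r_sb:.3f}, alpha={full.alpha:.3f}")

    di_scores = scoring.score_di_trials(di)
    retest = reliability.retest_reliability(di_scores[di_scores["session"] == 1],
                                            di_scores[di_scores["session"] == 2])
    print(f"test-retest (n={retest['n']}): r={retest['r']:.3f}")

    grid = reliability.downsample_grid(
        mat, n_values=range(10, 101, 2), t_values=range(20, 81, 2),
        iterations=100, seed=SEED)
    io.write_table(grid.to_frame(), OUT / "downsample_grid.csv")
    cell = grid.cell(20, 50)
    print(f"down-sampling grid {len(grid.n_values)} x {len(grid.t_values)} cells "
          f"x {grid.iterations} iterations (seed {SEED})")
    print(f"cell (n=20, t=50): mean r'={cell['mean_r_sb']:.3f}, "
          f"mean alpha={cell['mean_alpha']:.3f} -> "
          f"{'clears' if cell['mean_r_sb'] >= 0.80 else 'below'} .80")

    frontier = grid.to_frame().query("mean_r_sb >= 0.80").groupby("n")["t"].min()
    print("smallest t with mean r' >= .80, by n:",
          {int(k): int(v) for k, v in frontier.head(8).items()})

    payload = {
        "di_split_half": {"r_half": full.r_half, "r_sb": full.r_sb, "alpha": full.alpha,
                          "n": full.n_participants, "t": full.n_trials},
        "di_test_retest": retest,
        "cell_20_50": cell,
    }
    (OUT / "reliability.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    print("wrote reliability.json and downsample_grid.csv")


if __name__ == "__main__":
    main()
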