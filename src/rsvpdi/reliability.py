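"""Reliability engines for trial-based individual-differences measures.

Implements split-half reliability with the Spearman-Brown prophecy
correction, Cronbach's alpha over binary trial items (equal to KR-20),
test-retest correlation, split-half of derived difference scores, and the
iterative down-sampling procedure that maps mean reliability over a grid of
(participants n, trials t) subsample sizes.

Undefined results (zero-variance halves, degenerate subsamples) raise
:class:`~rsvpdi.errors.UndefinedResultError`; the down-sampling grid drops
such iterations from cell means and records per-cell valid-iteration counts
so the behaviour is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedResultError

SPLIT_SCHEMES = ("odd_even", "random")


@dataclass(frozen=True)
class ReliabilityResult:
    r_half: float
    r_sb: float
    alpha: float | None
    n_participants: int
    n_trials: int
    split_scheme: str


@dataclass
class DownsampleGrid:
    """Mean corrected split-half reliability and alpha per (n, t) cell."""

    n_values: np.ndarray
    t_values: np.ndarray
    mean_r_sb: np.ndarray  # shape (len(n_values), len(t_values))
    mean_alpha: np.ndarray
    valid_iterations: np.ndarray  # iterations where both statistics exist
    valid_r_sb: np.ndarray
    valid_alpha: np.ndarray
    iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (n, t) cell."""
        rows = []
        for i, n in enumerate(self.n_values):
            for j, t in enumerate(self.t_values):
                rows.append({
                    "n": int(n), "t": int(t),
                    "mean_r_sb": self.mean_r_sb[i, j],
                    "mean_alpha": self.mean_alpha[i, j],
                    "valid_iterations": int(self.valid_iterations[i, j]),
                    "valid_r_sb": int(self.valid_r_sb[i, j]),
                    "valid_alpha": int(self.valid_alpha[i, j]),
                })
        return pd.DataFrame(rows)

    def cell(self, n: int, t: int) -> dict:
        i = int(np.flatnonzero(self.n_values == n)[0])
        j = int(np.flatnonzero(self.t_values == t)[0])
        return {"n": n, "t": t, "mean_r_sb": float(self.mean_r_sb[i, j]),
                "mean_alpha": float(self.mean_alpha[i, j]),
                "valid_iterations": int(self.valid_iterations[i, j])}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0 or not (np.isfinite(sx) and np.isfinite(sy)):
        raise UndefinedResultError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def split_half(matrix: np.ndarray, scheme: str = "odd_even",
               rng: np.random.Generator | None = None) -> float:
    """Raw half-score correlation of a participants x binary-trials matrix.

    ``odd_even`` partitions trials by 0-based index parity (even indices form
    the first half); ``random`` draws an equal-as-possible random partition.
    Half scores are intrusion proportions; the return value is their Pearson
    correlation, uncorrected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ConfigurationError("need >= 3 participants and >= 2 trials")
    if scheme not in SPLIT_SCHEMES:
        raise ConfigurationError(f"unknown split scheme {scheme!r}")
    t = m.shape[1]
    if scheme == "odd_even":
        first = np.arange(0, t, 2)
        second = np.arange(1, t, 2)
    else:
        if rng is None:
            raise ConfigurationError("random split requires an rng")
        perm = rng.permutation(t)
        first, second = perm[: t // 2], perm[t // 2:]
    return _pearson(m[:, first].mean(axis=1), m[:, second].mean(axis=1))


def spearman_brown(r_half: float) -> float:
    """Prophecy correction to full test length: 2r / (1 + r)."""
    if not -1.0 < r_half <= 1.0:
        raise UndefinedResultError(f"Spearman-Brown undefined for r_half={r_half}")
    return 2.0 * r_half / (1.0 + r_half)


def cronbach_alpha(matrix: np.ndarray) -> float:
    """Internal consistency over trial items, aligned by within-participant
    trial rank: alpha = k/(k-1) * (1 - sum(item variances) / total variance).

    Variances use the sample (ddof=1) denominator throughout; on binary items
    this is exactly KR-20.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ConfigurationError("need >= 3 participants and >= 2 items")
    k = m.shape[1]
    total_var = m.sum(axis=1).std(ddof=1) ** 2
    if total_var == 0.0:
        raise UndefinedResultError("zero total-score variance; alpha undefined")
    item_var = m.std(axis=0, ddof=1) ** 2
    return float(k / (k - 1.0) * (1.0 - item_var.sum() / total_var))


def split_half_reliability(matrix: np.ndarray, scheme: str = "odd_even",
                           rng: np.random.Generator | None = None,
                           with_alpha: bool = True) -> ReliabilityResult:
    """Convenience bundle: raw half correlation, corrected value, and alpha."""
    r = split_half(matrix, scheme, rng)
    alpha = None
    if with_alpha:
        try:
            alpha = cronbach_alpha(matrix)
        except UndefinedResultError:
            alpha = None
    return ReliabilityResult(
        r_half=r, r_sb=spearman_brown(r), alpha=alpha,
        n_participants=matrix.shape[0], n_trials=matrix.shape[1], split_scheme=scheme,
    )


def downsample_grid(matrix: np.ndarray, n_values, t_values, iterations: int = 100,
                    seed: int = 0) -> DownsampleGrid:
    """Iterative down-sampling over an (n, t) grid.

    For each cell, repeat ``iterations`` times: sample n participants and t
    trials uniformly without replacement (trial order preserved), then
    compute odd/even split-half -> Spearman-Brown and Cronbach's alpha on the
    subsample.  Cell values are means over iterations where the statistic is
    defined.  Each cell owns an independent counter-based RNG stream derived
    from the single grid seed, so any cell is reproducible in isolation.
    """
    m = np.asarray(matrix, dtype=float)
    n_values = np.asarray(sorted(n_values), dtype=int)
    t_values = np.asarray(sorted(t_values), dtype=int)
    if n_values.max() > m.shape[0]:
        raise ConfigurationError(f"max n {n_values.max()} exceeds participants {m.shape[0]}")
    if t_values.max() > m.shape[1]:
        raise ConfigurationError(f"max t {t_values.max()} exceeds trials {m.shape[1]}")

    shape = (len(n_values), len(t_values))
    sums_r = np.zeros(shape)
    sums_a = np.zeros(shape)
    valid_r = np.zeros(shape, dtype=int)
    valid_a = np.zeros(shape, dtype=int)
    valid_both = np.zeros(shape, dtype=int)

    for i, n in enumerate(n_values):
        for j, t in enumerate(t_values):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(int(i), int(j)))
            )
            for _ in range(iterations):
                rows = np.sort(rng.choice(m.shape[0], size=n, replace=False))
                cols = np.sort(rng.choice(m.shape[1], size=t, replace=False))
                sub = m[np.ix_(rows, cols)]
                ok_r = ok_a = False
                try:
                    r_sb = spearman_brown(split_half(sub, "odd_even"))
                    sums_r[i, j] += r_sb
                    valid_r[i, j] += 1
                    ok_r = True
                except UndefinedResultError:
                    pass
                try:
                    a = cronbach_alpha(sub)
                    sums_a[i, j] += a
                    valid_a[i, j] += 1
                    ok_a = True
                except UndefinedResultError:
                    pass
                if ok_r and ok_a:
                    valid_both[i, j] += 1

    with np.errstate(invalid="ignore"):
        mean_r = np.where(valid_r > 0, sums_r / np.maximum(valid_r, 1), np.nan)
        mean_a = np.where(valid_a > 0, sums_a / np.maximum(valid_a, 1), np.nan)
    return DownsampleGrid(
        n_values=n_values, t_values=t_values, mean_r_sb=mean_r, mean_alpha=mean_a,
        valid_iterations=valid_both, valid_r_sb=valid_r, valid_alpha=valid_a,
        iterations=iterations, seed=int(seed),
    )


def retest_reliability(scores_s1: pd.DataFrame, scores_s2: pd.DataFrame,
                       measure: str = "di_rate") -> dict:
    """Between-session Pearson correlation of a score, paired by participant."""
    merged = scores_s1[["participant_id", measure]].merge(
        scores_s2[["participant_id", measure]], on="participant_id",
        suffixes=("_s1", "_s2"),
    ).dropna()
    if len(merged) < 3:
        raise ConfigurationError(f"need >= 3 paired participants, got {len(merged)}")
    r = _pearson(merged[f"{measure}_s1"].to_numpy(), merged[f"{measure}_s2"].to_numpy())
    return {"r": r, "n": int(len(merged)), "measure": measure}


def split_half_derived(trials: pd.DataFrame, score_fn, scheme: str = "odd_even",
                       rng: np.random.Generator | None = None) -> ReliabilityResult:
    """Split-half reliability of a derived measure (AB magnitude, RT effects).

    Trials are partitioned within participant by trial-index parity (or at
    random), each half is scored *fully* by ``score_fn`` (a function mapping
    a trial table to a participant-indexed Series), and the two per-half
    scores are correlated and Spearman-Brown corrected.
    """
    if scheme not in SPLIT_SCHEMES:
        raise ConfigurationError(f"unknown split scheme {scheme!r}")
    if scheme == "odd_even":
        in_first = (trials["trial_index"] % 2) == 0
    else:
        if rng is None:
            raise ConfigurationError("random split requires an rng")
        in_first = pd.Series(rng.random(len(trials)) < 0.5, index=trials.index)
    s1 = score_fn(trials[in_first])
    s2 = score_fn(trials[~in_first])
    both = pd.concat([s1.rename("h1"), s2.rename("h2")], axis=1).dropna()
    if len(both) < 3:
        raise ConfigurationError("fewer than 3 participants with both halves defined")
    r = _pearson(both["h1"].to_numpy(), both["h2"].to_numpy())
    return ReliabilityResult(r_half=r, r_sb=spearman_brown(r), alpha=None,
                             n_participants=len(both),
                             n_trials=int(trials["trial_index"].nunique()),
                             split_scheme=scheme)
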