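"""Synthetic cohort generator for RSVP distractor-intrusion studies.

Generates trial-level data for four task families — single-target RSVP
distractor-intrusion (DI) trials, two-target attentional-blink (AB) trials,
rotating-clock time-judgment trials, and speeded RT trials (spatial cueing
and Simon) — from a single-common-factor latent participant model.

The latent trait ``theta`` (standard normal; higher = slower attentional
engagement) drives every measure through a monotone link plus
measure-specific noise.  The intrusion propensity uses an inverse-logit
link whose intercept/slope are solved numerically so the population mean
and SD of the propensity match the configured targets; loadings for the
other measures are solved so the population product-moment correlation of
each measure with the intrusion propensity hits its configured target.

All randomness is governed by one top-level seed; identical seed + config
give byte-identical trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .errors import ConfigurationError

DIGITS = np.arange(2, 10)  # reportable digits 2-9

_GH_POINTS = 101


def _gh_nodes(m: int = _GH_POINTS) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for E[f(Z)], Z ~ N(0,1)."""
    x, w = np.polynomial.hermite_e.hermegauss(m)
    return x, w / w.sum()


def _logitnormal_moments(a: float, b: float) -> tuple[float, float]:
    x, w = _gh_nodes()
    p = expit(a + b * x)
    m = float(w @ p)
    v = float(w @ (p - m) ** 2)
    return m, float(np.sqrt(v))


def solve_logit_link(mean: float, sd: float) -> tuple[float, float]:
    """Solve (a, b) so that expit(a + b*Z), Z~N(0,1), has the given mean and SD.

    Raises ConfigurationError when the requested SD is infeasible for a
    distribution supported on (0, 1) with that mean.
    """
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(f"mean must be in (0,1), got {mean}")
    if sd < 0:
        raise ConfigurationError(f"sd must be >= 0, got {sd}")
    if sd == 0.0:
        return float(logit(mean)), 0.0
    if sd ** 2 >= mean * (1.0 - mean):
        raise ConfigurationError(
            f"sd={sd} infeasible for a (0,1)-supported distribution with mean={mean}"
        )

    def fun(ab):
        m, s = _logitnormal_moments(ab[0], ab[1])
        return [m - mean, s - sd]

    # delta-method start values
    a0, b0 = float(logit(mean)), sd / (mean * (1.0 - mean))
    sol = optimize.root(fun, x0=[a0, b0], method="hybr", tol=1e-12)
    if not sol.success or abs(sol.x[1]) > 50:
        raise ConfigurationError(
            f"logit-link moment matching failed for mean={mean}, sd={sd}: {sol.message}"
        )
    a, b = float(sol.x[0]), float(abs(sol.x[1]))
    return a, b


def _corr_p_theta(a: float, b: float) -> float:
    """corr(expit(a + b*theta), theta) under theta ~ N(0,1)."""
    if b == 0.0:
        return 0.0
    x, w = _gh_nodes()
    p = expit(a + b * x)
    mp = w @ p
    sp = np.sqrt(w @ (p - mp) ** 2)
    cov = w @ ((p - mp) * x)
    return float(cov / sp)


def _solve_loading_nonlinear(a: float, b: float, link, target: float) -> float:
    """Solve the loading lam so that corr(p(theta), link(lam*theta + sqrt(1-lam^2)*u))
    equals `target`, for theta, u independent standard normals.

    `link` maps an array of standard-normal latents to measure values and must
    be monotone increasing; the correlation is computed on a 2-D Gauss-Hermite
    product grid.
    """
    if target == 0.0:
        return 0.0
    x, w = _gh_nodes(81)
    p = expit(a + b * x)
    mp = w @ p
    sp = np.sqrt(w @ (p - mp) ** 2)
    if sp == 0.0:
        raise ConfigurationError("intrusion propensity has zero variance; loadings undefined")
    W = np.outer(w, w)

    def corr_at(lam: float) -> float:
        z = lam * x[:, None] + np.sqrt(1.0 - lam * lam) * x[None, :]
        m = link(z)
        mm = float((W * m).sum())
        sm = float(np.sqrt((W * (m - mm) ** 2).sum()))
        cov = float((W * (p[:, None] - mp) * (m - mm)).sum())
        return cov / (sp * sm)

    cmax = corr_at(0.999999)
    if abs(target) > abs(cmax):
        raise ConfigurationError(
            f"loading target {target} exceeds maximum attainable correlation {cmax:.3f}"
        )
    return float(optimize.brentq(lambda lam: corr_at(lam) - target, -0.999999, 0.999999, xtol=1e-10))


def _std_lognormal(z: np.ndarray, skew_sigma: float) -> np.ndarray:
    """Standardized shifted log-normal: mean 0, SD 1, right-skewed, monotone in z.

    Lower-bounded at -1/sqrt(exp(sigma^2)-1); skew grows with `skew_sigma`.
    """
    if skew_sigma == 0.0:
        return np.asarray(z, dtype=float)
    s = np.sqrt(np.expm1(skew_sigma ** 2))
    return (np.exp(skew_sigma * np.asarray(z, dtype=float) - skew_sigma ** 2 / 2.0) - 1.0) / s


@dataclass(frozen=True)
class LatentProfile:
    """Per-participant generative truths for all four task families."""

    participant_id: str
    theta: float
    p_correct: float
    p_intrusion: float
    p_other: float
    t1_acc_true: float
    t2_lag3_true: float
    t2_lag7_true: float
    mu_time_error: float  # degrees
    mu_rt: float  # ms, search-task overall mean
    age: float  # years
    reading_swe: float  # words / 45 s
    reading_pde: float  # words / 45 s

    def __post_init__(self):
        total = self.p_correct + self.p_intrusion + self.p_other
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"category probabilities sum to {total}, not 1")
        for name in ("p_correct", "p_intrusion", "p_other",
                     "t1_acc_true", "t2_lag3_true", "t2_lag7_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if self.mu_rt <= 0:
            raise ConfigurationError(f"mu_rt must be positive, got {self.mu_rt}")


def _default_loadings() -> dict[str, float]:
    # correlation-with-intrusion-propensity targets; zeros reproduce the
    # null associations (AB magnitude, reading) seen in the real cohorts
    return {
        "t1_acc": -0.68,
        "t2_lag3": 0.0,
        "t2_lag7": 0.0,
        "time_error": 0.40,
        "rt": 0.25,
        "reading_swe": 0.0,
        "reading_pde": 0.0,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration targets and design sizes for the synthetic cohort.

    Defaults reproduce the population structure of the real studies: DI
    propensity mean .296 / SD .200, T1 accuracy .829 (SD .148), T2 accuracy
    .811 at lag 7 vs .408 at lag 3 (AB magnitude .403), mean time error
    22.41 deg (SD 15.14), search / Simon RT means 547 / 436 ms.
    """

    n_participants: int = 100
    n_sessions: int = 2
    seed: int = 0

    di_mean: float = 0.296
    di_sd: float = 0.200
    guess_mean: float = 0.115  # fraction of non-intrusion mass that is a guess
    guess_concentration: float = 50.0

    t1_mean: float = 0.829
    t1_sd: float = 0.148
    t2_lag7_mean: float = 0.811
    t2_lag7_sd: float = 0.177
    t2_lag3_mean: float = 0.408
    t2_lag3_sd: float = 0.200

    time_error_mean: float = 22.41  # degrees, between-participant
    time_error_sd: float = 15.14
    time_error_within_sd: float = 40.0  # degrees, trial-level
    time_skew_sigma: float = 0.6
    wild_fraction: float = 0.02  # uniform-on-circle responses

    rt_mean_search: float = 547.0
    rt_sd_search: float = 58.0
    rt_mean_simon: float = 436.0
    rt_sd_simon: float = 52.0
    rt_within_sd: float = 100.0  # ms, trial-level
    rt_skew_sigma: float = 0.6
    # condition offsets (ms) relative to cue-absent / response-compatible
    cueing_offsets: dict = field(default_factory=lambda: {"absent": 0.0, "different": 37.0, "same": -36.0})
    cueing_probs: dict = field(default_factory=lambda: {"absent": 0.2, "different": 0.4, "same": 0.4})
    cueing_acc: dict = field(default_factory=lambda: {"absent": 0.975, "different": 0.950, "same": 0.978})
    simon_offsets: dict = field(default_factory=lambda: {"compatible": 0.0, "incompatible": 81.0})
    simon_probs: dict = field(default_factory=lambda: {"compatible": 0.75, "incompatible": 0.25})
    simon_acc: dict = field(default_factory=lambda: {"compatible": 0.989, "incompatible": 0.857})

    age_mean: float = 27.0
    age_sd: float = 6.0
    age_range: tuple = (18.0, 45.0)
    age_rt_corr: float = 0.36  # general slowing: corr(age, overall RT)

    reading_swe_mean: float = 78.0
    reading_swe_sd: float = 11.0
    reading_pde_mean: float = 48.0
    reading_pde_sd: float = 10.0

    loadings: dict = field(default_factory=_default_loadings)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0.0 < self.di_mean < 1.0:
            raise ConfigurationError(f"di_mean must be in (0,1), got {self.di_mean}")
        if self.di_sd < 0:
            raise ConfigurationError("di_sd must be >= 0")
        if self.di_sd > 0 and self.di_sd ** 2 >= self.di_mean * (1.0 - self.di_mean):
            raise ConfigurationError(
                f"di_sd={self.di_sd} infeasible for a propensity on (0,1) with mean {self.di_mean}"
            )
        if not 0.0 <= self.wild_fraction < 1.0:
            raise ConfigurationError("wild_fraction must be in [0,1)")
        for k in self.loadings:
            if k not in _default_loadings():
                raise ConfigurationError(f"unknown loading target {k!r}")


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def _pid(i: int) -> str:
    return f"P{i + 1:04d}"


def gen_profiles(config: GeneratorConfig) -> list[LatentProfile]:
    """Draw latent participant profiles from the single-common-factor model.

    theta ~ N(0,1); the intrusion propensity is inverse-logit in theta with
    intercept/slope moment-matched to (di_mean, di_sd); every other measure
    is a monotone link of its own latent z = lam*theta + sqrt(1-lam^2)*noise
    with lam solved so the population correlation with the propensity equals
    the configured loading target.
    """
    cfg = config
    n = cfg.n_participants
    rng = _rng(cfg.seed, 0)
    theta = rng.standard_normal(n)

    a, b = solve_logit_link(cfg.di_mean, cfg.di_sd)
    p_int = expit(a + b * theta)
    r_pt = _corr_p_theta(a, b)

    # guess propensity: independent beta fraction of the non-intrusion mass,
    # so p_correct >= 0 holds by construction
    gm, gc = cfg.guess_mean, cfg.guess_concentration
    if gm > 0:
        g = rng.beta(gm * gc, (1.0 - gm) * gc, size=n)
    else:
        g = np.zeros(n)
    p_other = g * (1.0 - p_int)
    p_correct = 1.0 - p_int - p_other

    def latent(name: str, lam: float) -> np.ndarray:
        eps = rng.standard_normal(n)
        return lam * theta + np.sqrt(max(0.0, 1.0 - lam * lam)) * eps

    load = {**_default_loadings(), **cfg.loadings}

    # bounded accuracy measures: logit-normal links, loadings solved on the
    # transformed scale so the propensity correlation is hit exactly
    a1, b1 = solve_logit_link(cfg.t1_mean, cfg.t1_sd)
    lam1 = _solve_loading_nonlinear(a, b, lambda z: expit(a1 + b1 * z), load["t1_acc"]) if cfg.di_sd > 0 else 0.0
    t1 = expit(a1 + b1 * latent("t1", lam1))

    a3, b3 = solve_logit_link(cfg.t2_lag3_mean, cfg.t2_lag3_sd)
    lam3 = _solve_loading_nonlinear(a, b, lambda z: expit(a3 + b3 * z), load["t2_lag3"]) if cfg.di_sd > 0 else 0.0
    t2l3 = expit(a3 + b3 * latent("t2_lag3", lam3))

    a7, b7 = solve_logit_link(cfg.t2_lag7_mean, cfg.t2_lag7_sd)
    lam7 = _solve_loading_nonlinear(a, b, lambda z: expit(a7 + b7 * z), load["t2_lag7"]) if cfg.di_sd > 0 else 0.0
    t2l7 = expit(a7 + b7 * latent("t2_lag7", lam7))

    # positively skewed between-participant time-error distribution
    te_link = lambda z: cfg.time_error_mean + cfg.time_error_sd * _std_lognormal(z, cfg.time_skew_sigma)
    lam_te = _solve_loading_nonlinear(a, b, te_link, load["time_error"]) if cfg.di_sd > 0 else 0.0
    mu_te = te_link(latent("time_error", lam_te))

    # age is trait-independent; it feeds RT directly (general slowing)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), *cfg.age_range)
    beta_age = cfg.age_rt_corr * cfg.rt_sd_search / cfg.age_sd
    var_age_part = (beta_age * cfg.age_sd) ** 2
    if var_age_part >= cfg.rt_sd_search ** 2:
        raise ConfigurationError("age_rt_corr too large for the configured RT SD")
    s_signal = np.sqrt(cfg.rt_sd_search ** 2 - var_age_part)
    # affine measure: loading scaled for the share of RT variance not due to age
    lam_rt = 0.0
    if cfg.di_sd > 0 and load["rt"] != 0.0:
        lam_rt = load["rt"] * cfg.rt_sd_search / (r_pt * s_signal)
        if abs(lam_rt) > 1.0:
            raise ConfigurationError(f"rt loading target {load['rt']} infeasible")
    mu_rt = cfg.rt_mean_search + s_signal * latent("rt", lam_rt) + beta_age * (age - cfg.age_mean)

    def affine(name, mean, sd, key):
        lam = 0.0
        if cfg.di_sd > 0 and load[key] != 0.0:
            lam = load[key] / r_pt
            if abs(lam) > 1.0:
                raise ConfigurationError(f"{key} loading target {load[key]} infeasible")
        return mean + sd * latent(name, lam)

    swe = affine("swe", cfg.reading_swe_mean, cfg.reading_swe_sd, "reading_swe")
    pde = affine("pde", cfg.reading_pde_mean, cfg.reading_pde_sd, "reading_pde")

    # numerical guard: keep exact simplex identity under float rounding
    p_correct = np.clip(p_correct, 0.0, 1.0)
    p_other = 1.0 - p_int - p_correct

    return [
        LatentProfile(
            participant_id=_pid(i),
            theta=float(theta[i]),
            p_correct=float(p_correct[i]),
            p_intrusion=float(p_int[i]),
            p_other=float(p_other[i]),
            t1_acc_true=float(t1[i]),
            t2_lag3_true=float(t2l3[i]),
            t2_lag7_true=float(t2l7[i]),
            mu_time_error=float(mu_te[i]),
            mu_rt=float(mu_rt[i]),
            age=float(age[i]),
            reading_swe=float(swe[i]),
            reading_pde=float(pde[i]),
        )
        for i in range(n)
    ]


def profiles_frame(profiles: list[LatentProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in profiles])


def _response_digits(rng, cat, target, post):
    """Map category codes (0 correct, 1 intrusion, 2 other) to reported digits."""
    resp = np.where(cat == 0, target, post)
    other_mask = cat == 2
    if other_mask.any():
        # uniform over the six digits that are neither target nor post-target
        offs = rng.integers(0, 6, size=int(other_mask.sum()))
        t, p = target[other_mask], post[other_mask]
        pool = np.tile(DIGITS, (len(offs), 1))
        bad = (pool == t[:, None]) | (pool == p[:, None])
        order = np.argsort(bad, axis=1, kind="stable")  # valid digits first
        picked = np.take_along_axis(pool, order, axis=1)[np.arange(len(offs)), offs]
        resp = resp.copy()
        resp[other_mask] = picked
    return resp


def gen_di_trials(profiles: list[LatentProfile], n_trials: int, session: int = 1,
                  seed: int = 0) -> pd.DataFrame:
    """Single-target DI trials: target digit, distinct post-target digit, and a
    response drawn from {target, post-target, other} with the profile's
    category probabilities.  Trials are exchangeable given the profile."""
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    rng = _rng(seed, 1, session)
    n_p = len(profiles)
    shape = (n_p, n_trials)
    pc = np.array([p.p_correct for p in profiles])[:, None]
    pi = np.array([p.p_intrusion for p in profiles])[:, None]

    target = rng.integers(0, 8, size=shape) + 2
    post = (target - 2 + 1 + rng.integers(0, 7, size=shape)) % 8 + 2
    u = rng.random(shape)
    cat = np.where(u < pc, 0, np.where(u < pc + pi, 1, 2))
    resp = _response_digits(rng, cat.ravel(), target.ravel(), post.ravel())

    return pd.DataFrame({
        "participant_id": np.repeat([p.participant_id for p in profiles], n_trials),
        "session": session,
        "trial_index": np.tile(np.arange(n_trials), n_p),
        "target_id": target.ravel(),
        "posttarget_id": post.ravel(),
        "response_id": resp,
    })


def gen_ab_trials(profiles: list[LatentProfile], n_trials: int, session: int = 1,
                  seed: int = 0) -> pd.DataFrame:
    """Attentional-blink task trials: half single-target (DI-capable), half
    two-target split equally between lag 3 and lag 7.  T2 fields are present
    only on two-target rows."""
    if n_trials % 4 != 0 or n_trials < 4:
        raise ConfigurationError(
            f"n_trials={n_trials} not divisible into the half-single / half-dual, "
            "equal-lag design (must be a positive multiple of 4)"
        )
    rng = _rng(seed, 2, session)
    n_single = n_trials // 2
    n_lag = n_trials // 4
    n_p = len(profiles)
    shape = (n_p, n_trials)

    # per-participant random order of single / dual-lag3 / dual-lag7 slots
    base = np.concatenate([np.zeros(n_single, dtype=int),
                           np.full(n_lag, 1), np.full(n_lag, 2)])
    kind = rng.permuted(np.tile(base, (n_p, 1)), axis=1)
    dual = kind > 0
    lag = np.where(kind == 1, 3.0, np.where(kind == 2, 7.0, np.nan))

    # single-target rows behave exactly like DI trials
    pc = np.array([p.p_correct for p in profiles])[:, None]
    pi = np.array([p.p_intrusion for p in profiles])[:, None]
    target = rng.integers(0, 8, size=shape) + 2
    post = (target - 2 + 1 + rng.integers(0, 7, size=shape)) % 8 + 2
    u = rng.random(shape)
    cat = np.where(u < pc, 0, np.where(u < pc + pi, 1, 2))
    resp = _response_digits(rng, cat.ravel(), target.ravel(), post.ravel()).reshape(shape)
    target = target.astype(float)
    post = post.astype(float)
    resp = resp.astype(float)
    target[dual] = post[dual] = resp[dual] = np.nan

    t1_true = np.array([p.t1_acc_true for p in profiles])[:, None]
    t2l3 = np.array([p.t2_lag3_true for p in profiles])[:, None]
    t2l7 = np.array([p.t2_lag7_true for p in profiles])[:, None]
    t1_id = (rng.integers(0, 8, size=shape) + 2).astype(float)
    t2_id = (t1_id - 2 + 1 + rng.integers(0, 7, size=shape)) % 8 + 2
    t1_ok = rng.random(shape) < t1_true
    p2 = np.where(lag == 3.0, t2l3, t2l7)
    t2_ok = rng.random(shape) < p2
    wrong1 = (t1_id - 2 + 1 + rng.integers(0, 7, size=shape)) % 8 + 2
    wrong2 = (t2_id - 2 + 1 + rng.integers(0, 7, size=shape)) % 8 + 2
    t1_resp = np.where(t1_ok, t1_id, wrong1)
    t2_resp = np.where(t2_ok, t2_id, wrong2)
    t1_id[~dual] = t1_resp[~dual] = t2_id[~dual] = t2_resp[~dual] = np.nan

    return pd.DataFrame({
        "participant_id": np.repeat([p.participant_id for p in profiles], n_trials),
        "session": session,
        "trial_index": np.tile(np.arange(n_trials), n_p),
        "trial_type": np.where(dual, "dual", "single").ravel(),
        "lag": lag.ravel(),
        "t1_id": t1_id.ravel(),
        "t1_response": t1_resp.ravel(),
        "t2_id": t2_id.ravel(),
        "t2_response": t2_resp.ravel(),
        "target_id": target.ravel(),
        "posttarget_id": post.ravel(),
        "response_id": resp.ravel(),
    })


def gen_time_trials(profiles: list[LatentProfile], n_trials: int, seed: int = 0,
                    within_sd: float | None = None, skew_sigma: float | None = None,
                    wild_fraction: float | None = None,
                    config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Clock time-judgment trials: uniform cue angle, response = cue + signed
    error from a right-skewed distribution centered on the profile's mean
    time error, with a small fraction of wild (uniform-on-circle) responses."""
    cfg = config or GeneratorConfig()
    within_sd = cfg.time_error_within_sd if within_sd is None else within_sd
    skew_sigma = cfg.time_skew_sigma if skew_sigma is None else skew_sigma
    wild_fraction = cfg.wild_fraction if wild_fraction is None else wild_fraction
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    rng = _rng(seed, 3)
    n_p = len(profiles)
    shape = (n_p, n_trials)
    mu = np.array([p.mu_time_error for p in profiles])[:, None]
    cue = rng.uniform(0.0, 360.0, size=shape)
    err = mu + within_sd * _std_lognormal(rng.standard_normal(shape), skew_sigma)
    resp = (cue + err) % 360.0
    if wild_fraction > 0:
        wild = rng.random(shape) < wild_fraction
        resp[wild] = rng.uniform(0.0, 360.0, size=int(wild.sum()))
    return pd.DataFrame({
        "participant_id": np.repeat([p.participant_id for p in profiles], n_trials),
        "trial_index": np.tile(np.arange(n_trials), n_p),
        "cue_angle_deg": cue.ravel(),
        "response_angle_deg": resp.ravel(),
    })


RT_TASKS = ("cueing", "simon")


def gen_rt_trials(profiles: list[LatentProfile], task: str, n_trials: int,
                  seed: int = 0, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Speeded RT trials for the cueing (visual search) or Simon task.

    RT = participant task mean + condition offset + right-skewed noise;
    accuracy is Bernoulli per condition; condition frequencies follow the
    task designs (cue present 80%, Simon compatible 75%)."""
    cfg = config or GeneratorConfig()
    if task not in RT_TASKS:
        raise ConfigurationError(f"unknown RT task {task!r}; expected one of {RT_TASKS}")
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    if task == "cueing":
        offsets, probs, acc = cfg.cueing_offsets, cfg.cueing_probs, cfg.cueing_acc
    else:
        offsets, probs, acc = cfg.simon_offsets, cfg.simon_probs, cfg.simon_acc
    conds = sorted(offsets)
    pvec = np.array([probs[c] for c in conds])
    pvec = pvec / pvec.sum()
    mean_offset = float(sum(probs[c] * offsets[c] for c in conds) / sum(probs.values()))
    rng = _rng(seed, 4, RT_TASKS.index(task))
    n_p = len(profiles)
    shape = (n_p, n_trials)
    mu_base = np.array([p.mu_rt for p in profiles])[:, None]
    if task != "cueing":
        mu_base = cfg.rt_mean_simon + (mu_base - cfg.rt_mean_search) * (cfg.rt_sd_simon / cfg.rt_sd_search)
    ci = np.searchsorted(np.cumsum(pvec), rng.random(shape), side="right")
    off = np.array([offsets[c] for c in conds])[ci]
    noise = cfg.rt_within_sd * _std_lognormal(rng.standard_normal(shape), cfg.rt_skew_sigma)
    rt = mu_base - mean_offset + off + noise
    pacc = np.array([acc[c] for c in conds])[ci]
    correct = (rng.random(shape) < pacc).astype(int)
    return pd.DataFrame({
        "participant_id": np.repeat([p.participant_id for p in profiles], n_trials),
        "task": task,
        "condition": np.array(conds, dtype=object)[ci].ravel(),
        "trial_index": np.tile(np.arange(n_trials), n_p),
        "rt_ms": rt.ravel(),
        "correct": correct.ravel(),
    })


def gen_covariates(profiles: list[LatentProfile], seed: int = 0) -> pd.DataFrame:
    """Participant covariate table: age, task-order group, reading scores."""
    rng = _rng(seed, 5)
    order = rng.permutation(len(profiles))
    group = np.where(order < len(profiles) // 2, "search_first", "simon_first")
    return pd.DataFrame({
        "participant_id": [p.participant_id for p in profiles],
        "age": [p.age for p in profiles],
        "order_group": group,
        "reading_swe": [p.reading_swe for p in profiles],
        "reading_pde": [p.reading_pde for p in profiles],
    })


@dataclass
class Cohort:
    """Bundle of all generated tables for one synthetic study."""

    config: GeneratorConfig
    profiles: list[LatentProfile]
    di_trials: pd.DataFrame  # all sessions stacked
    ab_trials: pd.DataFrame
    time_trials: pd.DataFrame
    rt_trials: pd.DataFrame  # both tasks stacked
    covariates: pd.DataFrame


def generate_cohort(config: GeneratorConfig | None = None, *,
                    di_trials_per_session: int = 60, ab_trials: int = 96,
                    time_trials: int = 100, rt_trials_per_task: int = 160) -> Cohort:
    """Run the full generator: profiles plus all four trial tables.

    Every stage derives its stream from the config's top-level seed, so the
    cohort is byte-identical across runs with the same arguments.
    """
    cfg = config or GeneratorConfig()
    profiles = gen_profiles(cfg)
    di = pd.concat(
        [gen_di_trials(profiles, di_trials_per_session, session=s, seed=cfg.seed)
         for s in range(1, cfg.n_sessions + 1)],
        ignore_index=True,
    )
    ab = gen_ab_trials(profiles, ab_trials, session=1, seed=cfg.seed)
    tt = gen_time_trials(profiles, time_trials, seed=cfg.seed, config=cfg)
    rt = pd.concat(
        [gen_rt_trials(profiles, task, rt_trials_per_task, seed=cfg.seed, config=cfg)
         for task in RT_TASKS],
        ignore_index=True,
    )
    cov = gen_covariates(profiles, seed=cfg.seed)
    return Cohort(cfg, profiles, di, ab, tt, rt, cov)


def di_trial_matrix(di_trials: pd.DataFrame, session: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Pivot DI trials to a participants x trials binary intrusion matrix."""
    df = di_trials
    if session is not None:
        df = df[df["session"] == session]
    intr = (df["response_id"] == df["posttarget_id"]).astype(int)
    wide = (df.assign(intrusion=intr)
              .pivot_table(index="participant_id", columns="trial_index",
                           values="intrusion", aggfunc="first")
              .sort_index())
    if wide.isna().any().any():
        raise ConfigurationError("ragged trial table: participants differ in trial indices")
    return wide.to_numpy(dtype=int), list(wide.index)


def mechanistic_di_trials(profiles: list[LatentProfile], n_trials: int, seed: int = 0,
                          soa_ms: float = 100.0, tau1_ms: float | None = None,
                          tau2_ms: float | None = None, latency_sigma: float = 0.35,
                          median_scale_ms: float = 25.0) -> pd.DataFrame:
    """Optional mechanistic DI generator based on attentional-engagement latency.

    Each trial draws an engagement latency L ~ LogNormal with a theta-dependent
    median; L <= tau1 yields a correct report, tau1 < L <= tau2 an intrusion,
    and L > tau2 a guess.  Thresholds default to one and two SOAs (100 ms per
    frame), mirroring the diachronic account of intrusions qualitatively.
    """
    tau1 = soa_ms if tau1_ms is None else tau1_ms
    tau2 = 2 * soa_ms if tau2_ms is None else tau2_ms
    if not 0 < tau1 < tau2:
        raise ConfigurationError("need 0 < tau1 < tau2")
    rng = _rng(seed, 6)
    rows = []
    for prof in profiles:
        median = tau1 * np.exp(latency_sigma * prof.theta)
        lat = median * np.exp(latency_sigma * rng.standard_normal(n_trials))
        cat = np.where(lat <= tau1, 0, np.where(lat <= tau2, 1, 2))
        target = rng.choice(DIGITS, size=n_trials)
        post = (target - 2 + 1 + rng.integers(0, 7, size=n_trials)) % 8 + 2
        resp = _response_digits(rng, cat, target, post)
        rows.append(pd.DataFrame({
            "participant_id": prof.participant_id,
            "session": 1,
            "trial_index": np.arange(n_trials),
            "target_id": target,
            "posttarget_id": post,
            "response_id": resp,
        }))
    return pd.concat(rows, ignore_index=True)
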