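"""The semi-Markov process (SMP) model of free-association generation.

Generative process for one trial, given a cue's typicality norms and a
participant's seven parameters:

1. A candidate association ``A_i`` is sampled from the *tempered* generation
   distribution ``P(A_i) = pTP_i**exp(beta) / sum_j pTP_j**exp(beta)``.
2. Its generation time is gamma distributed with mean
   ``mu_i = exp(s_mu) * (-log P(A_i))`` (weaker associations are slower) and
   standard deviation ``sigma_i = lam * mu_i``.
3. The candidate is accepted with probability
   ``logistic(10 * (MX(pTP)_i - alpha_I))`` when ``alpha_sign = +1`` (the
   mirrored ``MX(1 - pTP)`` form when ``alpha_sign = -1``), where ``MX`` is a
   min-max transform of the cue's typicalities.  Rejected candidates are
   resampled from scratch (memoryless), each costing its generation time.
4. The reaction time is the sum of all generation times plus a uniform
   non-decision time on ``[tau0, tau0 + tau_r]``.

The reaction time is thus a first-passage time to acceptance: a geometric
number of gamma-distributed holding times.  In transform space the joint
density of (reported association j, total generation time) is

    L_j(s) = P_j * acc_j * G_j(s) / (1 - sum_i P_i * (1 - acc_i) * G_i(s))

with ``G_i`` the gamma-time transform.  :func:`trial_joint_density` inverts
this characteristic function numerically (FFT on a uniform grid) and
composes it with the uniform non-decision window analytically, as a CDF
difference divided by ``tau_r``.
"""

from __future__ import annotations

import numpy as np

from .norms import CueNorms
from .params import SMPParameters

#: Fixed slope of the acceptance logistic (not a free parameter).
ACCEPTANCE_SLOPE = 10.0

#: Log-density floor: guards importance weights against -inf.
LOG_DENSITY_FLOOR = -745.0

#: Cap on candidate draws per simulated trial; exceeded only for
#: pathological parameter settings where acceptance is essentially zero.
SIMULATION_CANDIDATE_CAP = 10_000


class DivergentTrialError(RuntimeError):
    """Raised when a simulated trial fails to accept within the candidate cap."""


# ---------------------------------------------------------------------------
# Elementary model components


def generation_distribution(typicalities: np.ndarray | CueNorms, beta: float) -> np.ndarray:
    """Tempered generation distribution over a cue's candidate set.

    ``P(A_i) = pTP_i**exp(beta) / sum_j pTP_j**exp(beta)``.  ``beta = 0``
    reproduces the typicalities themselves (when normalized); ``beta -> -inf``
    flattens toward uniform.
    """
    if isinstance(typicalities, CueNorms):
        typicalities = typicalities.typicalities
    t = np.asarray(typicalities, dtype=float)
    if t.size == 0:
        raise ValueError("empty candidate set")
    if np.any(t <= 0):
        raise ValueError("typicalities must be positive")
    # work in logs for numerical safety at extreme beta
    logw = np.exp(beta) * np.log(t)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def minmax_transform(values: np.ndarray) -> np.ndarray:
    """Min-max transform to [0, 1]; an all-equal vector maps to 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def acceptance_probability(
    typicalities: np.ndarray | CueNorms,
    index: int | None,
    alpha_I: float,
    alpha_sign: int,
) -> float | np.ndarray:
    """Probability that a sampled candidate is accepted and reported.

    With ``alpha_sign = +1`` acceptance increases with (min-max transformed)
    typicality; with ``-1`` it decreases.  The logistic slope is the fixed
    constant :data:`ACCEPTANCE_SLOPE`.  ``index=None`` returns the whole
    vector.
    """
    if isinstance(typicalities, CueNorms):
        typicalities = typicalities.typicalities
    t = np.asarray(typicalities, dtype=float)
    mx = minmax_transform(t)
    if alpha_sign == 1:
        p = _logistic(ACCEPTANCE_SLOPE * (mx - alpha_I))
    elif alpha_sign == -1:
        # MX is affine, so MX(1 - pTP) = 1 - MX(pTP)
        p = _logistic(ACCEPTANCE_SLOPE * ((1.0 - mx) - alpha_I))
    else:
        raise ValueError("alpha_sign must be +1 or -1")
    if index is None:
        return p
    return float(p[index])


def generation_time_spec(probabilities: np.ndarray, s_mu: float, lam: float) -> dict:
    """Gamma generation-time parameters for each candidate association.

    ``mu_i = exp(s_mu) * (-log P(A_i))`` and ``sigma_i = lam * mu_i``; the
    gamma shape is the constant ``1/lam**2`` and the scale ``lam**2 * mu_i``
    (moment matching).  A sure association (P = 1) has a point mass at 0.
    """
    p = np.asarray(probabilities, dtype=float)
    if lam <= 0:
        raise ValueError("lam must be positive")
    mu = np.exp(s_mu) * (-np.log(p))
    mu = np.where(p >= 1.0, 0.0, mu)
    sigma = lam * mu
    shape = np.full_like(mu, 1.0 / lam**2)
    scale = lam**2 * mu
    return {"mu": mu, "sigma": sigma, "gamma_shape": shape, "gamma_scale": scale}


# ---------------------------------------------------------------------------
# Forward simulation


def simulate_trial(
    norms_for_cue: CueNorms,
    params: SMPParameters,
    rng: np.random.Generator,
    no_rejection: bool = False,
) -> tuple[str, float, int]:
    """Simulate one trial; returns (reported lemma, rt seconds, n_rejected).

    Candidates are drawn with replacement from the tempered distribution;
    each costs a gamma generation time; the first accepted one is reported.
    RT adds a Uniform(tau0, tau0 + tau_r) non-decision time.
    """
    p = generation_distribution(norms_for_cue.typicalities, params.beta)
    if no_rejection:
        acc = np.ones_like(p)
    else:
        acc = acceptance_probability(
            norms_for_cue.typicalities, None, params.alpha_I, params.alpha_sign
        )
        if np.all(acc <= 1e-6):
            raise DivergentTrialError(
                f"acceptance probabilities all <= 1e-6 for cue {norms_for_cue.cue_id}"
            )
    spec = generation_time_spec(p, params.s_mu, params.lam)
    shape, scale = spec["gamma_shape"], spec["gamma_scale"]

    total = 0.0
    n_rejected = 0
    for _ in range(SIMULATION_CANDIDATE_CAP):
        i = int(rng.choice(len(p), p=p))
        if scale[i] > 0:
            total += rng.gamma(shape[i], scale[i])
        if rng.random() < acc[i]:
            ndt = params.tau0 + params.tau_r * rng.random()
            return norms_for_cue.lemmas[i], total + ndt, n_rejected
        n_rejected += 1
    raise DivergentTrialError(
        f"no acceptance within {SIMULATION_CANDIDATE_CAP} candidates "
        f"for cue {norms_for_cue.cue_id}"
    )


# ---------------------------------------------------------------------------
# Joint density of (reported association, RT) via transform inversion


def _gamma_cf(omega: np.ndarray, shape: float, scale: np.ndarray) -> np.ndarray:
    """E[exp(-i*omega*T)] for Gamma(shape, scale_i); broadcast over scales.

    Computed as (1 + i*omega*scale)^(-shape) through magnitude/phase, which
    avoids complex powers.  scale = 0 gives the unit transform (point mass
    at zero).
    """
    x = omega[..., None, :] * scale[..., :, None] if scale.ndim else omega * scale
    logmag = -0.5 * shape * np.log1p(x * x)
    phase = -shape * np.arctan(x)
    return np.exp(logmag) * (np.cos(phase) + 1j * np.sin(phase))


def _generation_time_grid(
    p: np.ndarray,
    acc: np.ndarray,
    j: int,
    s_mu: float,
    lam: float,
    n_grid: int,
    t_max: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Sub-density (mass P_j*acc_j / sum_i P_i*acc_i) of the total generation
    time for trials reported as association ``j``, on a uniform grid.

    Returns (density values at k*dt for k = 0..n_grid-1, dt, atom at zero).
    """
    spec = generation_time_spec(p, s_mu, lam)
    mu, scale = spec["mu"], spec["gamma_scale"]
    shape = 1.0 / lam**2

    q = float(np.sum(p * (1.0 - acc)))  # per-draw rejection mass
    q = min(q, 1.0 - 1e-12)
    expected_draws = 1.0 / (1.0 - q)
    m1 = float(np.sum(p * mu))
    m2 = float(np.sum(p * mu * mu * (1.0 + lam**2)))
    mean_total = expected_draws * m1
    var_bound = expected_draws * m2 + q * expected_draws**2 * m1**2
    if t_max is None:
        t_max = mean_total + 14.0 * np.sqrt(var_bound) + 1e-6
        t_max = float(np.clip(t_max, 1e-3, 2000.0))
    dt = t_max / n_grid

    if mu[j] == 0.0 and q <= 1e-12:
        # sure, instantaneous report: pure atom at zero
        atom = float(p[j] * acc[j] / max(np.sum(p * acc), 1e-300))
        return np.zeros(n_grid), dt, atom

    omega = 2.0 * np.pi * np.arange(n_grid // 2 + 1) / (n_grid * dt)
    cf_all = _gamma_cf(omega, shape, scale)  # (n_cand, n_freq)
    numer = p[j] * acc[j] * cf_all[j]
    denom = 1.0 - (p * (1.0 - acc)) @ cf_all
    psi = numer / denom
    dens = np.fft.irfft(psi, n_grid) / dt
    return np.maximum(dens, 0.0), dt, 0.0


def trial_joint_density(
    norms_for_cue: CueNorms,
    params: SMPParameters,
    reported: str,
    rt: float,
    n_grid: int = 8192,
    no_rejection: bool = False,
) -> float:
    """Joint density of (reported association, reaction time) for one trial.

    ``rt`` is in seconds.  RTs at or below ``tau0`` have density 0 (the
    non-decision floor).  Unseen reported lemmas are added to the candidate
    set with smoothed typicality.
    """
    if rt <= params.tau0:
        return 0.0
    cn, j = norms_for_cue.with_smoothed(reported)
    p = generation_distribution(cn.typicalities, params.beta)
    if no_rejection:
        acc = np.ones_like(p)
    else:
        acc = acceptance_probability(cn.typicalities, None, params.alpha_I, params.alpha_sign)
    dens, dt, atom = _generation_time_grid(
        p, acc, j, params.s_mu, params.lam, n_grid,
        t_max=None if rt - params.tau0 < 1500.0 else 1.5 * (rt - params.tau0),
    )
    # convolution with Uniform(tau0, tau0 + tau_r) = CDF difference / tau_r
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])) * dt)) + atom

    def F(t: float) -> float:
        if t <= 0:
            return 0.0 if t < 0 else atom
        k = t / dt
        if k >= n_grid - 1:
            return float(cdf[-1])
        i = int(k)
        frac = k - i
        return float(cdf[i] * (1 - frac) + cdf[i + 1] * frac)

    a = rt - params.tau0
    b = rt - params.tau0 - params.tau_r
    result = max((F(a) - F(b)) / params.tau_r, 0.0)
    # deep tails: below the FFT noise floor, fall back to the exact
    # zero-rejection gamma-window density (a lower bound on the truth)
    spec = generation_time_spec(p, params.s_mu, params.lam)
    n0 = gamma_window_logdensity(
        1.0 / params.lam**2, spec["gamma_scale"][j], a, b, params.tau_r,
        float(np.log(max(p[j] * acc[j], 1e-300))),
    )
    noise = 1e-12 * float(np.max(dens)) / params.tau_r if np.any(dens > 0) else 0.0
    if result <= noise:
        result = 0.0
    return max(result, float(np.exp(n0)))


def gamma_window_logdensity(
    shape,
    scale,
    a,
    b,
    tau_r,
    log_front=0.0,
):
    """log of ``front * (F(a) - F(b)) / tau_r`` for a Gamma(shape, scale) CDF F.

    This is the exact joint density contribution of a zero-rejection path
    (one gamma generation time composed with the uniform non-decision
    window).  Deep tails where the CDF difference underflows are handled
    with the lower-tail series ``F(x) ~ (x/scale)^shape / Gamma(shape+1)``
    in log space, so the result degrades gracefully to the log floor
    instead of collapsing to a numerical noise level.  Broadcasts over
    array inputs; ``scale = 0`` denotes a point mass at time zero.
    """
    from scipy.special import gammainc, gammaincc, gammaln

    shape, scale, a, b, tau_r, log_front = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (shape, scale, a, b, tau_r, log_front))
    )
    out = np.full(shape.shape, LOG_DENSITY_FLOOR)
    neg = a <= 0
    atom = (scale <= 0) & ~neg
    # point mass at 0: window density is front/tau_r iff the window covers 0
    out[atom & (b <= 0)] = (log_front - np.log(tau_r))[atom & (b <= 0)]

    reg = ~neg & ~atom
    if np.any(reg):
        k, th = shape[reg], scale[reg]
        aa, bb = a[reg], np.maximum(b[reg], 0.0)
        xa, xb = aa / th, bb / th
        with np.errstate(over="ignore", invalid="ignore"):
            diff_lower = gammainc(k, xa) - gammainc(k, xb)
            diff_upper = gammaincc(k, xb) - gammaincc(k, xa)
        diff = np.maximum(diff_lower, diff_upper)
        val = np.where(diff > 0, np.log(np.maximum(diff, 1e-300)), -np.inf)
        # lower-tail series where both CDFs underflowed
        tail = (diff <= 1e-290) & (xa < k)
        if np.any(tail):
            with np.errstate(divide="ignore", invalid="ignore"):
                log_fa = k[tail] * np.log(xa[tail]) - gammaln(k[tail] + 1.0)
                ratio = np.where(xb[tail] > 0,
                                 k[tail] * (np.log(np.maximum(xb[tail], 1e-300))
                                            - np.log(xa[tail])),
                                 -np.inf)
                log_fa = log_fa + np.log1p(-np.minimum(np.exp(ratio), 1 - 1e-16))
            val[tail] = log_fa
        out[reg] = log_front[reg] + val - np.log(tau_r[reg])
    return np.maximum(np.where(np.isfinite(out), out, LOG_DENSITY_FLOOR),
                      LOG_DENSITY_FLOOR)


def report_probabilities(
    norms_for_cue: CueNorms, params: SMPParameters, no_rejection: bool = False
) -> np.ndarray:
    """Marginal probability that each candidate is the reported association:
    ``P(A_j) * acc_j / sum_i P(A_i) * acc_i``."""
    p = generation_distribution(norms_for_cue.typicalities, params.beta)
    if no_rejection:
        return p
    acc = acceptance_probability(
        norms_for_cue.typicalities, None, params.alpha_I, params.alpha_sign
    )
    w = p * acc
    return w / w.sum()
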