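"""EM fitting of bivariate Gaussian mixtures with M-step-first initialization.

Instead of asking the user for 6c-1 start values, each event's membership
probabilities are drawn from a symmetric Dirichlet(alpha) and the M step is
run first, so the first parameter estimates come from the data themselves.
Iteration alternates M and E steps until the absolute change in total
log-likelihood drops to ``epsilon`` (default 1). A previously fitted model
(e.g. from a subsample run) can be passed as a warm-start prior, in which
case iteration begins with an E step on that model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    EventTable,
    MixtureModel,
    ResponsibilityMatrix,
    component_logdensities,
    param_count,
    regularize_covariance,
)

__all__ = ["EMConfig", "FitResult", "init_responsibilities", "m_step", "e_step", "run_em"]


@dataclass
class EMConfig:
    """Tunables of the EM engine.

    epsilon: absolute log-likelihood stopping threshold (default 1).
    n_starts: independent Dirichlet initializations; the best final
        log-likelihood wins (ties go to the lowest start index). Warm-started
        runs conventionally use 1.
    alpha: symmetric Dirichlet concentration for the initial
        responsibilities (default 1 = uniform over the simplex).
    reg: trace-scaled ridge used when a covariance estimate degenerates.
    min_iter: burn-in before the stopping test is applied to randomly
        initialized runs. Row-wise Dirichlet responsibilities average to a
        nearly symmetric mixture — a fixed point of EM whose escape
        transient produces sub-epsilon log-likelihood steps — so testing
        termination from the first iteration would freeze the fit there.
        Warm-started runs have no such transient and are tested from
        iteration 1.
    """

    epsilon: float = 1.0
    max_iter: int = 10_000
    n_starts: int = 10
    alpha: float = 1.0
    seed: int = 0
    reg: float = 1e-6
    min_iter: int = 20

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class FitResult:
    model: MixtureModel
    responsibilities: ResponsibilityMatrix
    loglik_trace: np.ndarray = field(repr=False)
    start_index: int = 0
    #: EM iterations summed over all random starts (cost bookkeeping);
    #: model.iterations holds the winning start's count only
    total_iterations: int = 0


def init_responsibilities(
    n_events: int, c: int, alpha: float, rng: np.random.Generator
) -> ResponsibilityMatrix:
    """Row-wise symmetric Dirichlet(alpha) membership probabilities."""
    if n_events < 1 or c < 1:
        raise ValueError(f"invalid shape ({n_events}, {c}) for responsibilities")
    if c == 1:
        return ResponsibilityMatrix(np.ones((n_events, 1)))
    values = rng.dirichlet(np.full(c, float(alpha)), size=n_events)
    return ResponsibilityMatrix(values)


def m_step(
    events: EventTable,
    responsibilities: ResponsibilityMatrix,
    reg: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> MixtureModel:
    """Maximum-likelihood parameters given soft memberships.

    Weights are column means of the responsibilities; means and covariances
    are responsibility-weighted moments. A component whose responsibility
    mass collapses (below 10*eps*n) is reborn at a randomly chosen event
    with the pooled covariance rather than silently producing NaNs.
    """
    X = events.values
    R = responsibilities.values
    n, c = R.shape
    if X.shape[0] != n:
        raise ValueError(
            f"events ({X.shape[0]}) and responsibilities ({n}) disagree on n"
        )
    mass = R.sum(axis=0)
    dead = mass < 10 * np.finfo(np.float64).eps * n
    weights = mass / n
    means = np.empty((c, 2))
    covs = np.empty((c, 2, 2))

    pooled = np.cov(X, rowvar=False, bias=True)
    pooled = regularize_covariance(np.atleast_2d(pooled), reg)
    if rng is None:
        rng = np.random.default_rng(0)

    for j in range(c):
        if dead[j]:
            means[j] = X[rng.integers(n)]
            covs[j] = pooled
            weights[j] = 1.0 / n
            continue
        means[j] = R[:, j] @ X / mass[j]
        dev = X - means[j]
        covs[j] = (R[:, j, None] * dev).T @ dev / mass[j]
        covs[j] = regularize_covariance(covs[j], reg)
    weights = weights / weights.sum()
    return MixtureModel(
        weights=weights, means=means, covariances=covs, channel_names=events.channel_names
    )


def e_step(events: EventTable, model: MixtureModel) -> tuple[ResponsibilityMatrix, float]:
    """Posterior responsibilities and the observed-data log-likelihood.

    Row normalization happens in the log domain, so an event far from every
    component still gets a well-defined membership row.
    """
    log_dens = component_logdensities(events, model)
    with np.errstate(divide="ignore"):
        weighted = log_dens + np.log(model.weights)
    norm = logsumexp(weighted, axis=1)
    resp = np.exp(weighted - norm[:, None])
    return ResponsibilityMatrix(resp), float(norm.sum())


def _em_once(
    events: EventTable,
    c: int,
    config: EMConfig,
    rng: np.random.Generator,
    prior: MixtureModel | None,
) -> FitResult:
    trace = []
    if prior is not None:
        resp, loglik = e_step(events, prior)
        trace.append(loglik)
    else:
        resp = init_responsibilities(events.n_events, c, config.alpha, rng)
        loglik = -np.inf

    model = None
    iterations = 0
    converged = False
    # c=1 has no symmetry to break; warm starts have no plateau transient
    check_from = 1 if (prior is not None or c == 1) else max(1, config.min_iter)
    prev_delta = np.inf
    for iterations in range(1, config.max_iter + 1):
        model = m_step(events, resp, reg=config.reg, rng=rng)
        resp, new_loglik = e_step(events, model)
        if not np.isfinite(new_loglik):
            raise FloatingPointError(
                f"non-finite log-likelihood at EM iteration {iterations}"
            )
        trace.append(new_loglik)
        delta = abs(new_loglik - loglik)
        # fire only on sub-epsilon AND non-growing deltas: during the
        # symmetric-start transient the increments grow geometrically while
        # still tiny, and stopping there would freeze the fit at the plateau
        if (
            iterations >= check_from
            and np.isfinite(loglik)
            and delta <= config.epsilon
            and delta <= prev_delta
        ):
            loglik = new_loglik
            converged = True
            break
        prev_delta = delta
        loglik = new_loglik

    model.loglik = loglik
    model.n_fit = events.n_events
    model.iterations = iterations
    model.converged = converged
    return FitResult(
        model=model,
        responsibilities=resp,
        loglik_trace=np.asarray(trace),
    )


def run_em(
    events: EventTable,
    c: int,
    config: EMConfig | None = None,
    prior: MixtureModel | None = None,
) -> FitResult:
    """Fit a c-component mixture; with ``n_starts`` > 1 keep the best start.

    Without a prior, each start draws fresh Dirichlet responsibilities from
    a per-start substream of the master seed and begins with an M step.
    With a prior model, iteration starts from an E step on it. Returns the
    best final iterate even when the epsilon criterion was not reached
    within ``max_iter`` (flagged via ``converged=False``).
    """
    config = config or EMConfig()
    if c < 1:
        raise ValueError(f"component count must be >= 1, got {c}")
    if events.n_events < param_count(c):
        raise ValueError(
            f"need at least {param_count(c)} events to fit c={c} components, "
            f"got {events.n_events}"
        )
    n_starts = 1 if prior is not None else config.n_starts
    streams = np.random.SeedSequence(config.seed).spawn(n_starts)
    best: FitResult | None = None
    total_iterations = 0
    for s, stream in enumerate(streams):
        fit = _em_once(events, c, config, np.random.default_rng(stream), prior)
        fit.start_index = s
        total_iterations += fit.model.iterations
        if best is None or fit.model.loglik > best.model.loglik:
            best = fit
    best.total_iterations = total_iterations
    return best
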