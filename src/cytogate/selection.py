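"""BIC model-order selection and the two-stage subsample -> full-data fit.

The number of cell clusters in a microbial sample is unknown a priori
(typically 10-20 on a two-channel plot), so candidate component counts are
scanned and scored with the Bayesian Information Criterion,
``BIC = -2 log L + k ln(n)`` with k = 6c - 1. The BIC curve flattens once
the true structure is captured; the selection rule takes the smallest c at
which the successive BIC difference first drops to ``delta`` (default 50).

Fitting every candidate on 200 000 events is wasteful, so stage 1 runs on a
stride subsample (every 20th or 40th event), and stage 2 warm-starts the
full-data EM from the stage-1 winner over a small extended range of c, to
give rare clusters lost in the subsample a chance to reappear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EventTable, MixtureModel, param_count
from .em import EMConfig, FitResult, run_em
from .preprocess import subsample_stride

__all__ = ["SelectionTrace", "bic", "select_c", "two_stage_fit", "augment_model"]


@dataclass
class SelectionTrace:
    """BIC scan bookkeeping: stage-1 curve plus optional stage-2 rescoring."""

    c_values: np.ndarray
    bic_values: np.ndarray
    loglik_values: np.ndarray
    chosen_c: int = 0
    rule_satisfied: bool = True
    stage2_c_values: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    stage2_bic_values: np.ndarray = field(default_factory=lambda: np.array([]))
    stage2_loglik_values: np.ndarray = field(default_factory=lambda: np.array([]))
    stage2_chosen_c: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            {"stage": 1, "c": int(c), "loglik": ll, "bic": b}
            for c, ll, b in zip(self.c_values, self.loglik_values, self.bic_values)
        ]
        rows += [
            {"stage": 2, "c": int(c), "loglik": ll, "bic": b}
            for c, ll, b in zip(
                self.stage2_c_values, self.stage2_loglik_values, self.stage2_bic_values
            )
        ]
        return pd.DataFrame(rows)


def bic(loglik: float, c: int, n_fit: int) -> float:
    """Bayesian Information Criterion: -2 log L + (6c - 1) ln(n_fit)."""
    if n_fit < 1:
        raise ValueError(f"n_fit must be >= 1, got {n_fit}")
    return -2.0 * float(loglik) + param_count(c) * np.log(n_fit)


def select_c(trace: SelectionTrace, delta: float = 50.0) -> int:
    """Smallest c whose successive BIC difference first drops to ``delta``.

    If no adjacent pair satisfies |BIC(c) - BIC(c+1)| <= delta, the largest
    candidate is returned, ``rule_satisfied`` is cleared and a warning is
    emitted: the scan range was too narrow to see the curve flatten.
    """
    cs = np.asarray(trace.c_values, dtype=int)
    if len(cs) < 2:
        raise ValueError("need at least 2 candidate component counts")
    diffs = np.abs(np.diff(np.asarray(trace.bic_values, dtype=float)))
    hit = np.nonzero(diffs <= delta)[0]
    if len(hit):
        trace.chosen_c = int(cs[hit[0]])
        trace.rule_satisfied = True
    else:
        trace.chosen_c = int(cs[-1])
        trace.rule_satisfied = False
        warnings.warn(
            f"no successive BIC difference <= {delta} in c={cs[0]}..{cs[-1]}; "
            "falling back to the largest candidate",
            stacklevel=2,
        )
    return trace.chosen_c


def augment_model(
    model: MixtureModel,
    c_new: int,
    events: EventTable,
    rng: np.random.Generator,
) -> MixtureModel:
    """Grow a fitted model to ``c_new`` components for warm-started refits.

    Existing components are kept; each extra component is born at a randomly
    drawn event with the pooled data covariance and weight 1/(c+1), after
    which all weights are renormalized.
    """
    if c_new < model.c:
        raise ValueError(f"cannot shrink a model from {model.c} to {c_new}")
    if c_new == model.c:
        return model
    X = events.values
    pooled = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
    weights = list(model.weights)
    means = list(model.means)
    covs = list(model.covariances)
    for _ in range(c_new - model.c):
        means.append(X[rng.integers(len(X))])
        covs.append(pooled.copy())
        weights.append(1.0 / (len(weights) + 1))
    weights = np.asarray(weights)
    return MixtureModel(
        weights=weights / weights.sum(),
        means=np.asarray(means),
        covariances=np.asarray(covs),
        channel_names=model.channel_names,
    )


def two_stage_fit(
    events: EventTable,
    c_min: int,
    c_max: int,
    stride: int,
    config: EMConfig | None = None,
    extension: int = 3,
    delta: float = 50.0,
    stage1_fits: dict | None = None,
) -> tuple[SelectionTrace, FitResult]:
    """Subsample BIC scan, then warm-started full-data refit.

    Stage 1: thin the events by ``stride``; for each c in [c_min, c_max]
    run multi-start EM and record the subsample BIC; pick c* by the
    delta-BIC rule. Stage 2: on the full data, warm-start single-run EM for
    each c in [c*, c* + extension] (extra components born via
    :func:`augment_model`) and keep the fit with the best full-data BIC.

    ``stage1_fits``, if passed a dict, receives the stage-1 FitResult per c
    (diagnostics).
    """
    config = config or EMConfig()
    if c_min < 2:
        raise ValueError(f"c_min must be >= 2, got {c_min}")
    if c_max < c_min:
        raise ValueError(f"c_max ({c_max}) must be >= c_min ({c_min})")
    sub = subsample_stride(events, stride)
    if sub.n_events < param_count(c_max):
        raise ValueError(
            f"subsample of {sub.n_events} events cannot support c_max={c_max} "
            f"({param_count(c_max)} parameters)"
        )

    cs = np.arange(c_min, c_max + 1)
    logliks = np.empty(len(cs))
    bics = np.empty(len(cs))
    fits: dict[int, FitResult] = {}
    for i, c in enumerate(cs):
        fit = run_em(sub, int(c), config)
        fits[int(c)] = fit
        logliks[i] = fit.model.loglik
        bics[i] = bic(fit.model.loglik, int(c), sub.n_events)
    trace = SelectionTrace(c_values=cs, bic_values=bics, loglik_values=logliks)
    c_star = select_c(trace, delta=delta)
    if stage1_fits is not None:
        stage1_fits.update(fits)

    # stage 2: warm-started full-data refits over the extended range
    warm_cfg = EMConfig(
        epsilon=config.epsilon,
        max_iter=config.max_iter,
        n_starts=1,
        alpha=config.alpha,
        seed=config.seed,
        reg=config.reg,
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    base = fits[c_star].model
    s2_cs, s2_ll, s2_bic = [], [], []
    best_fit: FitResult | None = None
    best_bic = np.inf
    for c in range(c_star, c_star + extension + 1):
        if events.n_events < param_count(c):
            break
        prior = augment_model(base, c, events, rng)
        fit = run_em(events, c, warm_cfg, prior=prior)
        b = bic(fit.model.loglik, c, events.n_events)
        s2_cs.append(c)
        s2_ll.append(fit.model.loglik)
        s2_bic.append(b)
        if b < best_bic:
            best_bic = b
            best_fit = fit
    trace.stage2_c_values = np.asarray(s2_cs, dtype=int)
    trace.stage2_loglik_values = np.asarray(s2_ll)
    trace.stage2_bic_values = np.asarray(s2_bic)
    trace.stage2_chosen_c = best_fit.model.c
    return trace, best_fit
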