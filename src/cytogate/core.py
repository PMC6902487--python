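"""Domain types and probabilistic primitives for 2-D Gaussian mixture gating.

Microbial flow cytometry resolves community structure on a two-channel
projection (typically forward scatter vs. a DNA-stain fluorescence), with
each cell cluster modelled as a bivariate Gaussian of arbitrary orientation.
This module holds the event container, the mixture-model container, and the
numerically careful density primitives everything else builds on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "EventTable",
    "MixtureModel",
    "ResponsibilityMatrix",
    "mvn_logdensity",
    "mixture_loglik",
    "param_count",
    "regularize_covariance",
]

#: Full instrument scale of the cytometer channels (linear, inclusive).
CHANNEL_MAX = 65536.0

LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class EventTable:
    """An n x 2 matrix of linear channel intensities, one row per event.

    Event order is preserved end to end: it carries no biological meaning,
    but deterministic stride subsampling depends on it.
    """

    values: np.ndarray
    channel_names: tuple[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError(
                f"EventTable requires an n x 2 matrix, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EventTable values must all be finite")
        self.channel_names = (str(self.channel_names[0]), str(self.channel_names[1]))

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n_events


@dataclass
class MixtureModel:
    """Parameters of a c-component bivariate Gaussian mixture.

    ``weights`` lives on the probability simplex; ``means`` is (c, 2) in
    channel units; ``covariances`` is (c, 2, 2), each symmetric positive
    definite, in squared channel units.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float = np.nan
    n_fit: int = 0
    iterations: int = 0
    converged: bool = False
    channel_names: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        c = self.weights.shape[0]
        if self.means.shape != (c, 2) or self.covariances.shape != (c, 2, 2):
            raise ValueError(
                "inconsistent mixture shapes: "
                f"weights {self.weights.shape}, means {self.means.shape}, "
                f"covariances {self.covariances.shape}"
            )

    @property
    def c(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        """Check simplex and SPD invariants; raise ValueError on violation."""
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"weights must be a probability vector, got sum {self.weights.sum()!r}"
            )
        for j, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {j} is not symmetric:\n{cov}")
            eigvals = np.linalg.eigvalsh(cov)
            if np.any(eigvals <= 0):
                raise ValueError(
                    f"covariance {j} is not positive definite "
                    f"(eigenvalues {eigvals}):\n{cov}"
                )

    def axis_sds(self) -> np.ndarray:
        """Per-component per-axis standard deviations, shape (c, 2)."""
        return np.sqrt(np.diagonal(self.covariances, axis1=1, axis2=2))

    # -- JSON serialization (17 significant digits round-trips doubles) ----

    def to_json(self) -> str:
        doc = {
            "c": int(self.c),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.reshape(self.c, 4).tolist(),
            "loglik": None if np.isnan(self.loglik) else float(self.loglik),
            "n_fit": int(self.n_fit),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "channel_names": list(self.channel_names) if self.channel_names else None,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        doc = json.loads(text)
        c = int(doc["c"])
        return cls(
            weights=np.array(doc["weights"], dtype=np.float64),
            means=np.array(doc["means"], dtype=np.float64),
            covariances=np.array(doc["covariances"], dtype=np.float64).reshape(c, 2, 2),
            loglik=float("nan") if doc["loglik"] is None else float(doc["loglik"]),
            n_fit=int(doc["n_fit"]),
            iterations=int(doc["iterations"]),
            converged=bool(doc["converged"]),
            channel_names=tuple(doc["channel_names"]) if doc["channel_names"] else None,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MixtureModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class ResponsibilityMatrix:
    """n x c posterior membership probabilities; each row sums to 1."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("responsibilities must be a 2-D matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        v = self.values
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")


def regularize_covariance(cov: np.ndarray, reg: float = 1e-6) -> np.ndarray:
    """Return ``cov`` nudged back to SPD by a trace-scaled ridge if needed.

    The ridge added is ``reg * trace(cov)/2`` on the diagonal, repeated with
    growing strength until a Cholesky factorization succeeds. Degenerate
    clusters (all responsibility on collinear events) are the only way to
    get here in practice.
    """
    cov = 0.5 * (cov + cov.T)
    ridge = reg * max(np.trace(cov) / 2.0, 1e-12)
    for _ in range(40):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + ridge * np.eye(2)
            ridge *= 10.0
    raise np.linalg.LinAlgError(f"could not regularize covariance to SPD:\n{cov}")


def _chol_or_raise(covariance: np.ndarray):
    covariance = np.asarray(covariance, dtype=np.float64)
    if covariance.shape != (2, 2):
        raise ValueError(f"covariance must be 2x2, got shape {covariance.shape}")
    if not np.allclose(covariance, covariance.T, atol=1e-8):
        raise ValueError(f"covariance is not symmetric:\n{covariance}")
    try:
        return cho_factor(covariance, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance is not positive definite:\n{covariance}"
        ) from exc


def mvn_logdensity(x, mean, covariance) -> np.ndarray | float:
    """Log of the normalized bivariate normal density at ``x``.

    ``x`` may be a single 2-vector or an (n, 2) array. Computed through a
    Cholesky factorization so near-singular covariances never require an
    explicit inverse.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    mean = np.asarray(mean, dtype=np.float64).reshape(2)
    c, low = _chol_or_raise(covariance)
    dev = (x - mean).T  # (2, n)
    sol = cho_solve((c, low), dev)
    maha = np.einsum("ij,ij->j", dev, sol)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    out = -0.5 * (2.0 * LOG_2PI + logdet + maha)
    return out[0] if out.shape == (1,) else out


def component_logdensities(events: EventTable, model: MixtureModel) -> np.ndarray:
    """(n, c) matrix of per-component log N(x_i | mu_j, Sigma_j)."""
    n = events.n_events
    out = np.empty((n, model.c))
    for j in range(model.c):
        out[:, j] = mvn_logdensity(events.values, model.means[j], model.covariances[j])
    return out


def mixture_loglik(events: EventTable, model: MixtureModel) -> float:
    """Observed-data log-likelihood sum_i log sum_j pi_j N(x_i|mu_j, Sigma_j).

    Evaluated in the log domain with log-sum-exp, so widely separated
    components (axis SDs spanning 10 to 10 000 channel units) do not
    underflow to -inf.
    """
    if events.n_events == 0:
        raise ValueError("cannot compute a log-likelihood on an empty event table")
    log_dens = component_logdensities(events, model)
    with np.errstate(divide="ignore"):
        log_w = np.log(model.weights)
    return float(logsumexp(log_dens + log_w, axis=1).sum())


def param_count(c: int) -> int:
    """Free parameters of a c-component 2-D Gaussian mixture: 6c - 1.

    Per component: 2 mean entries, 3 free covariance entries, 1 weight;
    minus one degree of freedom for the simplex constraint on the weights.
    """
    if c < 1:
        raise ValueError(f"component count must be >= 1, got {c}")
    return 6 * int(c) - 1
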