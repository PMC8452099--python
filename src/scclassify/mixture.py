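"""Two-component univariate Gaussian mixture front-end for SCC.

The mixture density is f(v) = sum_j lambda_j phi(v; mu_j, sigma_j).  EM
alternates posterior responsibilities (E step) with weighted moment updates
(M step); the observed-data log-likelihood is non-decreasing across
iterations.  The per-observation responsibilities are posterior
probabilities over the components and feed directly into the SCC engine:
with two components the MAP assignment is the beta = 1/2 special case, and
each observation has a single loss-of-precision transition at its maximum
responsibility.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from scclassify.classify import ClassSet, PosteriorRecord
from scclassify.scc import (
    collective_certainty_sweep,
    default_beta_grid,
    scc_decide,
    threshold_sweep,
    transition_profile,
)

logger = logging.getLogger(__name__)

#: Component labels in ascending-mean order.
MIXTURE_CLASSES = ClassSet(("1", "2"))


class DegenerateMixtureError(RuntimeError):
    """A component collapsed onto a single point (sigma -> 0)."""


@dataclass(frozen=True)
class MixtureParams:
    """Weights, means and standard deviations of a k-component normal mixture."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w <= 0):
            raise ValueError(f"weights {self.weights} are not a positive simplex point")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError(f"standard deviations {self.sds} must be positive")
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds differ in length")

    @property
    def k(self) -> int:
        return len(self.weights)

    def pdf(self, values: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(values, dtype=float)
        dens = sum(
            w * stats.norm.pdf(v, m, s)
            for w, m, s in zip(self.weights, self.means, self.sds)
        )
        return dens

    def cdf(self, values: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(values, dtype=float)
        return sum(
            w * stats.norm.cdf(v, m, s)
            for w, m, s in zip(self.weights, self.means, self.sds)
        )

    def to_json(self, **extra: object) -> str:
        doc: dict[str, object] = {
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
        }
        doc.update(extra)
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MixtureParams":
        doc = json.loads(text)
        return cls(
            weights=tuple(doc["weights"]),
            means=tuple(doc["means"]),
            sds=tuple(doc["sds"]),
        )

    def save(self, path: str | Path, **extra: object) -> None:
        Path(path).write_text(self.to_json(**extra))

    @classmethod
    def load(cls, path: str | Path) -> "MixtureParams":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class Observation:
    """A scalar observation, e.g. a state's percent fully vaccinated."""

    item_id: str
    value: float
    external_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"{self.item_id}: value {self.value} is not finite")


def _log_component_densities(
    values: np.ndarray, params: MixtureParams
) -> np.ndarray:
    """(n, k) matrix of log(lambda_j) + log phi(v_i; mu_j, sigma_j)."""
    v = np.asarray(values, dtype=float)[:, None]
    mu = np.asarray(params.means)[None, :]
    sd = np.asarray(params.sds)[None, :]
    logw = np.log(np.asarray(params.weights))[None, :]
    return logw + stats.norm.logpdf(v, mu, sd)


def responsibility_matrix(
    values: Sequence[float], params: MixtureParams
) -> np.ndarray:
    """(n, k) posterior responsibilities, computed in log space."""
    logd = _log_component_densities(np.asarray(values, dtype=float), params)
    shifted = logd - logd.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=1, keepdims=True)


def responsibilities(value: float, params: MixtureParams) -> np.ndarray:
    """Posterior probability of each component for one observation."""
    return responsibility_matrix(np.array([value]), params)[0]


def fit_mixture_em(
    values: Sequence[float],
    k: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[MixtureParams, np.ndarray, dict]:
    """Fit a k-component univariate normal mixture by EM.

    Initialisation is quantile-based (observations split into k equal-rank
    blocks, each moment-matched), which makes the fit fully deterministic.
    Components are reported in ascending-mean order.  Convergence when the
    absolute change in observed-data log-likelihood drops below ``tol``.

    Returns (params, responsibilities, info); ``info`` carries the
    log-likelihood trajectory, iteration count and convergence flag.

    Raises
    ------
    DegenerateMixtureError
        when a component's standard deviation collapses toward zero
        (e.g. fewer distinct values than components).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2 * k:
        raise ValueError(f"need at least {2 * k} observations, got {len(v)}")
    if len(np.unique(v)) < 2 * k:
        raise DegenerateMixtureError(
            f"only {len(np.unique(v))} distinct values; a {k}-component "
            "mixture would collapse"
        )

    # quantile init: split at empirical quantiles, moment-match each block
    order = np.argsort(v)
    blocks = np.array_split(v[order], k)
    weights = np.array([len(b) / len(v) for b in blocks])
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(ddof=0), 1e-3 * (v.std() or 1.0)) for b in blocks])

    loglik_path: list[float] = []
    converged = False
    resp = np.full((len(v), k), 1.0 / k)
    for _ in range(max_iter):
        params = MixtureParams(tuple(weights), tuple(means), tuple(sds))
        logd = _log_component_densities(v, params)
        m = logd.max(axis=1, keepdims=True)
        log_mix = (m + np.log(np.exp(logd - m).sum(axis=1, keepdims=True)))[:, 0]
        loglik = float(log_mix.sum())
        loglik_path.append(loglik)
        if len(loglik_path) > 1 and abs(loglik - loglik_path[-2]) < tol:
            converged = True
            break
        resp = np.exp(logd - log_mix[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            raise DegenerateMixtureError("a component lost all responsibility mass")
        weights = nk / len(v)
        means = resp.T @ v / nk
        var = (resp * (v[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12 * max(v.var(), 1.0)):
            raise DegenerateMixtureError(
                "a component's variance collapsed toward zero"
            )
        sds = np.sqrt(var)
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last change {abs(loglik_path[-1] - loglik_path[-2]):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    # normalise component order by ascending mean
    perm = np.argsort(means, kind="stable")
    params = MixtureParams(
        tuple(weights[perm]), tuple(means[perm]), tuple(sds[perm])
    )
    resp = responsibility_matrix(v, params)
    info = {
        "loglik": loglik_path[-1],
        "loglik_path": loglik_path,
        "n_iter": len(loglik_path),
        "converged": converged,
    }
    return params, resp, info


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed-report style."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def posterior_records(
    observations: Sequence[Observation], params: MixtureParams
) -> list[PosteriorRecord]:
    """Responsibilities per observation as posterior records over '1'/'2'."""
    resp = responsibility_matrix([o.value for o in observations], params)
    return [
        PosteriorRecord(item_id=o.item_id, probs=r)
        for o, r in zip(observations, resp)
    ]


def scc_over_mixture(
    observations: Sequence[Observation],
    params: MixtureParams,
    betas: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SCC threshold sweep plus per-item loss-of-precision transition points.

    The transition table has one row per observation: ``item_id``, optional
    ``label``, ``map_component`` and ``transition_point_percent`` — the
    maximum responsibility as a percentage rounded half-up to two decimals.
    Above that threshold the decision widens from the single component to
    '1-or-2'.
    """
    class_set = MIXTURE_CLASSES
    if betas is None:
        betas = default_beta_grid(len(class_set))
    records = posterior_records(observations, params)
    sweep = threshold_sweep(records, class_set, betas)
    rows = []
    for obs, rec in zip(observations, records):
        prof = transition_profile(rec, class_set)
        map_dec = scc_decide(rec, class_set, 1.0 / len(class_set))
        rows.append(
            {
                "item_id": obs.item_id,
                "label": obs.external_label,
                "map_component": map_dec.decision[0],
                "transition_point_percent": round_half_up(
                    100.0 * float(prof.cut_points[0]), 2
                ),
            }
        )
    transitions = pd.DataFrame(rows)
    return sweep, transitions


def mixture_collective_certainty(
    observations: Sequence[Observation],
    params: MixtureParams,
    betas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Collective certainty of all observations' decisions across the beta grid."""
    records = posterior_records(observations, params)
    return collective_certainty_sweep(records, MIXTURE_CLASSES, betas)


def bootstrap_goodness_of_fit(
    params: MixtureParams,
    n: int,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[int, np.ndarray]:
    """Parametric-bootstrap KS check of a fitted mixture.

    Draws ``n_boot`` samples of size ``n`` from the mixture and KS-tests each
    against the mixture CDF; returns the rejection count at level ``alpha``
    and the p-values.  The count is stochastic — a calibration diagnostic,
    not a sharp statistic.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_boot)
    for b in range(n_boot):
        comp = rng.choice(params.k, size=n, p=params.weights)
        sample = rng.normal(
            np.asarray(params.means)[comp], np.asarray(params.sds)[comp]
        )
        pvals[b] = stats.kstest(sample, params.cdf).pvalue
    return int((pvals < alpha).sum()), pvals


# -- observation IO --------------------------------------------------------

def read_observations(path: str | Path) -> list[Observation]:
    """CSV with columns item_id, value and optional label."""
    df = pd.read_csv(path, dtype={"item_id": str})
    if "item_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: need columns item_id and value")
    has_label = "label" in df.columns
    out = []
    for _, row in df.iterrows():
        lab = row["label"] if has_label and pd.notna(row["label"]) else None
        out.append(
            Observation(
                item_id=str(row["item_id"]),
                value=float(row["value"]),
                external_label=lab,
            )
        )
    return out


def write_observations(obs: Iterable[Observation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"item_id": o.item_id, "value": o.value, "label": o.external_label}
            for o in obs
        ]
    ).to_csv(path, index=False, float_format="%.17g")
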