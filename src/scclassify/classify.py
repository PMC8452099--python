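"""Bayesian posteriors over an atomic class set, MAP decisions and summaries.

For an item with per-class log-likelihoods ``l_x`` and prior ``pi_x`` the
posterior is ``p(x) = pi_x exp(l_x) / sum_y pi_y exp(l_y)``, computed with a
max-shifted normalisation so that length-101 reads (log-likelihoods around
-140) never underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROB_TOL = 1e-9


@dataclass(frozen=True)
class ClassSet:
    """The ordered set of atomic decisions; order fixes all tie-breaking."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a class set needs at least two atomic classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate class labels in {self.labels}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class PosteriorRecord:
    """Per-item posterior probability vector, with optional ground truth."""

    item_id: str
    probs: np.ndarray
    truth: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < 0):
            raise ValueError(f"{self.item_id}: negative posterior entries")
        if abs(p.sum() - 1.0) > PROB_TOL:
            raise ValueError(
                f"{self.item_id}: posterior sums to {p.sum():.12g}, not 1"
            )


def posterior(
    item_id: str,
    log_likes: Sequence[float],
    prior: Sequence[float],
    truth: str | None = None,
) -> PosteriorRecord:
    """Bayes' rule in log space: probs[x] proportional to prior[x] * exp(l[x])."""
    ll = np.asarray(log_likes, dtype=float)
    pr = np.asarray(prior, dtype=float)
    if ll.shape != pr.shape:
        raise ValueError("prior and log-likelihood vectors differ in length")
    if np.any(pr < 0) or abs(pr.sum() - 1.0) > PROB_TOL:
        raise ValueError(f"{item_id}: prior is not a probability vector")
    log_prior = np.full_like(pr, -np.inf)
    np.log(pr, out=log_prior, where=pr > 0)
    log_post = log_prior + ll
    if not np.any(np.isfinite(log_post)):
        raise ValueError(
            f"{item_id}: every prior-weighted likelihood is zero; "
            "posterior undefined"
        )
    shifted = log_post - np.max(log_post[np.isfinite(log_post)])
    w = np.exp(shifted)
    return PosteriorRecord(item_id=item_id, probs=w / w.sum(), truth=truth)


def uniform_prior(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def map_decision(rec: PosteriorRecord, class_set: ClassSet) -> str:
    """Label of the maximal posterior entry; ties go to the first in class order."""
    return class_set.labels[int(np.argmax(rec.probs))]


def map_certainty(rec: PosteriorRecord) -> float:
    """Maximum posterior probability; at least 1/|A| by normalisation."""
    return float(np.max(rec.probs))


def posterior_entropy(rec: PosteriorRecord) -> float:
    """Shannon entropy in nats, with 0 log 0 = 0."""
    p = rec.probs[rec.probs > 0]
    return float(-(p * np.log(p)).sum())


def confusion_matrix(
    records: Iterable[PosteriorRecord], class_set: ClassSet
) -> tuple[pd.DataFrame, float]:
    """MAP confusion matrix (rows = truth, columns = decision) with margins.

    Returns the count table and the correct classification rate
    (trace / total).
    """
    records = list(records)
    missing = [r.item_id for r in records if r.truth is None]
    if missing:
        raise ValueError(f"records without truth labels: {missing}")
    labels = list(class_set.labels)
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for rec in records:
        table.loc[rec.truth, map_decision(rec, class_set)] += 1
    correct = float(np.trace(table.to_numpy()))
    total = float(table.to_numpy().sum())
    rate = correct / total if total else float("nan")
    table["Sum"] = table.sum(axis=1)
    table.loc["Sum"] = table.sum(axis=0)
    return table, rate


def certainty_ecdf(
    records: Iterable[PosteriorRecord], group_by_truth: bool = True
) -> dict[str, pd.DataFrame]:
    """Empirical CDF of MAP certainty values, optionally per truth group.

    Each table has columns ``value`` (sorted) and ``cum_frac``; the last
    cumulative fraction is exactly 1.
    """
    records = list(records)
    groups: dict[str, list[float]] = {}
    if group_by_truth:
        for rec in records:
            key = rec.truth if rec.truth is not None else "<no-truth>"
            groups.setdefault(key, []).append(map_certainty(rec))
    else:
        groups["all"] = [map_certainty(r) for r in records]
    out: dict[str, pd.DataFrame] = {}
    for key, values in groups.items():
        if not values:
            logger.warning("certainty_ecdf: empty group %r omitted", key)
            continue
        v = np.sort(np.asarray(values))
        out[key] = pd.DataFrame(
            {"value": v, "cum_frac": np.arange(1, len(v) + 1) / len(v)}
        )
    return out


def entropy_ecdf(
    records: Iterable[PosteriorRecord], group_by_truth: bool = True
) -> dict[str, pd.DataFrame]:
    """Empirical CDF of posterior entropies, optionally per truth group."""
    records = list(records)
    groups: dict[str, list[float]] = {}
    for rec in records:
        key = (rec.truth or "<no-truth>") if group_by_truth else "all"
        groups.setdefault(key, []).append(posterior_entropy(rec))
    out: dict[str, pd.DataFrame] = {}
    for key, values in groups.items():
        v = np.sort(np.asarray(values))
        out[key] = pd.DataFrame(
            {"value": v, "cum_frac": np.arange(1, len(v) + 1) / len(v)}
        )
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test: (statistic, p-value)."""
    res = stats.ks_2samp(np.asarray(x), np.asarray(y), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# -- posterior table IO ----------------------------------------------------

def write_posteriors(
    records: Iterable[PosteriorRecord], class_set: ClassSet, path: str | Path
) -> None:
    """TSV with item_id, truth and one probability column per class label.

    Probabilities are written at 17 significant digits so the table
    round-trips bit-exactly.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {"item_id": rec.item_id, "truth": rec.truth}
        for lab, p in zip(class_set.labels, rec.probs):
            row[lab] = p
        rows.append(row)
    df = pd.DataFrame(rows, columns=["item_id", "truth", *class_set.labels])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_posteriors(
    path: str | Path, class_set: ClassSet | None = None
) -> tuple[list[PosteriorRecord], ClassSet]:
    """Inverse of :func:`write_posteriors`; infers the class set if omitted."""
    df = pd.read_csv(
        path, sep="\t", dtype={"item_id": str}, float_precision="round_trip"
    )
    if class_set is None:
        labels = [c for c in df.columns if c not in ("item_id", "truth")]
        class_set = ClassSet(tuple(labels))
    records = []
    for _, row in df.iterrows():
        truth = row.get("truth")
        if pd.isna(truth):
            truth = None
        probs = np.array([row[lab] for lab in class_set.labels], dtype=float)
        records.append(
            PosteriorRecord(item_id=str(row["item_id"]), probs=probs, truth=truth)
        )
    return records, class_set
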