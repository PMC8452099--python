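"""The Specified Certainty Classification decision engine.

Given a posterior vector over the atomic class set A and a certainty
threshold beta, the SCC decision is the shortest prefix of the
descending-sorted posterior whose cumulative mass reaches beta:

    K = min { j : p(A_1) + ... + p(A_j) >= beta }

and the decision set is {A_1, ..., A_K}.  beta = 1/|A| reproduces the MAP
classifier; beta near 1 forces low-precision (large-subset) decisions.
Cardinality of the decision is its *precision* (1 = atomic,
|A| = unclassifiable); the cumulative mass actually attained is the
*achieved certainty* (>= beta by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scclassify.classify import ClassSet, PosteriorRecord

logger = logging.getLogger(__name__)

#: Absolute tolerance on the threshold comparison, so beta = 1.0 terminates
#: at the last nonzero entry even when the floating-point cumulative sum is
#: 0.9999999999999998.
BETA_TOL = 1e-12


@dataclass(frozen=True)
class SCCDecision:
    """A set-valued decision: the top-K classes by posterior, K minimal."""

    item_id: str
    decision: tuple[str, ...]  # descending posterior order
    achieved_certainty: float
    precision: int
    beta: float

    def label(self) -> str:
        """Human-readable subset name, members joined by '-or-'."""
        return "-or-".join(self.decision)


@dataclass(frozen=True)
class TransitionProfile:
    """Loss-of-precision thresholds for one item.

    ``cut_points[j-1]`` is the cumulative posterior of the item's top *j*
    classes: its decision has precision <= j exactly when
    beta <= cut_points[j-1].  The first cut point equals the MAP certainty.
    """

    item_id: str
    cut_points: np.ndarray


def _sorted_order(rec: PosteriorRecord) -> np.ndarray:
    # Stable descending sort; equal posteriors keep class-set order.
    return np.argsort(-rec.probs, kind="stable")


def scc_decide(
    rec: PosteriorRecord, class_set: ClassSet, beta: float, tol: float = BETA_TOL
) -> SCCDecision:
    """Smallest sorted-prefix decision with cumulative posterior >= beta.

    Classes with posterior exactly 0 are never included (a zero-mass member
    adds no certainty), so a degenerate posterior keeps precision 1 even at
    beta = 1.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    order = _sorted_order(rec)
    cum = 0.0
    chosen: list[str] = []
    for idx in order:
        p = float(rec.probs[idx])
        if p == 0.0:
            break
        chosen.append(class_set.labels[idx])
        cum += p
        if cum >= beta - tol:
            break
    return SCCDecision(
        item_id=rec.item_id,
        decision=tuple(chosen),
        achieved_certainty=cum,
        precision=len(chosen),
        beta=beta,
    )


def transition_profile(rec: PosteriorRecord, class_set: ClassSet) -> TransitionProfile:
    """Cumulative sorted posteriors: the item's |A|-1 loss-of-precision points."""
    order = _sorted_order(rec)
    cum = np.cumsum(rec.probs[order])
    return TransitionProfile(item_id=rec.item_id, cut_points=cum[: len(class_set) - 1])


def is_correct(dec: SCCDecision, truth: str, class_set: ClassSet) -> bool:
    """A set-valued decision is correct when it contains the true class."""
    if truth not in class_set.labels:
        raise ValueError(f"unknown truth label {truth!r}")
    return truth in dec.decision


def default_beta_grid(n_classes: int) -> list[float]:
    """1/|A| (the MAP threshold) followed by 0.51, 0.52, ..., 0.99."""
    return [1.0 / n_classes] + [round(0.51 + 0.01 * i, 2) for i in range(49)]


def subset_label(decision: Sequence[str], class_set: ClassSet) -> str:
    """Canonical subset name: members in class-set order joined by '-or-'."""
    return "-or-".join(sorted(decision, key=class_set.index))


def threshold_sweep(
    records: Iterable[PosteriorRecord],
    class_set: ClassSet,
    betas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Decision-subset counts for every beta in the grid.

    Long-format table with columns ``beta``, ``subset`` (canonical '-or-'
    name), ``precision``, ``correct`` (boolean; NA when the record carries no
    truth) and ``count``.  Only occupied subsets appear.  At every beta the
    counts sum to the number of records.
    """
    records = list(records)
    if betas is None:
        betas = default_beta_grid(len(class_set))
    rows: dict[tuple[float, str, int, object], int] = {}
    for beta in betas:
        for rec in records:
            dec = scc_decide(rec, class_set, beta)
            correct = (
                is_correct(dec, rec.truth, class_set)
                if rec.truth is not None
                else pd.NA
            )
            key = (beta, subset_label(dec.decision, class_set), dec.precision, correct)
            rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [
            {"beta": b, "subset": s, "precision": p, "correct": c, "count": n}
            for (b, s, p, c), n in sorted(
                rows.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1])
            )
        ]
    )
    return df


def tradeoff_curve(
    records: Iterable[PosteriorRecord],
    class_set: ClassSet,
    betas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Correctness-versus-precision tradeoff, one row per beta.

    Two loss-of-precision counts are reported (both conventions circulate):
    ``n_compound`` counts decisions of precision >= 2, ``n_full_set`` counts
    precision = |A| (unclassifiable).  ``n_correct`` is the number of
    decisions containing the truth; it is non-decreasing in beta because
    decisions are nested.
    """
    records = list(records)
    if any(r.truth is None for r in records):
        raise ValueError("tradeoff_curve requires truth labels on every record")
    if betas is None:
        betas = default_beta_grid(len(class_set))
    k = len(class_set)
    out = []
    for beta in betas:
        decs = [scc_decide(r, class_set, beta) for r in records]
        out.append(
            {
                "beta": beta,
                "n_correct": sum(
                    is_correct(d, r.truth, class_set)
                    for d, r in zip(decs, records)
                ),
                "n_compound": sum(d.precision >= 2 for d in decs),
                "n_full_set": sum(d.precision == k for d in decs),
            }
        )
    return pd.DataFrame(out).sort_values("beta", ignore_index=True)


def collective_certainty(decisions: Iterable[SCCDecision]) -> tuple[float, float]:
    """Joint certainty of all decisions under the independence heuristic.

    Returns ``(product, log_product)`` where the product is over each item's
    achieved certainty; the log form survives underflow for large datasets.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("collective_certainty of an empty decision list")
    log_total = float(
        np.sum(np.log([d.achieved_certainty for d in decisions]))
    )
    return float(np.exp(log_total)), log_total


def collective_certainty_sweep(
    records: Iterable[PosteriorRecord],
    class_set: ClassSet,
    betas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Collective certainty at every beta; non-decreasing in beta."""
    records = list(records)
    if betas is None:
        betas = default_beta_grid(len(class_set))
    rows = []
    for beta in betas:
        prod, log_prod = collective_certainty(
            scc_decide(r, class_set, beta) for r in records
        )
        rows.append(
            {"beta": beta, "collective_certainty": prod, "log_collective": log_prod}
        )
    return pd.DataFrame(rows).sort_values("beta", ignore_index=True)


def _all_subsets(class_set: ClassSet) -> list[tuple[str, ...]]:
    labels = class_set.labels
    subsets: list[tuple[str, ...]] = []
    for mask in range(1, 2 ** len(labels)):
        subsets.append(
            tuple(lab for i, lab in enumerate(labels) if mask >> i & 1)
        )
    subsets.sort(key=lambda s: (len(s), tuple(class_set.index(x) for x in s)))
    return subsets


def cross_tabulate(
    decisions: Sequence[SCCDecision],
    external_labels: Sequence[str],
    class_set: ClassSet,
) -> pd.DataFrame:
    """Contingency table of decision subsets against an external label.

    Rows are decision subsets ordered singletons first then by size (every
    possible subset is retained, including empty rows, when |A| <= 4;
    otherwise only occupied subsets).  Margins included.
    """
    if len(decisions) != len(external_labels):
        raise ValueError(
            f"{len(decisions)} decisions but {len(external_labels)} labels"
        )
    col_labels = sorted(set(external_labels))
    if len(class_set) <= 4:
        row_subsets = [subset_label(s, class_set) for s in _all_subsets(class_set)]
    else:
        row_subsets = sorted(
            {subset_label(d.decision, class_set) for d in decisions}
        )
    table = pd.DataFrame(0, index=row_subsets, columns=col_labels, dtype=int)
    for dec, lab in zip(decisions, external_labels):
        table.loc[subset_label(dec.decision, class_set), lab] += 1
    table["Sum"] = table.sum(axis=1)
    table.loc["Sum"] = table.sum(axis=0)
    return table


# -- decision table IO -----------------------------------------------------

def write_decisions(
    decisions: Iterable[SCCDecision],
    path: str | Path,
    truths: dict[str, str] | None = None,
    class_set: ClassSet | None = None,
) -> None:
    """TSV of decisions: item_id, beta, decision, achieved_certainty, precision."""
    rows = []
    for d in decisions:
        row: dict[str, object] = {
            "item_id": d.item_id,
            "beta": d.beta,
            "decision": d.label(),
            "achieved_certainty": d.achieved_certainty,
            "precision": d.precision,
        }
        if truths is not None and class_set is not None:
            row["correct"] = is_correct(d, truths[d.item_id], class_set)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
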