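"""Triplet-distribution genome models and read likelihoods.

A reference genome is summarised by its *triplet distribution*: the
probability mass P3 over the 64 ordered 3-mers from {A, C, G, T}, estimated
from every length-3 window of the genome.  The likelihood of a read
r_1 ... r_L under the genome's model factorises through the pair distribution
P2 and the second-order Markov transition matrix T3::

    L(r) = P2(r_1 r_2) * prod_{k=3}^{L} T3(r_{k-2}, r_{k-1} -> r_k)

Undetermined bases (``N``) carry no information; windows containing them are
excluded when counting, and at likelihood time they are either skipped
factor-wise (default) or marginalised exactly over all substitutions.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = -1

#: Every character accepted in a genome or read after upper-casing.
VALID_CHARS = frozenset("ACGTN")

#: IUPAC ambiguity codes that may optionally be collapsed to N on load.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")

NHandling = Literal["skip", "marginalize"]


class GenomeError(ValueError):
    """Raised for malformed or unusable genome sequences."""


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise GenomeError(
                f"genome {self.name!r} contains invalid characters: "
                f"{sorted(bad)} (only A/C/G/T/N allowed; pass "
                f"ambiguous='to_n' to read_fasta to collapse IUPAC codes)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_raw(
        cls, name: str, raw: str, ambiguous: Literal["error", "to_n"] = "error"
    ) -> "Genome":
        """Build a Genome from raw text, upper-casing and handling IUPAC codes."""
        seq = raw.upper()
        if ambiguous == "to_n":
            seq = "".join(
                "N" if c in IUPAC_AMBIGUOUS else c for c in seq
            )
        return cls(name=name, sequence=seq)


def read_fasta(
    path: str | Path, ambiguous: Literal["error", "to_n"] = "error"
) -> list[Genome]:
    """Read a (multi-record) FASTA file; each record becomes one Genome."""
    genomes = [
        Genome.from_raw(rec.id, str(rec.seq), ambiguous=ambiguous)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not genomes:
        raise GenomeError(f"no FASTA records found in {path}")
    return genomes


def encode(seq: str) -> np.ndarray:
    """Map a base string to integer codes A,C,G,T -> 0..3 and N -> -1."""
    try:
        return np.fromiter(
            (_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq)
        )
    except KeyError as exc:  # pragma: no cover - guarded by Genome validation
        raise GenomeError(f"invalid base {exc.args[0]!r}") from exc


@dataclass
class TripletModel:
    """Likelihood engine for one reference genome.

    Attributes
    ----------
    genome_name:
        Identifier of the genome the model was built from.
    p3:
        (4, 4, 4) array; ``p3[a, b, c]`` is the probability of triplet *abc*.
    p2:
        (4, 4) array; marginal of ``p3`` over the third position.
    t3:
        (4, 4, 4) array; ``t3[a, b, c] = P(next = c | previous two = ab)``.
        Each (a, b) row sums to 1.
    pseudocount:
        Pseudocount added to each of the 64 triplet cells before any
        normalisation; 0 gives the raw empirical estimate.
    """

    genome_name: str
    p3: np.ndarray
    p2: np.ndarray
    t3: np.ndarray
    pseudocount: float
    _log_p2: np.ndarray = field(init=False, repr=False)
    _log_t3: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p3 = np.asarray(self.p3, dtype=float).reshape(4, 4, 4)
        self.p2 = np.asarray(self.p2, dtype=float).reshape(4, 4)
        self.t3 = np.asarray(self.t3, dtype=float).reshape(4, 4, 4)
        with np.errstate(divide="ignore"):
            self._log_p2 = np.log(self.p2)
            self._log_t3 = np.log(self.t3)

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        """Serialise with keys in fixed lexicographic order (AAA ... TTT)."""
        trip = {
            "".join(t): self.p3[tuple(_BASE_INDEX[c] for c in t)]
            for t in map("".join, itertools.product(BASES, repeat=3))
        }
        pair = {
            "".join(p): self.p2[tuple(_BASE_INDEX[c] for c in p)]
            for p in map("".join, itertools.product(BASES, repeat=2))
        }
        trans = {
            "".join(p): {
                c: self.t3[_BASE_INDEX[p[0]], _BASE_INDEX[p[1]], _BASE_INDEX[c]]
                for c in BASES
            }
            for p in map("".join, itertools.product(BASES, repeat=2))
        }
        doc = {
            "genome_name": self.genome_name,
            "pseudocount": self.pseudocount,
            "p3": trip,
            "p2": pair,
            "t3": trans,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TripletModel":
        doc = json.loads(text)
        p3 = np.zeros((4, 4, 4))
        for trip, v in doc["p3"].items():
            p3[tuple(_BASE_INDEX[c] for c in trip)] = v
        p2 = np.zeros((4, 4))
        for pair, v in doc["p2"].items():
            p2[tuple(_BASE_INDEX[c] for c in pair)] = v
        t3 = np.zeros((4, 4, 4))
        for pair, row in doc["t3"].items():
            for c, v in row.items():
                t3[_BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]], _BASE_INDEX[c]] = v
        return cls(
            genome_name=doc["genome_name"],
            p3=p3,
            p2=p2,
            t3=t3,
            pseudocount=doc["pseudocount"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TripletModel":
        return cls.from_json(Path(path).read_text())


def _triplet_windows(codes: np.ndarray) -> Iterator[tuple[int, int, int]]:
    for k in range(len(codes) - 2):
        a, b, c = codes[k], codes[k + 1], codes[k + 2]
        if a >= 0 and b >= 0 and c >= 0:
            yield int(a), int(b), int(c)


def build_triplet_model(genome: Genome, pseudocount: float = 0.5) -> TripletModel:
    """Estimate P3 / P2 / T3 from every all-determined length-3 window.

    Windows containing N are skipped.  ``pseudocount`` is added to each of the
    64 triplet cells before normalisation; the pair counts are the marginals
    of the pseudocounted triplet counts, which makes the factorisation
    ``p3 = p2 * t3`` exact.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if genome.length < 3:
        raise GenomeError(
            f"genome {genome.name!r} has length {genome.length} < 3; "
            "cannot estimate a triplet distribution"
        )
    codes = encode(genome.sequence)
    counts = np.zeros((4, 4, 4))
    n_windows = 0
    for a, b, c in _triplet_windows(codes):
        counts[a, b, c] += 1
        n_windows += 1
    if n_windows == 0 and pseudocount == 0:
        raise GenomeError(
            f"genome {genome.name!r} has no countable triplet windows "
            "(every window contains N) and pseudocount is 0"
        )
    counts += pseudocount
    total = counts.sum()
    p3 = counts / total
    pair_counts = counts.sum(axis=2)
    p2 = pair_counts / total
    with np.errstate(invalid="ignore", divide="ignore"):
        t3 = counts / pair_counts[:, :, None]
    t3 = np.nan_to_num(t3, nan=0.0)
    return TripletModel(
        genome_name=genome.name, p3=p3, p2=p2, t3=t3, pseudocount=pseudocount
    )


def log_likelihood(
    model: TripletModel, read: str, n_mode: NHandling = "skip"
) -> float:
    """Log-likelihood of a read under a triplet model.

    ``n_mode='skip'`` drops every factor whose 2- or 3-base window contains an
    N (length-comparable across models).  ``n_mode='marginalize'`` computes
    the exact likelihood marginalised over all {A,C,G,T} substitutions of the
    Ns, by a forward pass over the 16 (previous-two-bases) states.

    Returns ``-inf`` when a required factor has probability zero (possible
    only with pseudocount 0); never raises for that case.
    """
    if len(read) < 3:
        raise ValueError(f"read of length {len(read)} < 3 cannot be scored")
    codes = encode(read.upper())
    if n_mode == "skip":
        return _loglik_skip(model, codes)
    if n_mode == "marginalize":
        return _loglik_marginalize(model, codes)
    raise ValueError(f"unknown n_mode {n_mode!r}")


def _loglik_skip(model: TripletModel, codes: np.ndarray) -> float:
    total = 0.0
    a, b = codes[0], codes[1]
    if a >= 0 and b >= 0:
        total += model._log_p2[a, b]
    for k in range(2, len(codes)):
        a, b, c = codes[k - 2], codes[k - 1], codes[k]
        if a >= 0 and b >= 0 and c >= 0:
            total += model._log_t3[a, b, c]
    return float(total)


def _allowed(code: int) -> np.ndarray:
    return np.arange(4) if code < 0 else np.array([code])


def _loglik_marginalize(model: TripletModel, codes: np.ndarray) -> float:
    # Forward algorithm over the joint state (r_{k-1}, r_k); Ns sum over all
    # four bases.  Linear space with per-step rescaling to dodge underflow.
    alpha = np.zeros((4, 4))
    i0, i1 = _allowed(codes[0]), _allowed(codes[1])
    alpha[np.ix_(i0, i1)] = model.p2[np.ix_(i0, i1)]
    log_scale = 0.0
    for k in range(2, len(codes)):
        ic = _allowed(codes[k])
        # new[b, c] = sum_a alpha[a, b] * t3[a, b, c]
        new = np.zeros((4, 4))
        new[:, ic] = np.einsum("ab,abc->bc", alpha, model.t3[:, :, ic])
        mass = new.sum()
        if mass == 0.0:
            return float("-inf")
        alpha = new / mass
        log_scale += math.log(mass)
    final = alpha.sum()
    if final == 0.0:
        return float("-inf")
    return float(log_scale + math.log(final))
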