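"""Seeded synthetic data: random genomes, error-containing reads, genome
degradation and mixture draws.

The read generator emulates short-read sequencing: reads of fixed length
(default 101) drawn uniformly along the genome at a target coverage, with
per-base i.i.d. substitutions, indels and undetermined bases (N).  The
genome "variator" applies iterated rounds of random point mutations and
indels, producing progressively degraded reference genomes for
model-mismatch experiments.  Every generator is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from scclassify.genome_model import BASES, Genome


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation settings; defaults follow an Illumina-like profile
    (length-101 reads at ~6X coverage with low substitution/indel/N rates)."""

    read_length: int = 101
    coverage: float = 6.0
    substitution_rate: float = 0.004
    insertion_rate: float = 0.0005
    deletion_rate: float = 0.0005
    n_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 3:
            raise ValueError("read_length must be at least 3")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate", "n_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name}={r} outside [0, 1)")


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read with its error-free twin and source label."""

    read_id: str
    sequence: str
    error_free: str
    truth: str
    start: int


def random_genome(
    length: int, gc_content: float = 0.5, seed: int | None = None
) -> Genome:
    """I.i.d. random genome with P(G) = P(C) = gc_content / 2."""
    if length < 3:
        raise ValueError("genome length must be at least 3")
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    probs = [at, gc, gc, at]  # A, C, G, T
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
    return Genome(name=f"random_{seed}" if seed is not None else "random", sequence=seq)


#: (name, length, GC content) of the synthetic reference trio: an
#: adenovirus-like genome and two coronavirus-like genomes.  Lengths and GC
#: contents mirror the real genomes (human adenovirus ~55% GC; SARS-CoV-2
#: ~38%; SARS ~41%), so the trio is separable by base composition the way
#: real reference genomes are — uniform-GC random genomes would be
#: statistically indistinguishable by construction.
REFERENCE_TRIO: tuple[tuple[str, int, float], ...] = (
    ("adeno", 34125, 0.55),
    ("covid", 29926, 0.38),
    ("sars", 29751, 0.41),
)


def reference_genome_trio(
    seed: int = 0, length: int | None = None
) -> list[Genome]:
    """Three random genomes emulating an adenovirus/SARS-CoV-2/SARS trio.

    ``length`` overrides all three lengths for scaled-down runs; GC contents
    always follow :data:`REFERENCE_TRIO`.
    """
    genomes = []
    for i, (name, default_len, gc) in enumerate(REFERENCE_TRIO):
        g = random_genome(
            length if length is not None else default_len,
            gc_content=gc,
            seed=None if seed is None else seed + i,
        )
        genomes.append(Genome(name=name, sequence=g.sequence))
    return genomes


def _corrupt(
    template: str, cfg: ReadSimConfig, rng: np.random.Generator, genome_tail: str
) -> str:
    """Apply per-base substitution/indel/N errors; pad from the genome tail so
    the corrupted read keeps exactly ``cfg.read_length`` bases."""
    out: list[str] = []
    source = template + genome_tail
    for base in source:
        if len(out) >= cfg.read_length:
            break
        if rng.random() < cfg.deletion_rate:
            continue
        b = base
        if rng.random() < cfg.substitution_rate:
            b = BASES[(BASES.index(base) + rng.integers(1, 4)) % 4] if base in BASES else base
        if rng.random() < cfg.n_rate:
            b = "N"
        out.append(b)
        if len(out) < cfg.read_length and rng.random() < cfg.insertion_rate:
            out.append(BASES[rng.integers(0, 4)])
    # genome exhausted before the window filled (only near the 3' end)
    while len(out) < cfg.read_length:
        out.append("N")
    return "".join(out[: cfg.read_length])


def simulate_reads(
    genome: Genome, cfg: ReadSimConfig, truth_label: str | None = None
) -> list[SimulatedRead]:
    """Uniform-start reads at ``round(coverage * genome_length / read_length)``.

    Each read carries its error-free original (the raw genome window) and
    the corrupted sequence actually "observed".
    """
    if genome.length < cfg.read_length:
        raise ValueError(
            f"genome {genome.name!r} (length {genome.length}) shorter than "
            f"read length {cfg.read_length}"
        )
    truth = truth_label if truth_label is not None else genome.name
    n_reads = int(round(cfg.coverage * genome.length / cfg.read_length))
    rng = np.random.default_rng(cfg.seed)
    reads = []
    max_start = genome.length - cfg.read_length
    for i in range(n_reads):
        start = int(rng.integers(0, max_start + 1))
        clean = genome.sequence[start : start + cfg.read_length]
        tail = genome.sequence[
            start + cfg.read_length : start + 2 * cfg.read_length
        ]
        corrupted = _corrupt(clean, cfg, rng, tail)
        reads.append(
            SimulatedRead(
                read_id=f"{truth}_read{i}",
                sequence=corrupted,
                error_free=clean,
                truth=truth,
                start=start,
            )
        )
    return reads


def degrade_genome(
    genome: Genome,
    iterations: int,
    snp_rate: float = 2.5e-5,
    indel_rate: float = 2.5e-6,
    seed: int | None = None,
) -> Genome:
    """Iterated random mutation of a genome (a reference-degradation model).

    Each iteration draws per-base Bernoulli point mutations at ``snp_rate``
    and single-base indels (insert or delete, equal odds) at ``indel_rate``.
    ``iterations=0`` is the identity.  Defaults give heavy but unsaturated
    divergence after 1000-2000 iterations.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    for _ in range(iterations):
        n = len(seq)
        n_snp = rng.binomial(n, snp_rate)
        for pos in rng.integers(0, n, size=n_snp):
            base = seq[pos]
            if base in BASES:
                seq[pos] = BASES[(BASES.index(base) + rng.integers(1, 4)) % 4]
        n_indel = rng.binomial(n, indel_rate)
        for _ in range(n_indel):
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5 and len(seq) > 3:
                del seq[pos]
            else:
                seq.insert(pos, BASES[rng.integers(0, 4)])
    return Genome(name=f"{genome.name}_degraded{iterations}", sequence="".join(seq))


def simulate_mixture_data(
    params, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """I.i.d. draws from a normal mixture.

    Returns ``(values, components)``: the observations and the hidden
    component index (0-based) each was drawn from.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(params.k, size=n, p=np.asarray(params.weights))
    values = rng.normal(
        np.asarray(params.means)[comp], np.asarray(params.sds)[comp]
    )
    return values, comp


# -- simulated-read IO -----------------------------------------------------

def write_reads_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """FASTQ with constant quality 'I' (the simulator models no quality)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_reads_fasta(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_read_sidecar(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Truth labels and error-free twins, one row per read."""
    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "truth": r.truth,
                "start": r.start,
                "error_free": r.error_free,
            }
            for r in reads
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sidecar_truths(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["read_id"], df["truth"]))


def write_genomes_fasta(genomes: Iterable[Genome], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, 80):
                fh.write(g.sequence[i : i + 80] + "\n")
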