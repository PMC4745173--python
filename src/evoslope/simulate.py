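"""Synthetic DNA and gene fixtures with the structure the method assumes.

Two sequence generators:

* :func:`random_dna` — iid multinomial letters, the null model used by the
  bootstrap and (approximately) what exons look like to the slope;
* :func:`markov_dna` — a first-order chain with tunable self-persistence,
  the simplest mechanism that produces the long runs / positive lag-1
  autocorrelation that drives spectral slopes negative.  It stands in for
  whatever real mechanism makes introns regular, which is not claimed.

:func:`synthetic_gene` alternates iid "exons" with persistent-Markov
"introns" and returns the matching annotation, so the whole
regions/spectra/stats pipeline can be exercised without any downloads.
Default composition targets mimic a GC-poor insect genome with long
introns: exon GC 32 %, intron GC 25 %, exon lengths 50-400 nt, intron
lengths 500-3000 nt.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import NucleotideSequence
from .regions import GeneAnnotation

_LETTER_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_EXON_PROBS = (0.34, 0.16, 0.16, 0.34)  # GC = 32 %
DEFAULT_INTRON_STATIONARY = (0.375, 0.125, 0.125, 0.375)  # GC = 25 %


def _rng(seed: "int | np.random.Generator | None") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _validate_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probs must be 4 nonnegative values summing to 1: {probs}")
    return p / p.sum()


def _to_residues(indices: np.ndarray) -> str:
    return _LETTER_BYTES[indices].tobytes().decode("ascii")


def random_dna(
    length: int,
    probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: "int | np.random.Generator | None" = None,
    id: str = "random",
) -> NucleotideSequence:
    """iid multinomial sequence with letter probabilities (pA, pC, pG, pT)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    p = _validate_probs(probs)
    rng = _rng(seed)
    return NucleotideSequence(id, _to_residues(rng.choice(4, size=length, p=p)))


def markov_dna(
    length: int,
    stationary: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    persistence: float = 0.95,
    seed: "int | np.random.Generator | None" = None,
    id: str = "markov",
) -> NucleotideSequence:
    """Persistent first-order chain with the given stationary distribution.

    Each step stays on the current letter with probability ``persistence``
    and otherwise redraws from ``stationary`` (so the transition matrix is
    ``rho * I + (1 - rho) * 1 p'``).  The marginal distribution equals
    ``stationary`` at every position, and the probability that adjacent
    letters agree is ``rho + (1 - rho) * sum(p**2)``.  ``rho = 0`` is iid.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= persistence < 1.0:
        raise ValueError(f"persistence must be in [0, 1), got {persistence}")
    p = _validate_probs(stationary)
    rng = _rng(seed)
    stay = rng.random(length) < persistence
    stay[0] = False
    fresh = rng.choice(4, size=length, p=p)
    last_fresh = np.maximum.accumulate(np.where(~stay, np.arange(length), -1))
    return NucleotideSequence(id, _to_residues(fresh[last_fresh]))


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Parameters of one synthetic gene (alternating exon/intron blocks)."""

    n_exons: int = 4
    exon_length_range: tuple[int, int] = (50, 400)
    intron_length_range: tuple[int, int] = (500, 3000)
    exon_probs: tuple[float, float, float, float] = DEFAULT_EXON_PROBS
    intron_stationary: tuple[float, float, float, float] = DEFAULT_INTRON_STATIONARY
    intron_persistence: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")
        _validate_probs(self.exon_probs)
        _validate_probs(self.intron_stationary)
        if not 0.0 <= self.intron_persistence < 1.0:
            raise ValueError("intron_persistence must be in [0, 1)")


def synthetic_gene(
    spec: SyntheticGeneSpec,
    gene_id: str = "gene",
    seed: "int | np.random.Generator | None" = None,
) -> tuple[NucleotideSequence, GeneAnnotation]:
    """One gene: exon, intron, exon, ... with the matching annotation."""
    rng = _rng(spec.seed if seed is None else seed)
    pieces: list[str] = []
    exon_intervals: list[tuple[int, int]] = []
    pos = 1
    for i in range(spec.n_exons):
        if i > 0:
            ilen = int(
                rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1)
            )
            pieces.append(
                markov_dna(
                    ilen, spec.intron_stationary, spec.intron_persistence, seed=rng
                ).residues
            )
            pos += ilen
        elen = int(
            rng.integers(spec.exon_length_range[0], spec.exon_length_range[1] + 1)
        )
        pieces.append(random_dna(elen, spec.exon_probs, seed=rng).residues)
        exon_intervals.append((pos, pos + elen - 1))
        pos += elen
    residues = "".join(pieces)
    annotation = GeneAnnotation(
        gene_id=gene_id,
        strand="+",
        length=len(residues),
        exon_intervals=tuple(exon_intervals),
    )
    return NucleotideSequence(gene_id, residues), annotation


def synthetic_gene_set(
    n_genes: int = 20,
    seed: int | None = None,
    n_exons_range: tuple[int, int] = (3, 6),
    base_spec: SyntheticGeneSpec | None = None,
) -> list[tuple[NucleotideSequence, GeneAnnotation]]:
    """The default study fixture: ``n_genes`` genes with 3-6 exons each."""
    rng = _rng(seed)
    base = base_spec or SyntheticGeneSpec()
    genes = []
    for g in range(n_genes):
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        spec = replace(base, n_exons=n_exons)
        genes.append(synthetic_gene(spec, gene_id=f"synthgene{g + 1:03d}", seed=rng))
    return genes


def write_fixture(
    genes: Sequence[tuple[NucleotideSequence, GeneAnnotation]],
    fasta_path: "str | Path",
    bed_path: "str | Path",
    meta_path: "str | Path",
    meta: dict | None = None,
) -> None:
    """Write a gene set as FASTA + BED6 + JSON metadata sidecar.

    BED intervals are the exons, 0-based half-open, one record per gene
    sequence (chrom == gene id).
    """
    from .io import write_fasta  # local import: io depends on encoding only

    write_fasta([seq for seq, _ in genes], fasta_path)
    with open(bed_path, "w") as fh:
        for _, ann in genes:
            for start, end in ann.exon_intervals:
                fh.write(
                    f"{ann.gene_id}\t{start - 1}\t{end}\t{ann.gene_id}\t0\t{ann.strand}\n"
                )
    payload = {
        "n_genes": len(genes),
        "gene_lengths": {ann.gene_id: ann.length for _, ann in genes},
        "synthetic": True,
    }
    if meta:
        payload.update(meta)
    with open(meta_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def spec_as_dict(spec: SyntheticGeneSpec) -> dict:
    return asdict(spec)
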