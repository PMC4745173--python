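"""Gene-structure handling: strand correction, window labels, section pooling.

A gene is described by its exon intervals (1-based inclusive, on the
gene's own coordinates after strand correction); whatever is left inside
the gene is intron.  Sliding windows are labelled *exon* when every
residue is exonic, *intron* when every residue is intronic, and
*combination* when they straddle a boundary — combination windows are
reported but never pooled, so exon and intron slopes are not averaged
together.  Maximal runs of equally-labelled windows form *sections*;
a section containing any non-finite window slope is excluded from the
pooled samples, and exclusions are counted per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .encoding import NucleotideSequence, as_sequence, sequence_rows
from .spectra import SlopeSeries, format_value

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

LABELS = ("exon", "intron", "combination")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def strand_correct(seq: NucleotideSequence | str, strand: str) -> NucleotideSequence:
    """Return the sequence read 5'->3' on the gene's own strand.

    '+' genes pass through; '-' genes are reverse-complemented so every
    gene reads left to right.
    """
    s = as_sequence(seq)
    if strand == "+":
        return s
    if strand == "-":
        return NucleotideSequence(s.id, reverse_complement(s.residues))
    raise ValueError(f"unknown strand symbol {strand!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Exon intervals of one gene, in strand-corrected gene coordinates."""

    gene_id: str
    strand: str
    length: int
    exon_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        bad = [
            iv
            for iv in self.exon_intervals
            if not (1 <= iv[0] <= iv[1] <= self.length)
        ]
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: intervals out of bounds 1..{self.length}: {bad}"
            )
        ivs = self.exon_intervals
        offenders = [
            (ivs[i], ivs[i + 1])
            for i in range(len(ivs) - 1)
            if ivs[i + 1][0] <= ivs[i][1]
        ]
        if offenders:
            raise ValueError(
                f"gene {self.gene_id!r}: unsorted or overlapping intervals: {offenders}"
            )

    @property
    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        """Complement of the exons within the gene."""
        out = []
        pos = 1
        for start, end in self.exon_intervals:
            if start > pos:
                out.append((pos, start - 1))
            pos = end + 1
        if pos <= self.length:
            out.append((pos, self.length))
        return tuple(out)

    def exonic_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.exon_intervals:
            mask[start - 1 : end] = True
        return mask


def label_window(window: tuple[int, int], annotation: GeneAnnotation) -> str:
    """'exon', 'intron' or 'combination' for a 1-based inclusive window."""
    start, end = window
    if not (1 <= start <= end <= annotation.length):
        raise ValueError(
            f"window {window} outside gene bounds 1..{annotation.length}"
        )
    width = end - start + 1
    exonic = 0
    for a, b in annotation.exon_intervals:
        exonic += max(0, min(end, b) - max(start, a) + 1)
    if exonic == width:
        return "exon"
    if exonic == 0:
        return "intron"
    return "combination"


def label_series(series: SlopeSeries, annotation: GeneAnnotation) -> list[str]:
    """One label per window of a slope series."""
    return [
        label_window((int(s), int(e)), annotation)
        for s, e in zip(series.starts, series.ends)
    ]


@dataclass(frozen=True)
class RegionSection:
    """A maximal run of equally-labelled windows."""

    label: str
    first_window: int  # 0-based index into the series
    n_windows: int
    start: int  # 1-based first residue covered
    end: int  # 1-based last residue covered
    mean_slope: float  # mean over finite window slopes (NaN if none)
    excluded: bool  # any non-finite window slope in the section
    has_infinite: bool
    has_missing: bool


def sectionize(series: SlopeSeries, labels: Sequence[str]) -> list[RegionSection]:
    """Collapse per-window labels into sections with summary slopes."""
    if len(labels) != len(series):
        raise ValueError(f"{len(labels)} labels for {len(series)} windows")
    sections: list[RegionSection] = []
    i = 0
    values = series.values
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        chunk = values[i:j]
        finite = chunk[np.isfinite(chunk)]
        has_inf = bool(np.isinf(chunk).any())
        has_missing = bool(np.isnan(chunk).any())
        sections.append(
            RegionSection(
                label=labels[i],
                first_window=i,
                n_windows=j - i,
                start=int(series.starts[i]),
                end=int(series.ends[j - 1]),
                mean_slope=float(finite.mean()) if finite.size else math.nan,
                excluded=has_inf or has_missing,
                has_infinite=has_inf,
                has_missing=has_missing,
            )
        )
        i = j
    return sections


@dataclass(frozen=True)
class PooledSections:
    """Section-mean samples pooled over genes, plus exclusion bookkeeping."""

    exon: np.ndarray
    intron: np.ndarray
    combination: np.ndarray
    n_sections_total: int
    n_sections_excluded: int
    n_genes_with_infinite: int
    n_genes_infinite_intron_only: int


def pool_sections(
    sections_by_gene: Mapping[str, Sequence[RegionSection]],
) -> PooledSections:
    """Pool non-excluded section means into exon/intron/combination samples.

    Also counts genes having at least one infinite-slope section, and the
    subset of those whose infinite slopes occur in intron sections only.
    """
    samples: dict[str, list[float]] = {label: [] for label in LABELS}
    total = excluded = genes_inf = genes_inf_intron_only = 0
    for sections in sections_by_gene.values():
        inf_labels = {sec.label for sec in sections if sec.has_infinite}
        if inf_labels:
            genes_inf += 1
            if inf_labels == {"intron"}:
                genes_inf_intron_only += 1
        for sec in sections:
            total += 1
            if sec.excluded:
                excluded += 1
            else:
                samples[sec.label].append(sec.mean_slope)
    return PooledSections(
        exon=np.array(samples["exon"]),
        intron=np.array(samples["intron"]),
        combination=np.array(samples["combination"]),
        n_sections_total=total,
        n_sections_excluded=excluded,
        n_genes_with_infinite=genes_inf,
        n_genes_infinite_intron_only=genes_inf_intron_only,
    )


@dataclass(frozen=True)
class Composition:
    length: int
    n_mapped: int
    proportions: dict[str, float]  # over mapped residues; sums to 1
    gc: float


def composition_stats(seq: NucleotideSequence | str) -> Composition:
    """Base proportions (over mapped residues), GC content and length."""
    s = as_sequence(seq)
    rows = sequence_rows(s.residues)
    mapped = rows[rows >= 0]
    counts = np.bincount(mapped, minlength=4)
    n = int(counts.sum())
    props = counts / n if n else np.full(4, math.nan)
    proportions = dict(zip("ACGT", (float(p) for p in props)))
    return Composition(
        length=len(s),
        n_mapped=n,
        proportions=proportions,
        gc=proportions["C"] + proportions["G"],
    )


def sections_to_tsv(sections_by_gene: Mapping[str, Sequence[RegionSection]], handle) -> None:
    """TSV: gene_id, section_index, label, start, end, n_windows, mean_slope, excluded."""
    handle.write(
        "gene_id\tsection_index\tlabel\tstart\tend\tn_windows\tmean_slope\texcluded\n"
    )
    for gene_id, sections in sections_by_gene.items():
        for idx, sec in enumerate(sections):
            handle.write(
                f"{gene_id}\t{idx}\t{sec.label}\t{sec.start}\t{sec.end}\t"
                f"{sec.n_windows}\t{format_value(sec.mean_slope)}\t"
                f"{str(sec.excluded).lower()}\n"
            )
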