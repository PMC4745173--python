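"""File I/O: FASTA sequences, BED6/GFF3 gene annotations, run configuration.

Coordinate conventions: everything in memory is 1-based inclusive (the
GFF convention).  BED input (0-based half-open) is converted exactly at
the file boundary.  Minus-strand genes are remapped so their annotation
lives on the strand-corrected (reverse-complemented) sequence: an
interval (s, e) on a gene of length L becomes (L - e + 1, L - s + 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .encoding import NucleotideSequence
from .regions import GeneAnnotation


class ParseError(ValueError):
    """Malformed annotation or sequence file."""


def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    """All records of a FASTA file, ids preserved, residues uppercased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"empty record {rec.id!r} in {path}")
        records.append(NucleotideSequence(rec.id, str(rec.seq)))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    seqs: Sequence[NucleotideSequence], path: "str | Path", width: int = 70
) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def _flip_intervals(
    intervals: Sequence[tuple[int, int]], length: int
) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((length - e + 1, length - s + 1) for s, e in intervals))


def read_bed(
    path: "str | Path", seq_lengths: Mapping[str, int]
) -> dict[str, GeneAnnotation]:
    """BED6 exon intervals grouped by the name column.

    Each BED line lies on the sequence named in its first column (one
    FASTA record per gene); ``seq_lengths`` supplies gene lengths.
    Minus-strand genes are remapped to strand-corrected coordinates.
    """
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s0, e0 = int(start), int(end)
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from err
            if e0 <= s0:
                raise ParseError(f"{path}:{lineno}: empty interval {start}-{end}")
            entry = raw.setdefault(name, {"chrom": chrom, "strand": strand, "ivs": []})
            if entry["strand"] != strand or entry["chrom"] != chrom:
                raise ParseError(f"{path}:{lineno}: inconsistent strand/chrom for {name!r}")
            entry["ivs"].append((s0 + 1, e0))  # 0-based half-open -> 1-based inclusive
    out = {}
    for name, entry in raw.items():
        if entry["chrom"] not in seq_lengths:
            raise ParseError(f"no sequence length known for {entry['chrom']!r}")
        length = seq_lengths[entry["chrom"]]
        ivs = sorted(entry["ivs"])
        if entry["strand"] == "-":
            ivs = list(_flip_intervals(ivs, length))
        out[name] = GeneAnnotation(
            gene_id=name,
            strand=entry["strand"],
            length=length,
            exon_intervals=tuple(ivs),
        )
    return out


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3(path: "str | Path") -> dict[str, GeneAnnotation]:
    """GFF3 genes with their CDS features (CDS intervals define exons).

    ``gene`` features define the bounds; CDS features are attached to a
    gene via their ``Parent`` attribute, directly or through one level of
    mRNA/transcript.  Coordinates are returned on the gene's own
    strand-corrected axis (1 = 5' end of the gene).
    """
    genes: dict[str, tuple[int, int, str]] = {}
    parent_of: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                s1, e1 = int(start), int(end)
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from err
            a = _gff_attributes(attrs)
            if ftype == "gene":
                if "ID" not in a:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[a["ID"]] = (s1, e1, strand)
            elif ftype in ("mRNA", "transcript"):
                if "ID" in a and "Parent" in a:
                    parent_of[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                parent = a.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: CDS feature without Parent")
                cds.setdefault(parent, []).append((s1, e1))
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for parent, ivs in cds.items():
        gene_id = parent if parent in genes else parent_of.get(parent)
        if gene_id is None or gene_id not in genes:
            raise ParseError(f"cannot resolve CDS parent {parent!r} to a gene")
        per_gene.setdefault(gene_id, []).extend(ivs)
    out = {}
    for gene_id, (gs, ge, strand) in genes.items():
        if gene_id not in per_gene:
            continue  # gene without CDS annotation: skip, as in the source data
        length = ge - gs + 1
        local = sorted((s - gs + 1, e - gs + 1) for s, e in per_gene[gene_id])
        if strand == "-":
            local = list(_flip_intervals(local, length))
        out[gene_id] = GeneAnnotation(
            gene_id=gene_id, strand=strand, length=length, exon_intervals=tuple(local)
        )
    return out


def read_annotation(
    path: "str | Path",
    fmt: str = "bed",
    seq_lengths: Mapping[str, int] | None = None,
) -> dict[str, GeneAnnotation]:
    """Dispatch to the BED6 or GFF3 reader."""
    if fmt == "bed":
        if seq_lengths is None:
            raise ValueError("BED input needs seq_lengths (gene/record lengths)")
        return read_bed(path, seq_lengths)
    if fmt == "gff3":
        return read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


@dataclass(frozen=True)
class RunConfig:
    """Serializable run parameters shared by the CLI subcommands."""

    mode: str = "invariant"
    code: str = "ACGT"
    log_base: str = "e"
    window: int = 32
    step: int = 8
    mallat_threshold: int = 2 ** 11
    seed: int | None = None
    strict_alphabet: bool = False

    def to_file(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_file(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
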