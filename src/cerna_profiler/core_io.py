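"""Readers and writers for the external formats the pipeline touches.

Expression matrices travel as plain TSV (header row of sample ids, one row
per gene, tab-separated, ``.`` decimal, no quoting).  Transcript structure
comes from GTF-like exon lines; spliced sequences from FASTA.  Networks go
out as edge-list TSV or Cytoscape SIF.  Genomic coordinates are 1-based
inclusive throughout, matching GTF; any BED-style export converts to
0-based half-open at the boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "TranscriptRecord",
    "MiRNARecord",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_transcripts",
    "read_fasta",
    "read_mirnas",
    "load_profile3_fixtures",
    "write_network",
    "read_network",
]

_RNA_ALPHABET = set("ACGU")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression (FPKM or counts)
    with an ordered condition design.

    ``condition_order`` fixes the biological ordering of the groups
    (e.g. Sham, PD, NLID, LID) that profile clustering relies on.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    condition_of_sample: dict[str, str]
    condition_order: list[str]
    values: np.ndarray
    is_counts: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.condition_order) < 2:
            raise ValueError("condition_order needs at least 2 conditions")
        if len(set(self.condition_order)) != len(self.condition_order):
            raise ValueError("condition_order entries must be unique")
        for s in self.sample_ids:
            cond = self.condition_of_sample.get(s)
            if cond is None:
                raise ValueError(f"sample {s!r} missing from condition map")
            if cond not in self.condition_order:
                raise ValueError(
                    f"sample {s!r} maps to unknown condition {cond!r}"
                )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_of_condition(self, condition: str) -> list[int]:
        """Column indices of the samples belonging to ``condition``."""
        if condition not in self.condition_order:
            raise KeyError(f"unknown condition {condition!r}")
        return [
            j
            for j, s in enumerate(self.sample_ids)
            if self.condition_of_sample[s] == condition
        ]

    def condition_means(self) -> np.ndarray:
        """Per-gene mean expression within each condition.

        Returns an array of shape (n_genes, n_conditions), columns ordered
        by ``condition_order``.
        """
        cols = []
        for cond in self.condition_order:
            idx = self.samples_of_condition(cond)
            if not idx:
                raise ValueError(f"condition {cond!r} has no samples")
            cols.append(self.values[:, idx].mean(axis=1))
        return np.column_stack(cols)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        return self.values[i]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            condition_of_sample=dict(self.condition_of_sample),
            condition_order=list(self.condition_order),
            values=self.values[rows],
            is_counts=self.is_counts,
        )


@dataclass
class TranscriptRecord:
    """A transcript's genomic structure plus optional spliced sequence.

    Coordinates are 1-based inclusive.  ``exons`` are sorted, non-overlapping
    and contained in ``span``.  ``sequence``, when present, is the spliced
    sense-strand sequence and must match the spliced length.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    sequence: str | None = None
    biotype: str = "novel"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.biotype not in {"known_coding", "known_lncRNA", "novel"}:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        start, end = self.span
        if start > end or start < 1:
            raise ValueError(f"invalid span {self.span} for {self.transcript_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for es, ee in self.exons:
            if es > ee:
                raise ValueError(f"invalid exon ({es},{ee}) in {self.transcript_id}")
            if es < start or ee > end:
                raise ValueError(
                    f"exon ({es},{ee}) outside span {self.span} "
                    f"in {self.transcript_id}"
                )
            if es <= prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = ee
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != spliced length "
                f"{self.spliced_length} for {self.transcript_id}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(ee - es + 1 for es, ee in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class MiRNARecord:
    """A mature miRNA sequence, 5'->3', RNA alphabet."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if len(self.sequence) < 7:
            raise ValueError(
                f"miRNA {self.mirna_id} shorter than 7 nt "
                f"({len(self.sequence)})"
            )
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.mirna_id} has non-ACGU characters {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_matrix(
    path: str | Path,
    condition_map: Mapping[str, str],
    condition_order: Sequence[str],
    is_counts: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        condition_of_sample=dict(condition_map),
        condition_order=list(condition_order),
        values=df.to_numpy(dtype=float),
        is_counts=is_counts,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# GTF / FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mirnas(path: str | Path) -> list[MiRNARecord]:
    return [MiRNARecord(mid, seq) for mid, seq in read_fasta(path).items()]


def _gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcripts(
    gtf_path: str | Path, fasta_path: str | Path | None = None
) -> list[TranscriptRecord]:
    """Assemble TranscriptRecords from GTF exon lines, attaching sequences.

    Only ``exon`` features are used; ``transcript`` lines, when present,
    define the span (otherwise the exon envelope does).  A FASTA keyed by
    transcript_id supplies spliced sequences; length mismatches are errors.
    """
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gid, chrom, strand)
    declared_spans: dict[str, tuple[int, int]] = {}  # from explicit transcript lines
    exons: dict[str, list[tuple[int, int]]] = {}
    biotypes: dict[str, str] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
            attrs = _gtf_attributes(attr_field)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF line missing transcript_id: {line!r}")
            if tid not in order:
                order.append(tid)
            meta.setdefault(tid, (attrs.get("gene_id", tid), chrom, strand))
            if "biotype" in attrs:
                biotypes[tid] = attrs["biotype"]
            if feature == "transcript":
                declared_spans[tid] = (int(start), int(end))
            elif feature == "exon":
                exons.setdefault(tid, []).append((int(start), int(end)))

    sequences = read_fasta(fasta_path) if fasta_path is not None else {}
    records = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise ValueError(f"transcript {tid} has no exons")
        envelope = (ex[0][0], ex[-1][1])
        if tid in declared_spans:
            span = declared_spans[tid]
            # declared spans are authoritative: exons outside are a file error
            if envelope[0] < span[0] or envelope[1] > span[1]:
                raise ValueError(f"exon outside declared transcript span for {tid}")
        else:
            span = envelope
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                span=span,
                exons=ex,
                sequence=sequences.get(tid),
                biotype=biotypes.get(tid, "novel"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Fixtures


def load_profile3_fixtures() -> tuple[list[str], list[str]]:
    """The Profile-3 gene lists packaged with the artifact.

    Returns ``(mrnas, lncrnas)`` exactly as printed — entries are not
    de-duplicated (one mRNA identifier appears twice in the source table),
    so the entry counts are 135 and 79.
    """
    pkg = importlib.resources.files("cerna_profiler") / "data"
    mrnas = (pkg / "profile3_mrnas.txt").read_text().split()
    lncrnas = (pkg / "profile3_lncrnas.txt").read_text().split()
    return mrnas, lncrnas


# ---------------------------------------------------------------------------
# Networks

_NETWORK_FORMATS = {"tsv", "sif"}


def write_network(
    edges: Iterable[tuple[str, str, Mapping[str, object]]],
    path: str | Path,
    fmt: str = "tsv",
    interaction: str = "coexp",
) -> None:
    """Write an undirected edge list as TSV or Cytoscape SIF.

    Edges are sorted lexicographically by node pair so output is
    bit-reproducible regardless of input order.
    """
    if fmt not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; use one of {_NETWORK_FORMATS}")
    cleaned = []
    for a, b, attrs in edges:
        if not a or not b:
            raise ValueError("node names must be non-empty")
        cleaned.append((str(a), str(b), dict(attrs)))
    cleaned.sort(key=lambda e: (e[0], e[1]))
    attr_keys = sorted({k for _, _, attrs in cleaned for k in attrs})
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t".join(["node_a", "node_b", *attr_keys]) + "\n")
            for a, b, attrs in cleaned:
                row = [a, b] + [repr(attrs[k]) if isinstance(attrs.get(k), float) else str(attrs.get(k, "")) for k in attr_keys]
                fh.write("\t".join(row) + "\n")
        else:  # SIF: "node relationship node", no header
            for a, b, attrs in cleaned:
                rel = attrs.get("interaction", interaction)
                fh.write(f"{a}\t{rel}\t{b}\n")


def read_network(path: str | Path, fmt: str = "tsv") -> list[tuple[str, str, dict]]:
    """Read a network written by :func:`write_network`."""
    if fmt not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}")
    edges = []
    with open(path) as fh:
        if fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            attr_keys = header[2:]
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                a, b = fields[0], fields[1]
                attrs = {}
                for k, v in zip(attr_keys, fields[2:]):
                    try:
                        attrs[k] = float(v)
                    except ValueError:
                        attrs[k] = v
                edges.append((a, b, attrs))
        else:
            for line in fh:
                if not line.strip():
                    continue
                a, rel, b = line.rstrip("\n").split("\t")
                edges.append((a, b, {"interaction": rel}))
    return edges
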