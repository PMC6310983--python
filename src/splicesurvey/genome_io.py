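"""Genome and annotation input: FASTA assemblies, GFF3 gene models, gene filtering.

All internal coordinates are 0-based half-open on the forward genomic strand;
GFF3's 1-based inclusive convention is converted at the I/O boundary. Only
``gene``, ``mRNA``/``transcript`` and ``CDS`` features are read — the survey is
restricted to coding regions, so UTR-level exon structure is deliberately
ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeAssembly",
    "TranscriptModel",
    "GeneModel",
    "GeneAnnotation",
    "FilterReport",
    "read_genome",
    "read_annotation",
    "write_annotation",
    "filter_genes",
    "select_representative_transcript",
]


@dataclass
class GenomeAssembly:
    """Named nucleotide sequences, uppercased, IUPAC alphabet."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, seq_name: str, start: int, end: int) -> str:
        """Substring of a sequence over a 0-based half-open interval."""
        seq = self.sequences[seq_name]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for sequence "
                f"{seq_name!r} of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, seq_name: str) -> bool:
        return seq_name in self.sequences


@dataclass
class TranscriptModel:
    """One transcript as its ordered CDS segments on the genome.

    ``cds_segments`` are 0-based half-open intervals sorted by genomic
    position regardless of strand; biological (5'->3') order on the minus
    strand is therefore the reverse of the stored order.
    """

    transcript_id: str
    seq_name: str
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def coding_sequence(self, assembly: GenomeAssembly) -> str:
        """Spliced CDS in biological orientation (starts with the start codon)."""
        parts = [assembly.fetch(self.seq_name, s, e) for s, e in self.cds_segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GeneModel:
    gene_id: str
    seq_name: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class GeneAnnotation:
    genes: list[GeneModel]
    source: str = ""
    n_dropped_off_assembly: int = 0

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class FilterReport:
    """Accounting of genes removed by :func:`filter_genes`, by reason."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    @property
    def counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.removed.items()}

    def removed_gene_ids(self) -> list[str]:
        return [gid for ids in self.removed.values() for gid in ids]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("gene_id\treason\n")
            for reason, ids in sorted(self.removed.items()):
                for gid in ids:
                    out.write(f"{gid}\t{reason}\n")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_retained": self.n_retained,
                    "n_removed": self.n_removed,
                    "removed_per_reason": self.counts,
                },
                out,
                indent=2,
            )


def read_genome(path: str | Path) -> GenomeAssembly:
    """Read a (multi-)FASTA file into a :class:`GenomeAssembly`.

    Sequence names are the header token before the first whitespace;
    residues are uppercased. Duplicate names and empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate sequence name {name!r} in {path}")
        sequences[name] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return GenomeAssembly(sequences=sequences)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_annotation(
    path: str | Path, assembly: GenomeAssembly | None = None
) -> GeneAnnotation:
    """Read gene/mRNA/CDS features from a GFF3 file.

    Coordinates are converted from GFF3 1-based inclusive to internal 0-based
    half-open. CDS segments are grouped per transcript and sorted by genomic
    position. Features on sequences absent from ``assembly`` (when given) are
    dropped and counted. A CDS or transcript whose Parent is never defined is
    an error naming the offending line.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    transcript_parent: dict[str, str] = {}
    # (lineno, transcript_id, interval) for CDS seen before their mRNA row
    cds_rows: list[tuple[int, str, str, str, tuple[int, int]]] = []
    n_dropped = 0

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            seq_name, _src, ftype, start_s, end_s, _score, strand, _phase, attr = fields
            if ftype not in ("gene", "mRNA", "transcript", "CDS"):
                continue
            if assembly is not None and seq_name not in assembly:
                n_dropped += 1
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start_s}-{end_s}")
            attrs = _parse_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                if gid in genes:
                    raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
                genes[gid] = GeneModel(gene_id=gid, seq_name=seq_name, strand=strand)
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(
                        f"{path}:{lineno}: transcript without ID/Parent attribute"
                    )
                transcripts[tid] = TranscriptModel(
                    transcript_id=tid, seq_name=seq_name, strand=strand
                )
                transcript_parent[tid] = parent
            else:  # CDS
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: CDS without Parent attribute")
                for tid in parent.split(","):
                    cds_rows.append((lineno, tid, seq_name, strand, (start, end)))

    for tid, parent in transcript_parent.items():
        if parent not in genes:
            raise ValueError(
                f"{path}: transcript {tid!r} references unknown gene {parent!r}"
            )
        genes[parent].transcripts.append(transcripts[tid])

    for lineno, tid, seq_name, strand, interval in cds_rows:
        if tid not in transcripts:
            raise ValueError(
                f"{path}:{lineno}: CDS references unknown Parent transcript {tid!r}"
            )
        transcripts[tid].cds_segments.append(interval)

    for tr in transcripts.values():
        tr.cds_segments.sort()

    return GeneAnnotation(
        genes=list(genes.values()),
        source=str(path),
        n_dropped_off_assembly=n_dropped,
    )


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write gene/mRNA/CDS rows back to GFF3 (1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in annotation.genes:
            intervals = [
                iv for tr in gene.transcripts for iv in tr.cds_segments
            ]
            if not intervals:
                continue
            g_start = min(s for s, _ in intervals) + 1
            g_end = max(e for _, e in intervals)
            out.write(
                f"{gene.seq_name}\tsplicesurvey\tgene\t{g_start}\t{g_end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tr in gene.transcripts:
                if not tr.cds_segments:
                    continue
                t_start = tr.cds_segments[0][0] + 1
                t_end = tr.cds_segments[-1][1]
                out.write(
                    f"{tr.seq_name}\tsplicesurvey\tmRNA\t{t_start}\t{t_end}\t.\t"
                    f"{tr.strand}\t.\tID={tr.transcript_id};Parent={gene.gene_id}\n"
                )
                segments = tr.cds_segments
                # phase: bases to skip to reach the next codon start, in
                # biological order
                ordered = segments if tr.strand == "+" else list(reversed(segments))
                phases: dict[tuple[int, int], int] = {}
                consumed = 0
                for seg in ordered:
                    phases[seg] = (3 - consumed % 3) % 3
                    consumed += seg[1] - seg[0]
                for s, e in segments:
                    out.write(
                        f"{tr.seq_name}\tsplicesurvey\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{tr.strand}\t{phases[(s, e)]}\t"
                        f"ID=cds-{tr.transcript_id};Parent={tr.transcript_id}\n"
                    )


# reasons checked in this order; the first failure is the one reported
_REASON_ORDER = (
    "no_cds",
    "out_of_bounds",
    "overlapping_cds",
    "length_not_multiple_of_3",
    "internal_stop",
)


def _transcript_failure(
    tr: TranscriptModel, assembly: GenomeAssembly
) -> str | None:
    """First reason this transcript fails validation, or None if clean."""
    if not tr.cds_segments:
        return "no_cds"
    seq_len = assembly.lengths.get(tr.seq_name)
    if seq_len is None:
        return "out_of_bounds"
    for s, e in tr.cds_segments:
        if s < 0 or e > seq_len:
            return "out_of_bounds"
    for (s1, e1), (s2, e2) in zip(tr.cds_segments, tr.cds_segments[1:]):
        if s2 < e1:
            return "overlapping_cds"
    if tr.total_cds_length % 3 != 0 or tr.total_cds_length < 3:
        return "length_not_multiple_of_3"
    protein = str(Seq(tr.coding_sequence(assembly)).translate())
    if "*" in protein[:-1]:
        return "internal_stop"
    return None


def filter_genes(
    annotation: GeneAnnotation, assembly: GenomeAssembly
) -> tuple[GeneAnnotation, FilterReport]:
    """Drop genes with inconsistent gene models.

    A gene is retained if at least one of its transcripts has in-bounds,
    non-overlapping CDS segments whose total length is a multiple of three and
    whose strand-aware conceptual translation has no internal stop codon.
    Retained genes keep only their valid transcripts; removed genes are
    accounted per reason (the first failing check of the transcript closest to
    passing, i.e. the one failing latest in the check order).
    """
    retained: list[GeneModel] = []
    report = FilterReport(n_input=len(annotation.genes))
    for gene in annotation.genes:
        valid = []
        failures: list[str] = []
        for tr in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            reason = _transcript_failure(tr, assembly)
            if reason is None:
                valid.append(tr)
            else:
                failures.append(reason)
        if valid:
            retained.append(
                GeneModel(
                    gene_id=gene.gene_id,
                    seq_name=gene.seq_name,
                    strand=gene.strand,
                    transcripts=valid,
                )
            )
        else:
            reason = (
                max(failures, key=_REASON_ORDER.index) if failures else "no_cds"
            )
            report.removed.setdefault(reason, []).append(gene.gene_id)
    return (
        GeneAnnotation(
            genes=retained,
            source=annotation.source,
            n_dropped_off_assembly=annotation.n_dropped_off_assembly,
        ),
        report,
    )


def select_representative_transcript(gene: GeneModel) -> TranscriptModel:
    """The transcript encoding the longest polypeptide.

    Total CDS nucleotide length is the peptide-length proxy (equivalent once
    CDS lengths are multiples of three). Ties break to the lexicographically
    smallest transcript ID so the choice is deterministic and independent of
    input order.
    """
    candidates = [tr for tr in gene.transcripts if tr.cds_segments]
    if not candidates:
        raise ValueError(f"gene {gene.gene_id!r} has no transcript with CDS")
    return min(candidates, key=lambda t: (-t.total_cds_length, t.transcript_id))
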