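"""Synthetic genomes, annotations, coverage tracks and VCFs with ground truth.

The generator emulates the input shape of a multi-species annotation survey:
protein-coding genes with CDS-flanked introns whose border dinucleotides are
planted from a configurable splice-class composition (defaulting to the
plant-genome averages: ~98.7% GT-AG, 1.2% GC-AG, 0.06% AT-AC, 0.09% minor),
a short-mode intron-length distribution with a configurable heavy tail past
5 kb, a strand mix, optional ambiguity characters, per-intron spliced
fractions driving simulated coverage, and homozygous SNPs drawn from a
specified 12-category substitution spectrum. Every planted feature is
recorded in a :class:`TruthManifest` so downstream results can be checked
exactly.

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .splice_sites import (
    ALL_COMBOS,
    CANONICAL,
    MAJOR_COMBOS,
    hamming_distance,
    reverse_complement,
)
from .variant_spectra import SUBSTITUTIONS, SubstitutionSpectrum

__all__ = [
    "GeneratorConfig",
    "TruthManifest",
    "generate_genome",
    "simulate_coverage",
    "simulate_vcf",
]

_MINOR_COMBOS = tuple(
    c for c in ALL_COMBOS if c != CANONICAL and c not in MAJOR_COMBOS
)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    "".join(p)
    for p in itertools.product("ACGT", repeat=3)
    if "".join(p) not in _STOP_CODONS
)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genome.

    ``composition`` gives the class fractions (canonical, GC-AG, AT-AC,
    minor) and must sum to 1; the default uses the published plant averages
    with the dominant canonical class absorbing their rounding remainder.
    ``minor_mode`` distributes the minor fraction either uniformly over the
    253 minor combinations or proportional to 3^−d (d = Hamming distance to
    GT-AG), mimicking the observed divergence gradient.
    """

    seed: int
    n_genes: int = 100
    introns_per_gene: int | tuple[int, int] = (1, 8)
    exon_length_range: tuple[int, int] = (60, 240)
    intron_length_mode: float = 200.0
    intron_length_sigma: float = 0.6
    min_intron_length: int = 20
    long_tail_fraction: float = 0.01
    long_tail_range: tuple[int, int] = (5001, 9000)
    composition: dict[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.9865,
            "major_GC_AG": 0.012,
            "major_AT_AC": 0.0006,
            "minor": 0.0009,
        }
    )
    minor_mode: str = "uniform"  # or "distance_weighted"
    forward_strand_fraction: float = 0.5
    ambiguity_rate: float = 0.0
    spacer_length_range: tuple[int, int] = (150, 450)
    genes_per_sequence: int = 50
    spliced_fraction: float | tuple[float, float] = 0.9
    n_out_of_bounds_genes: int = 0
    n_internal_stop_genes: int = 0

    def validate(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_intron_length < 4:
            raise ValueError("min_intron_length must be >= 4")
        if self.minor_mode not in ("uniform", "distance_weighted"):
            raise ValueError(f"unknown minor_mode {self.minor_mode!r}")


@dataclass
class TruthManifest:
    """Ground truth for everything the generator planted."""

    sequence_lengths: dict[str, int] = field(default_factory=dict)
    genes: list[dict] = field(default_factory=list)
    introns: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    variant_spectrum: dict[str, float] = field(default_factory=dict)
    error_genes: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def combo_counts(self, min_length: int = 20) -> dict[str, int]:
        """Planted unambiguous combination counts over introns >= min_length."""
        counts: dict[str, int] = {}
        for intron in self.introns:
            if intron["end"] - intron["start"] < min_length:
                continue
            combo = intron["combo"]
            if any(c not in "ACGT" for c in combo):
                continue
            counts[combo] = counts.get(combo, 0) + 1
        return counts

    def n_ambiguous(self, min_length: int = 20) -> int:
        return sum(
            1
            for i in self.introns
            if i["end"] - i["start"] >= min_length
            and any(c not in "ACGT" for c in i["combo"])
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return rng.choice(_BASES, size=n).tobytes().decode()


def _minor_weights(mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.full(len(_MINOR_COMBOS), 1.0 / len(_MINOR_COMBOS))
    weights = np.array(
        [3.0 ** -hamming_distance(c, CANONICAL) for c in _MINOR_COMBOS]
    )
    return weights / weights.sum()


def _sample_combo(rng, config, minor_weights) -> str:
    classes = ("canonical", "major_GC_AG", "major_AT_AC", "minor")
    probs = np.array([config.composition[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    if cls == "canonical":
        combo = CANONICAL
    elif cls == "major_GC_AG":
        combo = "GCAG"
    elif cls == "major_AT_AC":
        combo = "ATAC"
    else:
        combo = _MINOR_COMBOS[rng.choice(len(_MINOR_COMBOS), p=minor_weights)]
    if config.ambiguity_rate > 0 and rng.random() < config.ambiguity_rate:
        pos = int(rng.integers(0, 4))
        combo = combo[:pos] + "N" + combo[pos + 1 :]
    return combo


def _intron_length(rng, config) -> int:
    if rng.random() < config.long_tail_fraction:
        lo, hi = config.long_tail_range
        return int(rng.integers(lo, hi + 1))
    mu = math.log(config.intron_length_mode) + config.intron_length_sigma**2
    length = int(round(rng.lognormal(mu, config.intron_length_sigma)))
    return max(length, config.min_intron_length)


def _build_gene(rng, config, minor_weights, inject_stop: bool):
    """One gene in design (mRNA) orientation.

    Returns (sequence, cds_intervals, introns) with intervals local to the
    gene; introns carry (start, end, combo, spliced_fraction).
    """
    if isinstance(config.introns_per_gene, int):
        n_introns = config.introns_per_gene
    else:
        lo, hi = config.introns_per_gene
        n_introns = int(rng.integers(lo, hi + 1))
    n_exons = n_introns + 1
    lo, hi = config.exon_length_range
    exon_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    total = sum(exon_lengths)
    exon_lengths[-1] += (3 - total % 3) % 3
    total = sum(exon_lengths)

    n_codons = total // 3
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in middle] + ["TAA"]
    if inject_stop:
        codons[n_codons // 2] = "TAA"
    cds = "".join(codons)

    parts = []
    cds_intervals = []
    introns = []
    pos = 0
    consumed = 0
    for i, exon_len in enumerate(exon_lengths):
        exon_seq = cds[consumed : consumed + exon_len]
        consumed += exon_len
        parts.append(exon_seq)
        cds_intervals.append((pos, pos + exon_len))
        pos += exon_len
        if i < n_introns:
            combo = _sample_combo(rng, config, minor_weights)
            length = _intron_length(rng, config)
            interior = _random_seq(rng, length - 4)
            parts.append(combo[:2] + interior + combo[2:])
            if isinstance(config.spliced_fraction, tuple):
                s_lo, s_hi = config.spliced_fraction
                s = float(rng.uniform(s_lo, s_hi))
            else:
                s = float(config.spliced_fraction)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"spliced fraction {s} outside [0, 1]")
            introns.append((pos, pos + length, combo, s))
            pos += length
    return "".join(parts), cds_intervals, introns


def generate_genome(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[Path, Path, TruthManifest]:
    """Write a synthetic genome (FASTA), annotation (GFF3) and truth manifest.

    Genes are tiled onto chromosome-like sequences separated by random spacer
    DNA; minus-strand genes are designed in mRNA orientation and inserted as
    their reverse complement, so planted border combinations are always
    biological. The same (config, seed) produces byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    minor_weights = _minor_weights(config.minor_mode)

    stop_genes = set(range(config.n_internal_stop_genes))
    oob_genes = set(
        range(
            config.n_internal_stop_genes,
            config.n_internal_stop_genes + config.n_out_of_bounds_genes,
        )
    )

    manifest = TruthManifest(config={**asdict(config)})
    manifest.variant_spectrum = {}
    sequences: dict[str, list[str]] = {}
    gff_rows: list[tuple[str, int, str]] = []  # (seq, start, text) for sorting
    seq_index = 0
    seq_name = None
    cursor = 0
    chunks: list[str] = []

    def flush_sequence():
        nonlocal seq_name, cursor, chunks
        if seq_name is not None:
            sequences[seq_name] = chunks
            manifest.sequence_lengths[seq_name] = cursor
        seq_name, cursor, chunks = None, 0, []

    for g in range(config.n_genes):
        if g % config.genes_per_sequence == 0:
            flush_sequence()
            seq_index += 1
            seq_name = f"chr{seq_index}"
            cursor = 0
            chunks = []
        spacer = int(rng.integers(*config.spacer_length_range))
        chunks.append(_random_seq(rng, spacer))
        cursor += spacer

        gene_seq, cds_local, introns_local = _build_gene(
            rng, config, minor_weights, inject_stop=(g in stop_genes)
        )
        strand = "+" if rng.random() < config.forward_strand_fraction else "-"
        gene_len = len(gene_seq)
        g_start = cursor
        placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
        chunks.append(placed)
        cursor += gene_len

        def to_genomic(interval):
            s, e = interval
            if strand == "+":
                return (g_start + s, g_start + e)
            return (g_start + gene_len - e, g_start + gene_len - s)

        gene_id = f"gene{g + 1:05d}"
        tid = f"t-{gene_id}"
        cds_genomic = sorted(to_genomic(iv) for iv in cds_local)
        if g in oob_genes:
            # plant an annotation error: last CDS extends past the sequence
            bad = list(cds_genomic)
            s, e = bad[-1]
            bad[-1] = (s, e + 10_000_000)
            cds_genomic = bad
            manifest.error_genes.append(
                {"gene_id": gene_id, "reason": "out_of_bounds"}
            )
        elif g in stop_genes:
            manifest.error_genes.append(
                {"gene_id": gene_id, "reason": "internal_stop"}
            )
        else:
            manifest.genes.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "seq_name": seq_name,
                    "strand": strand,
                    "cds_segments": [list(iv) for iv in cds_genomic],
                }
            )
            for idx, (s, e, combo, frac) in enumerate(introns_local):
                gs, ge = to_genomic((s, e))
                manifest.introns.append(
                    {
                        "gene_id": gene_id,
                        "transcript_id": tid,
                        "seq_name": seq_name,
                        "start": gs,
                        "end": ge,
                        "strand": strand,
                        "index": idx,
                        "combo": combo,
                        "spliced_fraction": frac,
                    }
                )

        g_span = (
            min(s for s, _ in cds_genomic) + 1,
            max(e for _, e in cds_genomic),
        )
        rows = [
            f"{seq_name}\tsplicesurvey_sim\tgene\t{g_span[0]}\t{g_span[1]}\t.\t{strand}\t.\tID={gene_id}",
            f"{seq_name}\tsplicesurvey_sim\tmRNA\t{g_span[0]}\t{g_span[1]}\t.\t{strand}\t.\tID={tid};Parent={gene_id}",
        ]
        ordered = cds_genomic if strand == "+" else list(reversed(cds_genomic))
        consumed = 0
        phases = {}
        for seg in ordered:
            phases[seg] = (3 - consumed % 3) % 3
            consumed += seg[1] - seg[0]
        for s, e in cds_genomic:
            rows.append(
                f"{seq_name}\tsplicesurvey_sim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phases[(s, e)]}\tID=cds-{tid};Parent={tid}"
            )
        gff_rows.append((seq_name, g_span[0], "\n".join(rows)))

    # trailing spacer keeps the last gene away from the sequence edge
    tail = int(rng.integers(*config.spacer_length_range))
    chunks.append(_random_seq(rng, tail))
    cursor += tail
    flush_sequence()

    fasta_path = out_dir / "genome.fasta"
    with open(fasta_path, "w") as out:
        for name, parts in sequences.items():
            out.write(f">{name}\n")
            seq = "".join(parts)
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")

    gff_path = out_dir / "annotation.gff3"
    with open(gff_path, "w") as out:
        out.write("##gff-version 3\n")
        for _, _, text in sorted(gff_rows, key=lambda r: (r[0], r[1])):
            out.write(text + "\n")

    manifest.to_json(out_dir / "truth.json")
    return fasta_path, gff_path, manifest


def simulate_coverage(
    manifest: TruthManifest,
    out_path: str | Path,
    exon_depth: float = 100.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> Path:
    """Write a BedGraph coverage track realizing the planted spliced fractions.

    CDS bases get the exonic depth; every base of an intron with planted
    spliced fraction ``s`` gets ``exon_depth * (1 - s)``; everything else is
    uncovered. With ``noise == 0`` depths are exact; otherwise integer depths
    are drawn per base from a gamma-Poisson (negative binomial) with mean m
    and variance m + noise * m^2.
    """
    if exon_depth <= 0:
        raise ValueError("exon_depth must be > 0")
    rng = np.random.default_rng(seed)
    arrays = {
        name: np.zeros(length, dtype=float)
        for name, length in manifest.sequence_lengths.items()
    }
    for gene in manifest.genes:
        vec = arrays[gene["seq_name"]]
        for s, e in gene["cds_segments"]:
            vec[s:e] = exon_depth
    for intron in manifest.introns:
        s_frac = intron["spliced_fraction"]
        if not 0.0 <= s_frac <= 1.0:
            raise ValueError(f"spliced fraction {s_frac} outside [0, 1]")
        vec = arrays[intron["seq_name"]]
        vec[intron["start"] : intron["end"]] = exon_depth * (1.0 - s_frac)
    if noise > 0:
        for name, vec in arrays.items():
            covered = vec > 0
            means = vec[covered]
            gamma = rng.gamma(shape=1.0 / noise, scale=noise, size=means.size)
            vec[covered] = rng.poisson(means * gamma)
    out_path = Path(out_path)
    with open(out_path, "w") as out:
        for name, vec in arrays.items():
            rounded = np.round(vec, 6)
            # run-length encode, skipping uncovered stretches
            change = np.flatnonzero(np.diff(rounded)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(rounded)]))
            for s, e in zip(starts, ends):
                depth = rounded[s]
                if depth > 0:
                    depth_s = f"{int(depth)}" if depth == int(depth) else f"{depth:.6g}"
                    out.write(f"{name}\t{s}\t{e}\t{depth_s}\n")
    return out_path


def simulate_vcf(
    manifest: TruthManifest,
    sequences: dict[str, str],
    spectrum: SubstitutionSpectrum | dict[str, float],
    n_variants: int,
    seed: int | None = None,
    out_path: str | Path = "variants.vcf",
) -> Path:
    """Write homozygous biallelic SNPs drawn from a substitution spectrum.

    Variant positions are sampled uniformly over the genome, rejecting
    splice-site border bases and positions whose reference base does not
    match the sampled substitution's source base. Planted variants are
    appended to the manifest. Same seed, same VCF.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if isinstance(spectrum, SubstitutionSpectrum):
        rates = spectrum.rates()
    else:
        rates = {s: float(spectrum.get(s, 0.0)) for s in SUBSTITUTIONS}
    total = sum(rates.values())
    if total <= 0:
        raise ValueError("substitution spectrum is all zero")
    probs = np.array([rates[s] / total for s in SUBSTITUTIONS])
    manifest.variant_spectrum = {s: rates[s] / total for s in SUBSTITUTIONS}

    forbidden = set()
    for intron in manifest.introns:
        name, a, b = intron["seq_name"], intron["start"], intron["end"]
        forbidden.update({(name, a), (name, a + 1), (name, b - 2), (name, b - 1)})

    rng = np.random.default_rng(seed)
    names = list(sequences)
    lengths = np.array([len(sequences[n]) for n in names], dtype=float)
    seq_probs = lengths / lengths.sum()
    chosen: dict[tuple[str, int], tuple[str, str]] = {}
    attempts = 0
    max_attempts = 2000 * n_variants
    while len(chosen) < n_variants:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place all variants; genome too small for n_variants"
            )
        sub = SUBSTITUTIONS[rng.choice(len(SUBSTITUTIONS), p=probs)]
        ref, alt = sub[0], sub[2]
        si = rng.choice(len(names), p=seq_probs)
        name = names[si]
        pos = int(rng.integers(0, len(sequences[name])))
        if (name, pos) in forbidden or (name, pos) in chosen:
            continue
        if sequences[name][pos] != ref:
            continue
        chosen[(name, pos)] = (ref, alt)

    out_path = Path(out_path)
    with open(out_path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name in names:
            out.write(f"##contig=<ID={name},length={len(sequences[name])}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n")
        for (name, pos), (ref, alt) in sorted(
            chosen.items(), key=lambda kv: (names.index(kv[0][0]), kv[0][1])
        ):
            out.write(f"{name}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t1/1\n")
            manifest.variants.append(
                {"seq_name": name, "pos": pos, "ref": ref, "alt": alt}
            )
    return out_path
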