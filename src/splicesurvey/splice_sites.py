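"""Intron extraction and splice-site combination classification.

A splice-site *combination* is the 4-letter concatenation of the donor
dinucleotide (first two intronic bases, 5' end) and the acceptor dinucleotide
(last two intronic bases, 3' end), written in DNA letters on the coding
strand. GT-AG is canonical; GC-AG and AT-AC are the major non-canonical
combinations; the remaining 253 unambiguous combinations are minor
non-canonical. Combinations containing any non-ACGT character are ambiguous
and masked from diversity statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .genome_io import GenomeAssembly, TranscriptModel

__all__ = [
    "CANONICAL",
    "MAJOR_COMBOS",
    "ALL_COMBOS",
    "SpliceClass",
    "Intron",
    "SpeciesProfile",
    "AlternativePlacement",
    "reverse_complement",
    "is_ambiguous",
    "classify_combo",
    "hamming_distance",
    "closest_reference",
    "extract_introns",
    "build_profile",
    "detect_shift_equivalence",
    "write_intron_table",
    "write_profile",
    "read_profile",
    "write_intron_bed",
]

CANONICAL = "GTAG"
MAJOR_COMBOS = ("GCAG", "ATAC")
#: the 256 unambiguous donor+acceptor combinations, lexicographic
ALL_COMBOS = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn"
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SpliceClass(str, Enum):
    CANONICAL = "canonical"
    MAJOR_GC_AG = "major_GC_AG"
    MAJOR_AT_AC = "major_AT_AC"
    MINOR = "minor"
    AMBIGUOUS = "ambiguous"


def is_ambiguous(combo: str) -> bool:
    return any(c not in "ACGT" for c in combo)


def classify_combo(combo: str) -> SpliceClass:
    """Classify a 4-letter border combination.

    GTAG -> canonical; GCAG / ATAC -> major non-canonical; any non-ACGT
    character -> ambiguous; everything else -> minor non-canonical.
    """
    if len(combo) != 4:
        raise ValueError(f"splice combination must have length 4, got {combo!r}")
    if is_ambiguous(combo):
        return SpliceClass.AMBIGUOUS
    if combo == CANONICAL:
        return SpliceClass.CANONICAL
    if combo == "GCAG":
        return SpliceClass.MAJOR_GC_AG
    if combo == "ATAC":
        return SpliceClass.MAJOR_AT_AC
    return SpliceClass.MINOR


def hamming_distance(combo: str, reference: str) -> int:
    """Number of mismatching positions between two unambiguous combinations."""
    if len(combo) != len(reference):
        raise ValueError("combinations must have equal length")
    if is_ambiguous(combo) or is_ambiguous(reference):
        raise ValueError("hamming distance undefined for ambiguous combinations")
    return sum(a != b for a, b in zip(combo, reference))


_REFERENCES = (CANONICAL,) + MAJOR_COMBOS  # tie-break order: GTAG > GCAG > ATAC


def closest_reference(
    combo: str,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Closest of GT-AG / GC-AG / AT-AC and the implied substitutions.

    Returns the reference combination minimizing the Hamming distance (ties
    prefer GTAG, then GCAG, then ATAC — the globally more frequent origin) and
    the list of implied substitutions as (position 1..4, ref_base, obs_base).
    Only minor combinations are accepted: for canonical/major input there is
    nothing to infer.
    """
    cls = classify_combo(combo)
    if cls is not SpliceClass.MINOR:
        raise ValueError(f"closest_reference expects a minor combination, got {combo!r} ({cls.value})")
    best = min(_REFERENCES, key=lambda ref: hamming_distance(combo, ref))
    substitutions = [
        (pos + 1, ref_base, obs_base)
        for pos, (ref_base, obs_base) in enumerate(zip(best, combo))
        if ref_base != obs_base
    ]
    return best, substitutions


@dataclass
class Intron:
    """A CDS-flanked intron with its border combination.

    ``combo`` is read strand-awarely so the donor dinucleotide sits at the
    biological 5' end; ``index`` counts introns 5'->3' along the transcript.
    """

    seq_name: str
    start: int
    end: int
    strand: str
    combo: str
    transcript_id: str
    index: int
    flanked_by_cds: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def splice_class(self) -> SpliceClass:
        return classify_combo(self.combo)

    def border_positions(self) -> tuple[int, int, int, int]:
        """Genomic 0-based positions of the four border bases (donor pair, acceptor pair)."""
        donor = (self.start, self.start + 1)
        acceptor = (self.end - 2, self.end - 1)
        if self.strand == "-":
            donor, acceptor = (self.end - 1, self.end - 2), (self.start + 1, self.start)
        return (*donor, *acceptor)


def combo_at(assembly: GenomeAssembly, seq_name: str, start: int, end: int, strand: str) -> str:
    """Border combination of the interval [start, end), biological orientation."""
    if end - start < 4:
        raise ValueError("intron shorter than 4 nt has no border combination")
    left = assembly.fetch(seq_name, start, start + 2)
    right = assembly.fetch(seq_name, end - 2, end)
    if strand == "-":
        return reverse_complement(right) + reverse_complement(left)
    return left + right


def extract_introns(
    transcript: TranscriptModel, assembly: GenomeAssembly
) -> list[Intron]:
    """Introns between consecutive CDS segments of a transcript.

    One intron per positive-width gap; UTR introns never appear because only
    CDS segments are modelled. On the minus strand the border combination is
    read off the reverse complement and introns are indexed 5'->3'
    biologically (right to left on the genome).
    """
    segments = transcript.cds_segments
    gaps = [
        (e1, s2)
        for (_, e1), (s2, _) in zip(segments, segments[1:])
        if s2 > e1
    ]
    if transcript.strand == "-":
        gaps = gaps[::-1]
    introns = []
    for idx, (start, end) in enumerate(gaps):
        introns.append(
            Intron(
                seq_name=transcript.seq_name,
                start=start,
                end=end,
                strand=transcript.strand,
                combo=combo_at(assembly, transcript.seq_name, start, end, transcript.strand),
                transcript_id=transcript.transcript_id,
                index=idx,
            )
        )
    return introns


@dataclass
class SpeciesProfile:
    """Counts over the 256 unambiguous border combinations for one sample.

    Ambiguity-containing combinations are tallied separately in
    ``ambiguous_masked`` so that totals with either masking convention can be
    derived. ``sum(counts.values()) + ambiguous_masked == total_introns``.
    """

    species: str
    counts: dict[str, int] = field(default_factory=dict)
    ambiguous_masked: int = 0
    total_introns: int = 0

    def vector(self) -> list[int]:
        """Counts aligned to :data:`ALL_COMBOS` (absent = 0)."""
        return [self.counts.get(c, 0) for c in ALL_COMBOS]

    def class_counts(self) -> dict[str, int]:
        out = {cls.value: 0 for cls in SpliceClass}
        for combo, n in self.counts.items():
            out[classify_combo(combo).value] += n
        out[SpliceClass.AMBIGUOUS.value] = self.ambiguous_masked
        return out

    @property
    def n_canonical(self) -> int:
        return self.counts.get(CANONICAL, 0)

    @property
    def n_noncanonical(self) -> int:
        """Unambiguous non-canonical combinations (major + minor)."""
        return sum(n for c, n in self.counts.items() if c != CANONICAL)


def build_profile(
    introns: list[Intron], min_length: int = 20, species: str = "sample"
) -> SpeciesProfile:
    """Per-species combination counts over introns of at least ``min_length``.

    Sub-threshold introns are excluded entirely; ambiguous combinations are
    masked into a separate tally rather than counted.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    profile = SpeciesProfile(species=species)
    for intron in introns:
        if intron.length < min_length:
            continue
        profile.total_introns += 1
        if is_ambiguous(intron.combo):
            profile.ambiguous_masked += 1
        else:
            profile.counts[intron.combo] = profile.counts.get(intron.combo, 0) + 1
    return profile


@dataclass
class AlternativePlacement:
    """A shifted intron placement yielding the identical mature mRNA."""

    shift: int
    start: int
    end: int
    combo: str
    mRNA_identical: bool = True

    @property
    def splice_class(self) -> SpliceClass:
        return classify_combo(self.combo)


def detect_shift_equivalence(
    intron: Intron, assembly: GenomeAssembly, max_shift: int = 3
) -> list[AlternativePlacement]:
    """Alternative intron placements indistinguishable at the mRNA level.

    Moving both intron boundaries by the same offset ``s`` leaves the mature
    mRNA unchanged iff the ``|s|`` exonic bases given up at one end equal the
    ``|s|`` intronic bases exposed at the other end. Such shift-equivalent
    placements are the mechanism behind artifactual annotations like CA-GG
    in place of an overlapping GC-AG site. Shifts that would leave the
    sequence bounds are skipped silently.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    seq = assembly.sequences[intron.seq_name]
    a, b = intron.start, intron.end
    placements = []
    for s in range(-max_shift, max_shift + 1):
        if s == 0:
            continue
        if a + s < 0 or b + s > len(seq):
            continue
        if s > 0:
            equivalent = seq[a : a + s] == seq[b : b + s]
        else:
            equivalent = seq[a + s : a] == seq[b + s : b]
        if equivalent:
            placements.append(
                AlternativePlacement(
                    shift=s,
                    start=a + s,
                    end=b + s,
                    combo=combo_at(
                        assembly, intron.seq_name, a + s, b + s, intron.strand
                    ),
                )
            )
    return placements


def write_intron_table(introns: list[Intron], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(
            "seq_name\tstart\tend\tstrand\tlength\tcombo\tclass\ttranscript_id\tindex\n"
        )
        for i in introns:
            out.write(
                f"{i.seq_name}\t{i.start}\t{i.end}\t{i.strand}\t{i.length}\t"
                f"{i.combo}\t{i.splice_class.value}\t{i.transcript_id}\t{i.index}\n"
            )


def write_intron_bed(introns: list[Intron], path: str | Path) -> None:
    """BED6 export of intron intervals (name = combo, score = length)."""
    with open(path, "w") as out:
        for i in introns:
            out.write(
                f"{i.seq_name}\t{i.start}\t{i.end}\t{i.combo}\t{i.length}\t{i.strand}\n"
            )


def write_profile(profile: SpeciesProfile, path: str | Path) -> None:
    """256-row TSV of combination counts plus the masked-ambiguous tally."""
    with open(path, "w") as out:
        out.write(f"# species={profile.species}\n")
        out.write("combo\tcount\n")
        for combo in ALL_COMBOS:
            out.write(f"{combo}\t{profile.counts.get(combo, 0)}\n")
        out.write(f"ambiguous_masked\t{profile.ambiguous_masked}\n")


def read_profile(path: str | Path) -> SpeciesProfile:
    species = Path(path).stem
    counts: dict[str, int] = {}
    ambiguous = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("# species="):
                species = line.split("=", 1)[1]
                continue
            if not line or line.startswith("#") or line.startswith("combo\t"):
                continue
            key, value = line.split("\t")
            if key == "ambiguous_masked":
                ambiguous = int(value)
            elif int(value):
                counts[key] = int(value)
    total = sum(counts.values()) + ambiguous
    return SpeciesProfile(
        species=species, counts=counts, ambiguous_masked=ambiguous, total_introns=total
    )
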