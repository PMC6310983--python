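"""Stage orchestration: classify, validate, stats, substitution.

Each ``run_*`` function is a pure library entry point used both by the
command-line interface and by scripts; given the same inputs and seed the
primary outputs are byte-identical. Machine-readable outputs (TSV/JSON)
carry a provenance comment with the package version and the configuration
that produced them; logs go to stderr via :mod:`logging`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .genome_io import (
    GenomeAssembly,
    filter_genes,
    read_annotation,
    read_genome,
    select_representative_transcript,
)
from .splice_sites import (
    Intron,
    SpeciesProfile,
    SpliceClass,
    build_profile,
    extract_introns,
    read_profile,
    write_intron_bed,
    write_intron_table,
    write_profile,
)
from .coverage_validation import (
    boundary_depths,
    evaluate_support,
    read_coverage,
    summarize_usage,
    validation_ratio,
    write_support_calls,
)
from .profile_analysis import (
    correlate_counts,
    divergence_frequency_correlation,
    profile_similarity_matrix,
)
from .variant_spectra import (
    compare_spectra,
    overlap_variants,
    splice_site_spectrum,
    substitution_spectrum_from_vcf,
)

logger = logging.getLogger("splicesurvey")

__all__ = [
    "AnalysisConfig",
    "ClassificationResult",
    "classify_genome",
    "run_classify",
    "run_validate",
    "run_stats",
    "run_substitution",
]


@dataclass
class AnalysisConfig:
    """Survey thresholds, all positive; defaults follow the study design."""

    min_intron_length: int = 20
    min_drop: float = 0.2
    long_intron_threshold: int = 5000
    resample_reps: int = 100
    max_shift: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.min_intron_length < 1 or self.long_intron_threshold < 1:
            raise ValueError("length thresholds must be positive")
        if not 0 < self.min_drop < 1:
            raise ValueError("min_drop must be in (0, 1)")
        if self.resample_reps < 1 or self.max_shift < 1:
            raise ValueError("resample_reps and max_shift must be positive")

    def provenance(self) -> str:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
        return f"splicesurvey v{__version__} config={digest} seed={self.seed}"


@dataclass
class ClassificationResult:
    assembly: GenomeAssembly
    introns: list[Intron]
    profile: SpeciesProfile
    filter_report: object
    gene_summaries: list[tuple[int, bool]]
    n_genes_retained: int


def classify_genome(
    fasta: str | Path,
    gff3: str | Path,
    config: AnalysisConfig | None = None,
    species: str | None = None,
) -> ClassificationResult:
    """Full classification stage: read, filter, extract, profile.

    Selects the representative (longest-CDS) transcript per retained gene,
    extracts its CDS-flanked introns, and builds the species profile over
    introns of at least ``min_intron_length``. ``gene_summaries`` records,
    per gene with at least one sufficiently long intron, the intron count and
    whether any of its splice sites is non-canonical (unambiguous).
    """
    config = config or AnalysisConfig()
    species = species or Path(fasta).stem
    assembly = read_genome(fasta)
    annotation = read_annotation(gff3, assembly)
    retained, report = filter_genes(annotation, assembly)
    logger.info(
        "%s: %d genes read, %d retained, %d removed",
        species,
        report.n_input,
        report.n_retained,
        report.n_removed,
    )
    introns: list[Intron] = []
    gene_summaries: list[tuple[int, bool]] = []
    for gene in retained.genes:
        transcript = select_representative_transcript(gene)
        gene_introns = [
            i
            for i in extract_introns(transcript, assembly)
            if i.length >= config.min_intron_length
        ]
        introns.extend(gene_introns)
        if gene_introns:
            has_nc = any(
                i.splice_class
                in (SpliceClass.MAJOR_GC_AG, SpliceClass.MAJOR_AT_AC, SpliceClass.MINOR)
                for i in gene_introns
            )
            gene_summaries.append((len(gene_introns), has_nc))
    profile = build_profile(introns, min_length=config.min_intron_length, species=species)
    logger.info(
        "%s: %d introns >= %d bp (%d ambiguous masked)",
        species,
        profile.total_introns,
        config.min_intron_length,
        profile.ambiguous_masked,
    )
    return ClassificationResult(
        assembly=assembly,
        introns=introns,
        profile=profile,
        filter_report=report,
        gene_summaries=gene_summaries,
        n_genes_retained=len(retained.genes),
    )


def _write_json(payload: dict, path: Path, config: AnalysisConfig) -> None:
    payload = {"_provenance": config.provenance(), **payload}
    with open(path, "w") as out:
        json.dump(payload, out, indent=2, default=_jsonable)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_classify(
    fasta: str | Path,
    gff3: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    species: str | None = None,
) -> ClassificationResult:
    """Classification stage with file outputs: intron table, profile, report."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = classify_genome(fasta, gff3, config, species)
    if result.n_genes_retained == 0:
        raise ValueError("no genes retained after filtering")
    if result.profile.total_introns == 0:
        logger.warning("no introns passed the length threshold; profile is empty")
    write_intron_table(result.introns, out_dir / "introns.tsv")
    write_intron_bed(result.introns, out_dir / "introns.bed")
    write_profile(result.profile, out_dir / "profile.tsv")
    result.filter_report.to_tsv(out_dir / "filter_report.tsv")
    result.filter_report.to_json(out_dir / "filter_report.json")
    return result


def run_validate(
    fasta: str | Path,
    gff3: str | Path,
    coverage: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Coverage validation stage: support calls, usage summary, ratios."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = classify_genome(fasta, gff3, config)
    track = read_coverage(coverage, lengths=result.assembly.lengths)
    records = []
    calls = []
    n_skipped = 0
    for intron in result.introns:
        if intron.seq_name not in track:
            n_skipped += 1
            continue
        try:
            depths = boundary_depths(intron, track)
        except ValueError:
            n_skipped += 1
            continue
        call = evaluate_support(depths, min_drop=config.min_drop)
        records.append((intron, depths, call))
        calls.append((intron.splice_class, call))
    if n_skipped:
        logger.warning("%d introns skipped (no coverage or at sequence edge)", n_skipped)
    write_support_calls(records, out_dir / "support_calls.tsv")
    summaries = summarize_usage(calls) if calls else {}
    ratios = validation_ratio(calls) if calls else None
    _write_json(
        {
            "n_introns_evaluated": len(calls),
            "n_introns_skipped": n_skipped,
            "usage_by_class": summaries,
            "validation_ratios": ratios,
        },
        out_dir / "usage_summary.json",
        config,
    )
    return {"calls": calls, "usage_by_class": summaries, "validation_ratios": ratios}


def run_stats(
    profile_paths: list[str | Path],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    counts_table: str | Path | None = None,
) -> dict:
    """Profile statistics stage.

    Computes the divergence-frequency correlation over the pooled profiles,
    the pairwise profile similarity matrix (>= 2 profiles), and — when a
    per-species counts table (TSV with columns species, canonical,
    noncanonical, total and optionally genome_size) is supplied — the
    cross-species count correlations.
    """
    import pandas as pd

    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = [read_profile(p) for p in profile_paths]
    results: dict = {}
    results["divergence_frequency"] = divergence_frequency_correlation(profiles)
    if len(profiles) >= 2:
        matrix = profile_similarity_matrix(profiles)
        matrix.to_csv(out_dir / "similarity_matrix.tsv", sep="\t")
        results["similarity_matrix"] = matrix
    else:
        logger.warning("similarity matrix skipped: fewer than 2 profiles")
    if counts_table is not None:
        table = pd.read_csv(counts_table, sep="\t")
        corr: dict[str, object] = {}
        if {"noncanonical", "total"} <= set(table.columns):
            corr["noncanonical_vs_total"] = correlate_counts(
                table["noncanonical"], table["total"]
            )
        if "genome_size" in table.columns:
            for col in ("canonical", "noncanonical"):
                if col in table.columns:
                    corr[f"{col}_vs_genome_size"] = correlate_counts(
                        table[col], table["genome_size"]
                    )
        results["count_correlations"] = corr
    _write_json(
        {
            "divergence_frequency": results["divergence_frequency"],
            "count_correlations": results.get("count_correlations", {}),
        },
        out_dir / "stats.json",
        config,
    )
    return results


def run_substitution(
    fasta: str | Path,
    gff3: str | Path,
    vcf: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Substitution-spectrum stage: genome vs splice-site spectra, overlap."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = classify_genome(fasta, gff3, config)
    genome_spectrum = substitution_spectrum_from_vcf(vcf)
    minor_combos = [
        i.combo for i in result.introns if i.splice_class is SpliceClass.MINOR
    ]
    site_spectrum = splice_site_spectrum(minor_combos)
    genome_spectrum.to_tsv(out_dir / "genome_spectrum.tsv")
    site_spectrum.to_tsv(out_dir / "splice_site_spectrum.tsv")
    chi2 = None
    if genome_spectrum.total == 0:
        logger.warning("VCF contains no homozygous SNPs; spectrum test skipped")
    elif site_spectrum.total == 0:
        logger.warning("no minor combinations observed; spectrum test skipped")
    else:
        try:
            chi2 = compare_spectra(site_spectrum, genome_spectrum)
        except ValueError as exc:
            logger.warning("spectrum test skipped: %s", exc)
    noncanonical_sites = [
        (i.seq_name, tuple(i.border_positions()))
        for i in result.introns
        if i.splice_class
        in (SpliceClass.MAJOR_GC_AG, SpliceClass.MAJOR_AT_AC, SpliceClass.MINOR)
    ]
    overlap = overlap_variants(noncanonical_sites, vcf)
    _write_json(
        {"chi_square": chi2, "overlap": overlap},
        out_dir / "substitution.json",
        config,
    )
    return {
        "genome_spectrum": genome_spectrum,
        "splice_site_spectrum": site_spectrum,
        "chi_square": chi2,
        "overlap": overlap,
    }
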