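"""Nucleotide substitution spectra: genome-wide vs. splice-site-implied.

A substitution spectrum tallies the 12 ordered single-nucleotide changes
X→Y. Genome-wide rates come from homozygous biallelic SNPs in a VCF; the
splice-site spectrum accumulates the substitutions implied by deriving each
minor non-canonical combination from its closest reference among GT-AG,
GC-AG and AT-AC. A Pearson chi-square compares the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from .splice_sites import closest_reference

__all__ = [
    "SUBSTITUTIONS",
    "SubstitutionSpectrum",
    "ChiSquareResult",
    "OverlapReport",
    "substitution_spectrum_from_vcf",
    "splice_site_spectrum",
    "compare_spectra",
    "overlap_variants",
]

#: the 12 ordered substitutions, lexicographic
SUBSTITUTIONS = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)


@dataclass
class SubstitutionSpectrum:
    """Counts (and derived rates) over the 12 ordered substitutions."""

    counts: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rates(self) -> dict[str, float]:
        """Counts normalized to sum to 1 (all-zero spectrum: all rates 0)."""
        total = self.total
        if total == 0:
            return {s: 0.0 for s in SUBSTITUTIONS}
        return {s: self.counts.get(s, 0) / total for s in SUBSTITUTIONS}

    def vector(self) -> np.ndarray:
        return np.array([self.counts.get(s, 0) for s in SUBSTITUTIONS], dtype=float)

    def add(self, ref: str, alt: str, n: int = 1) -> None:
        key = f"{ref}>{alt}"
        if key not in SUBSTITUTIONS:
            raise ValueError(f"not a single-nucleotide substitution: {key}")
        self.counts[key] = self.counts.get(key, 0) + n

    def to_tsv(self, path: str | Path) -> None:
        rates = self.rates()
        with open(path, "w") as out:
            out.write("substitution\tcount\trate\n")
            for s in SUBSTITUTIONS:
                out.write(f"{s}\t{self.counts.get(s, 0)}\t{rates[s]:.6g}\n")


def _is_hom_alt(gt) -> bool | None:
    """True hom-alt, False het/hom-ref, None when the genotype is missing."""
    if gt is None or any(a is None for a in gt):
        return None
    if all(a == 1 for a in gt):
        return True
    return False


def substitution_spectrum_from_vcf(path: str | Path) -> SubstitutionSpectrum:
    """Genome-wide substitution spectrum from homozygous SNPs in a VCF.

    Only biallelic SNP records whose first-sample genotype is homozygous
    alternative are counted; indels, multi-allelic records, heterozygous and
    missing calls are skipped and tallied in ``skipped``.
    """
    spectrum = SubstitutionSpectrum()
    skipped = {"indel": 0, "multiallelic": 0, "het_or_ref": 0, "missing_gt": 0}
    with pysam.VariantFile(str(path)) as vcf:
        if len(vcf.header.samples) == 0:
            raise ValueError(f"{path}: VCF has no samples; genotypes are required")
        sample = vcf.header.samples[0]
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                skipped["indel"] += 1
                continue
            hom = _is_hom_alt(rec.samples[sample].get("GT"))
            if hom is None:
                skipped["missing_gt"] += 1
            elif hom:
                spectrum.add(ref, alt)
            else:
                skipped["het_or_ref"] += 1
    spectrum.skipped = skipped
    return spectrum


def splice_site_spectrum(minor_combos: list[str]) -> SubstitutionSpectrum:
    """Substitutions implied by minor combinations vs. their closest reference.

    Each minor combination contributes the mismatches between itself and the
    nearest of GT-AG, GC-AG and AT-AC, i.e. the mutations under the
    assumption that the site originated from that reference.
    """
    spectrum = SubstitutionSpectrum()
    for combo in minor_combos:
        _, substitutions = closest_reference(combo)
        for _pos, ref_base, obs_base in substitutions:
            spectrum.add(ref_base, obs_base)
    return spectrum


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    pooled_unmodeled: int = 0
    warning: str | None = None


def compare_spectra(
    observed: SubstitutionSpectrum, expected_rates: SubstitutionSpectrum | dict[str, float]
) -> ChiSquareResult:
    """Pearson chi-square of an observed spectrum against expected rates.

    Expected counts are the observed total times the expected relative rates.
    Categories with zero expected rate cannot enter the statistic; observed
    counts falling in them are pooled into an unmodeled remainder, reported
    with a warning. df = (categories used) − 1.
    """
    if isinstance(expected_rates, SubstitutionSpectrum):
        rates = expected_rates.rates()
    else:
        rates = {s: expected_rates.get(s, 0.0) for s in SUBSTITUTIONS}
    if observed.total < 1:
        raise ValueError("observed spectrum is empty")
    rate_total = sum(rates.values())
    if rate_total <= 0:
        raise ValueError("expected rates are all zero")
    rates = {s: r / rate_total for s, r in rates.items()}

    used = [s for s in SUBSTITUTIONS if rates[s] > 0]
    pooled = sum(observed.counts.get(s, 0) for s in SUBSTITUTIONS if rates[s] == 0)
    warning = None
    if pooled:
        warning = (
            f"{pooled} observed substitutions fall in categories with zero "
            "expected rate and were pooled out of the test"
        )
    obs = np.array([observed.counts.get(s, 0) for s in used], dtype=float)
    if obs.sum() == 0:
        raise ValueError(
            "observed spectrum has no counts in categories with non-zero "
            "expected rate"
        )
    exp_rates = np.array([rates[s] for s in used])
    exp = obs.sum() * exp_rates / exp_rates.sum()
    result = stats.chisquare(obs, exp)
    return ChiSquareResult(
        statistic=float(result.statistic),
        df=len(used) - 1,
        p_value=float(result.pvalue),
        observed={s: float(o) for s, o in zip(used, obs)},
        expected={s: float(e) for s, e in zip(used, exp)},
        pooled_unmodeled=pooled,
        warning=warning,
    )


@dataclass
class OverlapReport:
    n_sites: int
    n_overlapping: int
    n_reference_majority: int
    n_alternative_majority: int


def _majority_is_reference(rec) -> bool:
    """Majority allele at a variant record, from genotypes or AC/AN.

    Ties count as alternative-majority (conservative against the reference).
    """
    n_ref = n_alt = 0
    if len(rec.samples) > 0:
        for sample in rec.samples.values():
            gt = sample.get("GT")
            if gt is None:
                continue
            for allele in gt:
                if allele == 0:
                    n_ref += 1
                elif allele is not None:
                    n_alt += 1
    else:
        info = rec.info
        ac = info.get("AC")
        an = info.get("AN")
        if ac is not None and an is not None:
            n_alt = int(ac[0] if isinstance(ac, tuple) else ac)
            n_ref = int(an) - n_alt
    return n_ref > n_alt


def overlap_variants(
    site_positions: list[tuple[str, tuple[int, ...]]],
    vcf_path: str | Path,
) -> OverlapReport:
    """Overlap splice-site border bases with variant positions in a VCF.

    ``site_positions`` holds one entry per splice-site combination: the
    sequence name and the genomic 0-based positions of its four border bases.
    A combination overlaps if any of those bases coincides with a variant
    position; at overlapping combinations the majority allele across
    accessions decides whether the reference allele dominates.
    """
    variants: dict[tuple[str, int], bool] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            variants[(rec.chrom, rec.pos - 1)] = _majority_is_reference(rec)
    n_overlap = n_ref = 0
    for seq_name, positions in site_positions:
        hits = [
            variants[(seq_name, p)]
            for p in positions
            if (seq_name, p) in variants
        ]
        if hits:
            n_overlap += 1
            if hits[0]:
                n_ref += 1
    return OverlapReport(
        n_sites=len(site_positions),
        n_overlapping=n_overlap,
        n_reference_majority=n_ref,
        n_alternative_majority=n_overlap - n_ref,
    )
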