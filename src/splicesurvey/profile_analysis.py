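"""Statistics over splice-site profiles and intron properties.

Covers the survey's results layer: the divergence–frequency correlation,
pairwise profile similarity, count correlations across species, focal-vs-
background intron-length comparisons with resampling, enrichment of minor
combinations in very long introns, the per-intron-count probability of
carrying a non-canonical site, and gene-set proportion comparisons.

Spearman coefficients come from :func:`scipy.stats.spearmanr`; p-values use
the t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splice_sites import (
    ALL_COMBOS,
    CANONICAL,
    Intron,
    SpeciesProfile,
    SpliceClass,
    classify_combo,
    hamming_distance,
)

__all__ = [
    "CorrelationResult",
    "ResamplingResult",
    "ComboEnrichment",
    "GeneSetComparison",
    "divergence_frequency_correlation",
    "profile_similarity_matrix",
    "correlate_counts",
    "compare_intron_lengths",
    "long_intron_enrichment",
    "noncanonical_by_intron_count",
    "compare_gene_sets",
]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _spearman(x, y) -> CorrelationResult:
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


def divergence_frequency_correlation(
    profiles: SpeciesProfile | list[SpeciesProfile],
    pool: bool = True,
    normalize: bool = False,
    include_canonical: bool = True,
) -> CorrelationResult:
    """Spearman correlation of combination divergence against frequency.

    Each of the 256 unambiguous combinations contributes one observation:
    x = Hamming distance to the canonical GT-AG, y = its pooled count across
    profiles (or the mean per-profile frequency with ``normalize=True``).
    With ``pool=False`` every (species, combination) pair is an observation.
    A negative coefficient means diverged combinations are rarer.
    """
    if isinstance(profiles, SpeciesProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("at least one profile required")
    combos = [
        c for c in ALL_COMBOS if include_canonical or c != CANONICAL
    ]
    distances = np.array([hamming_distance(c, CANONICAL) for c in combos])
    matrix = np.array(
        [[p.counts.get(c, 0) for c in combos] for p in profiles], dtype=float
    )
    if matrix.sum() == 0:
        raise ValueError("all combination counts are zero")
    if normalize:
        totals = matrix.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        matrix = matrix / totals
    if pool:
        y = matrix.sum(axis=0) if not normalize else matrix.mean(axis=0)
        return _spearman(distances, y)
    x = np.tile(distances, len(profiles))
    return _spearman(x, matrix.ravel())


def profile_similarity_matrix(profiles: list[SpeciesProfile]) -> pd.DataFrame:
    """Pairwise Spearman similarity of species profiles.

    Entry (i, j) correlates the two species' counts over the 256 aligned
    combinations. The matrix is symmetric with unit diagonal; a profile with
    zero variance across combinations yields missing (NaN) off-diagonal
    entries.
    """
    if len(profiles) < 2:
        raise ValueError("at least two profiles required")
    labels = [p.species for p in profiles]
    vectors = np.array([p.vector() for p in profiles], dtype=float)
    n = len(profiles)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if vectors[i].std() == 0 or vectors[j].std() == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(vectors[i], vectors[j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=labels, columns=labels)


def correlate_counts(x, y) -> CorrelationResult:
    """Spearman correlation between two per-species count lists."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return _spearman(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


@dataclass
class ResamplingResult:
    """Focal-vs-resampled-background rank-sum comparison, replicated."""

    p_values: list[float]
    mean_differences: list[float]
    reps: int
    seed: int | None

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def mean_of_mean_differences(self) -> float:
        return float(np.mean(self.mean_differences))


def compare_intron_lengths(
    focal,
    background,
    reps: int = 100,
    seed: int | None = None,
) -> ResamplingResult:
    """Compare focal intron lengths against resampled background lengths.

    Each replicate draws ``len(focal)`` background lengths without
    replacement, applies a two-sided Wilcoxon rank-sum test and records the
    difference of means (focal − sample). Replication corrects for the
    randomness of the background draw.
    """
    focal = np.asarray(focal, dtype=float)
    background = np.asarray(background, dtype=float)
    if focal.size == 0:
        raise ValueError("focal set is empty")
    if background.size < focal.size:
        raise ValueError("background must be at least as large as focal")
    rng = np.random.default_rng(seed)
    p_values = []
    mean_diffs = []
    for _ in range(reps):
        sample = rng.choice(background, size=focal.size, replace=False)
        stat = stats.ranksums(focal, sample)
        p_values.append(float(stat.pvalue))
        mean_diffs.append(float(focal.mean() - sample.mean()))
    return ResamplingResult(
        p_values=p_values, mean_differences=mean_diffs, reps=reps, seed=seed
    )


@dataclass
class ComboEnrichment:
    combo: str
    count_long: int
    count_short: int
    proportion_long: float
    proportion_short: float
    ratio: float
    rank: int


def long_intron_enrichment(
    introns: list[Intron], threshold: int = 5000
) -> tuple[list[ComboEnrichment], pd.DataFrame, bool]:
    """Minor-combination enrichment in very long introns.

    Restricted to minor unambiguous combinations, counts each one among
    introns longer than ``threshold`` versus the rest, ranks by the
    pseudocount-stabilized ratio of proportions (descending; ties in
    lexicographic combination order), and reports the base composition of the
    combinations at each rank. Returns (enrichments, base table, warning);
    the warning flag is set when no long introns exist.
    """
    minors = [i for i in introns if i.splice_class is SpliceClass.MINOR]
    long_introns = [i for i in minors if i.length > threshold]
    short_introns = [i for i in minors if i.length <= threshold]
    if not long_introns:
        return [], pd.DataFrame(columns=["rank", "combo", "A", "C", "G", "T"]), True
    n_long, n_short = len(long_introns), len(short_introns)
    combos = sorted({i.combo for i in minors})
    counts_long = {c: 0 for c in combos}
    counts_short = {c: 0 for c in combos}
    for i in long_introns:
        counts_long[i.combo] += 1
    for i in short_introns:
        counts_short[i.combo] += 1
    records = []
    for combo in combos:
        cl, cs = counts_long[combo], counts_short[combo]
        # pseudocount 1 on counts keeps absent combinations comparable
        ratio = ((cl + 1) / (n_long + 1)) / ((cs + 1) / (n_short + 1))
        records.append(
            (
                combo,
                cl,
                cs,
                cl / n_long,
                cs / n_short if n_short else 0.0,
                ratio,
            )
        )
    records.sort(key=lambda r: (-r[5], r[0]))
    enrichments = [
        ComboEnrichment(
            combo=r[0],
            count_long=r[1],
            count_short=r[2],
            proportion_long=r[3],
            proportion_short=r[4],
            ratio=r[5],
            rank=rank,
        )
        for rank, r in enumerate(records, start=1)
    ]
    base_rows = [
        {
            "rank": e.rank,
            "combo": e.combo,
            **{base: e.combo.count(base) / 4 for base in "ACGT"},
        }
        for e in enrichments
    ]
    return enrichments, pd.DataFrame(base_rows), False


def noncanonical_by_intron_count(
    gene_summaries: dict[str, list[tuple[int, bool]]] | list[tuple[int, bool]],
    max_count: int | None = None,
) -> pd.DataFrame:
    """Probability of a gene carrying a non-canonical site, by intron count.

    ``gene_summaries`` maps a species label to (intron_count,
    has_noncanonical) pairs, one per gene (a bare list is treated as a single
    species). For each intron count the per-species proportion of genes with
    at least one non-canonical splice site is computed; across species the
    median and 25/75% quantiles are reported.
    """
    if isinstance(gene_summaries, list):
        gene_summaries = {"sample": gene_summaries}
    per_species: dict[str, dict[int, tuple[int, int]]] = {}
    for species, entries in gene_summaries.items():
        tally: dict[int, list[int]] = {}
        for count, has_nc in entries:
            if count < 1:
                raise ValueError("intron_count must be >= 1")
            prev = tally.setdefault(count, [0, 0])
            prev[0] += bool(has_nc)
            prev[1] += 1
        per_species[species] = {c: (h, t) for c, (h, t) in tally.items()}
    counts = sorted({c for sp in per_species.values() for c in sp})
    if max_count is not None:
        counts = [c for c in counts if c <= max_count]
    rows = []
    for count in counts:
        props = [
            h / t for sp in per_species.values() if count in sp for h, t in [sp[count]]
        ]
        rows.append(
            {
                "intron_count": count,
                "n_species": len(props),
                "median": float(np.median(props)),
                "q25": float(np.percentile(props, 25)),
                "q75": float(np.percentile(props, 75)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GeneSetComparison:
    statistic: float
    p_value: float
    mean_in_set: float
    mean_overall: float
    n: int


def compare_gene_sets(per_species: list[tuple[float, float]]) -> GeneSetComparison:
    """Two-sided Mann-Whitney U between gene-set and genome-wide proportions.

    ``per_species`` holds (proportion in the focal gene set, proportion over
    all genes) per species, e.g. the fraction of single-copy genes with a
    non-canonical splice site versus the genome-wide fraction.
    """
    if len(per_species) < 3:
        raise ValueError("need at least 3 species pairs")
    in_set = np.array([a for a, _ in per_species], dtype=float)
    overall = np.array([b for _, b in per_species], dtype=float)
    result = stats.mannwhitneyu(in_set, overall, alternative="two-sided")
    return GeneSetComparison(
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        mean_in_set=float(in_set.mean()),
        mean_overall=float(overall.mean()),
        n=len(per_species),
    )
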