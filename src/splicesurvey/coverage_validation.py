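"""RNA-Seq coverage validation of annotated splice sites.

A splice site counts as supported by RNA-Seq when the per-base read depth
drops by at least ``min_drop`` (default 20%) stepping from the terminal
exonic base into the adjacent intronic base. Splice-site *usage* is
1 − intron-edge depth / exon-edge depth, clipped to [0, 1] — an estimate of
how often the intron is spliced out — so "supported" coincides with
usage ≥ min_drop.

Coverage is consumed as BedGraph-style text (seq, start, end, depth;
0-based half-open), the shape produced by standard genome-arithmetic tools
from a BAM file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .splice_sites import Intron, SpliceClass

__all__ = [
    "CoverageTrack",
    "BoundaryDepths",
    "SupportCall",
    "UsageSummary",
    "ValidationRatios",
    "read_coverage",
    "boundary_depths",
    "evaluate_support",
    "summarize_usage",
    "validation_ratio",
    "write_support_calls",
]

# tolerance for ties on the drop rule, so that floating-point rounding of
# 1 - I/E cannot flip an exact-boundary call
_TIE_EPS = 1e-9


@dataclass
class CoverageTrack:
    """Per-base read depths, one vector per sequence."""

    depths: dict[str, np.ndarray]

    def __contains__(self, seq_name: str) -> bool:
        return seq_name in self.depths


def read_coverage(
    path: str | Path, lengths: dict[str, int] | None = None
) -> CoverageTrack:
    """Expand a BedGraph-style file into per-base depth vectors.

    Positions not covered by any row get depth 0. Overlapping rows with
    conflicting depths, and negative depths, are errors. ``lengths`` (e.g.
    from an assembly) fixes vector lengths; otherwise the maximum end
    coordinate per sequence is used.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            seq_name = fields[0]
            try:
                start, end, depth = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row") from exc
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            rows.setdefault(seq_name, []).append((start, end, depth))

    depths: dict[str, np.ndarray] = {}
    for seq_name, intervals in rows.items():
        size = (
            lengths[seq_name]
            if lengths is not None
            else max(end for _, end, _ in intervals)
        )
        vec = np.zeros(size, dtype=float)
        seen = np.zeros(size, dtype=bool)
        for start, end, depth in intervals:
            if lengths is not None and end > size:
                raise ValueError(
                    f"coverage interval {start}-{end} exceeds length of {seq_name!r}"
                )
            window = slice(start, end)
            conflict = seen[window] & (vec[window] != depth)
            if conflict.any():
                raise ValueError(
                    f"conflicting depths for {seq_name!r} around position "
                    f"{start + int(np.argmax(conflict))}"
                )
            vec[window] = depth
            seen[window] = True
        depths[seq_name] = vec
    if lengths is not None:
        for seq_name, size in lengths.items():
            depths.setdefault(seq_name, np.zeros(size, dtype=float))
    return CoverageTrack(depths=depths)


@dataclass
class BoundaryDepths:
    """Depths at the four bases flanking an intron, biological orientation.

    E5/I5 straddle the donor border (last exonic base, first intronic base);
    I3/E3 straddle the acceptor border.
    """

    E5: float
    I5: float
    I3: float
    E3: float


def boundary_depths(intron: Intron, track: CoverageTrack) -> BoundaryDepths:
    """The four border depths of an intron, mapped strand-awarely."""
    if intron.seq_name not in track:
        raise KeyError(f"no coverage for sequence {intron.seq_name!r}")
    vec = track.depths[intron.seq_name]
    a, b = intron.start, intron.end
    if a < 1:
        raise ValueError("intron at sequence start: no upstream exonic base")
    if b > len(vec) - 1:
        raise ValueError("intron at sequence end: no downstream exonic base")
    if intron.strand == "-":
        return BoundaryDepths(
            E5=float(vec[b]), I5=float(vec[b - 1]), I3=float(vec[a]), E3=float(vec[a - 1])
        )
    return BoundaryDepths(
        E5=float(vec[a - 1]), I5=float(vec[a]), I3=float(vec[b - 1]), E3=float(vec[b])
    )


@dataclass
class SupportCall:
    donor_supported: bool
    acceptor_supported: bool
    donor_usage: float | None
    acceptor_usage: float | None
    donor_reason: str | None = None
    acceptor_reason: str | None = None

    @property
    def combination_supported(self) -> bool:
        return self.donor_supported and self.acceptor_supported

    @property
    def expressed(self) -> bool:
        """Both flanking exon bases show non-zero coverage."""
        return self.donor_reason != "no_expression" and self.acceptor_reason != "no_expression"


def _side_call(exon: float, intron: float, min_drop: float):
    if exon <= 0:
        return False, None, "no_expression"
    raw_usage = 1.0 - intron / exon
    supported = raw_usage >= min_drop - _TIE_EPS
    return supported, min(max(raw_usage, 0.0), 1.0), None


def evaluate_support(depths: BoundaryDepths, min_drop: float = 0.2) -> SupportCall:
    """Apply the coverage-drop rule to one intron's border depths.

    A side is supported iff its exon depth is positive and the intron depth
    is at most (1 − min_drop) of it; usage is the relative drop clipped to
    [0, 1] and is undefined (None, reason ``no_expression``) at zero exon
    depth. The combination is supported iff both sides are.
    """
    if not 0 < min_drop < 1:
        raise ValueError("min_drop must be in (0, 1)")
    d_sup, d_use, d_reason = _side_call(depths.E5, depths.I5, min_drop)
    a_sup, a_use, a_reason = _side_call(depths.E3, depths.I3, min_drop)
    return SupportCall(
        donor_supported=d_sup,
        acceptor_supported=a_sup,
        donor_usage=d_use,
        acceptor_usage=a_use,
        donor_reason=d_reason,
        acceptor_reason=a_reason,
    )


@dataclass
class UsageSummary:
    splice_class: str
    n_donor: int
    n_acceptor: int
    n_pairs: int
    median_donor_usage: float | None
    median_acceptor_usage: float | None
    donor_acceptor_rho: float | None
    rho_undefined_constant: bool
    supported_fraction: float | None


def summarize_usage(
    calls: list[tuple[SpliceClass, SupportCall]]
) -> dict[str, UsageSummary]:
    """Per-class usage statistics: n, medians, and donor/acceptor correlation.

    For each splice-site class the defined donor and acceptor usages are
    summarized by their medians; the Spearman correlation pairs the usages of
    introns where both sides are defined. Constant inputs leave the
    correlation undefined and flagged. Classes with no defined usage are
    simply absent from the result.
    """
    by_class: dict[str, list[tuple[SpliceClass, SupportCall]]] = {}
    for cls, call in calls:
        by_class.setdefault(cls.value, []).append((cls, call))
    summaries: dict[str, UsageSummary] = {}
    for cls_name, entries in by_class.items():
        donor = [c.donor_usage for _, c in entries if c.donor_usage is not None]
        acceptor = [c.acceptor_usage for _, c in entries if c.acceptor_usage is not None]
        pairs = [
            (c.donor_usage, c.acceptor_usage)
            for _, c in entries
            if c.donor_usage is not None and c.acceptor_usage is not None
        ]
        if not donor and not acceptor:
            continue
        rho = None
        constant = False
        if len(pairs) >= 3:
            xs = np.array([p[0] for p in pairs])
            ys = np.array([p[1] for p in pairs])
            # near-constant inputs (within float rounding) have no defined rank
            # correlation
            if np.ptp(xs) < 1e-9 or np.ptp(ys) < 1e-9:
                constant = True
            else:
                rho = float(stats.spearmanr(xs, ys).statistic)
        supported = [c.combination_supported for _, c in entries if c.expressed]
        summaries[cls_name] = UsageSummary(
            splice_class=cls_name,
            n_donor=len(donor),
            n_acceptor=len(acceptor),
            n_pairs=len(pairs),
            median_donor_usage=float(np.median(donor)) if donor else None,
            median_acceptor_usage=float(np.median(acceptor)) if acceptor else None,
            donor_acceptor_rho=rho,
            rho_undefined_constant=constant,
            supported_fraction=(sum(supported) / len(supported)) if supported else None,
        )
    return summaries


@dataclass
class ValidationRatios:
    """Fractions of RNA-Seq-supported splice sites, overall and per class."""

    n_total: int
    n_expressed: int
    n_supported: int
    ratio_excluding_unexpressed: float | None
    ratio_including_unexpressed: float
    donor_ratio_excluding: float | None
    acceptor_ratio_excluding: float | None
    per_class: dict[str, dict[str, float | int | None]] = field(default_factory=dict)


def validation_ratio(
    calls: list[tuple[SpliceClass, SupportCall]]
) -> ValidationRatios:
    """Supported / total splice-site combinations, split by class.

    Reported both excluding introns without expression (zero exon coverage on
    either side) and including them as unsupported.
    """
    if not calls:
        raise ValueError("at least one call required")

    def ratios(entries):
        total = len(entries)
        expressed = [c for _, c in entries if c.expressed]
        supported = sum(c.combination_supported for c in expressed)
        d_sup = sum(c.donor_supported for _, c in entries if c.donor_reason is None)
        d_n = sum(1 for _, c in entries if c.donor_reason is None)
        a_sup = sum(c.acceptor_supported for _, c in entries if c.acceptor_reason is None)
        a_n = sum(1 for _, c in entries if c.acceptor_reason is None)
        return {
            "n_total": total,
            "n_expressed": len(expressed),
            "n_supported": supported,
            "ratio_excluding_unexpressed": supported / len(expressed) if expressed else None,
            "ratio_including_unexpressed": supported / total,
            "donor_ratio_excluding": d_sup / d_n if d_n else None,
            "acceptor_ratio_excluding": a_sup / a_n if a_n else None,
        }

    overall = ratios(calls)
    per_class = {}
    for cls in SpliceClass:
        entries = [(c, call) for c, call in calls if c is cls]
        if entries:
            per_class[cls.value] = ratios(entries)
    return ValidationRatios(
        n_total=overall["n_total"],
        n_expressed=overall["n_expressed"],
        n_supported=overall["n_supported"],
        ratio_excluding_unexpressed=overall["ratio_excluding_unexpressed"],
        ratio_including_unexpressed=overall["ratio_including_unexpressed"],
        donor_ratio_excluding=overall["donor_ratio_excluding"],
        acceptor_ratio_excluding=overall["acceptor_ratio_excluding"],
        per_class=per_class,
    )


def write_support_calls(
    records: list[tuple[Intron, BoundaryDepths, SupportCall]], path: str | Path
) -> None:
    """Per-intron TSV of border depths, usages and support flags."""

    def fmt(x):
        return "NA" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))

    with open(path, "w") as out:
        out.write(
            "seq_name\tstart\tend\tstrand\tcombo\tclass\tE5\tI5\tI3\tE3\t"
            "donor_usage\tacceptor_usage\tdonor_supported\tacceptor_supported\t"
            "combination_supported\tdonor_reason\tacceptor_reason\n"
        )
        for intron, d, call in records:
            out.write(
                "\t".join(
                    [
                        intron.seq_name,
                        str(intron.start),
                        str(intron.end),
                        intron.strand,
                        intron.combo,
                        intron.splice_class.value,
                        fmt(d.E5),
                        fmt(d.I5),
                        fmt(d.I3),
                        fmt(d.E3),
                        fmt(call.donor_usage),
                        fmt(call.acceptor_usage),
                        str(call.donor_supported),
                        str(call.acceptor_supported),
                        str(call.combination_supported),
                        fmt(call.donor_reason),
                        fmt(call.acceptor_reason),
                    ]
                )
                + "\n"
            )
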