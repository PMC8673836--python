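"""ChIP-seq/RNA-seq regulon integration chain.

Implements the filter chain used to go from factor binding and knockdown
expression data to a short candidate-gene list: replicate peak consensus,
promoter windows around transcription start sites, promoter-bound gene calls,
histone-mark co-occupancy fractions, differential-expression set overlaps
with hypergeometric enrichment, and the final bound-and-coregulated
candidate filter.

Genomic coordinates follow the BED convention throughout: 0-based,
half-open.  The overlap predicate everywhere is >= 1 bp, so abutting
half-open intervals do not overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedFractionError, ValidationError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class PromoterWindowSpec:
    flank: int = 5000
    chrom_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValidationError("flank must be >= 0")


@dataclass
class GeneSet:
    label: str
    genes: frozenset[str]

    def __init__(self, label: str, genes: Iterable[str]):
        self.label = label
        genes = list(genes)
        unique = frozenset(genes)
        if len(unique) != len(genes):
            raise ValidationError(f"gene set {label!r}: identifiers must be unique")
        self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)


class VennCounts(NamedTuple):
    size_a: int
    size_b: int
    overlap: int


class Percentage(NamedTuple):
    percent: float  # full precision
    rounded: int  # half-away-from-zero integer


@dataclass
class EnrichmentResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Interval engine (sorted-sweep; semantics match a base-resolution bitmap)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: BED line needs >= 3 fields")
        try:
            iv = GenomicInterval(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                name=fields[3] if len(fields) > 3 else "",
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        intervals.append(iv)
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    lines = [
        "\t".join([iv.chrom, str(iv.start), str(iv.end)] + ([iv.name] if iv.name else []))
        for iv in sorted(intervals)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for chrom in out:
        out[chrom].sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals per chromosome; sorted output."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_start = cur_end = None
        for iv in _by_chrom_single(intervals, chrom):
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _by_chrom_single(intervals: Iterable[GenomicInterval], chrom: str) -> list[GenomicInterval]:
    return sorted(
        (iv for iv in intervals if iv.chrom == chrom), key=lambda iv: (iv.start, iv.end)
    )


def replicate_consensus(
    peaks_rep1: Sequence[GenomicInterval], peaks_rep2: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two replicate peak sets, merged and sorted.

    Equivalent to intersecting the genome coverage of the two replicates:
    a base belongs to the consensus iff it is covered by both.
    """
    a = merge_intervals(peaks_rep1)
    b = merge_intervals(peaks_rep2)
    out: list[GenomicInterval] = []
    a_by, b_by = _by_chrom(a), _by_chrom(b)
    for chrom in sorted(set(a_by) & set(b_by)):
        i = j = 0
        xs, ys = a_by[chrom], b_by[chrom]
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def promoter_windows(
    tss_table: pd.DataFrame, spec: PromoterWindowSpec = PromoterWindowSpec()
) -> dict[str, GenomicInterval]:
    """Symmetric promoter window per gene: [tss - flank, tss + flank + 1).

    The half-open end of ``tss + flank + 1`` makes both boundary bases
    inclusive.  Windows are clipped at zero and, when chromosome sizes are
    given, at the chromosome end.  Strand is ignored (the window is
    symmetric); the table needs columns gene, chrom, tss.
    """
    required = {"gene", "chrom", "tss"}
    if not required.issubset(tss_table.columns):
        raise ValidationError(f"TSS table must have columns {sorted(required)}")
    windows: dict[str, GenomicInterval] = {}
    for row in tss_table.itertuples():
        tss = int(row.tss)
        if tss < 0:
            raise ValidationError(f"gene {row.gene}: negative TSS position {tss}")
        start = max(0, tss - spec.flank)
        end = tss + spec.flank + 1
        if spec.chrom_sizes is not None and row.chrom in spec.chrom_sizes:
            end = min(end, int(spec.chrom_sizes[row.chrom]))
        if str(row.gene) in windows:
            raise ValidationError(f"duplicate gene {row.gene} in TSS table")
        windows[str(row.gene)] = GenomicInterval(str(row.chrom), start, end, name=str(row.gene))
    return windows


def _overlap_flags(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> list[bool]:
    """For each query, whether any target overlaps it by >= 1 bp."""
    t_by = _by_chrom(targets)
    starts: dict[str, np.ndarray] = {}
    runmax_end: dict[str, np.ndarray] = {}
    for chrom, ivs in t_by.items():
        starts[chrom] = np.array([iv.start for iv in ivs])
        runmax_end[chrom] = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
    flags = []
    for q in queries:
        if q.chrom not in starts:
            flags.append(False)
            continue
        # targets with start < q.end whose running-max end exceeds q.start
        idx = int(np.searchsorted(starts[q.chrom], q.end, side="left"))
        flags.append(idx > 0 and bool(runmax_end[q.chrom][idx - 1] > q.start))
    return flags


def peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    windows: Mapping[str, GenomicInterval],
    label: str = "bound",
) -> GeneSet:
    """Genes whose promoter window overlaps >= 1 bp of any peak."""
    genes = list(windows)
    flags = _overlap_flags([windows[g] for g in genes], peaks)
    return GeneSet(label, [g for g, f in zip(genes, flags) if f])


def cooccupancy_fraction(
    peaks: Sequence[GenomicInterval], mark_peaks: Sequence[GenomicInterval]
) -> float:
    """Fraction of peaks overlapping (>= 1 bp) any interval of a mark."""
    if not peaks:
        raise UndefinedFractionError("co-occupancy over an empty peak list is undefined")
    flags = _overlap_flags(list(peaks), list(mark_peaks))
    return sum(flags) / len(flags)


# ---------------------------------------------------------------------------
# Gene-set arithmetic and enrichment


def intersect_deg_sets(a: GeneSet, b: GeneSet) -> VennCounts:
    return VennCounts(size_a=len(a), size_b=len(b), overlap=len(a.genes & b.genes))


def overlap_percentage(venn: VennCounts, side: str = "A") -> Percentage:
    """Overlap as percent of one side, full precision plus rounded integer."""
    size = {"A": venn.size_a, "B": venn.size_b}.get(side.upper())
    if size is None:
        raise ValidationError("side must be 'A' or 'B'")
    if size == 0:
        raise UndefinedFractionError(f"side {side} is empty; percentage undefined")
    percent = 100.0 * venn.overlap / size
    return Percentage(percent=percent, rounded=int(np.floor(percent + 0.5)))


def hypergeom_enrichment(k: int, n_a: int, n_b: int, universe: int) -> EnrichmentResult:
    """Upper-tail hypergeometric p-value for an overlap of k genes.

    With X ~ Hypergeometric(N=universe, K=n_a, n=n_b), returns P(X >= k).
    Benjamini-Hochberg adjustment across a declared family is applied
    separately via :func:`adjust_family`.
    """
    if not (0 <= k <= min(n_a, n_b) and max(n_a, n_b) <= universe):
        raise ValidationError(
            f"infeasible counts: k={k}, n_a={n_a}, n_b={n_b}, universe={universe}"
        )
    p = float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))
    return EnrichmentResult(overlap=k, size_a=n_a, size_b=n_b, universe=universe, p_value=p)


def adjust_family(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg adjustment across a family of enrichment tests."""
    if not results:
        return []
    ps = np.array([r.p_value for r in results])
    adj = stats.false_discovery_control(ps, method="bh")
    for r, q in zip(results, adj):
        r.p_adjusted = float(max(q, r.p_value))
    return list(results)


def filter_candidates(
    bound: GeneSet, down_on_knockdown: GeneSet, down_in_dko: GeneSet
) -> tuple[GeneSet, GeneSet]:
    """Final candidate filter: bound AND down on factor knockdown AND down in
    the comparison (double-knockout) regulon.

    Returns (candidates, bound_and_down) where the second set is the
    intermediate promoter-bound, positively-regulated stage.
    """
    bound_and_down = GeneSet("bound_and_down", bound.genes & down_on_knockdown.genes)
    candidates = GeneSet("candidates", bound_and_down.genes & down_in_dko.genes)
    return candidates, bound_and_down


# ---------------------------------------------------------------------------
# Report assembly


@dataclass
class IntegrationReport:
    consensus_peak_count: int
    cooccupancy: dict[str, float]
    bound_genes: list[str]
    bound_and_down: list[str]
    candidates: list[str]
    venn_all: VennCounts | None = None
    venn_down: VennCounts | None = None
    enrichment: EnrichmentResult | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.candidates) <= set(self.bound_genes):
            raise ValidationError("candidates must be a subset of bound genes")

    def to_dict(self) -> dict:
        def venn_dict(v: VennCounts | None):
            if v is None:
                return None
            pa = overlap_percentage(v, "A")
            pb = overlap_percentage(v, "B")
            return {
                "size_a": v.size_a,
                "size_b": v.size_b,
                "overlap": v.overlap,
                "percent_of_a": pa.percent,
                "percent_of_a_rounded": pa.rounded,
                "percent_of_b": pb.percent,
                "percent_of_b_rounded": pb.rounded,
            }

        enr = None
        if self.enrichment is not None:
            enr = {
                "overlap": self.enrichment.overlap,
                "size_a": self.enrichment.size_a,
                "size_b": self.enrichment.size_b,
                "universe": self.enrichment.universe,
                "p_value": self.enrichment.p_value,
                "p_adjusted": self.enrichment.p_adjusted,
            }
        return {
            "consensus_peak_count": self.consensus_peak_count,
            "cooccupancy": self.cooccupancy,
            "n_bound_genes": len(self.bound_genes),
            "n_bound_and_down": len(self.bound_and_down),
            "n_candidates": len(self.candidates),
            "candidates": sorted(self.candidates),
            "venn_all_degs": venn_dict(self.venn_all),
            "venn_down_degs": venn_dict(self.venn_down),
            "enrichment": enr,
            "params": self.params,
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def integrate(
    peaks_rep1: Sequence[GenomicInterval],
    peaks_rep2: Sequence[GenomicInterval],
    tss_table: pd.DataFrame,
    marks: Mapping[str, Sequence[GenomicInterval]],
    deg_all_kd: GeneSet,
    deg_all_ref: GeneSet,
    down_kd: GeneSet,
    down_ref: GeneSet,
    universe: int,
    window_spec: PromoterWindowSpec = PromoterWindowSpec(),
) -> IntegrationReport:
    """Run the full integration chain and assemble a report.

    Stages: replicate consensus -> mark co-occupancy -> promoter windows ->
    promoter-bound genes -> DEG Venns with hypergeometric enrichment of the
    down/down overlap -> bound-and-coregulated candidate filter.
    """
    consensus = replicate_consensus(peaks_rep1, peaks_rep2)
    co = {name: cooccupancy_fraction(consensus, mk) for name, mk in marks.items()}
    windows = promoter_windows(tss_table, window_spec)
    bound = peaks_to_genes(consensus, windows)
    venn_all = intersect_deg_sets(deg_all_kd, deg_all_ref)
    venn_down = intersect_deg_sets(down_kd, down_ref)
    enrichment = hypergeom_enrichment(venn_down.overlap, len(down_kd), len(down_ref), universe)
    adjust_family([enrichment])
    candidates, bound_and_down = filter_candidates(bound, down_kd, down_ref)
    return IntegrationReport(
        consensus_peak_count=len(consensus),
        cooccupancy=co,
        bound_genes=sorted(bound.genes),
        bound_and_down=sorted(bound_and_down.genes),
        candidates=sorted(candidates.genes),
        venn_all=venn_all,
        venn_down=venn_down,
        enrichment=enrichment,
        params={"flank": window_spec.flank, "universe": universe},
    )
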