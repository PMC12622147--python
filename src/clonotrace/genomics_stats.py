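"""Region/gene annotation and the exact statistics behind the headline
tallies: TSS proximal/distal classification at 1 kb, nearest-gene
association of regions to co-regulated gene lists, a two-sided Fisher exact
test built from the hypergeometric mass, and exact-rational percentage
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

__all__ = [
    "GeneModel",
    "RegionCall",
    "ContingencyTable2x2",
    "tss_distance",
    "classify_locality",
    "gene_region_table",
    "fisher_exact_two_sided",
    "fraction_report",
]

PROXIMAL_THRESHOLD_BP = 1000

# Relative slack on the "probability <= observed" comparison; guards against
# float round-off when two tables have mathematically equal mass.
_MASS_RTOL = 1e-7


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    tss_position: int  # 0-based; transcript 5' end respecting strand
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss_position < 0:
            raise ValueError("tss_position must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class RegionCall:
    chromosome: str
    start: int
    end: int  # half-open
    direction: str  # induced | suppressed
    locality: str  # proximal | distal | indeterminate
    nearest_gene_id: str | None
    distance_bp: int | None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def tss_distance(start: int, end: int, tss: int) -> int:
    """Gap in bp between a half-open region and a TSS point (0 when the TSS
    lies inside the region; adjacency downstream of the region counts 1)."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - end + 1


def classify_locality(
    regions: Iterable[tuple[str, int, int, str]],
    genes: Sequence[GeneModel],
    threshold_bp: int = PROXIMAL_THRESHOLD_BP,
) -> list[RegionCall]:
    """Annotate regions (chrom, start, end, direction) with the nearest TSS.

    distal iff the distance to the nearest same-chromosome TSS is
    >= threshold_bp; equidistant genes break ties lexicographically.
    Regions on chromosomes without genes are flagged indeterminate.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        by_chrom.setdefault(g.chromosome, []).append(g)
    calls = []
    for chrom, start, end, direction in regions:
        candidates = by_chrom.get(chrom, [])
        if not candidates:
            calls.append(
                RegionCall(chrom, start, end, direction, "indeterminate", None, None)
            )
            continue
        best = min(
            candidates, key=lambda g: (tss_distance(start, end, g.tss_position), g.gene_id)
        )
        d = tss_distance(start, end, best.tss_position)
        locality = "proximal" if d < threshold_bp else "distal"
        calls.append(
            RegionCall(chrom, start, end, direction, locality, best.gene_id, d)
        )
    return calls


def gene_region_table(
    gene_set: Sequence[str],
    region_calls: Sequence[RegionCall],
    direction: str,
    background: Sequence[str] | None = None,
) -> tuple[ContingencyTable2x2, float]:
    """Count genes from ``gene_set`` associated with proximal regions of the
    matching direction (a gene is associated iff it is the nearest gene of at
    least one such region).

    Returns the 2x2 table [[associated, not], [background associated, not]]
    and the associated percentage of ``gene_set`` with one decimal.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    associated = {
        r.nearest_gene_id
        for r in region_calls
        if r.locality == "proximal"
        and r.direction == direction
        and r.nearest_gene_id is not None
    }
    a = sum(1 for g in gene_set if g in associated)
    b = len(gene_set) - a
    if background:
        rest = [g for g in background if g not in set(gene_set)]
        c = sum(1 for g in rest if g in associated)
        d = len(rest) - c
    else:
        c = d = 0
    return ContingencyTable2x2(a, b, c, d), fraction_report(a, len(gene_set))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by probability-mass ordering.

    Sums the hypergeometric probability of every same-margin table whose
    mass is <= the observed table's (within relative tolerance 1e-7),
    computed directly from binomial coefficients.
    """
    if table.total == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    row1 = a + b
    col1 = a + c
    n = table.total
    denom = comb(n, col1)

    def mass(k: int) -> float:
        return comb(row1, k) * comb(n - row1, col1 - k) / denom

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    observed = mass(a)
    p = sum(
        m for k in range(lo, hi + 1)
        if (m := mass(k)) <= observed * (1.0 + _MASS_RTOL)
    )
    return min(p, 1.0)


def fraction_report(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, in exact rational
    arithmetic before rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    tenths = Fraction(numerator, denominator) * 1000  # percent x 10
    whole = tenths.numerator // tenths.denominator
    remainder = tenths - whole
    if remainder >= Fraction(1, 2):
        whole += 1
    return whole / 10.0
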