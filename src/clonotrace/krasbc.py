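"""KrasBC-Seq caller: from targeted paired reads to per-cell clonotypes.

Stages: error-tolerant anchor trimming of R2, substitution-distance
assignment against the wildtype + barcoded-allele reference, UMI collapsing
keyed on (cellBC, allele, UMI), within-cell merging of near-identical
barcodes (edit distance < 3), dominant-clonotype calling with
malignant/somatic/excluded classification, and allelic-imbalance scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequence import best_window_distance, encode, hamming, levenshtein
from .barcode_design import BarcodeAllele

__all__ = [
    "TaggedRead",
    "CellAlleleCounts",
    "ClonotypeCall",
    "trim_krasbc",
    "assign_allele",
    "AlleleAssigner",
    "collapse_umis",
    "merge_barcodes",
    "call_clonotype",
    "classify_imbalance",
    "depth_scale_from",
    "run_krasbc_pipeline",
    "read_fastq_pairs",
    "write_clonotype_table",
    "clone_size_summary",
]

DEFAULT_ANCHOR_5P = "CTCTATCGTAGGGTCATA"
DEFAULT_ANCHOR_3P = "CATTTTCAGCAGGCCT"
DEFAULT_MAX_ERROR_RATE = 0.2

MERGE_MAX_DISTANCE = 3  # merge below this (strict <)

WT_LABEL = "WT"
UNASSIGNED = None


@dataclass(frozen=True)
class TaggedRead:
    cell_barcode: str
    umi: str
    payload: str


@dataclass
class CellAlleleCounts:
    cell_barcode: str
    wt_umis: int = 0
    barcode_umis: dict[str, int] = field(default_factory=dict)
    transcriptome_umis: int = 0
    depth_scale: float = 1.0


@dataclass(frozen=True)
class ClonotypeCall:
    cell_barcode: str
    dominant_barcode: str | None
    cell_class: str  # malignant | somatic | excluded
    imbalance_state: str  # balanced | g12d_high | wt_high | indeterminate
    wt_umis: int = 0
    g12d_umis: int = 0
    kras_abundance: float = float("nan")


def _find_anchor(read: str, anchor: str, max_errors: int) -> tuple[int, int] | None:
    """Best full-length substitution match of ``anchor`` in ``read``.

    Returns (start, mismatches) of the leftmost best window with
    mismatches <= max_errors, else None.
    """
    la = len(anchor)
    if len(read) < la:
        return None
    a = encode(anchor)
    r = encode(read)
    windows = np.lib.stride_tricks.sliding_window_view(r, la)
    dists = (windows != a).sum(axis=1)
    start = int(dists.argmin())
    if dists[start] > max_errors:
        return None
    return start, int(dists[start])


def trim_krasbc(
    read2: str,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    anchor_5p: str = DEFAULT_ANCHOR_5P,
    anchor_3p: str = DEFAULT_ANCHOR_3P,
) -> str | None:
    """Remove the required 5' anchor (and anything before it) and, when
    present, the optional 3' anchor (and anything after it).

    Anchors match with at most floor(rate * anchor_length) substitutions.
    Reads lacking a 5'-anchor match are dropped (None).
    """
    if not read2:
        return None
    hit5 = _find_anchor(read2, anchor_5p.upper(), int(max_error_rate * len(anchor_5p)))
    if hit5 is None:
        return None
    payload = read2[hit5[0] + len(anchor_5p):]
    hit3 = _find_anchor(payload, anchor_3p.upper(), int(max_error_rate * len(anchor_3p)))
    if hit3 is not None:
        payload = payload[: hit3[0]]
    return payload or None


class AlleleAssigner:
    """Vectorized nearest-reference assignment.

    Equal-length payloads are compared column-wise against the whole
    reference matrix at once; other lengths fall back to best-window
    substitution distance per reference.
    """

    def __init__(
        self,
        wildtype: str,
        alleles: Sequence[BarcodeAllele],
        max_mismatch_rate: float = 0.1,
    ):
        self.labels = [WT_LABEL] + [a.barcode_id for a in alleles]
        self.seqs = [wildtype] + [a.coding_sequence for a in alleles]
        self.max_mismatch_rate = max_mismatch_rate
        self._matrix: np.ndarray | None = None
        if len({len(s) for s in self.seqs}) == 1:
            self._matrix = np.vstack([encode(s) for s in self.seqs])
        self._exact = {s: lab for s, lab in zip(self.seqs, self.labels)}

    def __call__(self, payload: str) -> str | None:
        return self.assign(payload)

    def assign(self, payload: str) -> str | None:
        if not payload:
            return UNASSIGNED
        exact = self._exact.get(payload)
        if exact is not None:
            return exact
        if self._matrix is not None and len(payload) == self._matrix.shape[1]:
            dists = (self._matrix != encode(payload)).sum(axis=1)
        else:
            dists = np.array(
                [best_window_distance(payload, s)[0] for s in self.seqs]
            )
        order = np.argsort(dists, kind="stable")
        best = int(dists[order[0]])
        if best > int(np.ceil(self.max_mismatch_rate * len(payload))):
            return UNASSIGNED
        if len(dists) > 1 and int(dists[order[1]]) - best < 1:
            return UNASSIGNED  # ambiguous between two references
        return self.labels[order[0]]

    def assign_many(self, payloads: Iterable[str]) -> dict[str, str | None]:
        """Batched assignment of unique payloads (vectorized for payloads
        matching the reference length)."""
        unique = set(payloads)
        out: dict[str, str | None] = {}
        batch: list[str] = []
        for p in unique:
            if p in self._exact:
                out[p] = self._exact[p]
            elif self._matrix is not None and len(p) == self._matrix.shape[1]:
                batch.append(p)
            else:
                out[p] = self.assign(p)
        if batch:
            q = np.vstack([encode(p) for p in batch])
            # distances: (payloads x refs)
            dists = (q[:, None, :] != self._matrix[None, :, :]).sum(axis=2)
            limit = int(np.ceil(self.max_mismatch_rate * self._matrix.shape[1]))
            part = np.argsort(dists, axis=1, kind="stable")
            n_refs = self._matrix.shape[0]
            for i, p in enumerate(batch):
                best_j = int(part[i, 0])
                best = int(dists[i, best_j])
                ambiguous = (
                    n_refs > 1 and int(dists[i, int(part[i, 1])]) - best < 1
                )
                out[p] = (
                    UNASSIGNED if best > limit or ambiguous else self.labels[best_j]
                )
        return out


def assign_allele(
    payload: str,
    wildtype: str,
    alleles: Sequence[BarcodeAllele],
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """One-shot form of :class:`AlleleAssigner`."""
    return AlleleAssigner(wildtype, alleles, max_mismatch_rate).assign(payload)


def collapse_umis(
    assignments: Iterable[tuple[TaggedRead, str | None]]
) -> dict[str, CellAlleleCounts]:
    """Collapse reads into unique (cellBC, allele, UMI) transcripts.

    Duplicate triples count once; unassigned reads are ignored. The same UMI
    observed under two alleles in one cell counts once under each (the
    collapse key includes the allele).
    """
    triples: set[tuple[str, str, str]] = set()
    for read, label in assignments:
        if label is None:
            continue
        triples.add((read.cell_barcode, label, read.umi))
    cells: dict[str, CellAlleleCounts] = {}
    for cellbc, label, _umi in sorted(triples):
        cell = cells.setdefault(cellbc, CellAlleleCounts(cellbc))
        if label == WT_LABEL:
            cell.wt_umis += 1
        else:
            cell.barcode_umis[label] = cell.barcode_umis.get(label, 0) + 1
    return cells


def merge_barcodes(
    barcode_umis: Mapping[str, int],
    max_distance: int = MERGE_MAX_DISTANCE,
    metric: str = "levenshtein",
) -> dict[str, int]:
    """Within one cell, pool UMIs of near-identical barcodes.

    Barcodes within edit distance < ``max_distance`` of one another (taken
    transitively) form a cluster; the cluster's UMIs are assigned to its
    highest-count member, processed from highest count downward with a
    lexicographic tie-break for determinism.
    """
    if len(barcode_umis) <= 1:
        return dict(barcode_umis)
    if metric == "levenshtein":
        def dist(a: str, b: str) -> int:
            return levenshtein(a, b, max_distance - 1)
    elif metric == "hamming":
        def dist(a: str, b: str) -> int:
            return hamming(a, b) if len(a) == len(b) else max_distance
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # Union-by-distance: connected components of the < max_distance graph,
    # each component's UMIs pooled onto its highest-count member.
    order = sorted(barcode_umis, key=lambda b: (-barcode_umis[b], b))
    rank = {bc: i for i, bc in enumerate(order)}
    parent = {bc: bc for bc in order}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if find(a) != find(b) and dist(a, b) < max_distance:
                # attach to the earlier (higher-count) member's root
                ra, rb = find(a), find(b)
                keep, drop = sorted((ra, rb), key=rank.__getitem__)
                parent[drop] = keep
    merged: dict[str, int] = {}
    for bc in order:
        r = find(bc)
        merged[r] = merged.get(r, 0) + barcode_umis[bc]
    return merged


def call_clonotype(counts: CellAlleleCounts) -> ClonotypeCall:
    """Dominant-barcode clonotype call with cell classification.

    Somatic: >= 2 wildtype UMIs and no barcode UMIs. Excluded: no barcode
    UMIs and <= 1 wildtype UMI, tied dominant barcodes, or zero
    transcriptome UMIs. Otherwise malignant with the argmax barcode.
    """
    merged = merge_barcodes(counts.barcode_umis)
    total_bc = sum(merged.values())
    wt = counts.wt_umis
    abundance = float("nan")
    if counts.transcriptome_umis > 0:
        abundance = (wt + total_bc) / counts.transcriptome_umis * counts.depth_scale

    if total_bc == 0:
        cls = "somatic" if wt >= 2 else "excluded"
        return ClonotypeCall(
            counts.cell_barcode, None, cls, "indeterminate", wt, 0, abundance
        )
    top = max(merged.values())
    leaders = sorted(b for b, c in merged.items() if c == top)
    if len(leaders) > 1:
        return ClonotypeCall(
            counts.cell_barcode, None, "excluded", "indeterminate", wt, 0, abundance
        )
    if counts.transcriptome_umis == 0:
        return ClonotypeCall(
            counts.cell_barcode, None, "excluded", "indeterminate", wt,
            merged[leaders[0]], abundance,
        )
    return ClonotypeCall(
        counts.cell_barcode, leaders[0], "malignant", "indeterminate", wt,
        merged[leaders[0]], abundance,
    )


def classify_imbalance(
    call: ClonotypeCall,
    min_total: int = 4,
    high_fraction: float = 0.75,
) -> ClonotypeCall:
    """Set the allelic-balance state of a malignant call from dominant-
    barcode vs wildtype UMI fractions."""
    if call.cell_class != "malignant":
        raise ValueError("imbalance is defined for malignant cells only")
    total = call.g12d_umis + call.wt_umis
    if total < min_total:
        state = "indeterminate"
    elif call.g12d_umis / total >= high_fraction:
        state = "g12d_high"
    elif call.wt_umis / total >= high_fraction:
        state = "wt_high"
    else:
        state = "balanced"
    return dataclasses.replace(call, imbalance_state=state)


def depth_scale_from(transcriptome_umis: Mapping[str, int]) -> float:
    """Per-sample depth factor: the median transcriptome UMI count."""
    if not transcriptome_umis:
        return 1.0
    return float(np.median(list(transcriptome_umis.values())))


def read_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    cellbc_length: int = 16,
    umi_length: int = 10,
) -> Iterator[tuple[str, str, str]]:
    """Yield (cellBC, UMI, read2) from paired FASTQ files."""
    with open(r1_path) as f1, open(r2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline(); f1.readline()
            f2.readline()
            s2 = f2.readline().strip()
            f2.readline(); f2.readline()
            if len(s1) < cellbc_length + umi_length:
                continue
            yield s1[:cellbc_length], s1[cellbc_length:cellbc_length + umi_length], s2


def run_krasbc_pipeline(
    r1_path: str | Path,
    r2_path: str | Path,
    wildtype: str,
    alleles: Sequence[BarcodeAllele],
    transcriptome_umis: Mapping[str, int] | None = None,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    max_mismatch_rate: float = 0.1,
    min_total: int = 4,
    high_fraction: float = 0.75,
) -> list[ClonotypeCall]:
    """End-to-end KrasBC-Seq: FASTQ pairs to per-cell clonotype calls."""
    assigner = AlleleAssigner(wildtype, alleles, max_mismatch_rate)
    tagged = []
    for cellbc, umi, read2 in read_fastq_pairs(r1_path, r2_path):
        payload = trim_krasbc(read2, max_error_rate)
        if payload is not None:
            tagged.append(TaggedRead(cellbc, umi, payload))
    label_of = assigner.assign_many(t.payload for t in tagged)
    cells = collapse_umis((t, label_of[t.payload]) for t in tagged)
    scale = depth_scale_from(transcriptome_umis or {})
    calls = []
    for cellbc in sorted(cells):
        cell = cells[cellbc]
        if transcriptome_umis is not None:
            cell.transcriptome_umis = int(transcriptome_umis.get(cellbc, 0))
        cell.depth_scale = scale
        call = call_clonotype(cell)
        if call.cell_class == "malignant":
            call = classify_imbalance(call, min_total, high_fraction)
        calls.append(call)
    return calls


def write_clonotype_table(calls: Sequence[ClonotypeCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_barcode": c.cell_barcode,
                "dominant_barcode": c.dominant_barcode or "",
                "cell_class": c.cell_class,
                "imbalance_state": c.imbalance_state,
                "wt_umis": c.wt_umis,
                "g12d_umis": c.g12d_umis,
                "kras_abundance": c.kras_abundance,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def clone_size_summary(calls: Sequence[ClonotypeCall]) -> pd.DataFrame:
    """Cells per clonotype among malignant cells, largest first."""
    sizes: dict[str, int] = {}
    for c in calls:
        if c.cell_class == "malignant" and c.dominant_barcode:
            sizes[c.dominant_barcode] = sizes.get(c.dominant_barcode, 0) + 1
    rows = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["dominant_barcode", "n_cells"])
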