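"""Ground-truthed synthetic experiments for the targeted-sequencing callers
and the copy-number stage.

Simulates a barcoded tumor (power-law clone sizes, one barcode per malignant
cell, allelic imbalance, bimodal Kdm8 detection, foreign spike-in cells),
emits the corresponding KrasBC-Seq / Kdm8-Seq paired FASTQ with PCR
duplicates and substitution errors, and draws per-bin scWGS read counts with
GC bias over integer copy-number states. Every generator is deterministic
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._sequence import DNA_ALPHABET
from .barcode_design import BarcodeAllele

__all__ = [
    "TumorModel",
    "CellGroundTruth",
    "ReadSimConfig",
    "ScwgsSimConfig",
    "simulate_tumor",
    "emit_krasbc_fastq",
    "emit_kdm8_fastq",
    "simulate_scwgs_counts",
    "random_genome",
    "write_truth_table",
    "read_truth_table",
]

CELLBC_LENGTH = 16
UMI_LENGTH = 10

# Targeted-amplicon anchors flanking the barcode region (5' chemistry).
DEFAULT_ADAPTER_5P = "CTCTATCGTAGGGTCATA"
DEFAULT_ADAPTER_3P = "CATTTTCAGCAGGCCT"

KDM8_PREFIX_LENGTH = 26
# TSO-like constant 26-nt prefix preceding the transcript fragment on R2.
KDM8_CONSTANT_PREFIX = "AAGCAGTGGTATCAACGCAGAGTACA"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TumorModel:
    n_cells: int = 1000
    n_clones: int = 20
    clone_size_alpha: float = 1.5
    p_imbalanced: float = 0.2
    p_somatic: float = 0.1
    p_kdm8_positive: float = 0.114
    p_spikein: float = 0.0
    kras_umi_mean: float = 15.0
    kras_umi_dispersion: float = 2.0
    kdm8_umi_mean: float = 4.0
    transcriptome_umi_mean: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_imbalanced", "p_somatic", "p_kdm8_positive", "p_spikein"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.p_somatic + self.p_spikein > 1.0:
            raise SimulationError("p_somatic + p_spikein must not exceed 1")
        if self.n_clones > self.n_cells:
            raise SimulationError("n_clones > n_cells")


@dataclass(frozen=True)
class CellGroundTruth:
    cell_barcode: str
    clone_barcode_id: str | None
    kras_g12d_umis: int
    kras_wt_umis: int
    kdm8_umis: int
    transcriptome_umis: int
    cell_class: str  # malignant | somatic | spikein
    imbalance_state: str  # balanced | g12d_high | wt_high


@dataclass(frozen=True)
class ReadSimConfig:
    substitution_error_rate: float = 0.0
    reads_per_umi: float = 1.0  # mean extra PCR duplicates; emitted Poisson+1
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    umi_length: int = UMI_LENGTH
    cellbc_length: int = CELLBC_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_error_rate <= 0.2:
            raise SimulationError("substitution_error_rate outside [0, 0.2]")
        if not self.adapter_5p or not self.adapter_3p:
            raise SimulationError("adapter strings must be non-empty")


@dataclass(frozen=True)
class ScwgsSimConfig:
    cn_states: dict[str, int] = field(default_factory=dict)  # chrom -> CN
    gc_bias_slope: float = 0.0
    reads_total: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(cn < 0 for cn in self.cn_states.values()):
            raise SimulationError("copy numbers must be >= 0")


def _random_distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random DNA strings of a given length."""
    out: set[str] = set()
    bases = np.array(list(DNA_ALPHABET))
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            out.add("".join(bases[row]))
            if len(out) == n:
                break
    return sorted(out)


def simulate_tumor(
    model: TumorModel, alleles: Sequence[BarcodeAllele]
) -> list[CellGroundTruth]:
    """Draw per-cell ground truth for one tumor.

    Clone sizes follow a truncated discrete power law (weight k^-alpha for
    clone rank k). Per-cell Kras UMI totals are negative binomial; g12d_high
    cells draw their G12D transcript fraction uniformly from [0.75, 1] while
    balanced cells draw a beta-binomial split centered on 0.5.
    """
    if model.n_clones > len(alleles):
        raise SimulationError(
            f"n_clones={model.n_clones} exceeds {len(alleles)} available alleles"
        )
    rng = np.random.default_rng(model.seed)
    n = model.n_cells

    cellbcs = _random_distinct_seqs(rng, n, CELLBC_LENGTH)
    rng.shuffle(cellbcs)  # decorrelate lexicographic order from cell index

    # cell classes
    u = rng.random(n)
    is_spike = u < model.p_spikein
    is_somatic = (~is_spike) & (u < model.p_spikein + model.p_somatic)
    is_malig = ~(is_spike | is_somatic)

    # clone assignment: Zipf weights over clone ranks
    ranks = np.arange(1, model.n_clones + 1, dtype=float)
    weights = ranks ** (-model.clone_size_alpha)
    weights /= weights.sum()
    clone_of = rng.choice(model.n_clones, size=n, p=weights)

    # negative binomial via gamma-Poisson mixture
    def nb(mean: float, dispersion: float, size: int) -> np.ndarray:
        lam = rng.gamma(dispersion, mean / dispersion, size=size)
        return rng.poisson(lam)

    kras_total = nb(model.kras_umi_mean, model.kras_umi_dispersion, n)
    txn_umis = np.maximum(
        nb(model.transcriptome_umi_mean, 5.0, n), 1
    )

    imb = rng.random(n) < model.p_imbalanced
    g12d_frac = np.where(
        imb,
        rng.uniform(0.75, 1.0, size=n),
        rng.beta(20.0, 20.0, size=n),  # tight around 0.5
    )
    kdm8_pos = rng.random(n) < model.p_kdm8_positive

    cells: list[CellGroundTruth] = []
    for i in range(n):
        if is_spike[i]:
            cells.append(
                CellGroundTruth(cellbcs[i], None, 0, 0, 0, int(txn_umis[i]),
                                "spikein", "balanced")
            )
            continue
        if is_somatic[i]:
            wt = int(nb(model.kras_umi_mean / 2.0, model.kras_umi_dispersion, 1)[0])
            kdm8 = int(1 + rng.poisson(model.kdm8_umi_mean)) if kdm8_pos[i] else 0
            cells.append(
                CellGroundTruth(cellbcs[i], None, 0, wt, kdm8, int(txn_umis[i]),
                                "somatic", "balanced")
            )
            continue
        total = int(kras_total[i])
        g12d = int(rng.binomial(total, g12d_frac[i]))
        wt = total - g12d
        state = "g12d_high" if imb[i] else "balanced"
        kdm8 = int(1 + rng.poisson(model.kdm8_umi_mean)) if kdm8_pos[i] else 0
        cells.append(
            CellGroundTruth(
                cellbcs[i],
                alleles[clone_of[i]].barcode_id,
                g12d,
                wt,
                kdm8,
                int(txn_umis[i]),
                "malignant",
                state,
            )
        )
    return cells


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _write_fastq(path: Path, records: Iterable[tuple[str, str]]) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def _emit_pairs(
    truth: Sequence[CellGroundTruth],
    payload_of: dict[str, str],
    umis_of,
    cfg: ReadSimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    r2_builder,
) -> int:
    """Shared FASTQ emitter: per ground-truth UMI emit Poisson(mean)+1
    duplicate read pairs with substitution errors on R2."""
    rng = np.random.default_rng(cfg.seed)
    r1_records: list[tuple[str, str]] = []
    r2_records: list[tuple[str, str]] = []
    serial = 0
    for cell in truth:
        for allele_key, n_umis in umis_of(cell):
            if n_umis == 0:
                continue
            payload = payload_of[allele_key]
            umis = _random_distinct_seqs(rng, n_umis, cfg.umi_length)
            for umi in umis:
                dups = 1 + int(rng.poisson(cfg.reads_per_umi))
                for _ in range(dups):
                    serial += 1
                    name = f"read{serial}"
                    r1 = cell.cell_barcode + umi
                    r2 = _mutate(
                        rng, r2_builder(payload), cfg.substitution_error_rate
                    )
                    r1_records.append((name, r1))
                    r2_records.append((name, r2))
    _write_fastq(Path(r1_path), r1_records)
    return _write_fastq(Path(r2_path), r2_records)


def emit_krasbc_fastq(
    truth: Sequence[CellGroundTruth],
    alleles: Sequence[BarcodeAllele],
    wildtype: str,
    cfg: ReadSimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write the KrasBC-Seq read pairs.

    R1 = cellBC + UMI; R2 = 5' anchor + allele (or wildtype) coding segment +
    3' anchor, with per-base substitution errors. Returns the read count.
    """
    payload_of = {a.barcode_id: a.coding_sequence for a in alleles}
    payload_of["WT"] = wildtype
    for cell in truth:
        if cell.clone_barcode_id is not None and cell.clone_barcode_id not in payload_of:
            raise SimulationError(
                f"clone barcode {cell.clone_barcode_id} has no allele sequence"
            )

    def umis_of(cell: CellGroundTruth):
        if cell.clone_barcode_id is not None:
            yield cell.clone_barcode_id, cell.kras_g12d_umis
        yield "WT", cell.kras_wt_umis

    return _emit_pairs(
        truth, payload_of, umis_of, cfg, r1_path, r2_path,
        lambda payload: cfg.adapter_5p + payload + cfg.adapter_3p,
    )


def emit_kdm8_fastq(
    truth: Sequence[CellGroundTruth],
    kdm8_transcript: str,
    cfg: ReadSimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    fragment_length: int = 80,
) -> int:
    """Write Kdm8-Seq read pairs: R2 = 26-nt constant prefix + transcript
    fragment. Returns the read count."""
    if len(kdm8_transcript) < fragment_length:
        raise SimulationError("kdm8 transcript shorter than fragment_length")
    prefix = KDM8_CONSTANT_PREFIX
    fragment = kdm8_transcript[:fragment_length]
    payload_of = {"KDM8": fragment}

    def umis_of(cell: CellGroundTruth):
        yield "KDM8", cell.kdm8_umis

    return _emit_pairs(
        truth, payload_of, umis_of, cfg, r1_path, r2_path,
        lambda payload: prefix + payload,
    )


def random_genome(
    rng_or_seed, chrom_lengths: dict[str, int]
) -> dict[str, str]:
    """Random toy genome; at these sizes nearly every k-mer is unique."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    bases = np.array(list(DNA_ALPHABET))
    return {
        chrom: "".join(bases[rng.integers(0, 4, size=length)])
        for chrom, length in chrom_lengths.items()
    }


def simulate_scwgs_counts(cfg: ScwgsSimConfig, binmap) -> np.ndarray:
    """Draw per-bin read counts multinomially with intensity proportional to
    copy number x GC weight, so the total equals ``reads_total`` exactly."""
    lam = np.empty(len(binmap.bins))
    for i, b in enumerate(binmap.bins):
        if b.chromosome not in cfg.cn_states:
            raise SimulationError(f"no copy-number state for {b.chromosome}")
        if not np.isfinite(b.gc_fraction):
            raise SimulationError(f"bin {i} has undefined GC")
        gc_weight = max(1.0 + cfg.gc_bias_slope * (b.gc_fraction - 0.5), 1e-6)
        lam[i] = cfg.cn_states[b.chromosome] * gc_weight
    if lam.sum() == 0:
        return np.zeros(len(lam), dtype=int)
    rng = np.random.default_rng(cfg.seed)
    return rng.multinomial(cfg.reads_total, lam / lam.sum())


_TRUTH_COLUMNS = [f.name for f in dataclasses.fields(CellGroundTruth)]


def write_truth_table(truth: Sequence[CellGroundTruth], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(c) for c in truth], columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[CellGroundTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if d["clone_barcode_id"] in ("", "None"):
            d["clone_barcode_id"] = None
        for k in ("kras_g12d_umis", "kras_wt_umis", "kdm8_umis", "transcriptome_umis"):
            d[k] = int(d[k])
        out.append(CellGroundTruth(**d))
    return out
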