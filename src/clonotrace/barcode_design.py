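"""Synonymous-mutation barcode library design over the murine Kras
codon 2-31 template.

The engineered allele carries three kinds of change relative to wildtype:

* the G12D driver substitution (GGT -> GAT at codon 12),
* a block of synonymous substitutions across codons 3-8 that destroys the
  sgKras protospacer match (sgRNA resistance),
* combinations of synonymous (mostly wobble-base) substitutions at a
  calibrated set of variable codons that act as heritable clone barcodes.

The shipped variable-position design (``data/kras_barcode_design.tsv``)
yields a library diversity of 2,359,296 = 2^18 x 3^2 distinct barcodes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from math import prod
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonTemplate",
    "VariablePositionSet",
    "BarcodeAllele",
    "KRAS_CODONS_2_31",
    "SGKRAS_PROTOSPACER",
    "WILDTYPE_RECORD_NAME",
    "default_template",
    "load_default_varset",
    "enumerate_diversity",
    "apply_fixed_mutations",
    "sample_alleles",
    "write_reference",
    "read_reference",
    "protospacer_mismatches",
]


class DesignError(ValueError):
    """Invalid barcode library design."""


# Murine Kras codons 2-31 (90 nt downstream of the start codon).
KRAS_CODONS_2_31 = (
    "ACT GAG TAT AAA CTT GTG GTG GTT GGA GCT GGT GGC GTA GGC AAG "
    "AGC GCC TTG ACG ATA CAG CTA ATT CAG AAT CAC TTT GTG GAT GAA"
).replace(" ", "")

# Printed sgKras spacer (5'->3'); spans the last base of ATG plus codons 2-8.
SGKRAS_PROTOSPACER = "GACTGAGTATAAACTTGTGG"

# Protospacer-disrupting synonymous block at codons 3-8.
SG_RESISTANCE_FROM = "GAGTATAAACTTGTGGTG"
SG_RESISTANCE_TO = "GAATACAAGCTAGTAGTC"

G12D_FROM = "GGT"
G12D_TO = "GAT"

WILDTYPE_RECORD_NAME = "Kras_WT"

FIRST_CODON = 2  # template codon numbering starts at Kras codon 2


@dataclass(frozen=True)
class CodonTemplate:
    """Wildtype codons 2-31 plus the positions excluded from variation."""

    codons: tuple[str, ...] = tuple(
        KRAS_CODONS_2_31[i : i + 3] for i in range(0, 90, 3)
    )
    fixed_codon_indices: frozenset[int] = frozenset({3, 4, 5, 6, 7, 8, 12})
    g12d_index: int = 12

    def __post_init__(self) -> None:
        if len(self.codons) != 30:
            raise DesignError(f"expected 30 codons, got {len(self.codons)}")
        for c in self.codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise DesignError(f"bad codon {c!r}")
        if self.g12d_index not in self.fixed_codon_indices:
            raise DesignError("G12D codon must be fixed")

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def codon(self, codon_index: int) -> str:
        return self.codons[codon_index - FIRST_CODON]

    @property
    def protein(self) -> str:
        return str(Seq(self.sequence).translate())


@dataclass(frozen=True)
class VariablePositionSet:
    """Per-codon allowed synonymous alternatives defining the barcode space."""

    entries: tuple[tuple[int, tuple[str, ...]], ...]

    def validate(self, template: CodonTemplate) -> None:
        seen: set[int] = set()
        for idx, allowed in self.entries:
            if idx in template.fixed_codon_indices:
                raise DesignError(f"codon {idx} is fixed but listed as variable")
            if idx in seen:
                raise DesignError(f"duplicate entry for codon {idx}")
            seen.add(idx)
            wt_aa = Seq(template.codon(idx)).translate()
            for codon in allowed:
                if Seq(codon).translate() != wt_aa:
                    raise DesignError(
                        f"codon {codon} at position {idx} is not synonymous"
                    )
            if len(set(allowed)) != len(allowed):
                raise DesignError(f"duplicate allowed codon at position {idx}")

    @property
    def radices(self) -> tuple[int, ...]:
        return tuple(len(allowed) for _, allowed in self.entries)


@dataclass(frozen=True)
class BarcodeAllele:
    """One engineered Kras^G12D coding variant."""

    barcode_id: str
    coding_sequence: str
    barcode_string: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.coding_sequence) != 90:
            raise DesignError("coding_sequence must be 90 nt")


def default_template() -> CodonTemplate:
    return CodonTemplate()


def load_default_varset(path: str | Path | None = None) -> VariablePositionSet:
    """Read the calibrated variable-position design (TSV: codon_index,
    wildtype_codon, allowed_codons)."""
    if path is None:
        ref = importlib.resources.files("clonotrace.data").joinpath(
            "kras_barcode_design.tsv"
        )
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries = []
    lines = text.strip().splitlines()
    for line in lines[1:]:
        idx_s, _wt, allowed_s = line.rstrip("\n").split("\t")
        entries.append((int(idx_s), tuple(allowed_s.split(","))))
    varset = VariablePositionSet(tuple(entries))
    varset.validate(default_template())
    return varset


def enumerate_diversity(
    template: CodonTemplate, varset: VariablePositionSet
) -> int:
    """Number of distinct barcodes: the product of per-position synonymous
    degeneracies. Never materializes the space."""
    varset.validate(template)
    return prod(varset.radices) if varset.entries else 1


def apply_fixed_mutations(template: CodonTemplate) -> str:
    """Return the template with the sgRNA-resistance block and the G12D
    substitution applied (no barcode variation)."""
    seq = template.sequence
    if SG_RESISTANCE_FROM not in seq:
        raise DesignError("template lacks the sgKras protospacer segment")
    seq = seq.replace(SG_RESISTANCE_FROM, SG_RESISTANCE_TO, 1)
    g12d_offset = (template.g12d_index - FIRST_CODON) * 3
    codon = seq[g12d_offset : g12d_offset + 3]
    if codon != G12D_FROM:
        raise DesignError(f"expected {G12D_FROM} at codon 12, found {codon}")
    return seq[:g12d_offset] + G12D_TO + seq[g12d_offset + 3 :]


def _allele_from_digits(
    base: str, varset: VariablePositionSet, digits: Sequence[int]
) -> BarcodeAllele:
    codons = [base[i : i + 3] for i in range(0, 90, 3)]
    chosen = []
    for (idx, allowed), d in zip(varset.entries, digits):
        codons[idx - FIRST_CODON] = allowed[d]
        chosen.append(allowed[d])
    barcode_id = "BC_" + "-".join(
        f"{idx}{allowed[d]}" for (idx, allowed), d in zip(varset.entries, digits)
    )
    return BarcodeAllele(barcode_id, "".join(codons), "".join(chosen))


def sample_alleles(
    template: CodonTemplate,
    varset: VariablePositionSet,
    n: int,
    seed: int,
) -> list[BarcodeAllele]:
    """Draw ``n`` distinct alleles from the barcode space.

    Sampling is index-based over the mixed-radix space, so the full library
    is never materialized; deterministic for a fixed seed.
    """
    diversity = enumerate_diversity(template, varset)
    if n > diversity:
        raise DesignError(f"requested {n} alleles from a space of {diversity}")
    rng = np.random.default_rng(seed)
    if diversity <= 4 * n or diversity < 10_000:
        indices = rng.choice(diversity, size=n, replace=False)
    else:  # rejection-free enough: draw extra and deduplicate
        picked: list[int] = []
        seen: set[int] = set()
        while len(picked) < n:
            for v in rng.integers(0, diversity, size=2 * (n - len(picked))):
                iv = int(v)
                if iv not in seen:
                    seen.add(iv)
                    picked.append(iv)
                    if len(picked) == n:
                        break
        indices = np.array(picked)
    base = apply_fixed_mutations(template)
    radices = varset.radices
    alleles = []
    for index in indices:
        digits = []
        rem = int(index)
        for r in reversed(radices):
            digits.append(rem % r)
            rem //= r
        alleles.append(_allele_from_digits(base, varset, digits[::-1]))
    return alleles


def write_reference(
    alleles: Iterable[BarcodeAllele], wildtype: str, path: str | Path
) -> int:
    """Write the allele reference FASTA (one record per allele plus the
    wildtype record). Returns the record count."""
    alleles = list(alleles)
    if not alleles:
        raise DesignError("empty allele list")
    ids = [a.barcode_id for a in alleles]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate barcode_id in allele list")
    records = [
        SeqRecord(Seq(wildtype), id=WILDTYPE_RECORD_NAME, description="")
    ] + [
        SeqRecord(Seq(a.coding_sequence), id=a.barcode_id, description="")
        for a in alleles
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_reference(path: str | Path) -> tuple[str, list[BarcodeAllele]]:
    """Read back a reference FASTA; returns (wildtype, alleles)."""
    wildtype = None
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == WILDTYPE_RECORD_NAME:
            wildtype = str(rec.seq)
        else:
            alleles.append(BarcodeAllele(rec.id, str(rec.seq)))
    if wildtype is None:
        raise DesignError(f"reference lacks the {WILDTYPE_RECORD_NAME} record")
    return wildtype, alleles


def protospacer_mismatches(coding_sequence: str) -> int:
    """Best-window substitution distance of the sgKras protospacer against
    an allele coding sequence (both strands)."""
    from ._sequence import best_window_distance, reverse_complement

    fwd, _ = best_window_distance(SGKRAS_PROTOSPACER, coding_sequence)
    rev, _ = best_window_distance(
        reverse_complement(SGKRAS_PROTOSPACER), coding_sequence
    )
    return min(fwd, rev)
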