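import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotrace import krasbc as kb
from clonotrace import synthetic_data as sim
from clonotrace._sequence import levenshtein


ANCHOR5 = kb.DEFAULT_ANCHOR_5P
ANCHOR3 = kb.DEFAULT_ANCHOR_3P


def oracle_trim(read: str, anchor5: str, anchor3: str, rate: float = 0.2):
    """Independent trimming oracle: exhaustive window scan, leftmost best
    full-length substitution match of each anchor."""

    def best(seq: str, anchor: str):
        hits = []
        for i in range(len(seq) - len(anchor) + 1):
            mm = sum(a != b for a, b in zip(seq[i:i + len(anchor)], anchor))
            hits.append((mm, i))
        if not hits:
            return None
        mm, i = min(hits)
        return (i, mm) if mm <= math.floor(rate * len(anchor)) else None

    h5 = best(read, anchor5)
    if h5 is None:
        return None
    rest = read[h5[0] + len(anchor5):]
    h3 = best(rest, anchor3)
    if h3 is not None:
        rest = rest[: h3[0]]
    return rest or None


class TestTrim:
    def test_exact_anchors(self):
        payload = "ACGTACGTACGT"
        read = ANCHOR5 + payload + ANCHOR3
        assert kb.trim_krasbc(read) == payload

    def test_three_substitutions_in_5p_anchor(self):
        noisy5 = "AT" + ANCHOR5[2:-1] + "A"  # 3 substitutions, rate 3/18
        payload = "TTTTGGGGCCCC"
        assert kb.trim_krasbc(noisy5 + payload) == payload

    def test_missing_5p_anchor_drops_read(self):
        assert kb.trim_krasbc("ACGT" * 20) is None

    def test_empty_read(self):
        assert kb.trim_krasbc("") is None

    def test_optional_3p_anchor(self):
        payload = "AAAACCCCGGGG"
        assert kb.trim_krasbc(ANCHOR5 + payload) == payload

    def test_fuzzed_reads_match_alignment_oracle(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            payload = "".join(rng.choice(bases, size=rng.integers(5, 60)))
            read = ANCHOR5 + payload + ANCHOR3
            arr = list(read)
            n_err = int(rng.integers(0, 7))
            for i in rng.choice(len(arr), size=min(n_err, len(arr)), replace=False):
                arr[i] = str(rng.choice(bases[bases != arr[i]]))
            fuzzed = "".join(arr)
            assert kb.trim_krasbc(fuzzed) == oracle_trim(fuzzed, ANCHOR5, ANCHOR3)


class TestAssignAllele:
    def test_wildtype_exact(self, template, alleles):
        assert kb.assign_allele(template.sequence, template.sequence, alleles) == "WT"

    def test_one_substitution_outside_variable_positions(self, template, varset, alleles):
        # exhaustive-distance check on a toy reference: mutate a fixed codon
        a = alleles[0]
        seq = list(a.coding_sequence)
        off = (4 - 2) * 3  # codon 4, inside the fixed sgRNA-resistance block
        seq[off] = "A" if seq[off] != "A" else "C"
        mutated = "".join(seq)
        label = kb.assign_allele(mutated, template.sequence, alleles)
        assert label == a.barcode_id
        # oracle: brute-force hamming over the whole reference
        refs = {"WT": template.sequence, **{x.barcode_id: x.coding_sequence for x in alleles}}
        dists = {
            k: sum(p != q for p, q in zip(mutated, s)) for k, s in refs.items()
        }
        assert min(dists, key=lambda k: (dists[k], k)) == a.barcode_id

    def test_equidistant_payload_unassigned(self, template):
        from clonotrace.barcode_design import BarcodeAllele

        a = BarcodeAllele("BC_A", "A" * 90)
        b = BarcodeAllele("BC_B", "C" * 90)
        payload = "A" * 45 + "C" * 45
        assert kb.assign_allele(payload, template.sequence, [a, b], 1.0) is None

    def test_too_distant_unassigned(self, template, alleles):
        assert kb.assign_allele("T" * 90, template.sequence, alleles, 0.1) is None

    def test_empty_payload(self, template, alleles):
        assert kb.assign_allele("", template.sequence, alleles) is None


class TestCollapseUmis:
    def _read(self, cell="C" * 16, umi="U" * 10, payload="X"):
        return kb.TaggedRead(cell, umi, payload)

    def test_duplicates_count_once(self):
        reads = [(self._read(), "BC_1")] * 5
        cells = kb.collapse_umis(reads)
        assert cells["C" * 16].barcode_umis == {"BC_1": 1}

    def test_same_umi_two_alleles_counts_under_each(self):
        reads = [(self._read(), "WT"), (self._read(), "BC_1")]
        cell = kb.collapse_umis(reads)["C" * 16]
        assert cell.wt_umis == 1
        assert cell.barcode_umis == {"BC_1": 1}

    def test_empty(self):
        assert kb.collapse_umis([]) == {}

    def test_unassigned_ignored(self):
        assert kb.collapse_umis([(self._read(), None)]) == {}

    def test_monotone_adding_reads(self):
        base = [
            (self._read(umi=f"{i:010d}"), "BC_1") for i in range(4)
        ]
        before = kb.collapse_umis(base)["C" * 16].barcode_umis["BC_1"]
        after = kb.collapse_umis(
            base + [(self._read(umi="9999999999"), "BC_1")]
        )["C" * 16].barcode_umis["BC_1"]
        assert after >= before


def oracle_merge(barcode_umis: dict[str, int], max_distance: int = 3) -> dict[str, int]:
    """Brute-force union-by-distance: connected components of the
    pairwise (< max_distance) Levenshtein graph; all UMIs pooled onto each
    component's highest-count member (lexicographic tie-break)."""
    bcs = list(barcode_umis)
    comp = {b: {b} for b in bcs}
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(bcs, 2):
            if comp[a] is comp[b]:
                continue
            if any(
                levenshtein(x, y) < max_distance
                for x in comp[a] for y in comp[b]
            ) or levenshtein(a, b) < max_distance:
                union = comp[a] | comp[b]
                for m in union:
                    comp[m] = union
                changed = True
    seen = []
    out = {}
    for b in bcs:
        if any(comp[b] is s for s in seen):
            continue
        seen.append(comp[b])
        rep = sorted(comp[b], key=lambda x: (-barcode_umis[x], x))[0]
        out[rep] = sum(barcode_umis[m] for m in comp[b])
    return out


class TestMergeBarcodes:
    def test_error_absorption(self):
        assert kb.merge_barcodes({"AAAA": 10, "AAAT": 1}) == {"AAAA": 11}

    def test_beyond_threshold_unchanged(self):
        got = kb.merge_barcodes({"AAAA": 10, "TTTT": 4})
        assert got == {"AAAA": 10, "TTTT": 4}

    def test_distance_exactly_three_not_merged(self):
        # strict < 3 per the calling rule
        got = kb.merge_barcodes({"AAAAAA": 10, "TTTAAA": 2})
        assert got == {"AAAAAA": 10, "TTTAAA": 2}

    def test_empty_and_singleton(self):
        assert kb.merge_barcodes({}) == {}
        assert kb.merge_barcodes({"A": 3}) == {"A": 3}

    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=3, max_size=8),
            st.integers(min_value=1, max_value=50),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_union_by_distance_oracle(self, barcode_umis):
        assert kb.merge_barcodes(barcode_umis) == oracle_merge(barcode_umis)

    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=4, max_size=10),
            st.integers(min_value=1, max_value=100),
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_umi_conservation(self, barcode_umis):
        merged = kb.merge_barcodes(barcode_umis)
        assert sum(merged.values()) == sum(barcode_umis.values())


class TestCallClonotype:
    def _counts(self, wt=0, bcs=None, txn=100):
        return kb.CellAlleleCounts(
            "C" * 16, wt_umis=wt, barcode_umis=bcs or {}, transcriptome_umis=txn
        )

    def test_somatic(self):
        call = kb.call_clonotype(self._counts(wt=3))
        assert call.cell_class == "somatic"
        assert call.dominant_barcode is None

    def test_excluded_no_signal(self):
        assert kb.call_clonotype(self._counts(wt=0)).cell_class == "excluded"
        assert kb.call_clonotype(self._counts(wt=1)).cell_class == "excluded"

    def test_malignant_with_merge(self):
        # BC2 is 1 edit from BC1 and donates its UMI before the call
        call = kb.call_clonotype(self._counts(wt=1, bcs={"BCAAAA": 7, "BCAAAT": 1}))
        assert call.cell_class == "malignant"
        assert call.dominant_barcode == "BCAAAA"
        assert call.g12d_umis == 8

    def test_tie_excluded(self):
        call = kb.call_clonotype(self._counts(wt=0, bcs={"AAAAAAA": 5, "TTTTTTT": 5}))
        assert call.cell_class == "excluded"

    def test_zero_transcriptome_excluded(self):
        call = kb.call_clonotype(self._counts(wt=5, bcs={"AAAAAAA": 5}, txn=0))
        assert call.cell_class == "excluded"
        assert math.isnan(call.kras_abundance)

    def test_abundance(self):
        counts = self._counts(wt=2, bcs={"AAAAAAA": 8}, txn=100)
        counts.depth_scale = 50.0
        call = kb.call_clonotype(counts)
        assert call.kras_abundance == pytest.approx((2 + 8) / 100 * 50)

    def test_partition_exhaustive(self):
        # somatic/excluded/malignant partition over a grid of inputs
        for wt in range(4):
            for nbc in range(3):
                bcs = {"AAAAAAA": nbc} if nbc else {}
                call = kb.call_clonotype(self._counts(wt=wt, bcs=bcs))
                if nbc:
                    assert call.cell_class == "malignant"
                elif wt >= 2:
                    assert call.cell_class == "somatic"
                else:
                    assert call.cell_class == "excluded"


class TestClassifyImbalance:
    def _call(self, g12d, wt):
        return kb.ClonotypeCall(
            "C" * 16, "BC_1", "malignant", "indeterminate", wt, g12d, 1.0
        )

    def test_g12d_high(self):
        assert kb.classify_imbalance(self._call(10, 0)).imbalance_state == "g12d_high"

    def test_balanced(self):
        assert kb.classify_imbalance(self._call(5, 5)).imbalance_state == "balanced"

    def test_wt_high(self):
        assert kb.classify_imbalance(self._call(1, 9)).imbalance_state == "wt_high"

    def test_low_depth_indeterminate(self):
        assert kb.classify_imbalance(self._call(2, 1)).imbalance_state == "indeterminate"

    def test_boundary_fraction(self):
        assert kb.classify_imbalance(self._call(3, 1)).imbalance_state == "g12d_high"

    def test_non_malignant_rejected(self):
        call = kb.ClonotypeCall("C" * 16, None, "somatic", "indeterminate", 3, 0, 1.0)
        with pytest.raises(ValueError):
            kb.classify_imbalance(call)


class TestEndToEnd:
    def test_error_free_calls_equal_truth(self, template, alleles, tmp_path):
        model = sim.TumorModel(
            n_cells=200, n_clones=10, p_somatic=0.1, p_imbalanced=0.25, seed=11
        )
        truth = sim.simulate_tumor(model, alleles)
        cfg = sim.ReadSimConfig(substitution_error_rate=0.0, reads_per_umi=0.5, seed=11)
        sim.emit_krasbc_fastq(
            truth, alleles, template.sequence, cfg,
            tmp_path / "r1.fq", tmp_path / "r2.fq",
        )
        txn = {c.cell_barcode: c.transcriptome_umis for c in truth}
        calls = kb.run_krasbc_pipeline(
            tmp_path / "r1.fq", tmp_path / "r2.fq", template.sequence, alleles, txn
        )
        by_cell = {c.cell_barcode: c for c in calls}
        for cell in truth:
            if cell.cell_class != "malignant" or cell.kras_g12d_umis == 0:
                continue
            call = by_cell[cell.cell_barcode]
            assert call.dominant_barcode == cell.clone_barcode_id

    def test_imbalance_label_recovery_at_depth_20(self, alleles):
        # simulated imbalance labels recovered >= 95% at mean depth 20
        model = sim.TumorModel(
            n_cells=2000, n_clones=10, p_somatic=0.0, p_imbalanced=0.25,
            kras_umi_mean=20.0, seed=17,
        )
        truth = sim.simulate_tumor(model, alleles)
        agree = total = 0
        for cell in truth:
            counts = kb.CellAlleleCounts(
                cell.cell_barcode,
                wt_umis=cell.kras_wt_umis,
                barcode_umis=(
                    {cell.clone_barcode_id: cell.kras_g12d_umis}
                    if cell.kras_g12d_umis else {}
                ),
                transcriptome_umis=cell.transcriptome_umis,
            )
            call = kb.call_clonotype(counts)
            if call.cell_class != "malignant":
                continue
            call = kb.classify_imbalance(call, min_total=20)
            if call.imbalance_state == "indeterminate":
                continue
            total += 1
            agree += call.imbalance_state == cell.imbalance_state
        assert total > 500
        assert agree / total >= 0.95

    def test_read_order_invariance(self, template, alleles, tmp_path):
        model = sim.TumorModel(n_cells=50, n_clones=5, seed=13)
        truth = sim.simulate_tumor(model, alleles)
        cfg = sim.ReadSimConfig(substitution_error_rate=0.01, seed=13)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        sim.emit_krasbc_fastq(truth, alleles, template.sequence, cfg, r1, r2)
        txn = {c.cell_barcode: c.transcriptome_umis for c in truth}
        calls = kb.run_krasbc_pipeline(r1, r2, template.sequence, alleles, txn)

        # reverse both FASTQs in concert
        def reverse_fastq(path):
            recs = path.read_text().strip().split("\n")
            blocks = ["\n".join(recs[i:i + 4]) for i in range(0, len(recs), 4)]
            path.write_text("\n".join(reversed(blocks)) + "\n")

        reverse_fastq(r1)
        reverse_fastq(r2)
        calls_rev = kb.run_krasbc_pipeline(r1, r2, template.sequence, alleles, txn)
        assert calls == calls_rev


class TestTableOutputs:
    def test_clonotype_table_and_summary(self, tmp_path):
        calls = [
            kb.ClonotypeCall("A" * 16, "BC_1", "malignant", "balanced", 2, 5, 1.2),
            kb.ClonotypeCall("C" * 16, "BC_1", "malignant", "g12d_high", 0, 9, 2.0),
            kb.ClonotypeCall("G" * 16, None, "somatic", "indeterminate", 4, 0, 0.5),
        ]
        out = tmp_path / "calls.tsv"
        kb.write_clonotype_table(calls, out)
        assert out.read_text().count("\n") == 4
        summary = kb.clone_size_summary(calls)
        assert summary.iloc[0]["dominant_barcode"] == "BC_1"
        assert int(summary.iloc[0]["n_cells"]) == 2

    def test_depth_scale_median(self):
        assert kb.depth_scale_from({"a": 10, "b": 30, "c": 20}) == 20.0
        assert kb.depth_scale_from({}) == 1.0
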