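"""DE thresholding, target calling, hypergeometric overlap tests."""

import math

import numpy as np
import pytest

from chiptargets.annotate import associate_peaks
from chiptargets.integrate import (
    ACTIVATED,
    REPRESSED,
    UNCHANGED,
    benjamini_hochberg,
    call_targets,
    classify_regulation,
    hypergeom_overlap,
    overlap_test,
)
from chiptargets.io import DERecord, GeneModel, GenomicInterval
from util import cons, hypergeom_enumerate


def de(gene, log2fc, padj, contrast="low_cu"):
    return DERecord(gene, contrast, log2fc, padj, 10.0)


class TestClassifyRegulation:
    def test_strong_activation(self):
        # WT/mutant ratio 4,700 under low Cu -> log2fc ~ 12.2, activated
        (c,) = classify_regulation([de("FSD1", math.log2(4700), 1e-30)])
        assert c.regulation == ACTIVATED

    def test_missing_padj_unchanged(self):
        (c,) = classify_regulation([de("X", 5.0, None)])
        assert c.regulation == UNCHANGED

    def test_condition_dependence(self):
        # significant ratio 32 in one condition, "-" (no call) in the other
        recs = [
            de("ZIP2", math.log2(32), 1e-6, "low_cu"),
            de("ZIP2", 0.1, 0.8, "control_cu"),
        ]
        got = {c.condition: c.regulation for c in classify_regulation(recs)}
        assert got == {"low_cu": ACTIVATED, "control_cu": UNCHANGED}

    def test_repression_and_threshold_edges(self):
        recs = [de("A", -2.0, 0.05), de("B", -2.0, 0.051), de("C", 0.0, 0.001)]
        got = {c.gene_id: c.regulation for c in classify_regulation(recs)}
        assert got == {"A": REPRESSED, "B": UNCHANGED, "C": UNCHANGED}

    def test_raising_padj_max_never_unclassifies(self):
        rng = np.random.default_rng(5)
        recs = [
            de(f"g{i}", float(rng.normal()), float(rng.uniform()))
            for i in range(200)
        ]
        loose = {
            c.gene_id for c in classify_regulation(recs, padj_max=0.2)
            if c.regulation != UNCHANGED
        }
        strict = {
            c.gene_id for c in classify_regulation(recs, padj_max=0.05)
            if c.regulation != UNCHANGED
        }
        assert strict <= loose

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_regulation([], padj_max=0.0)
        with pytest.raises(ValueError):
            classify_regulation([], min_abs_log2fc=-1.0)


class TestCallTargets:
    def _links(self, genes, condition="low_cu"):
        models = []
        pos = 10_000
        for g in genes:
            models.append(GeneModel(g, GenomicInterval("chr1", pos, pos + 1000, "+")))
            pos += 5000
        peaks = [
            cons(m.interval.start - 300, m.interval.start - 100,
                 condition=condition, name=f"pk_{m.gene_id}")
            for m in models
        ]
        return associate_peaks(peaks, models)

    def test_conjunction_of_peak_and_class(self):
        links = {"low_cu": self._links(["A", "B"])}
        classes = classify_regulation([de("A", 3.0, 1e-4), de("B", 3.0, 0.9)])
        calls, counts = call_targets(links, classes)
        assert [c.gene_id for c in calls] == ["A"]
        assert calls[0].verdict == "direct_activation_candidate"
        assert counts["low_cu"]["direct_activation_candidate"] == 1

    def test_matches_set_intersection_oracle(self):
        # 20 activated-with-peak + 30 peak-only + 30 DE-only -> exactly 20 calls
        with_peak_de = [f"both{i}" for i in range(20)]
        peak_only = [f"peak{i}" for i in range(30)]
        de_only = [f"de{i}" for i in range(30)]
        links = {"low_cu": self._links(with_peak_de + peak_only)}
        classes = classify_regulation(
            [de(g, 4.0, 1e-8) for g in with_peak_de + de_only]
        )
        calls, _ = call_targets(links, classes)
        assert {c.gene_id for c in calls} == set(with_peak_de)
        assert all(c.verdict == "direct_activation_candidate" for c in calls)

    def test_random_inputs_equal_brute_force(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            genes = [f"g{i}" for i in range(40)]
            linked = [g for g in genes if rng.random() < 0.5]
            links = {"low_cu": self._links(linked)}
            recs = [
                de(g, float(rng.normal(0, 3)), float(rng.uniform(0, 0.2)))
                for g in genes
                if rng.random() < 0.7
            ]
            classes = classify_regulation(recs)
            calls, _ = call_targets(links, classes)
            expected = {
                (c.gene_id, ACTIVATED if c.regulation == ACTIVATED else REPRESSED)
                for c in classes
                if c.regulation != UNCHANGED and c.gene_id in set(linked)
            }
            got = {
                (c.gene_id,
                 ACTIVATED if c.verdict == "direct_activation_candidate" else REPRESSED)
                for c in calls
            }
            assert got == expected

    def test_condition_specific_filter(self):
        links = {"low_cu": self._links(["A", "B"])}
        presence = {"pk_A": "low_cu_only", "pk_B": "shared"}
        classes = classify_regulation([de("A", 3.0, 1e-4), de("B", 3.0, 1e-4)])
        calls, _ = call_targets(
            links, classes, peak_presence_filter="condition_specific",
            presence_by_peak=presence,
        )
        assert [c.gene_id for c in calls] == ["A"]

    def test_filter_validation(self):
        with pytest.raises(ValueError):
            call_targets({}, [], peak_presence_filter="bogus")
        with pytest.raises(ValueError):
            call_targets({}, [], peak_presence_filter="condition_specific")


class TestHypergeomOverlap:
    def test_full_overlap_small_universe(self):
        # drawing all 5 of 5 marked from 10: p = 1/C(10,5) = 1/252
        res = hypergeom_overlap(10, 5, 5, 5)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_p_one(self):
        assert hypergeom_overlap(100, 10, 10, 0).p_value == 1.0

    def test_expected_overlap(self):
        assert hypergeom_overlap(100, 10, 10, 1).expected_overlap == pytest.approx(1.0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 11, 5, 2)

    def test_matches_exhaustive_enumeration(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        exact = float(hypergeom_enumerate(N, K, n, k))
                        got = hypergeom_overlap(N, K, n, k).p_value
                        assert got == pytest.approx(exact, rel=1e-12), (N, K, n, k)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_overlap(50, 20, 15, k).p_value for k in range(16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_overlap_test_restricts_to_universe(self):
        res = overlap_test(["a", "b", "c", "d"], ["a", "b", "zzz"], ["b", "c"])
        assert (res.set_a_size, res.set_b_size, res.observed_overlap) == (2, 2, 1)


class TestBenjaminiHochberg:
    def test_adjusts_upward_and_preserves_order(self):
        p = [0.001, 0.01, 0.04, 0.5]
        q = benjamini_hochberg(p)
        assert np.all(q >= p)
        assert np.all(np.diff(q) >= 0)

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0
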