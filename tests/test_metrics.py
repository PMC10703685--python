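"""Evaluation engine: bin assignment, call classification, recalibrated
precision, binned metrics, AUPRC and the binomial detection limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosabench as mb
from mosabench.metrics import f1_score

from .conftest import make_call, make_callset, make_truth


# --------------------------------------------------------------------------- #
# bins
# --------------------------------------------------------------------------- #

class TestBins:
    def test_default_schemes(self):
        assert mb.SNV_BINS.n_bins == 8
        assert mb.INDEL_BINS.n_bins == 7
        assert mb.SNV_BINS.labels[0] == "<1" and mb.SNV_BINS.labels[-1] == ">=25"

    @pytest.mark.parametrize(
        "vaf,scheme,label",
        [
            (5.0, mb.SNV_BINS, "4-7.5"),
            (9.6, mb.SNV_BINS, "9.6-25"),  # edges are left-closed
            (0.5, mb.SNV_BINS, "<1"),
            (100.0, mb.SNV_BINS, ">=25"),
            (4.5, mb.INDEL_BINS, "4-5"),
            (16.0, mb.INDEL_BINS, ">=16"),
        ],
    )
    def test_assignment(self, vaf, scheme, label):
        assert scheme.labels[mb.assign_bin(vaf, scheme)] == label

    @pytest.mark.parametrize("vaf", [-0.1, 100.1])
    def test_out_of_range_rejected(self, vaf):
        with pytest.raises(ValueError):
            mb.assign_bin(vaf, mb.SNV_BINS)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            mb.BinScheme("SNV", (1, 1, 2))


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #

def _toy_truth():
    return make_truth(
        positives=[
            ("chr1", 100, "A", "T", "SNV", 0, 0.05),
            ("chr1", 200, "C", "G", "SNV", 0, 0.20),
        ],
        set_b=[("chr1", 300, "G", "A", "SNV", 0.5)],
    )


class TestClassifyCalls:
    def test_exact_match_is_tp(self):
        truth = _toy_truth()
        cs = make_callset([make_call(pos=100, ref="A", alt="T")])
        cls = mb.classify_calls(cs, truth)
        assert cls.n_tp == 1 and cls.n_fn == 1 and cls.n_fp == 0

    def test_set_b_site_is_germline_fp(self):
        truth = _toy_truth()
        cs = make_callset([make_call(pos=300, ref="G", alt="A")])
        cls = mb.classify_calls(cs, truth)
        assert len(cls.fp_germline) == 1 and len(cls.fp_nonvariant) == 0

    def test_wrong_alt_at_positive_site_is_nonvariant_fp(self):
        truth = _toy_truth()
        cs = make_callset([make_call(pos=100, ref="A", alt="G")])
        cls = mb.classify_calls(cs, truth)
        assert len(cls.fp_nonvariant) == 1 and cls.n_tp == 0 and cls.n_fn == 2

    def test_out_of_region_calls_dropped_and_counted(self):
        truth = _toy_truth()
        cs = make_callset([make_call(pos=2_000_000)])
        cls = mb.classify_calls(cs, truth)
        assert cls.n_dropped_outside == 1 and cls.n_fp == 0

    def test_labels_partition_positives(self, callset_m3, truth_m3):
        cls = mb.classify_calls(callset_m3, truth_m3)
        assert cls.n_tp + cls.n_fn == len(truth_m3.positives)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Site-by-site dictionary comparison oracle on 50 random instances."""
        for _ in range(50):
            n_pos, n_b = rng.integers(1, 30), rng.integers(1, 10)
            pos_sites = rng.choice(2000, size=n_pos + n_b, replace=False) + 1
            truth = make_truth(
                positives=[
                    ("chr1", int(p), "A", "T", "SNV", 0, 0.1)
                    for p in pos_sites[:n_pos]
                ],
                set_b=[("chr1", int(p), "G", "A", "SNV", 0.5) for p in pos_sites[n_pos:]],
                region=mb.RegionSet.single("chr1", 3000),
            )
            calls = [
                make_call(pos=int(p), ref="A", alt="T" if rng.random() < 0.6 else "C")
                for p in rng.choice(2500, size=rng.integers(1, 40), replace=False) + 1
            ]
            cls = mb.classify_calls(make_callset(calls), truth)
            # oracle
            truth_d = {("chr1", int(p), "A", "T") for p in pos_sites[:n_pos]}
            setb_d = {("chr1", int(p)) for p in pos_sites[n_pos:]}
            exp = {"tp": set(), "fpg": set(), "fpnv": set()}
            for c in calls:
                k = (c.chrom, c.pos, c.ref, c.alt)
                if c.pos > 3000:
                    continue
                if k in truth_d:
                    exp["tp"].add(k)
                elif (c.chrom, c.pos) in setb_d:
                    exp["fpg"].add(k)
                else:
                    exp["fpnv"].add(k)
            assert cls.tp_sites() == exp["tp"]
            assert cls.fp_sites("germline") == exp["fpg"]
            assert cls.fp_sites("nonvariant") == exp["fpnv"]
            assert cls.n_fn == n_pos - len(exp["tp"])


# --------------------------------------------------------------------------- #
# recalibration
# --------------------------------------------------------------------------- #

class TestRecalibration:
    @pytest.mark.parametrize(
        "density,mbp,n_pos,w",
        [(1.0, 30.0, 7500, 0.004), (0.1, 30.0, 600, 0.005), (2.0, 5.0, 10, 1.0)],
    )
    def test_weight_formula(self, density, mbp, n_pos, w):
        assert mb.recalibration_weight(density, mbp, n_pos).w == pytest.approx(w)

    def test_weight_rejects_zero_positives(self):
        with pytest.raises(ValueError):
            mb.recalibration_weight(1.0, 30.0, 0)

    @pytest.mark.parametrize(
        "tp,fp,w,expected",
        [(50, 50, 1.0, 0.5), (7, 0, 0.3, 1.0), (1000, 10, 0.004, 4 / 14)],
    )
    def test_precision_formula(self, tp, fp, w, expected):
        assert mb.recalibrated_precision(tp, fp, w) == pytest.approx(expected)

    def test_precision_undefined_without_calls(self):
        assert math.isnan(mb.recalibrated_precision(0, 0, 1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(1, 1000),
        fp=st.integers(0, 1000),
        w=st.floats(1e-4, 10),
        dw=st.floats(0, 5),
        dtp=st.integers(0, 50),
        dfp=st.integers(0, 50),
    )
    def test_precision_monotonicity(self, tp, fp, w, dw, dtp, dfp):
        """Non-decreasing in w and tp, non-increasing in fp."""
        base = mb.recalibrated_precision(tp, fp, w)
        assert mb.recalibrated_precision(tp, fp, w + dw) >= base - 1e-12
        assert mb.recalibrated_precision(tp + dtp, fp, w) >= base - 1e-12
        assert mb.recalibrated_precision(tp, fp + dfp, w) <= base + 1e-12


# --------------------------------------------------------------------------- #
# binned metrics
# --------------------------------------------------------------------------- #

class TestBinnedMetrics:
    def test_counts_and_rates(self):
        truth = make_truth(
            positives=[("chr1", i, "A", "T", "SNV", 0, 0.05) for i in range(1, 101)],
        )
        # 90 TPs in bin 4-7.5 (truth VAF 5%), 10 FN; 100 FPs at 6% observed
        calls = [make_call(pos=i, observed_vaf=0.05) for i in range(1, 91)]
        calls += [
            make_call(pos=1000 + i, ref="A", alt="G", observed_vaf=0.06)
            for i in range(100)
        ]
        cls = mb.classify_calls(make_callset(calls), truth)
        cls.region_mbp = 50.0
        table = mb.binned_metrics(cls, mb.SNV_BINS, w=1.0, region_mbp=50.0)
        row = table[table["bin"] == "4-7.5"].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.9)
        assert row["fp_per_mbp"] == pytest.approx(2.0)
        assert row["recal_precision"] == pytest.approx(90 / 190)
        assert row["f1"] == pytest.approx(
            f1_score(0.9, 90 / 190)
        )

    def test_empty_bins_are_missing_not_zero(self):
        truth = make_truth(positives=[("chr1", 1, "A", "T", "SNV", 0, 0.05)])
        cls = mb.classify_calls(make_callset([]), truth)
        table = mb.binned_metrics(cls, mb.SNV_BINS, w=1.0)
        empty = table[table["bin"] == "<1"].iloc[0]
        assert math.isnan(empty["sensitivity"]) and math.isnan(empty["recal_precision"])
        # the bin holding the missed positive has sensitivity 0, not NaN
        missed = table[table["bin"] == "4-7.5"].iloc[0]
        assert missed["sensitivity"] == 0.0


# --------------------------------------------------------------------------- #
# AUPRC
# --------------------------------------------------------------------------- #

def _classified_from(scores, labels, n_fn=0):
    cls = mb.ClassifiedCalls(region_mbp=1.0)
    for i, (s, lab) in enumerate(zip(scores, labels)):
        call = make_call(pos=i + 1, score=s)
        if lab:
            cls.tp.append((call, 0.1))
        else:
            cls.fp_nonvariant.append(call)
    for j in range(n_fn):
        cls.fn.append((("chr1", 10_000 + j, "A", "T"), "SNV", 0.1))
    return cls


def brute_force_auprc(scores, labels, n_pos, w=1.0):
    """Threshold-enumeration oracle for average precision."""
    ap, prev_r = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and not l)
        r = tp / n_pos
        p = tp * w / (tp * w + fp) if tp + fp else 0.0
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestAuprc:
    def test_perfect_ranking_is_one(self):
        cls = _classified_from([5, 4, 3, 1, 0.5], [1, 1, 1, 0, 0])
        assert mb.auprc(cls) == pytest.approx(1.0)

    def test_tied_scores_reduce_to_single_threshold(self):
        cls = _classified_from([1.0] * 10, [1, 1, 1, 0, 0, 0, 0, 1, 1, 1])
        assert mb.auprc(cls, w=1.0) == pytest.approx(6 / 10)

    def test_four_call_toy_matches_brute_force(self):
        scores, labels = [4, 3, 2, 1], [1, 0, 1, 0]
        cls = _classified_from(scores, labels)
        assert mb.auprc(cls) == pytest.approx(brute_force_auprc(scores, labels, 2))
        # hand value: (1/2)*1 + (1/2)*(2/3) = 5/6
        assert mb.auprc(cls) == pytest.approx(5 / 6)

    def test_recalibrated_matches_brute_force_randomized(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 60))
            labels = (rng.random(n) < 0.5).astype(int)
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # many ties
            n_fn = int(rng.integers(0, 5))
            n_pos = int(labels.sum()) + n_fn
            if n_pos == 0:
                continue
            w = float(rng.uniform(0.01, 2.0))
            cls = _classified_from(scores.tolist(), labels.tolist(), n_fn=n_fn)
            assert mb.auprc(cls, w=w) == pytest.approx(
                brute_force_auprc(scores.tolist(), labels.tolist(), n_pos, w)
            )

    def test_label_consistent_refinement_never_decreases_ap(self, rng):
        """Breaking score ties so TPs rank above FPs within each tied group
        can only raise the step-integrated area."""
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() in (0, n):
                continue
            coarse = rng.integers(0, 3, size=n).astype(float)
            refined = coarse + 0.1 * labels  # TPs first within each tie group
            n_pos = int(labels.sum())
            ap_coarse = brute_force_auprc(coarse.tolist(), labels.tolist(), n_pos)
            ap_refined = brute_force_auprc(refined.tolist(), labels.tolist(), n_pos)
            assert ap_refined >= ap_coarse - 1e-12

    def test_non_finite_scores_rejected(self):
        cls = _classified_from([1.0, float("nan")], [1, 0])
        with pytest.raises(ValueError, match="non-finite"):
            mb.auprc(cls)


# --------------------------------------------------------------------------- #
# detection upper limit
# --------------------------------------------------------------------------- #

class TestDetectionUpperLimit:
    def test_zero_and_certainty(self):
        assert mb.detection_upper_limit(100, 0.0, 3) == 0.0
        assert mb.detection_upper_limit(100, 1.0, 3) == pytest.approx(1.0)

    def test_against_brute_force_summation(self):
        depth, vaf, k = 100, 0.01, 3
        exact = 1.0 - sum(
            math.comb(depth, i) * vaf**i * (1 - vaf) ** (depth - i) for i in range(k)
        )
        assert mb.detection_upper_limit(depth, vaf, k) == pytest.approx(exact)
        assert mb.detection_upper_limit(depth, vaf, k) == pytest.approx(0.0794, abs=5e-5)

    def test_monotonicity_grid(self):
        depths = [30, 100, 300, 1100]
        vafs = [0.005, 0.01, 0.05, 0.2]
        ks = [1, 2, 3, 5]
        for v in vafs:
            for k in ks:
                p = [mb.detection_upper_limit(d, v, k) for d in depths]
                assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))
        for d in depths:
            for k in ks:
                p = [mb.detection_upper_limit(d, v, k) for v in vafs]
                assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))
            for v in vafs:
                p = [mb.detection_upper_limit(d, v, k) for k in ks]
                assert all(a >= b - 1e-12 for a, b in zip(p, p[1:]))
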