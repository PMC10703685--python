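"""Feature-level discrimination analysis and post-filter efficiency.

Each feature a caller computes can be scored by how well it separates true
positives from each false-positive class (empirical ROC AUC, orientation
auto-flipped so AUC >= 0.5). Features group into three origin categories —
sequencing (raw read/base-quality values, n=20), alignment (read-mapping
patterns and noise, n=15) and genotype (likelihoods and confidence scores
produced during genotyping, n=13) — and the categories are compared with a
two-sided Wilcoxon rank-sum test. Independently adjustable post-filters are
scored by the F1 change when disabled (Delta F1 = F1 default - F1 disabled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .metrics import (
    ClassifiedCalls,
    classify_calls,
    f1_score,
    recalibrated_precision,
)

__all__ = [
    "default_registry",
    "FeatureAUC",
    "rank_auc",
    "feature_auc",
    "category_compare",
    "filter_efficiency",
]

# Features named in the field's tooling; the remainder of the 48-slot registry
# uses synthetic placeholder names (the full catalog is caller documentation,
# not part of this package's scope).
_SEQUENCING = [
    ("mfrl_alt", "MT2-to"),          # median fragment length, alt reads
    ("mfrl_ref", "MT2-to"),
    ("mbq_alt", "MT2-to"),           # median base quality, alt reads
    ("mbq_ref", "MT2-to"),
    ("base_quality", "HC"),
    ("base_quality_rank_sum", "HC"),
    ("depth", "HC"),
    ("low_coverage", "HC"),
    ("alt_read_count", "MF"),
    ("fragment_length", "M2S2MH"),
    ("weak_evidence", "MT2-to"),
]
_ALIGNMENT = [
    ("alt_softclip", "MF"),
    ("map_quality", "HC"),
    ("mq_rank_sum", "HC"),
    ("read_pos_rank_sum", "HC"),
    ("strand_bias", "HC"),
    ("mismatches_p", "MF"),
    ("clustered_events", "MT2-to"),
    ("haplotype_consistency", "MT2-to"),
    ("position_bias", "MT2-to"),
    ("multiallelic", "MT2-to"),
    ("slippage", "MT2-to"),
]
_GENOTYPE = [
    ("refhom_likelihood", "MF"),
    ("mosaic_likelihood", "MF"),
    ("het_likelihood", "MF"),
    ("qual", "HC"),
    ("quality_by_depth", "HC"),
    ("score2", "DM"),
    ("score3", "DM"),
    ("germq", "MT2-to"),
    ("tlod", "MT2-to"),
    ("somatic_evs", "STK2"),
    ("mosaic_probability", "MH"),
    ("germline_likelihood", "HC"),
    ("allele_posterior", "HC"),
]

_CATEGORY_SIZES = {"sequencing": 20, "alignment": 15, "genotype": 13}


def default_registry() -> pd.DataFrame:
    """The shipped 48-feature registry (20 sequencing / 15 alignment / 13
    genotype). Slots beyond the explicitly named features carry synthetic
    placeholder names (``<category>_feature_NN``)."""
    rows = []
    for category, named in (
        ("sequencing", _SEQUENCING),
        ("alignment", _ALIGNMENT),
        ("genotype", _GENOTYPE),
    ):
        size = _CATEGORY_SIZES[category]
        if len(named) > size:
            raise RuntimeError(f"too many named {category} features")
        for name, source in named:
            rows.append({"name": name, "category": category, "source": source})
        for i in range(len(named), size):
            rows.append(
                {
                    "name": f"{category}_feature_{i + 1:02d}",
                    "category": category,
                    "source": "synthetic",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureAUC:
    feature: str
    fp_class: str
    auc: float
    orientation: int  # +1: TP values higher; -1: flipped
    n_tp: int
    n_fp: int


def rank_auc(pos_values, neg_values) -> float:
    """Empirical ROC AUC as the normalized Mann-Whitney U statistic; tied
    values contribute one half."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one value in each class")
    u = mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (pos.size * neg.size)


def feature_auc(
    classified: ClassifiedCalls, feature: str, fp_class: str = "nonvariant"
) -> FeatureAUC:
    """Discrimination AUC of one feature between TPs and one FP class.

    Orientation is auto-flipped so the reported AUC is >= 0.5 (feature
    polarity differs across callers and only the magnitude is comparable);
    the flip is recorded. Calls lacking the feature are skipped.
    """
    tp_vals = [c.features[feature] for c, _ in classified.tp if feature in c.features]
    fp_calls = (
        classified.fp_nonvariant if fp_class == "nonvariant" else classified.fp_germline
    )
    fp_vals = [c.features[feature] for c in fp_calls if feature in c.features]
    if not tp_vals or not fp_vals:
        raise ValueError(
            f"feature {feature!r}: need >=1 TP and >=1 {fp_class} FP carrying it"
        )
    auc = rank_auc(tp_vals, fp_vals)
    orientation = 1
    if auc < 0.5:
        auc, orientation = 1.0 - auc, -1
    return FeatureAUC(feature, fp_class, auc, orientation, len(tp_vals), len(fp_vals))


def category_compare(auc_group_a, auc_group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two AUC groups.

    Exact enumeration when the combined sample is small (n <= 20), normal
    approximation otherwise. Returns (U statistic, p-value).
    """
    a = np.asarray(auc_group_a, dtype=float)
    b = np.asarray(auc_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if a.size + b.size <= 20 else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def filter_efficiency(
    callset_default,
    callset_disabled,
    truth,
    w=1.0,
    region=None,
    vtype: str | None = None,
) -> dict:
    """Efficiency of one post-filter from its default and filter-disabled
    call sets.

    A filter may only remove calls, so the default set must be a subset of
    the disabled set. Reports the extra TPs/FPs the filter had removed and
    delta_f1 = F1(default) - F1(disabled); a positive value means the filter
    helps, and negative values are possible.
    """
    w = getattr(w, "w", w)
    if not callset_default.sites <= callset_disabled.sites:
        raise ValueError("default call set is not a subset of the disabled one")
    cls_def = classify_calls(callset_default, truth, region=region, vtype=vtype)
    cls_dis = classify_calls(callset_disabled, truth, region=region, vtype=vtype)

    def overall_f1(cls: ClassifiedCalls) -> float:
        sens = cls.n_tp / cls.n_positives if cls.n_positives else float("nan")
        prec = (
            recalibrated_precision(cls.n_tp, cls.n_fp, w)
            if cls.n_tp + cls.n_fp > 0
            else float("nan")
        )
        return f1_score(sens, prec)

    extra_tp = cls_dis.n_tp - cls_def.n_tp
    extra_fp = cls_dis.n_fp - cls_def.n_fp
    return {
        "extra_tp": int(extra_tp),
        "extra_fp": int(extra_fp),
        "f1_default": overall_f1(cls_def),
        "f1_disabled": overall_f1(cls_dis),
        "delta_f1": overall_f1(cls_def) - overall_f1(cls_dis),
    }
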