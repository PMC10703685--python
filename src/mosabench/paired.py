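"""Paired-sample evaluation.

A pair of mixtures carries truth-shared variants (positive in both samples,
generally at different VAFs) and sample-specific variants. Detection is
evaluated for both classes, including: misclassification of truth-shared
variants as sample-specific (called in exactly one sample), VAF-balance
stratification (a shared variant is balanced when the two VAFs differ by
less than twofold), the 4x4 = 16-area landscape over the pair's VAF space,
and an overall F1 normalized so every VAF bin contributes equal positive
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from ._utils import Site, site_key
from .metrics import f1_score, recalibrated_precision

__all__ = [
    "PairedCallSet",
    "combine_single_genotyping",
    "enumerate_pairs",
    "shared_evaluation_total",
    "PairedClassification",
    "classify_paired",
    "balance_class",
    "AREA_EDGES",
    "AREA_LABELS",
    "N_AREAS",
    "area_assign",
    "paired_area_metrics",
    "area_landscape",
    "overall_f1_normalized",
]

#: Per-sample VAF range groups (percent): very_low <=5, low (5,10],
#: medium (10,25], high >25. Their product gives the 16 pair areas.
AREA_EDGES = (5.0, 10.0, 25.0)
AREA_LABELS = ("very_low", "low", "medium", "high")
N_AREAS = len(AREA_LABELS) ** 2


@dataclass
class PairedCallSet:
    """Shared and sample-specific calls of a sample pair.

    ``shared`` maps site -> (case call | None, control call | None); rescued
    sites may carry evidence from only one side. ``mode`` records whether the
    sets came from single genotyping (per-sample calling + set operations)
    or joint genotyping.
    """

    case_id: str
    control_id: str
    shared: dict = field(default_factory=dict)
    case_specific: dict = field(default_factory=dict)
    control_specific: dict = field(default_factory=dict)
    mode: str = "single"

    def __post_init__(self):
        overlap = set(self.shared) & (
            set(self.case_specific) | set(self.control_specific)
        )
        if overlap:
            raise ValueError(f"{len(overlap)} sites both shared and specific")

    @property
    def shared_sites(self) -> set:
        return set(self.shared)

    def shared_pair_vafs(self, site: Site) -> tuple[float, float]:
        """Observed (case, control) VAFs of a shared call; a side without a
        call (e.g. rescued) borrows the other side's VAF."""
        case, ctrl = self.shared[site]
        cv = case.observed_vaf if case is not None else ctrl.observed_vaf
        tv = ctrl.observed_vaf if ctrl is not None else case.observed_vaf
        return cv, tv


def combine_single_genotyping(calls_case, calls_ctrl) -> PairedCallSet:
    """Shared = intersection, specific = set differences, of the two per-sample
    call sets (single-genotyping composition)."""
    by_site_case = {c.site: c for c in calls_case.calls}
    by_site_ctrl = {c.site: c for c in calls_ctrl.calls}
    shared = {
        s: (by_site_case[s], by_site_ctrl[s])
        for s in by_site_case.keys() & by_site_ctrl.keys()
    }
    case_specific = {
        s: c for s, c in by_site_case.items() if s not in by_site_ctrl
    }
    ctrl_specific = {
        s: c for s, c in by_site_ctrl.items() if s not in by_site_case
    }
    return PairedCallSet(
        calls_case.sample_id, calls_ctrl.sample_id,
        shared, case_specific, ctrl_specific, mode="single",
    )


def enumerate_pairs(design, scheme: str = "case-control"):
    """Mixture pair/triple enumeration.

    all-pairs: unordered pairs of all mixtures (C(39,2) = 741 by default);
    case-control: one case from M3 against one control from M1 u M2
    (18 x 21 = 378); triples: one mixture from each category
    (9 x 12 x 18 = 1,944).
    """
    by_cat = {cat: design.by_category(cat) for cat in design.categories}
    for cat, members in by_cat.items():
        if not members:
            raise ValueError(f"category {cat} is empty")
    ids = {cat: [m.mixture_id for m in members] for cat, members in by_cat.items()}
    if scheme == "all-pairs":
        all_ids = [m.mixture_id for m in design.mixtures]
        return list(combinations(all_ids, 2))
    if scheme == "case-control":
        controls = ids.get("M1", []) + ids.get("M2", [])
        return [(case, ctrl) for case in ids.get("M3", []) for ctrl in controls]
    if scheme == "triples":
        return list(product(ids.get("M1", []), ids.get("M2", []), ids.get("M3", [])))
    raise ValueError(f"unknown pairing scheme {scheme!r}")


def shared_evaluation_total(design, per_pair_counts: dict) -> int:
    """Total shared-variant evaluations across all case-control pairs, given
    per-pair shared-site counts keyed by (case category, control category)."""
    pairs = enumerate_pairs(design, "case-control")
    total = 0
    for case, ctrl in pairs:
        key = (design.get(case).category, design.get(ctrl).category)
        total += per_pair_counts[key]
    return total


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #

def shared_truth_table(truth_case, truth_ctrl) -> pd.DataFrame:
    """Truth-shared sites with both truth VAFs (inner join on site identity)."""
    a = truth_case.positives.copy()
    b = truth_ctrl.positives.copy()
    a["site"] = [site_key(r.chrom, r.pos, r.ref, r.alt) for r in a.itertuples()]
    b["site"] = [site_key(r.chrom, r.pos, r.ref, r.alt) for r in b.itertuples()]
    merged = a.merge(
        b[["site", "truth_vaf"]], on="site", suffixes=("_case", "_ctrl")
    )
    return merged.rename(
        columns={"truth_vaf_case": "vaf_case", "truth_vaf_ctrl": "vaf_ctrl"}
    )


@dataclass
class PairedClassification:
    """Outcome bookkeeping for one pair.

    shared_tp/misclassified/shared_fn partition the truth-shared sites;
    misclassified sites (called in exactly one sample) count against shared
    sensitivity and as false positives of the specific class. ``shared_fp``
    holds called-shared sites that are not truth-shared, split by negative
    class.
    """

    shared_tp: list = field(default_factory=list)       # (site, vaf_case, vaf_ctrl)
    misclassified: list = field(default_factory=list)   # (site, vaf_case, vaf_ctrl)
    shared_fn: list = field(default_factory=list)       # (site, vaf_case, vaf_ctrl)
    shared_fp: list = field(default_factory=list)       # (site, class, vaf_case, vaf_ctrl)
    specific_tp_case: int = 0
    specific_fn_case: int = 0
    specific_tp_ctrl: int = 0
    specific_fn_ctrl: int = 0
    specific_fp: int = 0

    @property
    def n_shared_truth(self) -> int:
        return len(self.shared_tp) + len(self.misclassified) + len(self.shared_fn)

    @property
    def shared_sensitivity(self) -> float:
        n = self.n_shared_truth
        return len(self.shared_tp) / n if n else float("nan")

    @property
    def misclassification_proportion(self) -> float:
        n = self.n_shared_truth
        return len(self.misclassified) / n if n else float("nan")


def classify_paired(
    paired: PairedCallSet, truth_case, truth_ctrl
) -> PairedClassification:
    """Score a paired call set against the pair's truth sets.

    A truth-shared site called in both samples is a shared TP; called in
    exactly one, misclassified-as-specific; called in neither, a shared FN.
    Sample-specific truth positives are scored against the specific call
    sets analogously, and specific calls at sites that are not specific
    truth (including misclassified shared truth) count as specific FPs.
    """
    if truth_case.region.intervals != truth_ctrl.region.intervals:
        raise ValueError("truth pair regions are inconsistent")
    st = shared_truth_table(truth_case, truth_ctrl)
    shared_truth = dict(zip(st["site"], zip(st["vaf_case"], st["vaf_ctrl"])))
    setb = truth_case.set_b_positions()

    out = PairedClassification()
    called_any = (
        set(paired.shared) | set(paired.case_specific) | set(paired.control_specific)
    )
    for site, (vc, vt) in shared_truth.items():
        if site in paired.shared:
            out.shared_tp.append((site, vc, vt))
        elif site in called_any:
            out.misclassified.append((site, vc, vt))
        else:
            out.shared_fn.append((site, vc, vt))

    for site in paired.shared:
        if site not in shared_truth:
            cls = "germline" if (site[0], site[1]) in setb else "nonvariant"
            vc, vt = paired.shared_pair_vafs(site)
            out.shared_fp.append((site, cls, vc, vt))

    def specific_truth(truth_self, truth_other):
        other = {
            site_key(r.chrom, r.pos, r.ref, r.alt)
            for r in truth_other.positives.itertuples()
        }
        return {
            site_key(r.chrom, r.pos, r.ref, r.alt)
            for r in truth_self.positives.itertuples()
        } - other

    spec_case = specific_truth(truth_case, truth_ctrl)
    spec_ctrl = specific_truth(truth_ctrl, truth_case)
    out.specific_tp_case = len(spec_case & set(paired.case_specific))
    out.specific_fn_case = len(spec_case) - out.specific_tp_case
    out.specific_tp_ctrl = len(spec_ctrl & set(paired.control_specific))
    out.specific_fn_ctrl = len(spec_ctrl) - out.specific_tp_ctrl
    out.specific_fp = len(set(paired.case_specific) - spec_case) + len(
        set(paired.control_specific) - spec_ctrl
    )
    return out


# --------------------------------------------------------------------------- #
# balance / areas
# --------------------------------------------------------------------------- #

def balance_class(
    vaf_case: float, vaf_ctrl: float, fold: float = 2.0,
    boundary: str = "unbalanced",
) -> str:
    """'balanced' when the two VAFs differ by less than ``fold``-fold.

    An exactly ``fold``-fold difference is assigned by ``boundary``
    (default unbalanced). A shared variant must have support in both
    samples, so zero VAFs are rejected.
    """
    if vaf_case <= 0 or vaf_ctrl <= 0:
        raise ValueError("shared variant must have positive VAF in both samples")
    ratio = max(vaf_case, vaf_ctrl) / min(vaf_case, vaf_ctrl)
    if ratio > fold:
        return "unbalanced"
    if ratio == fold:
        return boundary
    return "balanced"


def area_assign(vaf_case: float, vaf_ctrl: float) -> tuple[int, int]:
    """16-area assignment: per-sample group index 0-3 over the VAF ranges
    (<=5, (5,10], (10,25], >25 percent). VAFs must lie in (0, 100]."""

    def group(v: float) -> int:
        if not 0 < v <= 100:
            raise ValueError(f"VAF {v} outside (0, 100]")
        return int(np.searchsorted(np.asarray(AREA_EDGES), v, side="left"))

    return group(vaf_case), group(vaf_ctrl)


def paired_area_metrics(cls: PairedClassification, w=1.0) -> pd.DataFrame:
    """Per-area shared sensitivity, recalibrated precision and F1.

    Truth-shared positives index areas by their truth VAF pair; shared FPs,
    having no truth VAF, by their observed VAF pair. Areas to which no
    positive controls could be assigned are NA, not zero.
    """
    w = getattr(w, "w", w)
    tp = np.zeros((4, 4), dtype=int)
    fn = np.zeros((4, 4), dtype=int)
    fp = np.zeros((4, 4), dtype=int)
    for _, vc, vt in cls.shared_tp:
        tp[area_assign(100 * vc, 100 * vt)] += 1
    for _, vc, vt in cls.misclassified + cls.shared_fn:
        fn[area_assign(100 * vc, 100 * vt)] += 1
    for _, _c, vc, vt in cls.shared_fp:
        fp[area_assign(100 * vc, 100 * vt)] += 1
    rows = []
    for i, ci in enumerate(AREA_LABELS):
        for j, cj in enumerate(AREA_LABELS):
            n_pos = tp[i, j] + fn[i, j]
            sens = tp[i, j] / n_pos if n_pos else float("nan")
            prec = (
                recalibrated_precision(tp[i, j], fp[i, j], w)
                if tp[i, j] + fp[i, j] > 0
                else float("nan")
            )
            rows.append(
                {
                    "area_case": ci,
                    "area_ctrl": cj,
                    "n_positives": n_pos,
                    "tp": tp[i, j],
                    "fn": fn[i, j],
                    "fp": fp[i, j],
                    "sensitivity": sens,
                    "recal_precision": prec,
                    "f1": f1_score(sens, prec) if n_pos else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def area_landscape(metrics_by_caller: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Best caller per area by F1 (ties: higher sensitivity, then fewer FPs);
    NA where no caller had assignable positives."""
    names = list(metrics_by_caller)
    first = metrics_by_caller[names[0]]
    rows = []
    for idx in range(len(first)):
        best_name, best_key = None, None
        for name in names:
            row = metrics_by_caller[name].iloc[idx]
            if np.isnan(row["f1"]):
                continue
            key = (row["f1"], row["sensitivity"], -row["fp"])
            if best_key is None or key > best_key:
                best_name, best_key = name, key
        rows.append(
            {
                "area_case": first.iloc[idx]["area_case"],
                "area_ctrl": first.iloc[idx]["area_ctrl"],
                "best_caller": best_name,
                "best_f1": best_key[0] if best_key else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def overall_f1_normalized(bin_counts: pd.DataFrame, w=1.0):
    """Overall F1 after equalizing the positive-control weight of every bin.

    ``bin_counts`` needs columns tp, fn, fp. Each bin with positives is
    rescaled so its positives carry unit weight (tp+fn -> 1) and its FPs are
    scaled by the same factor; FPs in bins without positives cannot be
    rescaled and are excluded (their count is reported). Returns a dict with
    f1, sensitivity, precision and n_unbinnable_fp.
    """
    w = getattr(w, "w", w)
    tp_n = fn_n = fp_n = 0.0
    n_bins = 0
    unbinnable = 0
    for row in bin_counts.itertuples():
        n_pos = row.tp + row.fn
        if n_pos == 0:
            unbinnable += int(row.fp)
            continue
        lam = 1.0 / n_pos
        tp_n += row.tp * lam
        fn_n += row.fn * lam
        fp_n += row.fp * lam
        n_bins += 1
    if n_bins == 0:
        return {
            "f1": float("nan"), "sensitivity": float("nan"),
            "precision": float("nan"), "n_unbinnable_fp": unbinnable,
        }
    sens = tp_n / (tp_n + fn_n)
    prec = recalibrated_precision(tp_n, fp_n, w) if tp_n + fp_n > 0 else float("nan")
    f1 = f1_score(sens, prec) if not np.isnan(prec) else 0.0
    if tp_n == 0 and fp_n == 0:
        f1 = 0.0  # empty call set
    return {
        "f1": f1, "sensitivity": sens, "precision": prec,
        "n_unbinnable_fp": unbinnable,
    }
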