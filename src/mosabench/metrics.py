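"""Single-sample evaluation: truth matching, VAF bins, recalibrated precision,
AUPRC and the binomial detection upper limit.

Because a mixture-derived truth set carries positives at a density orders of
magnitude above the genomic background (~1 mosaic SNV and ~0.1 INDEL per Mb),
naive precision would overweight true positives. Precision is therefore
recalibrated with a weight

    w = expected positive controls / positive controls in the data
    precision = (TP * w) / (TP * w + FP)

computed once per variant type over the whole region and applied to every bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._utils import Site, site_key

log = logging.getLogger(__name__)

__all__ = [
    "BinScheme",
    "SNV_BINS",
    "INDEL_BINS",
    "assign_bin",
    "ClassifiedCalls",
    "classify_calls",
    "RecalWeight",
    "recalibration_weight",
    "recalibrated_precision",
    "f1_score",
    "binned_metrics",
    "auprc",
    "detection_upper_limit",
]


# --------------------------------------------------------------------------- #
# VAF bins
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class BinScheme:
    """Ordered VAF breakpoints in percent; intervals are [lo, hi), with the
    first bin [0, edge0) and the last [edge-1, 100]."""

    vtype: str
    edges: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size == 0 or not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    @property
    def labels(self) -> list[str]:
        edges = list(self.edges)
        labels = [f"<{edges[0]:g}"]
        labels += [f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
        labels.append(f">={edges[-1]:g}")
        return labels


#: Eight SNV bins chosen so each holds roughly equal numbers of positives.
SNV_BINS = BinScheme("SNV", (1, 2, 3, 4, 7.5, 9.6, 25))
#: Seven INDEL bins on the same principle.
INDEL_BINS = BinScheme("INDEL", (1, 2, 4, 5, 9.6, 16))

DEFAULT_SCHEMES = {"SNV": SNV_BINS, "INDEL": INDEL_BINS}


def assign_bin(vaf: float, scheme: BinScheme) -> int:
    """Bin index of a VAF given in percent. Bins are left-closed."""
    arr = np.asarray(vaf, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError(f"VAF {vaf} outside [0, 100]")
    idx = np.searchsorted(np.asarray(scheme.edges), arr, side="right")
    return int(idx) if np.isscalar(vaf) or arr.ndim == 0 else idx


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #

@dataclass
class ClassifiedCalls:
    """Exhaustive, exclusive labelling of a call set against a truth set.

    tp: (call, truth_vaf) pairs; fp_nonvariant / fp_germline: calls;
    fn: (site, vtype, truth_vaf) tuples for missed positives.
    """

    tp: list = field(default_factory=list)
    fp_nonvariant: list = field(default_factory=list)
    fp_germline: list = field(default_factory=list)
    fn: list = field(default_factory=list)
    n_dropped_outside: int = 0
    n_rejected: int = 0
    region_mbp: float = float("nan")

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp_nonvariant) + len(self.fp_germline)

    @property
    def n_fn(self) -> int:
        return len(self.fn)

    @property
    def n_positives(self) -> int:
        return self.n_tp + self.n_fn

    def tp_sites(self) -> set:
        return {c.site for c, _ in self.tp}

    def fp_sites(self, fp_class: str) -> set:
        calls = self.fp_nonvariant if fp_class == "nonvariant" else self.fp_germline
        return {c.site for c in calls}


def classify_calls(callset, truth, region=None, vtype: str | None = None) -> ClassifiedCalls:
    """Label every call TP / FP_nonvariant / FP_germline and every missed
    positive FN, restricted to the high-confidence region.

    A call is a TP when its normalized (chrom, pos, ref, alt) matches a
    positive exactly; a call at a Set B locus is a germline false positive;
    any other in-region call is a nonvariant false positive (this includes
    wrong-alt calls at positive sites). Calls outside the region are dropped
    and counted. Malformed records are rejected per-record and logged.
    """
    region = region if region is not None else truth.region
    pos_df = truth.positives
    if vtype is not None:
        pos_df = pos_df[pos_df["vtype"] == vtype]
    truth_map: dict[Site, float] = {}
    truth_vtype: dict[Site, str] = {}
    for r in pos_df.itertuples():
        key = site_key(r.chrom, r.pos, r.ref, r.alt)
        truth_map[key] = r.truth_vaf
        truth_vtype[key] = r.vtype
    setb_loci = truth.set_b_positions()

    out = ClassifiedCalls(region_mbp=region.mbp)
    matched: set = set()
    seen: set = set()
    for call in callset.calls:
        if vtype is not None and call.vtype != vtype:
            continue
        try:
            key = call.site
        except ValueError:
            out.n_rejected += 1
            log.warning("rejecting malformed call at %s:%s", call.chrom, call.pos)
            continue
        chrom, pos = key[0], key[1]
        if not region.contains(chrom, pos):
            out.n_dropped_outside += 1
            continue
        if key in seen:
            continue  # duplicate record at the same site
        seen.add(key)
        if key in truth_map:
            matched.add(key)
            out.tp.append((call, truth_map[key]))
        elif (chrom, pos) in setb_loci:
            out.fp_germline.append(call)
        else:
            out.fp_nonvariant.append(call)
    for key, tv in truth_map.items():
        if key not in matched:
            out.fn.append((key, truth_vtype[key], tv))
    return out


# --------------------------------------------------------------------------- #
# recalibrated precision / binned metrics
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RecalWeight:
    w: float
    expected_density: float  # variants per Mbp
    region_mbp: float
    n_positives: int


def recalibration_weight(
    expected_density: float, region_mbp: float, n_positives: int
) -> RecalWeight:
    """w = expected positive density x region size / observed positives."""
    if expected_density <= 0 or region_mbp <= 0:
        raise ValueError("density and region size must be positive")
    if n_positives <= 0:
        raise ValueError("cannot recalibrate with zero positives")
    w = expected_density * region_mbp / n_positives
    return RecalWeight(w, expected_density, region_mbp, n_positives)


def recalibrated_precision(tp: int, fp: int, w: float) -> float:
    """(TP*w) / (TP*w + FP); NaN when no calls exist to assess."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0:
        return float("nan")
    return (tp * w) / (tp * w + fp)


def f1_score(sensitivity: float, precision: float) -> float:
    if np.isnan(sensitivity) or np.isnan(precision):
        return float("nan")
    if sensitivity + precision == 0:
        return 0.0
    return 2 * sensitivity * precision / (sensitivity + precision)


def _as_w(w) -> float:
    return w.w if isinstance(w, RecalWeight) else float(w)


def binned_metrics(
    classified: ClassifiedCalls, scheme: BinScheme, w, region_mbp: float | None = None
) -> pd.DataFrame:
    """Per-VAF-bin sensitivity, recalibrated precision, F1 and FP/Mbp.

    Positives (TP/FN) are binned by truth VAF; false positives, which have no
    truth VAF, by observed VAF. Bins with neither positives nor calls yield
    missing values, not zeros.
    """
    w = _as_w(w)
    region_mbp = classified.region_mbp if region_mbp is None else region_mbp
    nb = scheme.n_bins
    tp_b = np.zeros(nb, dtype=int)
    fn_b = np.zeros(nb, dtype=int)
    fp_nv_b = np.zeros(nb, dtype=int)
    fp_g_b = np.zeros(nb, dtype=int)
    for _, tv in classified.tp:
        tp_b[assign_bin(100 * tv, scheme)] += 1
    for _, _, tv in classified.fn:
        fn_b[assign_bin(100 * tv, scheme)] += 1
    for call in classified.fp_nonvariant:
        fp_nv_b[assign_bin(100 * call.observed_vaf, scheme)] += 1
    for call in classified.fp_germline:
        fp_g_b[assign_bin(100 * call.observed_vaf, scheme)] += 1

    rows = []
    for b in range(nb):
        n_pos = tp_b[b] + fn_b[b]
        fp = fp_nv_b[b] + fp_g_b[b]
        sens = tp_b[b] / n_pos if n_pos > 0 else float("nan")
        prec = recalibrated_precision(tp_b[b], fp, w) if tp_b[b] + fp > 0 else float("nan")
        rows.append(
            {
                "bin": scheme.labels[b],
                "n_positives": n_pos,
                "tp": tp_b[b],
                "fn": fn_b[b],
                "fp_nonvariant": fp_nv_b[b],
                "fp_germline": fp_g_b[b],
                "sensitivity": sens,
                "recal_precision": prec,
                "f1": f1_score(sens, prec),
                "fp_per_mbp": fp / region_mbp if region_mbp > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# AUPRC
# --------------------------------------------------------------------------- #

def auprc(classified: ClassifiedCalls, w=1.0, score_of=None) -> float:
    """Area under the recalibrated precision-recall curve.

    The curve is swept over call-score thresholds (ties grouped); precision is
    recalibrated with ``w`` at every threshold and the area accumulated
    step-wise (average-precision style), avoiding optimistic interpolation.
    Recall is measured against all truth positives (TP + FN).
    """
    w = _as_w(w)
    if score_of is None:
        score_of = lambda call: call.score  # noqa: E731
    labeled = [(score_of(c), 1) for c, _ in classified.tp]
    labeled += [(score_of(c), 0) for c in classified.fp_nonvariant]
    labeled += [(score_of(c), 0) for c in classified.fp_germline]
    bad = [s for s, _ in labeled if not np.isfinite(s)]
    if bad:
        raise ValueError(f"{len(bad)} call(s) with non-finite scores")
    n_pos = classified.n_positives
    if n_pos == 0 or not labeled:
        return float("nan")
    labeled.sort(key=lambda x: -x[0])
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(labeled):
        j = i
        while j < len(labeled) and labeled[j][0] == labeled[i][0]:
            tp += labeled[j][1]
            fp += 1 - labeled[j][1]
            j += 1
        recall = tp / n_pos
        precision = (tp * w) / (tp * w + fp) if tp + fp > 0 else 0.0
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


# --------------------------------------------------------------------------- #
# detection upper limit
# --------------------------------------------------------------------------- #

def detection_upper_limit(depth: int, vaf: float, k_min: int = 3) -> float:
    """Theoretical ceiling on sensitivity from mutant-allele depletion alone:
    P(X >= k_min) with X ~ Binomial(depth, vaf) — the chance that at least
    ``k_min`` mutant reads are present at all."""
    if depth < 1 or k_min < 1:
        raise ValueError("depth and k_min must be >= 1")
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must lie in [0, 1]")
    return float(binom.sf(k_min - 1, depth, vaf))
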