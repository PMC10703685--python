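"""Accuracy-improvement strategies.

Four procedures that reuse existing call sets rather than new algorithms:
an instant per-VAF-area ensemble that keeps each area's locally best caller;
the rescue re-genotyping of one-sample-only calls from the other sample's
read evidence; developmental-lineage filtering of a distal pair's shared
calls against a lineage-proximal third sample; and foreign-feature
filtering, where a discriminative feature computed by one caller thresholds
another caller's call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._utils import site_key
from .callers import CallSet
from .paired import PairedCallSet, area_assign

__all__ = [
    "StrategyConfig",
    "compose_area_ensemble",
    "rescue",
    "lineage_filter",
    "foreign_feature_filter",
]


@dataclass
class StrategyConfig:
    """Bundled strategy parameters (YAML-loadable).

    ensemble maps 'i,j' area keys to caller names; rescue holds min_alt
    (reads) and min_vaf (fraction); foreign_filters is a list of
    (feature, direction, threshold) with direction remove_above/remove_below.
    """

    ensemble: dict = field(default_factory=dict)
    rescue_min_alt: int = 2
    rescue_min_vaf: float = 0.005
    foreign_filters: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "StrategyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(
            ensemble=d.get("ensemble", {}),
            rescue_min_alt=d.get("rescue", {}).get("min_alt", 2),
            rescue_min_vaf=d.get("rescue", {}).get("min_vaf", 0.005),
            foreign_filters=[tuple(f) for f in d.get("foreign_filters", [])],
        )


def compose_area_ensemble(
    paired_by_caller: dict[str, PairedCallSet],
    area_map: dict[tuple[int, int], str],
    default_caller: str | None = None,
) -> PairedCallSet:
    """Compose a shared call set from the per-area mapped callers.

    Each shared call is routed to the area of its observed VAF pair; the
    ensemble keeps the call iff it belongs to the caller mapped to that
    area. Because the areas partition the pair's VAF space, the ensemble's
    per-area performance equals the mapped caller's by construction.
    """
    first = next(iter(paired_by_caller.values()))
    shared = {}
    for name, paired in paired_by_caller.items():
        for site in paired.shared:
            vc, vt = paired.shared_pair_vafs(site)
            area = area_assign(100 * vc, 100 * vt)
            owner = area_map.get(area, default_caller)
            if owner is None:
                raise ValueError(
                    f"area {area} contains calls but is unmapped and no "
                    "default caller was given"
                )
            if owner == name:
                shared[site] = paired.shared[site]
    return PairedCallSet(
        first.case_id, first.control_id, shared, {}, {}, mode="ensemble"
    )


def rescue(
    paired: PairedCallSet,
    ev_case,
    ev_ctrl,
    tier: int,
    min_alt: int = 2,
    min_vaf: float = 0.005,
) -> PairedCallSet:
    """Promote one-sample-only calls to shared when the other sample's read
    evidence supports them (alt reads >= min_alt and VAF >= min_vaf).

    Promotion-only: no call is removed and the union of shared and specific
    sites is unchanged. Raises if evidence lacks a queried site.
    """
    shared = dict(paired.shared)
    case_specific, ctrl_specific = {}, {}
    missing = []
    for specific, other_ev, keep in (
        (paired.case_specific, ev_ctrl, case_specific),
        (paired.control_specific, ev_case, ctrl_specific),
    ):
        for site, call in specific.items():
            chrom, pos = site[0], site[1]
            try:
                depth, alt = other_ev.lookup(tier, chrom, pos)
            except KeyError:
                missing.append(site)
                continue
            vaf = alt / depth if depth > 0 else 0.0
            if alt >= min_alt and vaf >= min_vaf:
                if specific is paired.case_specific:
                    shared[site] = (call, None)
                else:
                    shared[site] = (None, call)
            else:
                keep[site] = call
    if missing:
        raise KeyError(f"no evidence at {len(missing)} site(s): {missing[:5]}")
    return PairedCallSet(
        paired.case_id, paired.control_id, shared,
        case_specific, ctrl_specific, mode=paired.mode + "+rescue",
    )


def lineage_filter(shared_calls: dict, callset_c: CallSet) -> dict:
    """Filter a distal pair's shared calls against a lineage-proximal third
    sample: keep exactly the sites present in the third sample's call set.

    Developmentally, a variant truly shared by two distal lineages must have
    arisen before their split and so should also appear in a sample that is
    proximal to both; absence there marks a likely false call.
    """
    c_sites = callset_c.sites
    return {site: v for site, v in shared_calls.items() if site in c_sites}


def foreign_feature_filter(
    callset: CallSet,
    feature: str,
    direction: str,
    threshold: float,
    truth=None,
) -> tuple[CallSet, dict]:
    """Threshold a call set on a feature imported from another caller.

    Calls carrying the feature and violating the threshold are removed;
    calls lacking it are retained and counted unadjustable. When a truth set
    is supplied, the report includes the removed TP/FP fractions among
    adjustable calls of each class.
    """
    if direction not in ("remove_above", "remove_below"):
        raise ValueError(f"unknown direction {direction!r}")
    if not any(feature in c.features for c in callset.calls):
        raise ValueError(f"feature {feature!r} absent from every call")
    kept, removed = [], []
    n_unadjustable = 0
    for call in callset.calls:
        value = call.features.get(feature)
        if value is None:
            kept.append(call)
            n_unadjustable += 1
        elif (direction == "remove_above" and value > threshold) or (
            direction == "remove_below" and value < threshold
        ):
            removed.append(call)
        else:
            kept.append(call)
    report = {
        "feature": feature,
        "direction": direction,
        "threshold": threshold,
        "n_input": len(callset.calls),
        "n_removed": len(removed),
        "n_kept": len(kept),
        "n_unadjustable": n_unadjustable,
    }
    if truth is not None:
        truth_sites = {
            site_key(r.chrom, r.pos, r.ref, r.alt)
            for r in truth.positives.itertuples()
        }
        adj = [c for c in callset.calls if feature in c.features]
        adj_tp = sum(1 for c in adj if c.site in truth_sites)
        adj_fp = len(adj) - adj_tp
        rem_tp = sum(1 for c in removed if c.site in truth_sites)
        rem_fp = len(removed) - rem_tp
        report["removed_tp_fraction"] = rem_tp / adj_tp if adj_tp else float("nan")
        report["removed_fp_fraction"] = rem_fp / adj_fp if adj_fp else float("nan")
        report["n_removed_tp"] = rem_tp
        report["n_removed_fp"] = rem_fp
    return CallSet(callset.sample_id, kept, callset.region), report
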