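"""Parametric caller emulation.

Real mosaic callers are outside this package's scope; instead a caller is an
operating profile — per-VAF-bin sensitivities by depth tier, false-positive
rates per Mbp at nonvariant (Set A) and germline (Set B) loci, a monotone
score model, and binormal feature models with chosen discrimination AUCs.
Emulated call sets have known generating parameters, so the evaluation and
strategy layers can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit, ndtri

from ._utils import Site, as_rng, random_other_bases, site_key
from .metrics import DEFAULT_SCHEMES, BinScheme, assign_bin
from .truthsim import SiteEvidence, TruthSet

__all__ = [
    "FeatureModel",
    "CallerProfile",
    "Call",
    "CallSet",
    "binormal_mu",
    "binormal_feature",
    "emulate_caller",
    "emulate_pair",
]


@dataclass(frozen=True)
class FeatureModel:
    """A per-call feature separating TPs from one FP class with a target AUC.

    TP values ~ Normal(mu, 1) with mu = sqrt(2) * Phi^-1(target_auc); FP
    values ~ Normal(0, 1), so the expected empirical ROC AUC against the
    targeted class equals ``target_auc`` exactly (binormal model).
    """

    name: str
    category: str  # sequencing | alignment | genotype
    fp_class: str = "nonvariant"  # which FP class the feature discriminates
    target_auc: float = 0.8

    def __post_init__(self):
        if not 0.5 <= self.target_auc <= 1.0:
            raise ValueError("target AUC must lie in [0.5, 1]")


@dataclass
class CallerProfile:
    """Operating profile of an emulated caller.

    ``sens`` may be a scalar (flat sensitivity), a mapping tier -> scalar, or
    a mapping (vtype, tier) -> per-bin array matching the bin scheme.
    FP rates are per Mbp of region, matching the magnitudes reported for
    real callers (order 0.1-1 FP/Mbp).
    """

    name: str
    sens: object = 0.8
    fp_rate_nv: float = 0.5
    fp_rate_g: float = 0.1
    score_a: float = 0.6
    score_b: float = 3.0
    score_noise: float = 0.3
    features: list[FeatureModel] = field(default_factory=list)
    joint: bool = False  # joint genotyping: one detection draw per shared site

    def __post_init__(self):
        if self.fp_rate_nv < 0 or self.fp_rate_g < 0:
            raise ValueError("FP rates must be non-negative")

    def sens_for(self, vtype: str, tier: int, scheme: BinScheme) -> np.ndarray:
        """Per-bin sensitivity vector for a variant type and depth tier."""
        s = self.sens
        if isinstance(s, dict):
            if (vtype, tier) in s:
                s = s[(vtype, tier)]
            elif tier in s:
                s = s[tier]
            else:
                raise KeyError(f"profile {self.name} has no sensitivity for tier {tier}")
        arr = np.asarray(s, dtype=float)
        if arr.ndim == 0:
            arr = np.full(scheme.n_bins, float(arr))
        if arr.size != scheme.n_bins:
            raise ValueError(
                f"profile {self.name}: {arr.size} sensitivities for "
                f"{scheme.n_bins} {vtype} bins"
            )
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("sensitivities must lie in [0, 1]")
        return arr

    @classmethod
    def from_yaml(cls, path) -> "CallerProfile":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        feats = [FeatureModel(**f) for f in d.pop("features", [])]
        return cls(features=feats, **d)


@dataclass(frozen=True)
class Call:
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    observed_vaf: float
    alt_count: int
    depth: int
    score: float
    features: dict = field(default_factory=dict)
    sample_id: str = ""

    @property
    def site(self) -> Site:
        return site_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CallSet:
    sample_id: str
    calls: list[Call]
    region: object = None

    @property
    def sites(self) -> set:
        return {c.site for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def subset(self, sites: set) -> "CallSet":
        return CallSet(
            self.sample_id, [c for c in self.calls if c.site in sites], self.region
        )


# --------------------------------------------------------------------------- #
# binormal features
# --------------------------------------------------------------------------- #

def binormal_mu(target_auc: float) -> float:
    """Class separation giving the target binormal AUC: mu = sqrt(2)*Phi^-1(auc)."""
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target AUC must lie in [0.5, 1)")
    return float(np.sqrt(2.0) * ndtri(target_auc))


def binormal_feature(is_tp, target_auc: float, seed) -> np.ndarray:
    """Feature values with expected empirical AUC = ``target_auc``:
    TP ~ N(mu, 1), FP ~ N(0, 1)."""
    rng = as_rng(seed)
    is_tp = np.asarray(is_tp, dtype=bool)
    mu = binormal_mu(target_auc)
    return rng.normal(0.0, 1.0, size=is_tp.size) + mu * is_tp


# --------------------------------------------------------------------------- #
# emulation
# --------------------------------------------------------------------------- #

def _score(profile: CallerProfile, alt_count, vaf, rng) -> np.ndarray:
    noise = rng.normal(0.0, profile.score_noise, size=np.size(alt_count))
    z = profile.score_a * np.log1p(alt_count) + profile.score_b * np.asarray(vaf) + noise
    return expit(z - 2.0)


def _attach_features(calls_meta, profile, rng):
    """calls_meta: list of (dict-kwargs, label) with label in {tp, nonvariant, germline}."""
    n = len(calls_meta)
    feature_values = {}
    for fm in profile.features:
        mu = binormal_mu(min(fm.target_auc, 1 - 1e-12))
        base = rng.normal(0.0, 1.0, size=n)
        shift = np.array([mu if lab == "tp" else 0.0 for _, lab in calls_meta])
        feature_values[fm.name] = base + shift
    calls = []
    for i, (kw, _lab) in enumerate(calls_meta):
        kw["features"] = {name: float(vals[i]) for name, vals in feature_values.items()}
        calls.append(Call(**kw))
    return calls


def _detection_probs(df, profile, tier, schemes) -> np.ndarray:
    p = np.zeros(len(df))
    for vtype in df["vtype"].unique():
        scheme = schemes[vtype]
        sens = profile.sens_for(vtype, tier, scheme)
        mask = (df["vtype"] == vtype).to_numpy()
        bins = assign_bin(100 * df.loc[mask, "true_af"].to_numpy(dtype=float), scheme)
        p[mask] = sens[bins]
    return p


def _emit_positive_calls(df, detected, sample_id):
    meta = []
    for row, hit in zip(df.itertuples(), detected):
        if not hit:
            continue
        meta.append(
            (
                dict(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    vtype=row.vtype,
                    observed_vaf=row.alt_count / row.depth,
                    alt_count=int(row.alt_count),
                    depth=int(row.depth),
                    score=float("nan"),
                    sample_id=sample_id,
                ),
                "tp",
            )
        )
    return meta


def _emit_fp_calls(df, rate, region_mbp, label, rng, sample_id):
    lam = rate * region_mbp
    n = int(rng.poisson(lam)) if lam > 0 else 0
    usable = df[df["depth"] > 0]
    n = min(n, len(usable))
    if n == 0:
        return []
    picked = usable.iloc[rng.choice(len(usable), size=n, replace=False)]
    if label == "nonvariant":
        alts = random_other_bases(rng, picked["ref"].to_numpy())
    else:
        alts = picked["alt"].to_numpy()
    meta = []
    for row, alt in zip(picked.itertuples(), alts):
        alt_count = max(int(row.alt_count), 1)
        meta.append(
            (
                dict(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=str(alt),
                    vtype="SNV" if len(row.ref) == len(str(alt)) == 1 else "INDEL",
                    observed_vaf=alt_count / row.depth,
                    alt_count=alt_count,
                    depth=int(row.depth),
                    score=float("nan"),
                    sample_id=sample_id,
                ),
                label,
            )
        )
    return meta


def _finalize(meta, profile, rng, sample_id, region):
    calls = _attach_features(meta, profile, rng)
    alt_counts = np.array([c.alt_count for c in calls]) if calls else np.array([])
    vafs = np.array([c.observed_vaf for c in calls]) if calls else np.array([])
    scores = _score(profile, alt_counts, vafs, rng) if calls else []
    calls = [
        Call(**{**c.__dict__, "score": float(s)}) for c, s in zip(calls, scores)
    ]
    return CallSet(sample_id, calls, region)


def emulate_caller(
    truth: TruthSet,
    evidence: SiteEvidence,
    profile: CallerProfile,
    tier: int,
    seed,
    schemes=None,
    sample_id: str | None = None,
) -> CallSet:
    """Emulate one caller on one sample.

    Each detectable positive (>= 1 alt read at the tier) is emitted with the
    profile's bin/tier sensitivity. False positives are drawn Poisson with
    mean rate x region Mbp and placed uniformly without replacement over
    covered Set A (nonvariant) and Set B (germline) sites. Deterministic
    given the seed.
    """
    rng = as_rng(seed)
    schemes = schemes or DEFAULT_SCHEMES
    sample_id = sample_id or truth.mixture_id
    df = evidence.at_tier(tier)

    pos = df[(df["vclass"] == "POS") & (df["alt_count"] >= 1) & (df["depth"] > 0)]
    p_detect = _detection_probs(pos, profile, tier, schemes)
    detected = rng.random(len(pos)) < p_detect
    meta = _emit_positive_calls(pos, detected, sample_id)

    region_mbp = truth.region.mbp
    meta += _emit_fp_calls(
        df[df["vclass"] == "SETA"], profile.fp_rate_nv, region_mbp, "nonvariant",
        rng, sample_id,
    )
    meta += _emit_fp_calls(
        df[df["vclass"] == "SETB"], profile.fp_rate_g, region_mbp, "germline",
        rng, sample_id,
    )
    return _finalize(meta, profile, rng, sample_id, truth.region)


def emulate_pair(
    truth_case: TruthSet,
    truth_ctrl: TruthSet,
    ev_case: SiteEvidence,
    ev_ctrl: SiteEvidence,
    profile: CallerProfile,
    tier: int,
    seed,
    schemes=None,
) -> tuple[CallSet, CallSet]:
    """Emulate a caller on a sample pair.

    With ``profile.joint`` set, detection of a truth-shared site is a single
    Bernoulli event for the pair, with success probability the mean of the
    two per-sample sensitivities — a joint model pools the evidence of both
    samples, so strong support in one sample compensates weak support in the
    other and detection is robust to VAF imbalance. Otherwise detection
    events are independent per sample, as when each sample is genotyped
    singly and call sets are combined afterwards.
    """
    rng = as_rng(seed)
    schemes = schemes or DEFAULT_SCHEMES
    per_sample = []
    for truth, ev in ((truth_case, ev_case), (truth_ctrl, ev_ctrl)):
        df = ev.at_tier(tier)
        pos = df[(df["vclass"] == "POS") & (df["alt_count"] >= 1) & (df["depth"] > 0)]
        p_detect = _detection_probs(pos, profile, tier, schemes)
        keys = [
            site_key(r.chrom, r.pos, r.ref, r.alt) for r in pos.itertuples()
        ]
        per_sample.append({"truth": truth, "ev": ev, "pos": pos,
                           "p": p_detect, "keys": keys})

    if profile.joint:
        p_by_key = [dict(zip(s["keys"], s["p"])) for s in per_sample]
        shared_keys = set(p_by_key[0]) & set(p_by_key[1])
        shared_u = {k: rng.random() for k in sorted(shared_keys)}
    else:
        shared_keys, shared_u, p_by_key = set(), {}, None

    out = []
    for s_idx, s in enumerate(per_sample):
        truth, pos, p_detect = s["truth"], s["pos"], s["p"].copy()
        u = rng.random(len(pos))
        if profile.joint:
            other = p_by_key[1 - s_idx]
            for i, key in enumerate(s["keys"]):
                if key in shared_keys:
                    u[i] = shared_u[key]
                    p_detect[i] = 0.5 * (s["p"][i] + other[key])
        detected = u < p_detect
        meta = _emit_positive_calls(pos, detected, truth.mixture_id)
        df = s["ev"].at_tier(tier)
        region_mbp = truth.region.mbp
        meta += _emit_fp_calls(
            df[df["vclass"] == "SETA"], profile.fp_rate_nv, region_mbp,
            "nonvariant", rng, truth.mixture_id,
        )
        meta += _emit_fp_calls(
            df[df["vclass"] == "SETB"], profile.fp_rate_g, region_mbp,
            "germline", rng, truth.mixture_id,
        )
        out.append(_finalize(meta, profile, rng, truth.mixture_id, truth.region))
    return out[0], out[1]
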