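"""Synthetic mixture-based reference standards for mosaic variant benchmarking.

The module emulates how a physical mosaic reference standard is built from
cell lines: six founder genotype sets carry mutually exclusive germline
variants; cumulative mixing of the founders (mimicking mosaic variant
acquisition during early development) turns those germline variants into
mosaic-like variants whose expected VAF is determined by the mixture
composition. Thirty-nine mixtures in three categories (M1/M2/M3 with
9/12/18 members) form the default design. Each mixture's truth set carries
positives across a wide VAF spectrum (roughly 0.5-56%, with ~70% of
positives below 10% VAF) together with two negative-control classes:
nonvariant reference-homozygous sites (Set A) and germline variant sites
shared by all founders (Set B). Read-count evidence is simulated at nested
depth tiers (125x/250x/500x/1,100x) with capture-style depth unevenness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import (
    as_rng,
    normalize_allele_pair,
    random_bases,
    random_other_bases,
    site_key,
)
from .regions import RegionSet

__all__ = [
    "SimConfig",
    "FounderVariant",
    "FounderPanel",
    "Mixture",
    "MixingStep",
    "MixtureDesign",
    "TruthSet",
    "SiteEvidence",
    "simulate_founders",
    "build_mixture_design",
    "expected_vaf",
    "generate_truth_sets",
    "sample_site_evidence",
    "simulate_benchmark",
]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class SimConfig:
    """Desk-scale defaults for the synthetic reference standard.

    The defaults are the study conditions: a 2 Mb region, ~2,000 positives
    across six founders, ~200,000 Set A and ~1,000 Set B negatives, depth
    tiers 125/250/500/1,100x, and a mixing schedule whose pooled truth-VAF
    spectrum satisfies the 0.5-56% range with ~70% of positives under 10%.
    Founder variant counts double with depth in the mixing tree so that
    founders added late (small fractions, low VAFs) contribute more sites,
    as in real cumulative mixing designs that enrich for low-VAF mosaics.
    """

    chrom: str = "chr1"
    region_bp: int = 2_000_000
    founder_variant_counts: tuple[int, ...] = (140, 140, 280, 280, 560, 560)
    snv_indel_ratio: float = 40.0  # ~345,552:8,706 at full scale
    het_fraction: float = 0.55
    category_sizes: dict = field(
        default_factory=lambda: {"M1": 9, "M2": 12, "M3": 18}
    )
    carriers: dict = field(
        default_factory=lambda: {
            "M1": (0, 1, 2, 4),
            "M2": (0, 1, 3, 5),
            "M3": (0, 1, 2, 3, 4, 5),
        }
    )
    mixing_ratio_range: tuple[float, float] = (0.45, 0.55)
    max_founder_fraction: float = 0.56
    n_set_a: int = 200_000
    n_set_b: int = 1_000
    set_b_hom_fraction: float = 0.2
    depth_tiers: tuple[int, ...] = (125, 250, 500, 1100)
    depth_dispersion: float = 10.0
    error_rate: float = 1e-3

    @property
    def region(self) -> RegionSet:
        return RegionSet.single(self.chrom, self.region_bp)

    @property
    def n_founders(self) -> int:
        return len(self.founder_variant_counts)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["founder_variant_counts"] = list(self.founder_variant_counts)
        d["mixing_ratio_range"] = list(self.mixing_ratio_range)
        d["depth_tiers"] = list(self.depth_tiers)
        d["carriers"] = {k: list(v) for k, v in self.carriers.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("founder_variant_counts", "mixing_ratio_range", "depth_tiers"):
            if key in d:
                d[key] = tuple(d[key])
        if "carriers" in d:
            d["carriers"] = {k: tuple(v) for k, v in d["carriers"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FounderVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # "SNV" | "INDEL"
    founder_id: int
    zygosity: str  # "het" | "hom"

    @property
    def dosage(self) -> int:
        return 1 if self.zygosity == "het" else 2

    @property
    def site(self):
        return site_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FounderPanel:
    """Six founder genotype sets with mutually exclusive variant sites."""

    n_founders: int
    variants: list[FounderVariant]
    region: RegionSet

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "vtype": [v.vtype for v in self.variants],
                "founder_id": [v.founder_id for v in self.variants],
                "zygosity": [v.zygosity for v in self.variants],
                "dosage": [v.dosage for v in self.variants],
            }
        )

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])


@dataclass(frozen=True)
class Mixture:
    mixture_id: str
    category: str
    composition: tuple[float, ...]  # one non-negative fraction per founder

    def __post_init__(self):
        comp = np.asarray(self.composition, dtype=float)
        if (comp < 0).any():
            raise ValueError(f"negative founder fraction in {self.mixture_id}")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions of {self.mixture_id} do not sum to 1")


@dataclass(frozen=True)
class MixingStep:
    """One cumulative-mixing step: a founder joins a category's lineage."""

    category: str
    depth: int  # 0 = lineage root
    founder_id: int


@dataclass
class MixtureDesign:
    mixtures: list[Mixture]
    carriers: dict[str, tuple[int, ...]]
    mixing_tree: list[MixingStep]

    def by_category(self, category: str) -> list[Mixture]:
        return [m for m in self.mixtures if m.category == category]

    @property
    def categories(self) -> list[str]:
        seen = []
        for m in self.mixtures:
            if m.category not in seen:
                seen.append(m.category)
        return seen

    def get(self, mixture_id: str) -> Mixture:
        for m in self.mixtures:
            if m.mixture_id == mixture_id:
                return m
        raise KeyError(mixture_id)


@dataclass
class TruthSet:
    """Per-mixture positives plus the shared negative controls.

    ``positives`` columns: chrom, pos, ref, alt, vtype, founder_id, truth_vaf.
    ``set_a`` columns: chrom, pos, ref (nonvariant, reference-homozygous sites).
    ``set_b`` columns: chrom, pos, ref, alt, vtype, vaf (germline sites carried
    by all founders, so mixing leaves their VAF at 0.5 or 1.0).
    """

    mixture_id: str
    category: str
    positives: pd.DataFrame
    set_a: pd.DataFrame
    set_b: pd.DataFrame
    region: RegionSet
    #: all panel sites with this mixture's truth VAF (zero where the carrier
    #: founder is absent); lets evidence cover sites that are positive only
    #: in a paired sample, as a real pileup would
    panel_sites: pd.DataFrame | None = None

    def positive_sites(self) -> set:
        return {
            site_key(r.chrom, r.pos, r.ref, r.alt)
            for r in self.positives.itertuples()
        }

    def set_b_positions(self) -> set:
        return set(zip(self.set_b["chrom"], self.set_b["pos"]))

    def set_a_positions(self) -> set:
        return set(zip(self.set_a["chrom"], self.set_a["pos"]))


@dataclass
class SiteEvidence:
    """Read-count evidence for one mixture at nested depth tiers.

    Each tier's frame shares row order: chrom, pos, ref, alt, vclass
    (POS/SETA/SETB), vtype, true_af, depth, alt_count. Lower tiers are
    read-level subsamples of the tier above, so depth and alt_count are
    non-increasing from the deepest tier down at every site.
    """

    mixture_id: str
    tiers: dict[int, pd.DataFrame]
    _index: dict = field(default=None, repr=False)

    def at_tier(self, tier: int) -> pd.DataFrame:
        return self.tiers[tier]

    def lookup(self, tier: int, chrom: str, pos: int) -> tuple[int, int]:
        """(depth, alt_count) at a site; KeyError if the site is not covered."""
        if self._index is None:
            df = next(iter(self.tiers.values()))
            self._index = {
                (c, p): i for i, (c, p) in enumerate(zip(df["chrom"], df["pos"]))
            }
        i = self._index[(chrom, pos)]
        df = self.tiers[tier]
        return int(df["depth"].iat[i]), int(df["alt_count"].iat[i])


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def _apportion_indels(counts: np.ndarray, ratio: float) -> np.ndarray:
    """Largest-remainder apportionment of the panel-wide INDEL quota.

    The quota is fixed at the panel level (total/(ratio+1), rounded) so the
    shipped SNV:INDEL ratio is honoured within +-1 regardless of how counts
    split across founders.
    """
    n_total = int(counts.sum())
    n_indel = int(round(n_total / (ratio + 1.0)))
    quota = counts * n_indel / n_total
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = n_indel - base.sum()
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def simulate_founders(config: SimConfig, seed) -> FounderPanel:
    """Place mutually exclusive founder variants uniformly over the region.

    Deterministic given the seed. Raises if the region cannot hold the
    requested variants without positional collision.
    """
    rng = as_rng(seed)
    counts = np.asarray(config.founder_variant_counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("negative founder variant count")
    n_total = int(counts.sum())
    # keep a 4 bp tail margin so deletion REF alleles stay inside the region
    usable = config.region_bp - 4
    if n_total > usable or usable <= 0:
        raise ValueError(
            f"region of {config.region_bp} bp too small for {n_total} variants"
        )
    positions = np.sort(rng.choice(usable, size=n_total, replace=False) + 1)
    founder_ids = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(founder_ids)

    indel_quota = _apportion_indels(counts, config.snv_indel_ratio)
    is_indel = np.zeros(n_total, dtype=bool)
    for fid, q in enumerate(indel_quota):
        idx = np.flatnonzero(founder_ids == fid)
        if q > 0:
            is_indel[rng.choice(idx, size=q, replace=False)] = True

    het = rng.random(n_total) < config.het_fraction
    refs = random_bases(rng, n_total)
    alts = random_other_bases(rng, refs)
    ins_mask = rng.random(n_total) < 0.5
    tail_len = rng.integers(1, 4, size=n_total)

    variants = []
    for i in range(n_total):
        pos = int(positions[i])
        if is_indel[i]:
            tail = "".join(random_bases(rng, int(tail_len[i])))
            if ins_mask[i]:
                ref, alt = refs[i], refs[i] + tail
            else:
                ref, alt = refs[i] + tail, refs[i]
            pos, ref, alt = normalize_allele_pair(pos, ref, alt)
            vtype = "INDEL"
        else:
            ref, alt = refs[i], alts[i]
            vtype = "SNV"
        variants.append(
            FounderVariant(
                chrom=config.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                vtype=vtype,
                founder_id=int(founder_ids[i]),
                zygosity="het" if het[i] else "hom",
            )
        )
    if len({v.pos for v in variants}) != n_total:
        raise RuntimeError("positional collision in founder panel")
    return FounderPanel(len(counts), variants, config.region)


def _composition(carriers, ratio, cap, n_founders) -> np.ndarray:
    if ratio <= 0 or ratio >= 1:
        raise ValueError("mixing ratio must lie in (0, 1)")
    w = ratio ** np.arange(len(carriers), dtype=float)
    w = w / w.sum()
    if len(w) > 1 and w[0] > cap:
        # cap the dominant founder and spread the excess down the lineage
        w[1:] *= (1.0 - cap) / w[1:].sum()
        w[0] = cap
    comp = np.zeros(n_founders)
    comp[list(carriers)] = w
    return comp / comp.sum()


def build_mixture_design(config: SimConfig, seed=None) -> MixtureDesign:
    """Cumulative-mixing design: per category, a fixed carrier set with
    geometrically decaying fractions whose decay ratio varies across the
    category's mixtures.

    Every mixture in a category therefore shares the same mutation sites but
    represents them at different VAFs. The default sizes are 9/12/18.
    """
    lo, hi = config.mixing_ratio_range
    if lo <= 0:
        raise ValueError("mixing ratio schedule must be strictly positive")
    mixtures, tree = [], []
    for cat, size in config.category_sizes.items():
        if size < 1:
            raise ValueError(f"category {cat} must have at least one mixture")
        carriers = tuple(config.carriers[cat])
        if not carriers:
            raise ValueError(f"category {cat} has no carrier founders")
        for depth, fid in enumerate(carriers):
            tree.append(MixingStep(cat, depth, fid))
        ratios = np.linspace(lo, hi, size)
        for j, r in enumerate(ratios):
            comp = _composition(
                carriers, float(r), config.max_founder_fraction, config.n_founders
            )
            mixtures.append(
                Mixture(f"{cat}-{j + 1:02d}", cat, tuple(comp.tolist()))
            )
    return MixtureDesign(mixtures, dict(config.carriers), tree)


def expected_vaf(variant: FounderVariant, mixture: Mixture) -> float:
    """Expected allele fraction of a founder variant in a mixture:
    carrier fraction x dosage / 2 (het dosage 1, hom dosage 2)."""
    return mixture.composition[variant.founder_id] * variant.dosage / 2.0


def generate_truth_sets(
    panel: FounderPanel, design: MixtureDesign, config: SimConfig, seed
) -> list[TruthSet]:
    """Build per-mixture truth sets plus the shared Set A / Set B negatives.

    Positives are the panel sites with expected VAF > 0 under the mixture
    composition; Set A sites are sampled from nonvariant positions; Set B
    sites are germline in all founders (het -> VAF 0.5, hom -> VAF 1.0) so
    mixing leaves their VAF unchanged. The three classes are disjoint.
    """
    rng = as_rng(seed)
    var = panel.to_frame()
    occupied = set(var["pos"].tolist())
    n_neg = config.n_set_a + config.n_set_b
    candidates = np.setdiff1d(
        np.arange(1, config.region_bp + 1), np.fromiter(occupied, dtype=int)
    )
    if n_neg > candidates.size:
        raise ValueError("region too small for requested negative controls")
    chosen = rng.choice(candidates, size=n_neg, replace=False)
    set_a_pos = np.sort(chosen[: config.n_set_a])
    set_b_pos = np.sort(chosen[config.n_set_a:])

    set_a = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": set_a_pos.astype(int),
            "ref": random_bases(rng, set_a_pos.size),
        }
    )
    b_ref = random_bases(rng, set_b_pos.size)
    set_b = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": set_b_pos.astype(int),
            "ref": b_ref,
            "alt": random_other_bases(rng, b_ref),
            "vtype": "SNV",
            "vaf": np.where(
                rng.random(set_b_pos.size) < config.set_b_hom_fraction, 1.0, 0.5
            ),
        }
    )

    truth_sets = []
    dosage = var["dosage"].to_numpy()
    founder_idx = var["founder_id"].to_numpy()
    for mix in design.mixtures:
        comp = np.asarray(mix.composition)
        vaf = comp[founder_idx] * dosage / 2.0
        mask = vaf > 0
        panel_sites = var[["chrom", "pos", "ref", "alt", "vtype", "founder_id"]].copy()
        panel_sites["truth_vaf"] = vaf
        positives = panel_sites[mask].reset_index(drop=True)
        truth_sets.append(
            TruthSet(
                mixture_id=mix.mixture_id,
                category=mix.category,
                positives=positives,
                set_a=set_a,
                set_b=set_b,
                region=config.region,
                panel_sites=panel_sites,
            )
        )
    return truth_sets


def sample_site_evidence(truth: TruthSet, config: SimConfig, seed) -> SiteEvidence:
    """Simulate read-count evidence at nested depth tiers.

    Per-site depth at the deepest tier follows a negative-binomial model
    (mean = tier target, dispersion ``depth_dispersion``) emulating capture
    unevenness. alt_count ~ Binomial(depth, p) with p = truth VAF at
    positives, the per-base error rate at Set A and the germline VAF at
    Set B. Lower tiers subsample reads (binomial depth thinning, then
    hypergeometric draws of alt reads), so the tiers are nested.
    """
    rng = as_rng(seed)
    frames = []
    pos_df = truth.panel_sites if truth.panel_sites is not None else truth.positives
    vaf = pos_df["truth_vaf"].to_numpy(dtype=float)
    frames.append(
        pd.DataFrame(
            {
                "chrom": pos_df["chrom"],
                "pos": pos_df["pos"],
                "ref": pos_df["ref"],
                "alt": pos_df["alt"],
                # zero-VAF panel sites are nonvariant in this mixture; reads
                # there still show alt bases at the sequencing error rate
                "vclass": np.where(vaf > 0, "POS", "PANEL0"),
                "vtype": pos_df["vtype"],
                "true_af": np.where(vaf > 0, vaf, config.error_rate),
            }
        )
    )
    frames.append(
        pd.DataFrame(
            {
                "chrom": truth.set_a["chrom"],
                "pos": truth.set_a["pos"],
                "ref": truth.set_a["ref"],
                "alt": ".",
                "vclass": "SETA",
                "vtype": "SNV",
                "true_af": config.error_rate,
            }
        )
    )
    frames.append(
        pd.DataFrame(
            {
                "chrom": truth.set_b["chrom"],
                "pos": truth.set_b["pos"],
                "ref": truth.set_b["ref"],
                "alt": truth.set_b["alt"],
                "vclass": "SETB",
                "vtype": truth.set_b["vtype"],
                "true_af": truth.set_b["vaf"],
            }
        )
    )
    sites = pd.concat([f for f in frames if len(f)], ignore_index=True)
    n = len(sites)
    p = np.clip(sites["true_af"].to_numpy(dtype=float), 0.0, 1.0)

    tiers = sorted(config.depth_tiers, reverse=True)
    r = config.depth_dispersion
    top = tiers[0]
    depth = rng.negative_binomial(r, r / (r + top), size=n)
    alt = rng.binomial(depth, p)

    out: dict[int, pd.DataFrame] = {}
    prev_target = top
    for tier in tiers:
        if tier != prev_target:
            sub_depth = rng.binomial(depth, tier / prev_target)
            sub_alt = np.zeros(n, dtype=np.int64)
            nz = depth > 0
            sub_alt[nz] = rng.hypergeometric(
                alt[nz], depth[nz] - alt[nz], sub_depth[nz]
            )
            depth, alt = sub_depth, sub_alt
            prev_target = tier
        df = sites.copy()
        df["depth"] = depth
        df["alt_count"] = alt
        out[tier] = df
    return SiteEvidence(truth.mixture_id, out)


def simulate_benchmark(config: SimConfig, seed):
    """Convenience wrapper: panel + design + truth sets from one seed."""
    rng = as_rng(seed)
    panel = simulate_founders(config, rng)
    design = build_mixture_design(config, rng)
    truths = generate_truth_sets(panel, design, config, rng)
    return panel, design, truths
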