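"""Shared fixtures: a tiny desk-scale benchmark that every module test reuses."""

import numpy as np
import pandas as pd
import pytest

import mosabench as mb


def tiny_config(**overrides) -> mb.SimConfig:
    base = dict(
        region_bp=200_000,
        founder_variant_counts=(10, 10, 20, 20, 40, 40),
        n_set_a=2_000,
        n_set_b=100,
    )
    base.update(overrides)
    return mb.SimConfig(**base)


@pytest.fixture(scope="session")
def cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def bench(cfg):
    panel, design, truths = mb.simulate_benchmark(cfg, seed=11)
    return {"panel": panel, "design": design, "truths": truths}


@pytest.fixture(scope="session")
def truth_m3(bench):
    return next(t for t in bench["truths"] if t.category == "M3")


@pytest.fixture(scope="session")
def evidence_m3(truth_m3, cfg):
    return mb.sample_site_evidence(truth_m3, cfg, seed=12)


@pytest.fixture(scope="session")
def callset_m3(truth_m3, evidence_m3):
    profile = mb.CallerProfile(
        "unit", sens=0.8, fp_rate_nv=20.0, fp_rate_g=10.0,
        features=[
            mb.FeatureModel("alt_softclip", "alignment", "nonvariant", 0.9),
            mb.FeatureModel("het_likelihood", "genotype", "germline", 0.95),
        ],
    )
    return mb.emulate_caller(truth_m3, evidence_m3, profile, 1100, seed=13)


def make_truth(positives=None, set_a=None, set_b=None, region=None,
               mixture_id="T", category="M1") -> mb.TruthSet:
    """Hand-built truth set for rule-level tests."""
    pos_cols = ["chrom", "pos", "ref", "alt", "vtype", "founder_id", "truth_vaf"]
    a_cols = ["chrom", "pos", "ref"]
    b_cols = ["chrom", "pos", "ref", "alt", "vtype", "vaf"]
    return mb.TruthSet(
        mixture_id=mixture_id,
        category=category,
        positives=pd.DataFrame(positives or [], columns=pos_cols),
        set_a=pd.DataFrame(set_a or [], columns=a_cols),
        set_b=pd.DataFrame(set_b or [], columns=b_cols),
        region=region or mb.RegionSet.single("chr1", 1_000_000),
    )


def make_call(chrom="chr1", pos=100, ref="A", alt="T", vtype="SNV",
              observed_vaf=0.1, alt_count=10, depth=100, score=0.5,
              features=None, sample_id="S"):
    return mb.Call(chrom, pos, ref, alt, vtype, observed_vaf, alt_count,
                   depth, score, features or {}, sample_id)


def make_callset(calls, sample_id="S", region=None):
    return mb.CallSet(sample_id, list(calls), region)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
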