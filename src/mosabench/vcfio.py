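"""Interchange formats.

VCF 4.2 is the sole call/truth format: truth VCFs carry INFO keys TVAF
(truth VAF), VCLASS (POS/SETA/SETB) and CAT (mixture category); call VCFs
carry FORMAT AD/DP, INFO SCORE and FT_* feature keys. Regions travel as
0-based half-open BED, read-count evidence as TSV (pileup depth at
uncalled sites has no natural VCF home), configuration as YAML. Every
writer stamps the seed and config hash it was given so runs are
reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import re

import numpy as np
import pandas as pd
import pysam

from ._utils import config_hash
from .callers import Call, CallSet
from .regions import RegionSet
from .truthsim import SiteEvidence, TruthSet

log = logging.getLogger(__name__)

__all__ = [
    "write_truth_vcf",
    "load_truth",
    "write_callset_vcf",
    "load_callset",
    "write_evidence_tsv",
    "load_evidence_tsv",
    "write_report",
]

_FEATURE_KEY = re.compile(r"[^A-Za-z0-9_]")


def _feature_info_key(name: str) -> str:
    return "FT_" + _FEATURE_KEY.sub("_", name)


def _base_header(region: RegionSet, meta: dict | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chroms: dict[str, int] = {}
    for chrom, _start, end in region.intervals:
        chroms[chrom] = max(chroms.get(chrom, 0), end)
    for chrom, end in sorted(chroms.items()):
        header.contigs.add(chrom, length=end)
    for key, value in (meta or {}).items():
        header.add_line(f"##mosabench_{key}={value}")
    return header


# --------------------------------------------------------------------------- #
# truth VCF
# --------------------------------------------------------------------------- #

def write_truth_vcf(truth: TruthSet, path, meta: dict | None = None) -> None:
    meta = {"mixture_id": truth.mixture_id, **(meta or {})}
    header = _base_header(truth.region, meta)
    header.info.add("TVAF", 1, "Float", "Truth variant allele fraction")
    header.info.add("VCLASS", 1, "String", "Control class: POS, SETA or SETB")
    header.info.add("CAT", 1, "String", "Mixture category (M1/M2/M3)")

    records = []
    for r in truth.positives.itertuples():
        records.append((r.chrom, r.pos, r.ref, r.alt, r.truth_vaf, "POS"))
    for r in truth.set_a.itertuples():
        records.append((r.chrom, r.pos, r.ref, None, None, "SETA"))
    for r in truth.set_b.itertuples():
        records.append((r.chrom, r.pos, r.ref, r.alt, r.vaf, "SETB"))
    records.sort(key=lambda t: (t[0], t[1]))

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, ref, alt, tvaf, vclass in records:
            # "." writes a missing ALT (nonvariant Set A sites)
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt or "."),
            )
            if tvaf is not None:
                rec.info["TVAF"] = float(tvaf)
            rec.info["VCLASS"] = vclass
            rec.info["CAT"] = truth.category
            vcf.write(rec)


def load_truth(path, bed=None, mixture_id: str | None = None) -> TruthSet:
    """Read a truth VCF (TVAF/VCLASS INFO) back into a TruthSet; sites
    outside the BED are dropped and counted."""
    if bed is None or isinstance(bed, RegionSet):
        region = bed
    else:
        region = RegionSet.from_bed(bed)
    pos_rows, a_rows, b_rows = [], [], []
    n_outside = 0
    category = "NA"
    with pysam.VariantFile(str(path)) as vcf:
        if mixture_id is None:
            for line in str(vcf.header).splitlines():
                if line.startswith("##mosabench_mixture_id="):
                    mixture_id = line.split("=", 1)[1]
        if region is None:
            region = RegionSet(
                tuple((c.name, 0, c.length) for c in vcf.header.contigs.values())
            )
        for rec in vcf:
            if "VCLASS" not in rec.info:
                raise ValueError(f"record at {rec.chrom}:{rec.pos} lacks VCLASS")
            if not region.contains(rec.chrom, rec.pos):
                n_outside += 1
                continue
            vclass = rec.info["VCLASS"]
            category = rec.info.get("CAT", category)
            alt = rec.alts[0] if rec.alts else None
            if vclass == "POS":
                vtype = "SNV" if len(rec.ref) == len(alt) == 1 else "INDEL"
                pos_rows.append(
                    (rec.chrom, rec.pos, rec.ref, alt, vtype, -1,
                     float(rec.info["TVAF"]))
                )
            elif vclass == "SETA":
                a_rows.append((rec.chrom, rec.pos, rec.ref))
            elif vclass == "SETB":
                vtype = "SNV" if len(rec.ref) == len(alt) == 1 else "INDEL"
                b_rows.append(
                    (rec.chrom, rec.pos, rec.ref, alt, vtype,
                     float(rec.info["TVAF"]))
                )
    if n_outside:
        log.info("load_truth: %d record(s) outside region dropped", n_outside)
    positives = pd.DataFrame(
        pos_rows,
        columns=["chrom", "pos", "ref", "alt", "vtype", "founder_id", "truth_vaf"],
    )
    set_a = pd.DataFrame(a_rows, columns=["chrom", "pos", "ref"])
    set_b = pd.DataFrame(
        b_rows, columns=["chrom", "pos", "ref", "alt", "vtype", "vaf"]
    )
    return TruthSet(
        mixture_id=mixture_id or "NA",
        category=category,
        positives=positives,
        set_a=set_a,
        set_b=set_b,
        region=region,
    )


# --------------------------------------------------------------------------- #
# call VCF
# --------------------------------------------------------------------------- #

def write_callset_vcf(callset: CallSet, path, meta: dict | None = None) -> None:
    region = callset.region
    if region is None:
        raise ValueError("callset has no region; cannot build VCF contigs")
    header = _base_header(region, meta)
    header.info.add("SCORE", 1, "Float", "Caller confidence score")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    feature_names = sorted({f for c in callset.calls for f in c.features})
    for name in feature_names:
        header.info.add(_feature_info_key(name), 1, "Float", f"Feature {name}")
    header.add_sample(callset.sample_id or "SAMPLE")

    calls = sorted(callset.calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            rec = vcf.new_record(
                contig=call.chrom, start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            rec.filter.add("PASS")
            rec.info["SCORE"] = float(call.score)
            for name, value in call.features.items():
                rec.info[_feature_info_key(name)] = float(value)
            sample = rec.samples[0]
            sample["AD"] = (call.depth - call.alt_count, call.alt_count)
            sample["DP"] = call.depth
            vcf.write(rec)


def load_callset(
    path,
    keep_filters: tuple[str, ...] = ("PASS", "mosaic"),
    sample_id: str | None = None,
    region=None,
) -> CallSet:
    """Read a call VCF, keeping only records whose FILTER is in
    ``keep_filters`` (an empty FILTER column counts as PASS). VAF comes from
    AD/DP; records without usable depth fields are rejected and logged.
    """
    calls = []
    n_rejected = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sid = sample_id or (samples[0] if samples else "SAMPLE")
        for rec in vcf:
            filters = set(rec.filter.keys()) or {"PASS"}
            if not filters & set(keep_filters):
                continue
            if not rec.alts:
                n_rejected += 1
                continue
            try:
                alt = rec.alts[0]
                depth = alt_count = None
                if samples:
                    fmt = rec.samples[0]
                    if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
                        ad = fmt["AD"]
                        alt_count = int(ad[1])
                        depth = int(fmt["DP"]) if fmt.get("DP") is not None else int(sum(ad))
                if depth is None or depth <= 0:
                    raise ValueError("no usable AD/DP")
                features = {}
                for key, value in rec.info.items():
                    if key.startswith("FT_"):
                        features[key[3:]] = float(value)
                try:
                    score = float(rec.info["SCORE"])
                except (KeyError, ValueError):
                    score = 0.0  # SCORE absent or undeclared in the header
                vtype = "SNV" if len(rec.ref) == len(alt) == 1 else "INDEL"
                calls.append(
                    Call(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        vtype=vtype, observed_vaf=alt_count / depth,
                        alt_count=alt_count, depth=depth, score=score,
                        features=features, sample_id=sid,
                    )
                )
            except (ValueError, TypeError, KeyError, IndexError) as exc:
                n_rejected += 1
                log.warning(
                    "load_callset: rejecting record %s:%s (%s)",
                    rec.chrom, rec.pos, exc,
                )
    if n_rejected:
        log.info("load_callset: %d record(s) rejected", n_rejected)
    return CallSet(sid, calls, region)


# --------------------------------------------------------------------------- #
# evidence TSV / reports
# --------------------------------------------------------------------------- #

_EV_COLS = [
    "chrom", "pos", "ref", "alt", "vclass", "vtype", "true_af", "tier",
    "depth", "alt_count",
]


def write_evidence_tsv(evidence: SiteEvidence, path, meta: dict | None = None) -> None:
    frames = []
    for tier in sorted(evidence.tiers):
        df = evidence.tiers[tier].copy()
        df["tier"] = tier
        frames.append(df[_EV_COLS])
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write(f"# mixture_id={evidence.mixture_id}\n")
        out.to_csv(fh, sep="\t", index=False)


def load_evidence_tsv(path) -> SiteEvidence:
    mixture_id = "NA"
    with open(path) as fh:
        header_lines = []
        while True:
            position = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(position)
                break
            header_lines.append(line)
        for line in header_lines:
            if "mixture_id=" in line:
                mixture_id = line.split("mixture_id=")[1].strip()
        df = pd.read_csv(fh, sep="\t")
    tiers = {
        int(tier): sub.drop(columns="tier").reset_index(drop=True)
        for tier, sub in df.groupby("tier")
    }
    return SiteEvidence(mixture_id, tiers)


def write_report(results, tsv_path=None, json_path=None, meta: dict | None = None):
    """Write a metric table / dict deterministically, stamping seed and
    config hash as comment (TSV) or '_meta' (JSON) entries."""
    meta = dict(meta or {})
    meta.setdefault("config_hash", config_hash(meta))
    if tsv_path is not None:
        if not isinstance(results, pd.DataFrame):
            raise TypeError("TSV output requires a DataFrame")
        with open(tsv_path, "w") as fh:
            for key in sorted(meta):
                fh.write(f"# {key}={meta[key]}\n")
            results.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        if isinstance(results, pd.DataFrame):
            payload = results.replace({np.nan: None}).to_dict(orient="records")
        else:
            payload = results
        with open(json_path, "w") as fh:
            json.dump({"_meta": meta, "results": payload}, fh, indent=2, sort_keys=True)
            fh.write("\n")
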