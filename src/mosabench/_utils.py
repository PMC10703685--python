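"""Shared helpers: allele normalization, site identity, hashing, RNG plumbing."""

from __future__ import annotations

import hashlib
import json

import numpy as np

#: A variant site identity after normalization: (chrom, pos, ref, alt).
Site = tuple[str, int, str, str]

_BASES = np.array(list("ACGT"))


def as_rng(seed) -> np.random.Generator:
    """Return ``seed`` itself if it already is a Generator, else seed a new one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    # keep derived seeds below 2**31 so they survive any int32 round-trip
    return int(rng.integers(0, 2**31 - 1))


def normalize_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-normalize an allele pair by trimming shared bases.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    always leaving at least one base on each allele. This matches the usual
    left-normalization convention for anchored VCF indels; without access to
    the reference sequence no further left-shifting across repeat tracts is
    attempted (the simulator never emits alleles that would need it).
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def site_key(chrom: str, pos: int, ref: str, alt: str) -> Site:
    """Canonical site identity used for all set operations (VAF ignored)."""
    pos, ref, alt = normalize_allele_pair(pos, ref, alt)
    return (chrom, int(pos), ref, alt)


def random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def random_other_bases(rng: np.random.Generator, ref: np.ndarray) -> np.ndarray:
    """Random bases guaranteed to differ elementwise from ``ref``."""
    ref = np.asarray(ref)
    idx = np.searchsorted(_BASES, ref)
    shift = rng.integers(1, 4, size=ref.shape[0])
    return _BASES[(idx + shift) % 4]


def config_hash(obj) -> str:
    """Stable 12-hex-digit digest of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
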