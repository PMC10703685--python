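"""Call-set agreement: pairwise Jaccard similarity by error class and
cross-depth consistency partitions.

Site identity for all set operations is the normalized (chrom, pos, ref, alt)
key; VAF is ignored.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd

__all__ = ["jaccard", "similarity_matrix", "depth_consistency"]


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; NaN when the union is empty."""
    union = len(set_a | set_b)
    if union == 0:
        return float("nan")
    return len(set_a & set_b) / union


def similarity_matrix(site_sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric caller-by-caller Jaccard matrix; NA where the union is empty.

    NA cells are left as NaN so that downstream aggregates exclude them
    rather than treating them as zero agreement.
    """
    names = list(site_sets)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            mat.loc[a, b] = jaccard(site_sets[a], site_sets[b])
    return mat


def depth_consistency(sites_by_tier: dict[int, set]) -> pd.DataFrame:
    """Partition the union of per-tier call sets by exact tier membership.

    Returns one row per non-empty tier subset with its site count; the counts
    sum to the size of the union, exposing how inconsistent a caller is
    across sequencing depths.
    """
    if len(sites_by_tier) < 2:
        raise ValueError("depth consistency needs at least two tiers")
    tiers = sorted(sites_by_tier)
    union = set(chain.from_iterable(sites_by_tier.values()))
    counts: dict[tuple, int] = {}
    for site in union:
        member = tuple(t for t in tiers if site in sites_by_tier[t])
        counts[member] = counts.get(member, 0) + 1
    rows = []
    for k in range(1, len(tiers) + 1):
        for subset in combinations(tiers, k):
            if subset in counts:
                rows.append(
                    {"tiers": "+".join(map(str, subset)), "n_sites": counts[subset]}
                )
    return pd.DataFrame(rows, columns=["tiers", "n_sites"])
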