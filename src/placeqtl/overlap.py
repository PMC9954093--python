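"""Hypergeometric (one-sided Fisher) overlap tests of eGene lists against
reference study lists over a fixed expressed-gene background.

The default is the exact upper-tail hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

evaluated in log space (scipy's hypergeometric survival function); a
continuity-corrected normal approximation is available for comparison.  The
test is one-sided for over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapTest:
    N: int          # background gene count
    K: int          # reference list size
    n: int          # query list size
    k: int          # overlap count
    p_value: float
    method: str = "exact"


def fisher_overlap(N: int, K: int, n: int, k: int, normal_approx: bool = False) -> float:
    """Upper-tail probability of observing >= k overlapping genes."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require K <= N and n <= N")
    if k < 0 or k > min(K, n):
        raise ValueError("impossible overlap count k")
    if k == 0:
        return 1.0
    if normal_approx:
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        if var <= 0:
            return 1.0 if k <= mean else 0.0
        z = (k - 0.5 - mean) / np.sqrt(var)  # continuity-corrected
        return float(stats.norm.sf(z))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_report(query_genes, reference_lists: dict, N: int, normal_approx: bool = False) -> pd.DataFrame:
    """One overlap test per reference list.

    Gene identifiers are case-normalized and de-duplicated before counting;
    the intersection size k is computed by set intersection.
    """
    query = {str(g).strip().upper() for g in query_genes}
    rows = []
    for name, ref in reference_lists.items():
        ref_set = {str(g).strip().upper() for g in ref}
        if len(ref_set) > N:
            raise ValueError(f"reference list {name!r} exceeds background size N")
        k = len(query & ref_set)
        p = fisher_overlap(N, len(ref_set), len(query), k, normal_approx=normal_approx)
        rows.append(
            {
                "reference": name,
                "N": N,
                "K": len(ref_set),
                "n": len(query),
                "k": k,
                "p_value": p,
                "method": "normal" if normal_approx else "exact",
            }
        )
    return pd.DataFrame(rows)
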