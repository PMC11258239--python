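"""Independent reference computations used to cross-check the package.

These deliberately take different algorithmic routes than the implementation:
clustering via pairwise-graph connected components instead of a linear gap
scan, and Fisher p-values via explicit binomial-coefficient enumeration.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_clusters(flags: np.ndarray, d: int, min_methylated: int = 2):
    """Clusters as connected components of the pairwise within-d graph.

    Methylated occurrences i, j are adjacent when the number of unmethylated
    occurrences strictly between them is <= d.  Returns a sorted list of
    (first_index, last_index, n_methylated) per kept component.
    """
    flags = np.asarray(flags, dtype=bool)
    meth = np.flatnonzero(flags)
    if len(meth) == 0:
        return []
    unmeth_cum = np.cumsum(~flags)
    # unmethylated strictly between occurrence positions a < b
    between = np.abs(unmeth_cum[meth][:, None] - unmeth_cum[meth][None, :])
    adj = csr_matrix(between <= d)
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for comp in range(n_comp):
        members = meth[labels == comp]
        if len(members) >= min_methylated:
            out.append((int(members.min()), int(members.max()), len(members)))
    return sorted(out)


def hypergeom_enrichment_p(n_bg: int, k_bg: int, n_sel: int, k_sel: int) -> float:
    """P(X >= k_sel) by explicit enumeration of the hypergeometric pmf."""
    total = comb(n_bg, n_sel)
    p = 0.0
    for a in range(k_sel, min(n_sel, k_bg) + 1):
        if n_sel - a > n_bg - k_bg:
            continue
        p += comb(k_bg, a) * comb(n_bg - k_bg, n_sel - a) / total
    return min(1.0, p)
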