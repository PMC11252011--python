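"""Over-representation analysis of protein lists against gene sets.

For a hit list of size n drawn from a universe of N quantified proteins
and a gene set with m members in the universe, the overlap x is tested
with the upper tail of the hypergeometric distribution,
P(X >= x | N, m, n), and p-values are adjusted across sets with the
Benjamini-Hochberg step-up procedure.  The universe is the set of
proteins quantified in the relevant experiment, not the whole genome;
gene symbols are matched case-insensitively (MS tables mix cases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_p", "bh_adjust", "run_ora"]


@dataclass
class EnrichmentResult:
    set_name: str
    n_hits_in_set: int
    set_size_in_universe: int
    n_hits: int
    universe_size: int
    percent_of_set_detected: float
    p_value: float
    adjusted_p: float = np.nan


def hypergeom_p(n_hits_in_set: int, set_size: int, n_hits: int, universe: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_hits_in_set)."""
    if not (0 <= n_hits_in_set <= min(set_size, n_hits)):
        raise ValueError("overlap exceeds set or hit-list size")
    if set_size > universe or n_hits > universe:
        raise ValueError("set or hit list larger than universe")
    return float(hypergeom.sf(n_hits_in_set - 1, universe, set_size, n_hits))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(hit_proteins, gene_sets: dict, universe) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the hit list.

    Sets are intersected with the universe first and sets with no member
    in the universe are dropped.  Results are sorted by adjusted p
    (ties by name).
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    hits = {str(g).upper() for g in hit_proteins} & uni
    results = []
    for name in sorted(gene_sets):
        members = {str(g).upper() for g in gene_sets[name]} & uni
        if not members:
            continue
        overlap = len(members & hits)
        p = hypergeom_p(overlap, len(members), len(hits), len(uni))
        results.append(EnrichmentResult(
            set_name=name,
            n_hits_in_set=overlap,
            set_size_in_universe=len(members),
            n_hits=len(hits),
            universe_size=len(uni),
            percent_of_set_detected=100.0 * overlap / len(members),
            p_value=p,
        ))
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
        results.sort(key=lambda r: (r.adjusted_p, r.set_name))
    return results
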