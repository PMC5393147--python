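"""Pathway over-representation and permutation enrichment of miRNA targets.

Two complementary enrichment questions arise downstream of the screens:

* are the significantly altered metabolites over-represented in a metabolite
  pathway, given the measured universe? — answered by the upper-tail
  hypergeometric test (classic ORA);
* do the hypoxia-responsive miRNAs preferentially target a pathway's genes?
  — answered by a permutation test: predicted targets are filtered to
  confident interactions (mirSVR score strictly below −1.25), the number of
  distinct pathway genes targeted by the significant miRNA set is counted,
  and compared with the overlaps of B size-matched miRNA sets drawn without
  replacement from the non-significant pool. Fold enrichment is the observed
  overlap over the null mean, and the empirical p uses the add-one
  convention p = (#{k_b ≥ k_obs} + 1)/(B + 1), which can never reach zero.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence, Set

import numpy as np
from scipy import stats

from .datamodel import PathwayDB, TargetTable

logger = logging.getLogger(__name__)

__all__ = [
    "ORAResult",
    "EnrichmentResult",
    "MIRSVR_THRESHOLD",
    "filter_targets",
    "pathway_target_overlap",
    "ora_hypergeometric",
    "permutation_enrichment",
]

#: Default mirSVR confidence cut-off; records with score strictly below pass.
MIRSVR_THRESHOLD = -1.25


@dataclasses.dataclass
class ORAResult:
    """Hypergeometric over-representation of a hit list in one pathway."""

    pathway_name: str
    universe_size: int
    pathway_size: int
    hits_size: int
    overlap: int
    p: float


@dataclasses.dataclass
class EnrichmentResult:
    """Permutation enrichment of a pathway's genes among miRNA targets."""

    pathway_name: str
    observed_overlap: int
    null_counts: np.ndarray
    fold_enrichment: float
    p: float

    @property
    def n_permutations(self) -> int:
        return len(self.null_counts)


def filter_targets(table: TargetTable, threshold: float = MIRSVR_THRESHOLD) -> TargetTable:
    """Keep target records with mirSVR score strictly below ``threshold``."""
    return table.filtered(threshold)


def pathway_target_overlap(
    mirnas: Iterable[str], table: TargetTable, pathway_genes: Set[str]
) -> int:
    """Number of distinct pathway genes targeted by at least one miRNA in the
    set (a gene hit by several miRNAs counts once). The table is assumed
    already mirSVR-filtered by the caller."""
    targeted: set[str] = set()
    for m in mirnas:
        targeted |= table.targets_of(m)
    return len(targeted & set(pathway_genes))


def ora_hypergeometric(
    hits: Set[str],
    pathway: Set[str],
    universe: Set[str],
    pathway_name: str = "",
    strict: bool = False,
) -> ORAResult:
    """Upper-tail hypergeometric over-representation test.

    p = P(X ≥ k) for X ~ Hypergeom(N=|universe|, K=|pathway ∩ universe|,
    n=|hits|). Pathway members outside the universe are dropped with a
    warning (an error under ``strict``); hits outside the universe are an
    error under ``strict``.
    """
    hits, pathway, universe = set(hits), set(pathway), set(universe)
    stray_hits = hits - universe
    if stray_hits:
        if strict:
            raise ValueError(f"hits outside the universe: {sorted(stray_hits)}")
        logger.warning("dropping %d hits outside the universe", len(stray_hits))
        hits &= universe
    stray = pathway - universe
    if stray:
        if strict:
            raise ValueError(f"pathway members outside the universe: {sorted(stray)}")
        logger.warning(
            "pathway %r: dropping %d members outside the universe", pathway_name, len(stray)
        )
    pathway &= universe
    N, K, n = len(universe), len(pathway), len(hits)
    k = len(hits & pathway)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return ORAResult(
        pathway_name=pathway_name,
        universe_size=N,
        pathway_size=K,
        hits_size=n,
        overlap=k,
        p=min(p, 1.0),
    )


def permutation_enrichment(
    sig_mirnas: Set[str],
    nonsig_pool: Set[str],
    table: TargetTable,
    pathways: PathwayDB,
    B: int = 1000,
    threshold: float = MIRSVR_THRESHOLD,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation test of pathway-target enrichment for a significant miRNA set.

    For each pathway the observed overlap (distinct pathway genes targeted by
    the significant set after mirSVR filtering) is compared with the overlaps
    of ``B`` equally sized miRNA sets drawn uniformly without replacement
    from the non-significant pool. Fold enrichment is k_obs / mean(k_b)
    (+inf when the null mean is 0 but k_obs > 0; 1 when both are 0), and
    p = (#{k_b ≥ k_obs} + 1)/(B + 1).
    """
    sig = sorted(set(sig_mirnas))
    pool = sorted(set(nonsig_pool))
    if set(sig) & set(pool):
        raise ValueError("significant set and non-significant pool must be disjoint")
    if len(pool) < len(sig):
        raise ValueError(
            f"pool of {len(pool)} miRNAs cannot supply sets of size {len(sig)}"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    if not len(sig):
        raise ValueError("significant miRNA set is empty")

    filtered = table.filtered(threshold)
    genes = sorted({g for name, members in pathways.items() for g in members})
    gene_index = {g: j for j, g in enumerate(genes)}
    names = sorted(pathways.names)

    def hit_matrix(mirnas: Sequence[str]) -> np.ndarray:
        M = np.zeros((len(mirnas), len(genes)), dtype=bool)
        for i, m in enumerate(mirnas):
            for g in filtered.targets_of(m):
                j = gene_index.get(g)
                if j is not None:
                    M[i, j] = True
        return M

    M_sig = hit_matrix(sig)
    M_pool = hit_matrix(pool)
    G = np.zeros((len(names), len(genes)), dtype=bool)
    for pi, name in enumerate(names):
        for g in pathways.members(name):
            G[pi, gene_index[g]] = True
    Gf = G.astype(float)

    k_obs = Gf @ M_sig.any(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty((B, len(names)))
    for b in range(B):
        draw = rng.choice(len(pool), size=len(sig), replace=False)
        null[b] = Gf @ M_pool[draw].any(axis=0)

    results = []
    for pi, name in enumerate(names):
        ko = int(k_obs[pi])
        kb = null[:, pi]
        mean_kb = float(kb.mean())
        if mean_kb > 0:
            fe = ko / mean_kb
        else:
            fe = float("inf") if ko > 0 else 1.0
        p = (int((kb >= ko).sum()) + 1) / (B + 1)
        results.append(
            EnrichmentResult(
                pathway_name=name,
                observed_overlap=ko,
                null_counts=kb.astype(int),
                fold_enrichment=fe,
                p=p,
            )
        )
    return results
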