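"""Hypergeometric over-representation test between gene sets.

The final stage asks whether the metabolite-interacting gene set overlaps
the trait subnetwork's gene set more than chance, given that both are
drawn from the same discoverable gene universe. Roles in the 2x2 layout:
the population is the whole discoverable universe (N); successes are the
trait subnetwork's genes (K); the draw is the metabolite-interacting gene
set (n); observed successes are the overlap (k). The p-value is the
inclusive upper tail P[X >= k] — the standard ORA convention. A single
(pathway, keyword) pair is one test and carries no multiplicity
correction; callers running several pathways or keywords should adjust
across their own batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .catalog import GeneUniverse

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n), inclusive upper tail.

    Computed through the survival function, which scipy evaluates in
    log-space; exact to double precision for small counts.

    Raises ValueError naming the offending parameter when the bounds
    0 <= k <= min(K, n), K <= N, n <= N are violated.
    """
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if K > N:
        raise ValueError(f"K ({K}) exceeds N ({N})")
    if n > N:
        raise ValueError(f"n ({n}) exceeds N ({N})")
    if k > min(K, n):
        raise ValueError(f"k ({k}) exceeds min(K, n) ({min(K, n)})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class OraResult:
    """The 2x2 intersection counts and hypergeometric p-value."""

    universe_size: int      # N: discoverable genes
    trait_genes: int        # K: genes in the trait subnetwork
    metabolite_genes: int   # n: metabolite-interacting genes (the draw)
    overlap: int            # k: observed successes
    overlapping_symbols: tuple[str, ...]
    p_value: float

    def __post_init__(self) -> None:
        assert self.overlap == len(self.overlapping_symbols)


def ora_test(
    metabolite_genes: Iterable[str],
    trait_genes: Iterable[str],
    universe: GeneUniverse,
) -> OraResult:
    """Test the metabolite-gene / trait-gene intersection for enrichment.

    Symbols outside the universe are dropped (loudly logged) before
    counting: gene-symbol vintages drift between metabolite and catalog
    snapshots, and erroring on every stray symbol would make mixed
    vintages unusable.
    """
    metab = {g.upper() for g in metabolite_genes}
    trait = {g.upper() for g in trait_genes}
    metab_in = metab & universe.symbols
    trait_in = trait & universe.symbols
    dropped = (len(metab) - len(metab_in)) + (len(trait) - len(trait_in))
    if dropped:
        logger.warning(
            "ORA: dropped %d symbol(s) outside the %d-gene universe "
            "(%d metabolite-side, %d trait-side)",
            dropped, len(universe), len(metab) - len(metab_in), len(trait) - len(trait_in),
        )

    overlap = sorted(metab_in & trait_in)
    p = hypergeom_upper_tail(
        N=len(universe), K=len(trait_in), n=len(metab_in), k=len(overlap)
    )
    return OraResult(
        universe_size=len(universe),
        trait_genes=len(trait_in),
        metabolite_genes=len(metab_in),
        overlap=len(overlap),
        overlapping_symbols=tuple(overlap),
        p_value=p,
    )
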