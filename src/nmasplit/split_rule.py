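"""Decision rule for choosing which comparisons to split.

The rule: split the comparison ``x:y`` if and only if the reduced network --
the studies that do *not* contain both ``x`` and ``y`` -- still contains a
path between ``x`` and ``y``.  Intuitively the reduced network is exactly the
evidence that could disagree with the direct ``x:y`` evidence.

This module also provides an exhaustive enumeration of potentially
inconsistent loops, used as an independent oracle in the test-suite: a loop
qualifies when it is a simple cycle of at least three treatments and no two
of its edges share the same set of supporting evidence sources, where
sources are identified by their treatment set restricted to the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import networkx as nx

from .network_core import (
    ComparisonPair,
    Network,
    NetworkError,
    direct_comparisons,
)

__all__ = [
    "Loop",
    "reduced_network",
    "splittable",
    "comparisons_to_split",
    "potentially_inconsistent_loops",
    "count_parameterisations",
]

DEFAULT_LOOP_TREATMENT_BOUND = 12


@dataclass(frozen=True)
class Loop:
    """A simple cycle of >=3 treatments with per-edge evidence support.

    ``treatments`` is the canonical cyclic order (smallest treatment first,
    lexicographically smaller neighbour second); ``support`` maps each edge
    to the frozenset of identified evidence sources containing both of its
    endpoints.  A source is the restriction of a study's treatment set to
    the loop, so studies that agree on the loop count as one source.
    """

    treatments: tuple
    support: tuple  # tuple of (ComparisonPair, frozenset-of-sources)

    @property
    def edges(self) -> tuple:
        return tuple(pair for pair, _ in self.support)

    def __str__(self) -> str:
        return "-".join(self.treatments + (self.treatments[0],))


def reduced_network(network: Network, pair: ComparisonPair) -> Network:
    """Studies that do not include both treatments of ``pair`` (kept whole)."""
    treatments = set(network.treatments)
    for t in pair:
        if t not in treatments:
            raise NetworkError(f"treatment {t!r} not present in the network")
    return Network(
        studies=tuple(s for s in network.studies if not s.contains(pair))
    )


def splittable(network: Network, pair: ComparisonPair) -> bool:
    """True iff ``pair`` is connected in the reduced network.

    ``pair`` must have direct evidence (co-occur in at least one study);
    splitting a comparison without a direct estimate is undefined.
    """
    if pair not in direct_comparisons(network):
        raise NetworkError(f"comparison {pair} has no direct evidence")
    g = reduced_network(network, pair).graph()
    return g.has_node(pair.x) and g.has_node(pair.y) and nx.has_path(g, pair.x, pair.y)


def comparisons_to_split(network: Network) -> list:
    """Direct comparisons selected by the decision rule, in canonical order."""
    return [
        pair
        for pair in sorted(direct_comparisons(network))
        if splittable(network, pair)
    ]


def _loop_support(network: Network, cycle: tuple):
    """Per-edge support sets for a candidate cycle, or None if unsupported.

    Studies are identified by their treatment set restricted to the loop;
    the support of an edge is the set of identified sources containing both
    endpoints.  Every edge needs at least one source (direct evidence).
    """
    loop_set = set(cycle)
    sources = {frozenset(set(s.treatments) & loop_set) for s in network.studies}
    support = []
    closed = cycle + (cycle[0],)
    for a, b in zip(closed, closed[1:]):
        edge_support = frozenset(src for src in sources if a in src and b in src)
        if not edge_support:
            return None
        support.append((ComparisonPair(a, b), edge_support))
    return tuple(support)


def _canonical_cycles(treatments: tuple):
    """All distinct simple cycles (>=3 nodes) over subsets of treatments.

    Each cycle is produced once: smallest member first, and of the two
    traversal directions the one whose second element is smaller.
    """
    for size in range(3, len(treatments) + 1):
        for subset in combinations(treatments, size):
            first, rest = subset[0], subset[1:]
            for perm in permutations(rest):
                if perm[0] < perm[-1]:
                    yield (first,) + perm


def potentially_inconsistent_loops(
    network: Network, treatment_bound: int = DEFAULT_LOOP_TREATMENT_BOUND
) -> set:
    """Exhaustively enumerate the potentially inconsistent loops.

    A loop qualifies iff (1) it is a simple cycle of >=3 distinct treatments
    in which every edge has direct evidence and (2) no two edges share the
    same support set.  Exhaustive enumeration is guarded by a configurable
    treatment-count bound; this is a validation oracle, not a fast path.
    """
    treatments = network.treatments
    if len(treatments) > treatment_bound:
        raise NetworkError(
            f"network has {len(treatments)} treatments, above the exhaustive "
            f"enumeration bound of {treatment_bound}"
        )
    loops = set()
    for cycle in _canonical_cycles(treatments):
        support = _loop_support(network, cycle)
        if support is None:
            continue
        support_sets = [s for _, s in support]
        if len(set(support_sets)) == len(support_sets):
            loops.add(Loop(treatments=cycle, support=support))
    return loops


def count_parameterisations(network: Network, pair: ComparisonPair) -> int:
    """Number of alternative node-splitting models for ``pair``: ``2**k + 1``.

    ``k`` is the number of multi-arm (>=3 arms) studies that contain both
    treatments of ``pair``; the ``2**k`` arm-inclusion mixtures plus the one
    model that excludes both split treatments from the indirect network.
    """
    if not splittable(network, pair):
        raise NetworkError(f"comparison {pair} is not selected by the decision rule")
    k = sum(1 for s in network.studies if s.n_arms >= 3 and s.contains(pair))
    return 2**k + 1
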