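"""Automated construction of consistency and node-splitting model structures.

A model structure fixes, for each (possibly virtual) study, a reference
treatment and the ordered non-reference arms, and chooses the basic
parameters: a breadth-first spanning forest of the evidence graph, rooted at
the lexicographically first treatment of each component.  Any other relative
effect is a functional parameter, expressed as a +/-1 combination of basic
parameters along the unique tree path.

For node-splitting structures, every multi-arm study containing the split
pair ``x:y`` is subdivided into two virtual studies: one with only the
``x`` and ``y`` arms (direct evidence) and one with all remaining arms
(indirect evidence); a single-arm remainder is dropped since it carries no
relative-effect information.  Contrast-style multi-arm studies cannot be
subdivided (their reported contrasts are correlated through the reference
arm), so they are instead re-referenced to ``x`` with the ``x:y`` contrast
given an independent split distribution.  Indirect components disconnected
from the split pair are retained by default so that they keep informing the
shared heterogeneity parameter.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import networkx as nx
import numpy as np
from scipy import stats

from .network_core import ComparisonPair, Network, NetworkError, Study
from .split_rule import splittable

__all__ = [
    "StudyPlan",
    "ModelStructure",
    "PriorSpec",
    "StartingValues",
    "consistency_structure",
    "nodesplit_structure",
    "express_functional",
    "make_priors",
    "make_starting_values",
]


@dataclass(frozen=True)
class StudyPlan:
    """Parameterisation of one (possibly virtual) study.

    ``role`` is ``"consistency"`` (contrasts have functional-parameter
    means), ``"direct"`` (the single contrast estimates the direct split
    parameter) or ``"mixed"`` (contrast-style study containing the split
    pair: one split contrast plus consistency contrasts).
    """

    id: str
    source: str  # id of the real study holding the measurements
    reference: str
    nonref: Tuple[str, ...]
    role: str = "consistency"
    split_contrast_index: Optional[int] = None

    @property
    def treatments(self) -> Tuple[str, ...]:
        return (self.reference,) + self.nonref

    @property
    def n_contrasts(self) -> int:
        return len(self.nonref)

    @property
    def is_virtual(self) -> bool:
        return self.id != self.source


@dataclass(frozen=True)
class ModelStructure:
    """Basic parameters, per-study plans and the optional split descriptor."""

    basic: Tuple[Tuple[str, str], ...]  # directed edges (a, b): d_{a,b}
    plans: Tuple[StudyPlan, ...]
    split: Optional[ComparisonPair] = None
    virtual_map: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    components: Tuple[frozenset, ...] = ()

    def parameter_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b in self.basic:
            g.add_edge(a, b)
        for comp in self.components:
            g.add_nodes_from(comp)
        return g

    @property
    def split_name(self) -> Optional[str]:
        return None if self.split is None else f"d.dir.{self.split.x}.{self.split.y}"

    def to_dict(self) -> dict:
        return {
            "basic": [list(e) for e in self.basic],
            "split": None if self.split is None else [self.split.x, self.split.y],
            "plans": [
                {
                    "id": p.id,
                    "source": p.source,
                    "reference": p.reference,
                    "nonref": list(p.nonref),
                    "role": p.role,
                    "split_contrast_index": p.split_contrast_index,
                }
                for p in self.plans
            ],
            "virtual_map": {k: list(v) for k, v in self.virtual_map.items()},
            "components": [sorted(c) for c in self.components],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _bfs_forest(graph: nx.Graph):
    """Deterministic BFS forest: per component, root at the smallest node.

    Returns (edges, depth) where edges are (parent, child) in BFS order and
    depth maps every node to its distance from its component root.
    """
    edges: List[Tuple[str, str]] = []
    depth: Dict[str, int] = {}
    for comp in sorted(nx.connected_components(graph), key=min):
        root = min(comp)
        depth[root] = 0
        queue = deque([root])
        while queue:
            node = queue.popleft()
            for nb in sorted(graph.neighbors(node)):
                if nb not in depth:
                    depth[nb] = depth[node] + 1
                    edges.append((node, nb))
                    queue.append(nb)
    return edges, depth


def _plan_reference(treatments, depth):
    return min(treatments, key=lambda t: (depth[t], t))


def consistency_structure(network: Network) -> ModelStructure:
    """Spanning-forest parameterisation of the full evidence network."""
    if not network.studies:
        raise NetworkError("cannot build a model structure for an empty network")
    graph = network.graph()
    edges, depth = _bfs_forest(graph)
    plans = []
    for s in network.studies:
        ref = _plan_reference(s.treatments, depth)
        nonref = tuple(t for t in s.treatments if t != ref)
        plans.append(StudyPlan(id=s.id, source=s.id, reference=ref, nonref=nonref))
    components = tuple(sorted((frozenset(c) for c in nx.connected_components(graph)), key=min))
    return ModelStructure(
        basic=tuple(edges), plans=tuple(plans), split=None, components=components
    )


def nodesplit_structure(
    network: Network, pair: ComparisonPair, keep_disconnected: bool = True
) -> ModelStructure:
    """Structure splitting ``pair`` into direct and indirect parameters.

    Requires ``pair`` to be selected by the decision rule, which guarantees
    that the indirect network connects the two split treatments.
    """
    if not splittable(network, pair):
        raise NetworkError(f"comparison {pair} is not selected by the decision rule")
    x, y = pair.x, pair.y

    direct_plans: List[StudyPlan] = []
    indirect_studies: List[Tuple[str, str, Tuple[str, ...]]] = []  # (plan id, source, arms)
    mixed_plans: List[Tuple[str, Tuple[str, ...]]] = []  # (study id, other arms)
    virtual_map: Dict[str, Tuple[str, ...]] = {}

    for s in network.studies:
        if not s.contains(pair):
            indirect_studies.append((s.id, s.id, s.treatments))
            continue
        if s.n_arms == 2:
            direct_plans.append(
                StudyPlan(id=s.id, source=s.id, reference=x, nonref=(y,), role="direct")
            )
        elif s.style == "arm":
            remainder = tuple(t for t in s.treatments if t not in (x, y))
            dir_id = f"{s.id}::dir"
            direct_plans.append(
                StudyPlan(id=dir_id, source=s.id, reference=x, nonref=(y,), role="direct")
            )
            parts = [dir_id]
            if len(remainder) >= 2:
                ind_id = f"{s.id}::ind"
                indirect_studies.append((ind_id, s.id, remainder))
                parts.append(ind_id)
            virtual_map[s.id] = tuple(parts)
        else:
            # contrast-style multi-arm study: keep whole, reference x, the
            # x:y contrast independent of the consistency contrasts
            others = tuple(t for t in s.treatments if t not in (x, y))
            mixed_plans.append((s.id, others))

    # indirect-evidence parameter graph
    graph = nx.Graph()
    for _, _, arms in indirect_studies:
        graph.add_nodes_from(arms)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                graph.add_edge(arms[i], arms[j])
    for _, others in mixed_plans:
        for t in others:
            graph.add_edge(x, t)
    # the decision rule guarantees x and y are present and connected
    edges, depth = _bfs_forest(graph)
    components = tuple(sorted((frozenset(c) for c in nx.connected_components(graph)), key=min))

    if not keep_disconnected:
        main = next(c for c in components if x in c)
        indirect_studies = [
            (pid, src, arms) for pid, src, arms in indirect_studies if arms[0] in main
        ]
        components = (main,)
        edges = [(a, b) for a, b in edges if a in main]

    plans: List[StudyPlan] = []
    order = {s.id: i for i, s in enumerate(network.studies)}
    ind_plans = [
        StudyPlan(
            id=pid,
            source=src,
            reference=_plan_reference(arms, depth),
            nonref=tuple(t for t in arms if t != _plan_reference(arms, depth)),
        )
        for pid, src, arms in indirect_studies
    ]
    mix_plans = [
        StudyPlan(
            id=sid,
            source=sid,
            reference=x,
            nonref=(y,) + others,
            role="mixed",
            split_contrast_index=0,
        )
        for sid, others in mixed_plans
    ]
    plans = sorted(
        direct_plans + ind_plans + mix_plans, key=lambda p: (order[p.source], p.id)
    )
    return ModelStructure(
        basic=tuple(edges),
        plans=tuple(plans),
        split=pair,
        virtual_map=virtual_map,
        components=components,
    )


def express_functional(
    structure: ModelStructure, pair: Union[ComparisonPair, Tuple[str, str]]
) -> Dict[Tuple[str, str], int]:
    """Express ``d_{x,y}`` as a +/-1 combination of basic parameters.

    Returns a mapping from directed basic edges to coefficients such that
    ``d_{x,y} = sum(coef * d_edge)``; the empty mapping for ``x == y``.
    """
    x, y = (pair.x, pair.y) if isinstance(pair, ComparisonPair) else pair
    if x == y:
        return {}
    g = structure.parameter_graph()
    for t in (x, y):
        if t not in g:
            raise NetworkError(f"treatment {t!r} not present in the model structure")
    try:
        path = nx.shortest_path(g, x, y)
    except nx.NetworkXNoPath:
        raise NetworkError(f"{x!r} and {y!r} lie in different components")
    basic = set(structure.basic)
    combo: Dict[Tuple[str, str], int] = {}
    for a, b in zip(path, path[1:]):
        if (a, b) in basic:
            combo[(a, b)] = combo.get((a, b), 0) + 1
        else:
            combo[(b, a)] = combo.get((b, a), 0) - 1
    return {e: c for e, c in combo.items() if c != 0}


@dataclass(frozen=True)
class PriorSpec:
    """Vague-prior specification derived from the outcome scale of the data.

    ``scale`` is the largest absolute observed within-study contrast K;
    basic parameters and study baselines get N(0, effect_sd^2) priors and
    the heterogeneity standard deviation a U(0, heterogeneity_upper) prior.
    """

    scale: float
    effect_sd: float
    heterogeneity_upper: float

    def __post_init__(self) -> None:
        if not (self.effect_sd > 0 and self.heterogeneity_upper > 0):
            raise NetworkError("prior scales must be positive")


def make_priors(
    network: Network,
    effect_multiplier: float = 15.0,
    heterogeneity_multiplier: float = 1.0,
) -> PriorSpec:
    """Derive the outcome scale K and the vague priors from the data.

    K is the maximum absolute within-study contrast (difference of arm means
    for arm data, reported difference for contrast data); if every contrast
    is zero, K falls back to the largest arm-level dispersion so that the
    priors stay proper.  All-zero data are rejected.
    """
    contrasts: List[float] = []
    dispersions: List[float] = []
    for s in network.studies:
        if s.style == "arm":
            means = [m.mean for m in s.measurements]
            dispersions.extend(m.std_dev for m in s.measurements)
            for i in range(len(means)):
                for j in range(i + 1, len(means)):
                    contrasts.append(abs(means[i] - means[j]))
        else:
            for m in s.measurements:
                if not m.is_reference:
                    contrasts.append(abs(m.difference))
                    dispersions.append(m.std_err)
    if not contrasts:
        raise NetworkError("network has no measurements to scale priors from")
    scale = max(contrasts)
    if scale == 0.0:
        scale = max(dispersions, default=0.0)
    if scale == 0.0:
        raise NetworkError("degenerate all-zero data: outcome scale K would be 0")
    return PriorSpec(
        scale=scale,
        effect_sd=effect_multiplier * scale,
        heterogeneity_upper=heterogeneity_multiplier * scale,
    )


@dataclass(frozen=True)
class StartingValues:
    """Overdispersed but in-support starting values for one chain."""

    mu: Dict[str, float]
    basic: Dict[Tuple[str, str], float]
    sigma: float
    split: Optional[float] = None


def make_starting_values(
    structure: ModelStructure,
    priors: PriorSpec,
    n_chains: int,
    seed: int,
) -> List[StartingValues]:
    """Deterministic dispersed starting values for ``n_chains`` chains.

    Location parameters start at dispersed quantiles of N(0, (effect_sd/10)^2)
    with a small seeded per-parameter jitter; sigma starts equally spaced in
    (0.1, 0.9) times its prior upper bound.
    """
    if n_chains < 2:
        raise NetworkError("at least 2 chains are required")
    rng = np.random.default_rng(seed)
    sd = priors.effect_sd / 10.0
    mu_ids = [p.id for p in structure.plans]
    jitter = {
        name: rng.normal(0.0, sd / 10.0)
        for name in mu_ids + [f"d.{a}.{b}" for a, b in structure.basic] + ["d.dir"]
    }
    sigma_grid = np.linspace(0.1, 0.9, n_chains) * priors.heterogeneity_upper
    out = []
    for c in range(n_chains):
        offset = stats.norm.ppf((c + 1) / (n_chains + 1)) * sd
        mu = {pid: offset + jitter[pid] for pid in mu_ids}
        basic = {
            (a, b): offset + jitter[f"d.{a}.{b}"] for a, b in structure.basic
        }
        split = offset + jitter["d.dir"] if structure.split is not None else None
        out.append(
            StartingValues(mu=mu, basic=basic, sigma=float(sigma_grid[c]), split=split)
        )
    return out
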