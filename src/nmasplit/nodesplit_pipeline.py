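"""End-to-end node-splitting analysis.

Estimates the consistency model once, then one node-splitting model per
comparison selected by the decision rule.  All models share the prior
specification computed from the full network (so heterogeneity estimates are
comparable across models) and derive their sampler seeds deterministically
from one master seed.  Each split comparison is summarised by its direct,
indirect and network (consistency-model) estimates, the two-sided Bayesian
inconsistency p-value, and the split model's posterior median heterogeneity.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .inference import (
    ConvergenceReport,
    PosteriorSamples,
    assemble_model,
    gelman_rubin,
    sample_posterior,
)
from .model_gen import (
    consistency_structure,
    express_functional,
    make_priors,
    nodesplit_structure,
)
from .network_core import ComparisonPair, Network, NetworkError, connected_components
from .split_rule import comparisons_to_split

__all__ = [
    "Settings",
    "NodeSplitResult",
    "AnalysisReport",
    "run_nodesplit_analysis",
    "inconsistency_pvalue",
    "heterogeneity_table",
    "export_report",
    "export_densities",
]


@dataclass(frozen=True)
class Settings:
    """Sampler and analysis settings shared by all models in one analysis."""

    n_chains: int = 4
    n_adapt: int = 5000
    n_iter: int = 20000
    seed: int = 1
    psrf_threshold: float = 1.05
    alternative: str = "two-sided"  # or "one-sided"
    keep_disconnected: bool = True
    effect_multiplier: float = 15.0
    heterogeneity_multiplier: float = 1.0


@dataclass(frozen=True)
class NodeSplitResult:
    """Direct/indirect/network estimates and conflict assessment for one pair."""

    pair: ComparisonPair
    direct: Dict[str, float]
    indirect: Dict[str, float]
    network: Dict[str, float]
    p_value: float
    sigma_median: float
    convergence: ConvergenceReport


@dataclass
class AnalysisReport:
    """Results of a full node-splitting analysis."""

    consistency: pd.DataFrame
    results: List[NodeSplitResult]
    heterogeneity: pd.DataFrame
    convergence: Dict[str, ConvergenceReport]
    settings: Settings
    samples: Dict[str, PosteriorSamples] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(r.passed for r in self.convergence.values())


def _model_seed(master_seed: int, label: str) -> int:
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def _summarise(draws: np.ndarray) -> Dict[str, float]:
    return {
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)),
        "q2.5": float(np.quantile(draws, 0.025)),
        "median": float(np.quantile(draws, 0.5)),
        "q97.5": float(np.quantile(draws, 0.975)),
    }


def inconsistency_pvalue(
    direct_draws: np.ndarray,
    indirect_draws: np.ndarray,
    alternative: str = "two-sided",
) -> float:
    """Bayesian tail probability that direct and indirect evidence conflict.

    ``p = 2 * min(Pr(d_dir > d_ind), Pr(d_ind > d_dir))`` estimated from
    paired posterior draws, ties counted half to each side; the one-sided
    variant drops the factor 2.
    """
    direct_draws = np.asarray(direct_draws, dtype=float)
    indirect_draws = np.asarray(indirect_draws, dtype=float)
    if direct_draws.size == 0 or indirect_draws.size == 0:
        raise NetworkError("p-value requires non-empty draw vectors")
    if direct_draws.shape != indirect_draws.shape:
        raise NetworkError("direct and indirect draws must be paired")
    n = direct_draws.size
    greater = np.count_nonzero(direct_draws > indirect_draws)
    ties = np.count_nonzero(direct_draws == indirect_draws)
    p_gt = (greater + 0.5 * ties) / n
    tail = min(p_gt, 1.0 - p_gt)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * tail))
    if alternative == "one-sided":
        return float(tail)
    raise NetworkError(f"unknown alternative {alternative!r}")


def run_nodesplit_analysis(
    network: Network, settings: Settings = Settings()
) -> AnalysisReport:
    """Run the consistency model plus one split model per selected comparison."""
    if not network.studies:
        raise NetworkError("cannot analyse an empty network")
    if len(connected_components(network)) != 1:
        raise NetworkError("estimation requires a connected network")

    priors = make_priors(
        network,
        effect_multiplier=settings.effect_multiplier,
        heterogeneity_multiplier=settings.heterogeneity_multiplier,
    )

    cons_structure = consistency_structure(network)
    cons_model = assemble_model(network, cons_structure, priors)
    cons_samples = sample_posterior(
        cons_model,
        n_chains=settings.n_chains,
        n_adapt=settings.n_adapt,
        n_iter=settings.n_iter,
        seed=_model_seed(settings.seed, "consistency"),
    )
    convergence: Dict[str, ConvergenceReport] = {
        "consistency": gelman_rubin(cons_samples, settings.psrf_threshold)
    }
    samples: Dict[str, PosteriorSamples] = {"consistency": cons_samples}

    results: List[NodeSplitResult] = []
    for pair in comparisons_to_split(network):
        label = str(pair)
        structure = nodesplit_structure(
            network, pair, keep_disconnected=settings.keep_disconnected
        )
        model = assemble_model(network, structure, priors)
        split_samples = sample_posterior(
            model,
            n_chains=settings.n_chains,
            n_adapt=settings.n_adapt,
            n_iter=settings.n_iter,
            seed=_model_seed(settings.seed, label),
        )
        report = gelman_rubin(split_samples, settings.psrf_threshold)
        convergence[label] = report
        samples[label] = split_samples

        direct = split_samples.pooled(f"d.dir.{pair.x}.{pair.y}")
        indirect = split_samples.pooled(f"d.ind.{pair.x}.{pair.y}")
        expr = {
            f"d.{a}.{b}": float(c)
            for (a, b), c in express_functional(cons_structure, pair).items()
        }
        network_draws = cons_samples.linear_combination(expr)
        results.append(
            NodeSplitResult(
                pair=pair,
                direct=_summarise(direct),
                indirect=_summarise(indirect),
                network=_summarise(network_draws),
                p_value=inconsistency_pvalue(direct, indirect, settings.alternative),
                sigma_median=float(np.median(split_samples.pooled("sigma"))),
                convergence=report,
            )
        )

    rows = [
        {
            "model": "consistency",
            "sigma_median": float(np.median(cons_samples.pooled("sigma"))),
        }
    ] + [
        {"model": str(r.pair), "sigma_median": r.sigma_median} for r in results
    ]
    return AnalysisReport(
        consistency=cons_samples.summary(),
        results=results,
        heterogeneity=pd.DataFrame(rows, columns=["model", "sigma_median"]),
        convergence=convergence,
        settings=settings,
        samples=samples,
    )


def heterogeneity_table(report: AnalysisReport) -> pd.DataFrame:
    """One row per estimated model with its posterior median heterogeneity."""
    return report.heterogeneity.copy()


def _report_dict(report: AnalysisReport) -> dict:
    return {
        "consistency": report.consistency.reset_index().to_dict(orient="records"),
        "results": [
            {
                "comparison": str(r.pair),
                "direct": r.direct,
                "indirect": r.indirect,
                "network": r.network,
                "p_value": r.p_value,
                "sigma_median": r.sigma_median,
                "converged": r.convergence.passed,
            }
            for r in report.results
        ],
        "heterogeneity": report.heterogeneity.to_dict(orient="records"),
        "convergence": {
            label: {
                "passed": c.passed,
                "max_psrf": max(c.psrf.values()) if c.psrf else 1.0,
            }
            for label, c in report.convergence.items()
        },
        "settings": {
            "n_chains": report.settings.n_chains,
            "n_adapt": report.settings.n_adapt,
            "n_iter": report.settings.n_iter,
            "seed": report.settings.seed,
            "alternative": report.settings.alternative,
        },
    }


def export_report(report: AnalysisReport, format: str = "text") -> str:
    """Serialise the analysis report as ``text``, ``json`` or ``csv``."""
    if format == "json":
        return json.dumps(_report_dict(report), indent=2)
    if format == "csv":
        buf = io.StringIO()
        report.heterogeneity.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "text":
        lines = ["Node-splitting analysis", "======================="]
        for r in report.results:
            lines.append("")
            lines.append(f"comparison {r.pair}  (p = {r.p_value:.4f})")
            for label, summ in (
                ("direct", r.direct),
                ("indirect", r.indirect),
                ("network", r.network),
            ):
                lines.append(
                    f"  {label:9s} mean {summ['mean']: .4f}  sd {summ['sd']:.4f}"
                    f"  95% CrI ({summ['q2.5']: .4f}, {summ['q97.5']: .4f})"
                )
        lines.append("")
        lines.append("Heterogeneity (posterior median sigma):")
        for row in report.heterogeneity.itertuples(index=False):
            lines.append(f"  {row.model:12s} {row.sigma_median:.4f}")
        lines.append("")
        status = "passed" if report.converged else "FAILED"
        lines.append(f"Convergence: {status}")
        return "\n".join(lines) + "\n"
    raise NetworkError(f"unknown report format {format!r}")


def export_densities(
    report: AnalysisReport, pair: ComparisonPair, n_points: int = 512
) -> pd.DataFrame:
    """Kernel density estimates of the direct, indirect and network posteriors.

    Three-row layout per comparison: one ``series`` value per evidence source,
    each with an equally spaced grid and Gaussian-KDE density values.
    """
    label = str(pair)
    if label not in report.samples:
        raise NetworkError(f"no split model was estimated for {label}")
    split_samples = report.samples[label]
    series = {
        "direct": split_samples.pooled(f"d.dir.{pair.x}.{pair.y}"),
        "indirect": split_samples.pooled(f"d.ind.{pair.x}.{pair.y}"),
        "network": _network_draws(report, pair),
    }
    frames = []
    for name, draws in series.items():
        lo, hi = np.min(draws), np.max(draws)
        pad = 0.05 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, n_points)
        kde = stats.gaussian_kde(draws)
        frames.append(pd.DataFrame({"series": name, "x": grid, "density": kde(grid)}))
    return pd.concat(frames, ignore_index=True)


def _network_draws(report: AnalysisReport, pair: ComparisonPair) -> np.ndarray:
    """Consistency-model draws for a pair, via the basic-parameter tree path."""
    import networkx as nx

    cons_samples = report.samples["consistency"]
    g = nx.Graph()
    for name in cons_samples.names:
        parts = name.split(".")
        if len(parts) == 3 and parts[0] == "d":
            g.add_edge(parts[1], parts[2], name=name, head=parts[2])
    path = nx.shortest_path(g, pair.x, pair.y)
    coeffs: Dict[str, float] = {}
    for a, b in zip(path, path[1:]):
        data = g.get_edge_data(a, b)
        coeffs[data["name"]] = coeffs.get(data["name"], 0.0) + (
            1.0 if data["head"] == b else -1.0
        )
    return cons_samples.linear_combination(coeffs)
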