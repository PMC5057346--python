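"""Programmatic evidence-structure fixtures and outcome-data simulation.

The named fixtures reproduce small reference topologies used throughout the
test-suite (single loops with and without multi-arm trials, a four-arm-trial
network without potential inconsistency, and the seven-trial Parkinson
network, whose outcome data also ship with the package).  Outcome data with
known truth are simulated from the generative hierarchical model: study
baselines, compound-symmetry random effects, and normal sampling noise for
the observed arm means; an optional inconsistency offset ``omega`` shifts
one comparison within the studies holding its direct evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np

from .inference import build_re_covariance
from .network_core import (
    ArmMeasurement,
    ComparisonPair,
    Network,
    NetworkError,
    Study,
    read_network,
)

__all__ = [
    "FixtureNetwork",
    "SimulationTruth",
    "figure_networks",
    "parkinson_network",
    "simulate_network_data",
    "draw_random_effects",
    "replicate_two_arm_studies",
]


@dataclass(frozen=True)
class FixtureNetwork:
    """A named evidence topology: per-study treatment sets, no outcome data."""

    name: str
    studies: Tuple[Tuple[str, ...], ...]

    @property
    def treatments(self) -> Tuple[str, ...]:
        seen = set()
        for arms in self.studies:
            seen.update(arms)
        return tuple(sorted(seen))

    def skeleton_network(self) -> Network:
        """A data-valid network with placeholder arm outcomes.

        Only the topology matters for decision-rule computations; arm means
        are deterministic placeholders.
        """
        studies = []
        for k, arms in enumerate(self.studies, start=1):
            measurements = tuple(
                ArmMeasurement(treatment=t, mean=float(j), std_dev=1.0, sample_size=10)
                for j, t in enumerate(sorted(arms))
            )
            studies.append(Study(id=str(k), measurements=measurements))
        return Network(studies=tuple(studies))


def figure_networks() -> Dict[str, FixtureNetwork]:
    """The named reference topologies.

    ``fig1a`` and ``fig3b`` share the same composition (trials xy, xz, xyz);
    the three-treatment full loop ``fig3c`` adds a yz trial, and ``fig2a``
    is the four-arm-trial network in which every candidate loop is supported
    by the four-arm trial alone.
    """
    defs = {
        "fig1a": (("x", "y"), ("x", "z"), ("x", "y", "z")),
        "fig3a": (("x", "y"), ("x", "y", "z")),
        "fig3b": (("x", "y"), ("x", "z"), ("x", "y", "z")),
        "fig3c": (("x", "y"), ("x", "z"), ("y", "z"), ("x", "y", "z")),
        "fig2a": (("w", "x", "y", "z"), ("w", "z"), ("x", "y")),
        "fig4a": (
            ("x", "y", "z"),
            ("x", "y", "z"),
            ("x", "y", "z"),
            ("x", "y"),
            ("x", "z"),
        ),
        "parkinson": (
            ("A", "C"),
            ("A", "B"),
            ("A", "B", "D"),
            ("C", "D"),
            ("C", "D"),
            ("D", "E"),
            ("D", "E"),
        ),
    }
    return {name: FixtureNetwork(name=name, studies=studies) for name, studies in defs.items()}


def parkinson_network() -> Network:
    """The seven-trial Parkinson off-time dataset packaged with the library."""
    source = resources.files("nmasplit").joinpath("data/parkinson.csv")
    with resources.as_file(source) as path:
        return read_network(path, style="arm")


@dataclass(frozen=True)
class SimulationTruth:
    """Known generative truth for parameter-recovery simulations.

    ``effects`` maps treatments to their true relative effect versus an
    implicit zero baseline (missing treatments default to 0), so the true
    relative effect of ``b`` versus ``a`` is ``effects[b] - effects[a]``.
    ``omega`` is an optional inconsistency offset applied to one comparison:
    in every study containing both of its treatments, the effect of the
    lexicographically larger treatment is shifted by the offset.
    """

    effects: Dict[str, float] = field(default_factory=dict)
    sigma: float = 0.0
    n_per_arm: int = 100
    arm_sd: float = 1.0
    mu_range: Tuple[float, float] = (-1.0, 1.0)
    omega: Optional[Tuple[ComparisonPair, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise NetworkError("sigma must be non-negative")
        if self.n_per_arm < 2:
            raise NetworkError("simulated sample sizes must be at least 2")
        if not (self.arm_sd > 0):
            raise NetworkError("arm_sd must be positive")


def draw_random_effects(
    mean: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of a study's random-effect vector under compound symmetry."""
    mean = np.asarray(mean, dtype=float)
    if sigma == 0.0:
        return mean.copy()
    cov = build_re_covariance(len(mean), sigma)
    return rng.multivariate_normal(mean, cov)


def simulate_network_data(fixture: FixtureNetwork, truth: SimulationTruth) -> Network:
    """Simulate arm-based outcome data for a fixture topology."""
    if truth.omega is not None:
        pair, _ = truth.omega
        if not any(
            pair.x in arms and pair.y in arms for arms in fixture.studies
        ):
            raise NetworkError(
                f"omega targets comparison {pair}, absent from fixture {fixture.name!r}"
            )
    rng = np.random.default_rng(truth.seed)
    noise_sd = truth.arm_sd / np.sqrt(truth.n_per_arm)
    studies = []
    for k, arms in enumerate(fixture.studies, start=1):
        arms = tuple(sorted(arms))
        effect = {t: truth.effects.get(t, 0.0) for t in arms}
        if truth.omega is not None:
            pair, offset = truth.omega
            if pair.x in arms and pair.y in arms:
                effect[pair.y] = effect[pair.y] + offset
        ref, nonref = arms[0], arms[1:]
        delta = draw_random_effects(
            np.array([effect[t] - effect[ref] for t in nonref]), truth.sigma, rng
        )
        mu = rng.uniform(*truth.mu_range)
        theta = {ref: mu, **{t: mu + d for t, d in zip(nonref, delta)}}
        measurements = tuple(
            ArmMeasurement(
                treatment=t,
                mean=float(theta[t] + rng.normal(0.0, noise_sd)),
                std_dev=truth.arm_sd,
                sample_size=truth.n_per_arm,
            )
            for t in arms
        )
        studies.append(Study(id=str(k), measurements=measurements))
    return Network(studies=tuple(studies))


def replicate_two_arm_studies(fixture: FixtureNetwork, factor: int) -> FixtureNetwork:
    """Repeat every two-arm study ``factor`` times (multi-arm trials stay single).

    Useful for power studies, where a single trial per comparison gives very
    imprecise direct and indirect estimates.
    """
    if factor < 1:
        raise NetworkError("replication factor must be >= 1")
    studies = []
    for arms in fixture.studies:
        studies.extend([arms] * (factor if len(arms) == 2 else 1))
    return FixtureNetwork(name=f"{fixture.name}x{factor}", studies=tuple(studies))
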