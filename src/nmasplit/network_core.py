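"""Evidence-network data model and long-format (one arm per row) I/O.

An evidence network is an ordered collection of studies, each evaluating a
set of two or more treatments.  Outcome data are continuous on a linear
additive scale and come in one of two styles:

* **arm** -- per-arm absolute effects: mean, standard deviation and sample
  size (normal likelihood for the observed arm mean);
* **contrast** -- per-arm relative effects versus a study-specific reference
  arm, with the standard error of each contrast and, for studies with three
  or more arms, the standard error of the reference arm's absolute effect
  (needed to reconstruct the covariance between contrasts).

Treatments are plain case-sensitive string labels; all canonical orderings
are lexicographic on the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import networkx as nx
import pandas as pd

__all__ = [
    "NetworkError",
    "ComparisonPair",
    "ArmMeasurement",
    "ContrastMeasurement",
    "Study",
    "Network",
    "read_network",
    "write_network",
    "network_to_frame",
    "direct_comparisons",
    "connected_components",
    "arm_standard_error",
]

ARM_COLUMNS = ("study", "treatment", "mean", "std.dev", "sampleSize")
CONTRAST_COLUMNS = ("study", "treatment", "diff", "std.err", "base.se")


class NetworkError(ValueError):
    """Raised when evidence-network data violate a structural invariant."""


@dataclass(frozen=True, order=True)
class ComparisonPair:
    """Unordered treatment pair, canonicalised so that ``x < y``."""

    x: str
    y: str

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise NetworkError(f"degenerate comparison {self.x!r}:{self.y!r}")
        if self.y < self.x:
            x, y = self.y, self.x
            object.__setattr__(self, "x", x)
            object.__setattr__(self, "y", y)

    def __iter__(self):
        yield self.x
        yield self.y

    def __str__(self) -> str:
        return f"{self.x}:{self.y}"

    @classmethod
    def parse(cls, text: str) -> "ComparisonPair":
        parts = [p for p in text.replace(",", ":").split(":") if p]
        if len(parts) != 2:
            raise NetworkError(f"cannot parse comparison {text!r}")
        return cls(parts[0], parts[1])


@dataclass(frozen=True)
class ArmMeasurement:
    """Absolute outcome of one arm: mean, standard deviation, sample size."""

    treatment: str
    mean: float
    std_dev: float
    sample_size: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise NetworkError(f"non-finite mean for arm {self.treatment!r}")
        if not (self.std_dev > 0):
            raise NetworkError(
                f"std_dev must be positive for arm {self.treatment!r}, got {self.std_dev}"
            )
        if int(self.sample_size) != self.sample_size or self.sample_size < 1:
            raise NetworkError(
                f"sample_size must be an integer >= 1 for arm {self.treatment!r}"
            )


@dataclass(frozen=True)
class ContrastMeasurement:
    """Relative effect of one arm versus the study reference arm.

    The reference arm itself is represented by a row with ``difference`` and
    ``std_err`` absent; ``base_std_err`` lives on the reference row and is
    required for studies with three or more arms.
    """

    treatment: str
    difference: Optional[float] = None
    std_err: Optional[float] = None
    base_std_err: Optional[float] = None

    @property
    def is_reference(self) -> bool:
        return self.difference is None

    def __post_init__(self) -> None:
        if (self.difference is None) != (self.std_err is None):
            raise NetworkError(
                f"arm {self.treatment!r}: difference and std_err must be "
                "jointly present or jointly absent"
            )
        if self.std_err is not None and not (self.std_err > 0):
            raise NetworkError(f"std_err must be positive for arm {self.treatment!r}")
        if self.base_std_err is not None and not (self.base_std_err > 0):
            raise NetworkError(f"base_std_err must be positive for arm {self.treatment!r}")


Measurement = Union[ArmMeasurement, ContrastMeasurement]


@dataclass(frozen=True)
class Study:
    """A trial evaluating >=2 distinct treatments, one measurement per arm."""

    id: str
    measurements: tuple

    def __post_init__(self) -> None:
        if len(self.measurements) < 2:
            raise NetworkError(f"study {self.id!r} has fewer than 2 arms")
        treatments = [m.treatment for m in self.measurements]
        if len(set(treatments)) != len(treatments):
            raise NetworkError(f"study {self.id!r} lists a treatment more than once")
        styles = {type(m) for m in self.measurements}
        if len(styles) != 1:
            raise NetworkError(f"study {self.id!r} mixes arm and contrast measurements")
        if self.style == "contrast":
            refs = [m for m in self.measurements if m.is_reference]
            if len(refs) != 1:
                raise NetworkError(
                    f"contrast study {self.id!r} must have exactly one reference row"
                )
            if len(self.measurements) >= 3 and refs[0].base_std_err is None:
                raise NetworkError(
                    f"contrast study {self.id!r} has >=3 arms but no base.se on "
                    "the reference row"
                )

    @property
    def style(self) -> str:
        return "arm" if isinstance(self.measurements[0], ArmMeasurement) else "contrast"

    @property
    def treatments(self) -> tuple:
        """Treatment set T(S_i), lexicographically sorted."""
        return tuple(sorted(m.treatment for m in self.measurements))

    @property
    def n_arms(self) -> int:
        return len(self.measurements)

    def measurement(self, treatment: str) -> Measurement:
        for m in self.measurements:
            if m.treatment == treatment:
                return m
        raise KeyError(treatment)

    def contains(self, pair: ComparisonPair) -> bool:
        ts = set(self.treatments)
        return pair.x in ts and pair.y in ts


@dataclass(frozen=True)
class Network:
    """Ordered collection of studies; treatments are their union."""

    studies: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise NetworkError("study ids must be unique within a network")

    @property
    def treatments(self) -> tuple:
        seen = set()
        for s in self.studies:
            seen.update(s.treatments)
        return tuple(sorted(seen))

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.id == study_id:
                return s
        raise KeyError(study_id)

    def graph(self) -> nx.Graph:
        """Undirected evidence graph: edge = co-occurrence in some study."""
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for s in self.studies:
            ts = s.treatments
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    g.add_edge(ts[i], ts[j])
        return g

    @property
    def style(self) -> Optional[str]:
        return self.studies[0].style if self.studies else None


def _require_columns(frame: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise NetworkError(f"missing required columns: {missing}")


def read_network(source: Union[str, IO], style: str = "arm") -> Network:
    """Read a long-format CSV into a :class:`Network`.

    Parameters
    ----------
    source:
        Path or file-like object with one arm per row.
    style:
        ``"arm"`` expects columns ``study,treatment,mean,std.dev,sampleSize``;
        ``"contrast"`` expects ``study,treatment,diff,std.err,base.se`` with
        an empty ``diff``/``std.err`` on each study's reference row.
    """
    if style not in ("arm", "contrast"):
        raise NetworkError(f"unknown data style {style!r}")
    frame = pd.read_csv(source, dtype={"study": str, "treatment": str})
    return network_from_frame(frame, style)


def network_from_frame(frame: pd.DataFrame, style: str = "arm") -> Network:
    """Build a :class:`Network` from a long-format dataframe."""
    frame = frame.copy()
    frame["study"] = frame["study"].astype(str)
    frame["treatment"] = frame["treatment"].astype(str)
    if style == "arm":
        _require_columns(frame, ARM_COLUMNS)
    else:
        _require_columns(frame, ("study", "treatment", "diff", "std.err"))
        if "base.se" not in frame.columns:
            frame["base.se"] = float("nan")

    studies = []
    for study_id in frame["study"].drop_duplicates():
        rows = frame[frame["study"] == study_id]
        measurements = []
        for _, row in rows.iterrows():
            if style == "arm":
                measurements.append(
                    ArmMeasurement(
                        treatment=row["treatment"],
                        mean=float(row["mean"]),
                        std_dev=float(row["std.dev"]),
                        sample_size=int(row["sampleSize"]),
                    )
                )
            else:
                diff = row["diff"]
                se = row["std.err"]
                base = row["base.se"]
                measurements.append(
                    ContrastMeasurement(
                        treatment=row["treatment"],
                        difference=None if pd.isna(diff) else float(diff),
                        std_err=None if pd.isna(se) else float(se),
                        base_std_err=None if pd.isna(base) else float(base),
                    )
                )
        studies.append(Study(id=study_id, measurements=tuple(measurements)))
    return Network(studies=tuple(studies))


def network_to_frame(network: Network) -> pd.DataFrame:
    """Serialise a network back to its long-format dataframe."""
    records = []
    for s in network.studies:
        for m in s.measurements:
            if isinstance(m, ArmMeasurement):
                records.append(
                    {
                        "study": s.id,
                        "treatment": m.treatment,
                        "mean": m.mean,
                        "std.dev": m.std_dev,
                        "sampleSize": m.sample_size,
                    }
                )
            else:
                records.append(
                    {
                        "study": s.id,
                        "treatment": m.treatment,
                        "diff": m.difference,
                        "std.err": m.std_err,
                        "base.se": m.base_std_err,
                    }
                )
    columns = list(ARM_COLUMNS if network.style in (None, "arm") else CONTRAST_COLUMNS)
    return pd.DataFrame.from_records(records, columns=columns)


def write_network(network: Network, target: Union[str, IO]) -> None:
    """Write a network as long-format CSV (inverse of :func:`read_network`)."""
    network_to_frame(network).to_csv(target, index=False)


def direct_comparisons(network: Network) -> set:
    """All unordered treatment pairs co-occurring in at least one study."""
    pairs = set()
    for s in network.studies:
        ts = s.treatments
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                pairs.add(ComparisonPair(ts[i], ts[j]))
    return pairs


def connected_components(network: Network) -> tuple:
    """Partition of the treatments under the co-occurrence relation.

    Returns a tuple of frozensets ordered by their smallest member.
    """
    comps = nx.connected_components(network.graph())
    return tuple(sorted((frozenset(c) for c in comps), key=min))


def arm_standard_error(std_dev: float, sample_size: int) -> float:
    """Standard error of an observed arm mean: ``std_dev / sqrt(n)``."""
    if not (std_dev > 0):
        raise NetworkError(f"std_dev must be positive, got {std_dev}")
    if sample_size < 1:
        raise NetworkError(f"sample_size must be >= 1, got {sample_size}")
    return std_dev / math.sqrt(sample_size)
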