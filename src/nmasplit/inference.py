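"""Bayesian hierarchical random-effects estimation for evidence networks.

The joint model couples, for each (possibly virtual) study ``i``:

* arm data:      ``y_{i,t} ~ N(mu_i + delta_{i,t}, sd_{i,t}^2 / n_{i,t})``
  (``delta`` zero for the reference arm);
* contrast data: ``y'_i ~ N(A_i delta_i, Sigma_i)`` where ``A_i`` re-expresses
  the model-parameterised contrasts against the reported reference arm and
  ``Sigma_i`` has the squared contrast standard errors on the diagonal and
  the squared reference-arm standard error off it;
* random effects ``delta_i ~ N(W_i beta_d, sigma^2 C_i)`` where ``W_i`` holds
  the consistency (or split) expressions and ``C_i`` is the homogeneous
  compound-symmetry structure (unit diagonal, 1/2 off-diagonal, split
  row/column zeroed off-diagonal);
* priors ``N(0, effect_sd^2)`` on all location parameters (study baselines,
  basic parameters, the direct split parameter) and ``U(0, K)`` on ``sigma``.

Everything except ``sigma`` is linear-Gaussian, so the sampler collapses the
hierarchy: a reflected random-walk Metropolis step targets the exact marginal
posterior of ``sigma`` (location parameters and random effects integrated out
analytically), after which the location block -- and, on request, the random
effects -- are drawn exactly from their Gaussian conditionals.  This is a
partially collapsed Gibbs sampler with the same stationary distribution as
the uncollapsed Metropolis-within-Gibbs scheme, but with near-independent
draws for the location parameters.  The proposal scale for ``sigma`` adapts
only during the adaptation phase, so the recorded chain is Markovian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .model_gen import ModelStructure, PriorSpec, StartingValues, express_functional
from .network_core import (
    ComparisonPair,
    Network,
    NetworkError,
    Study,
    arm_standard_error,
)

__all__ = [
    "build_re_covariance",
    "ContrastLikelihoodSpec",
    "build_contrast_transform",
    "Model",
    "assemble_model",
    "PosteriorSamples",
    "sample_posterior",
    "ConvergenceReport",
    "gelman_rubin",
]


def build_re_covariance(
    n_contrasts: int, sigma: float, split_index: Optional[int] = None
) -> np.ndarray:
    """Compound-symmetry random-effects covariance for one study.

    ``sigma**2`` on the diagonal and ``sigma**2 / 2`` off it; if
    ``split_index`` is given, that row and column are zeroed off-diagonal so
    the split contrast is independent of the consistency contrasts.
    """
    if n_contrasts < 1:
        raise NetworkError("a study must have at least one contrast")
    if not (sigma > 0):
        raise NetworkError(f"sigma must be positive, got {sigma}")
    cov = np.full((n_contrasts, n_contrasts), sigma**2 / 2.0)
    np.fill_diagonal(cov, sigma**2)
    if split_index is not None:
        if not (0 <= split_index < n_contrasts):
            raise NetworkError(f"split_index {split_index} out of range")
        cov[split_index, :] = 0.0
        cov[:, split_index] = 0.0
        cov[split_index, split_index] = sigma**2
    return cov


@dataclass(frozen=True)
class ContrastLikelihoodSpec:
    """Multivariate-normal likelihood for one contrast-style study.

    ``observed ~ N(A @ delta, Sigma)`` where ``delta`` is the vector of
    model-parameterised relative effects (versus the plan reference, in plan
    non-reference order) and ``observed`` are the reported contrasts.
    """

    observed: np.ndarray
    A: np.ndarray
    Sigma: np.ndarray
    reported_treatments: Tuple[str, ...]


def build_contrast_transform(study: Study, plan) -> ContrastLikelihoodSpec:
    """Re-express reported contrasts against the plan's reference treatment.

    The reported contrasts are versus the study's own reference arm ``r``;
    the model contrasts are ``d_{b,t}`` for the plan reference ``b`` and each
    non-reference arm ``t``.  Each reported ``d_{r,t}`` equals
    ``d_{b,t} - d_{b,r}``, giving a +/-1 matrix ``A`` (the identity when the
    references coincide).
    """
    if study.style != "contrast":
        raise NetworkError(f"study {study.id!r} is not contrast-based")
    ref_row = next(m for m in study.measurements if m.is_reference)
    reported = [m for m in study.measurements if not m.is_reference]
    if len(study.measurements) >= 3 and ref_row.base_std_err is None:
        raise NetworkError(
            f"contrast study {study.id!r} has >=3 arms but no base standard error"
        )
    b = plan.reference
    model_contrasts = list(plan.nonref)
    col = {t: j for j, t in enumerate(model_contrasts)}
    r = ref_row.treatment
    A = np.zeros((len(reported), len(model_contrasts)))
    y = np.zeros(len(reported))
    for i, m in enumerate(reported):
        y[i] = m.difference
        if m.treatment != b:
            A[i, col[m.treatment]] += 1.0
        if r != b:
            A[i, col[r]] -= 1.0
    Sigma = np.zeros((len(reported), len(reported)))
    if len(reported) > 1:
        Sigma[:, :] = ref_row.base_std_err**2
    for i, m in enumerate(reported):
        Sigma[i, i] = m.std_err**2
    return ContrastLikelihoodSpec(
        observed=y,
        A=A,
        Sigma=Sigma,
        reported_treatments=tuple(m.treatment for m in reported),
    )


@dataclass(frozen=True)
class _PlanBlock:
    """Precomputed per-plan pieces of the joint likelihood."""

    plan_id: str
    obs_slice: slice
    L: np.ndarray  # observations x contrasts loading of delta
    C0: np.ndarray  # unit-sigma random-effects correlation structure
    W: np.ndarray  # contrasts x location-params expression matrix
    mu_col: Optional[int]
    contrast_names: Tuple[str, ...]


@dataclass(frozen=True)
class Model:
    """Assembled joint model ready for sampling."""

    y: np.ndarray
    X: np.ndarray
    R: np.ndarray
    G: np.ndarray  # unit-sigma^2 random-effects contribution to the marginal cov
    prior_var: np.ndarray  # prior variances of the location parameters
    names: Tuple[str, ...]  # location parameter names (columns of X)
    blocks: Tuple[_PlanBlock, ...]
    structure: ModelStructure
    priors: PriorSpec
    indirect_expression: Dict[str, float] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_location(self) -> int:
        return self.X.shape[1]

    @property
    def split(self) -> Optional[ComparisonPair]:
        return self.structure.split


def _consistency_row(structure, ref, t, col):
    row = np.zeros(len(col))
    for (a, b), coef in express_functional(structure, (ref, t)).items():
        row[col[f"d.{a}.{b}"]] = coef
    return row


def assemble_model(network: Network, structure: ModelStructure, priors: PriorSpec) -> Model:
    """Combine data, structure and priors into one joint model.

    One shared heterogeneity parameter spans every (virtual) study and every
    component; location parameters are the per-study baselines (arm-style
    studies only), the basic parameters and, for split structures, the
    direct split parameter.
    """
    study_ids = {s.id for s in network.studies}
    for p in structure.plans:
        if p.source not in study_ids:
            raise NetworkError(f"plan {p.id!r} refers to unknown study {p.source!r}")

    arm_plans = [p for p in structure.plans if network.study(p.source).style == "arm"]
    mu_names = [f"mu.{p.id}" for p in arm_plans]
    d_names = [f"d.{a}.{b}" for a, b in structure.basic]
    names: List[str] = mu_names + d_names
    if structure.split is not None:
        names.append(structure.split_name)
    col = {name: j for j, name in enumerate(names)}
    n_loc = len(names)

    y_parts, X_parts, R_blocks, G_blocks, blocks = [], [], [], [], []
    offset = 0
    for plan in structure.plans:
        study = network.study(plan.source)
        n_c = plan.n_contrasts
        # expression matrix W: one row per model contrast (ref -> nonref[j])
        W = np.zeros((n_c, n_loc))
        contrast_names = []
        for j, t in enumerate(plan.nonref):
            contrast_names.append(f"{plan.reference}.{t}")
            is_split_row = plan.role == "direct" or (
                plan.role == "mixed" and j == plan.split_contrast_index
            )
            if is_split_row:
                W[j, col[structure.split_name]] = 1.0
            else:
                W[j, :] = _consistency_row(structure, plan.reference, t, col)
        split_index = (
            plan.split_contrast_index
            if plan.role == "mixed"
            else (0 if plan.role == "direct" and n_c == 1 else None)
        )
        C0 = build_re_covariance(n_c, 1.0, split_index=split_index)

        if study.style == "arm":
            arms = plan.treatments
            ms = [study.measurement(t) for t in arms]
            y_p = np.array([m.mean for m in ms])
            se2 = np.array(
                [arm_standard_error(m.std_dev, m.sample_size) ** 2 for m in ms]
            )
            R_p = np.diag(se2)
            L = np.zeros((len(arms), n_c))
            for j in range(n_c):
                L[j + 1, j] = 1.0
            X_p = L @ W
            X_p[:, col[f"mu.{plan.id}"]] = 1.0
        else:
            spec = build_contrast_transform(study, plan)
            y_p = spec.observed
            L = spec.A
            R_p = spec.Sigma
            X_p = L @ W

        n_obs_p = y_p.shape[0]
        y_parts.append(y_p)
        X_parts.append(X_p)
        R_blocks.append(R_p)
        G_blocks.append(L @ C0 @ L.T)
        blocks.append(
            _PlanBlock(
                plan_id=plan.id,
                obs_slice=slice(offset, offset + n_obs_p),
                L=L,
                C0=C0,
                W=W,
                mu_col=col.get(f"mu.{plan.id}"),
                contrast_names=tuple(contrast_names),
            )
        )
        offset += n_obs_p

    y = np.concatenate(y_parts)
    X = np.vstack(X_parts)
    R = linalg.block_diag(*R_blocks)
    G = linalg.block_diag(*G_blocks)
    prior_var = np.full(n_loc, priors.effect_sd**2)

    indirect_expression: Dict[str, float] = {}
    if structure.split is not None:
        for edge, coef in express_functional(structure, structure.split).items():
            indirect_expression[f"d.{edge[0]}.{edge[1]}"] = float(coef)

    return Model(
        y=y,
        X=X,
        R=R,
        G=G,
        prior_var=prior_var,
        names=tuple(names),
        blocks=tuple(blocks),
        structure=structure,
        priors=priors,
        indirect_expression=indirect_expression,
    )


@dataclass
class PosteriorSamples:
    """MCMC draws indexed by chain x iteration x parameter."""

    names: Tuple[str, ...]
    draws: np.ndarray  # (n_chains, n_iter, n_params)
    seed: int
    n_adapt: int
    n_iter: int

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_iter)."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def linear_combination(self, coefficients: Dict[str, float]) -> np.ndarray:
        """Pooled draws of ``sum(coef * parameter)``."""
        out = np.zeros(self.draws.shape[0] * self.draws.shape[1])
        for name, coef in coefficients.items():
            out += coef * self.pooled(name)
        return out

    def summary(self, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        names = list(names) if names is not None else list(self.names)
        rows = []
        for name in names:
            x = self.pooled(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "q2.5": float(np.quantile(x, 0.025)),
                    "median": float(np.quantile(x, 0.5)),
                    "q97.5": float(np.quantile(x, 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_iter, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(n_chains * n_iter, -1), columns=list(self.names)
        )
        frame.insert(0, "iteration", np.tile(np.arange(1, n_iter + 1), n_chains))
        frame.insert(0, "chain", np.repeat(np.arange(1, n_chains + 1), n_iter))
        return frame

    def to_csv(self, target) -> None:
        self.to_frame().to_csv(target, index=False)


def _reflect(value: float, lower: float, upper: float) -> float:
    width = upper - lower
    v = (value - lower) % (2.0 * width)
    return lower + (v if v <= width else 2.0 * width - v)


def _sigma_start_grid(n_chains: int, upper: float) -> np.ndarray:
    return np.linspace(0.1, 0.9, n_chains) * upper


def sample_posterior(
    model: Model,
    n_chains: int = 4,
    n_adapt: int = 5000,
    n_iter: int = 20000,
    seed: int = 1,
    starting: Optional[List[StartingValues]] = None,
    sigma_fixed: Optional[float] = None,
    sample_delta: bool = False,
) -> PosteriorSamples:
    """Draw from the joint posterior; bit-reproducible given ``seed``.

    ``sigma_fixed`` clamps the heterogeneity standard deviation (useful for
    validation against closed-form posteriors); ``sample_delta`` additionally
    records per-study random-effect draws.
    """
    if n_chains < 2:
        raise NetworkError("at least 2 chains are required")
    if n_iter < 1 or n_adapt < 0:
        raise NetworkError("iteration counts must be positive")

    y, X, R, G = model.y, model.X, model.R, model.G
    prior_prec = 1.0 / model.prior_var
    XP0Xt = (X * model.prior_var) @ X.T
    upper = model.priors.heterogeneity_upper
    n_loc = model.n_location

    def marginal_loglik(sigma: float) -> float:
        C = R + sigma**2 * G + XP0Xt
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(y @ linalg.cho_solve(cf, y, check_finite=False))
        return -0.5 * (logdet + quad)

    delta_names: List[str] = []
    if sample_delta:
        for blk in model.blocks:
            delta_names.extend(
                f"delta.{blk.plan_id}.{c}" for c in blk.contrast_names
            )

    out_names = list(model.names) + ["sigma"]
    if model.split is not None:
        out_names.append(f"d.ind.{model.split.x}.{model.split.y}")
    out_names.extend(delta_names)

    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    sigma_grid = _sigma_start_grid(n_chains, upper)
    all_draws = np.empty((n_chains, n_iter, len(out_names)))

    for c in range(n_chains):
        rng = np.random.default_rng(child_seeds[c])
        if sigma_fixed is not None:
            sigma = float(sigma_fixed)
        elif starting is not None:
            sigma = float(starting[c].sigma)
        else:
            sigma = float(sigma_grid[c])
        if not (0.0 < sigma <= upper) and sigma_fixed is None:
            raise NetworkError(f"sigma starting value {sigma} outside (0, {upper}]")
        scale = 0.25 * upper
        current_ll = marginal_loglik(sigma)
        if not np.isfinite(current_ll):
            raise NetworkError("posterior density is not finite at the starting values")

        accepted = 0
        window = 0
        beta = np.zeros(n_loc)
        for it in range(-n_adapt, n_iter):
            if sigma_fixed is None:
                prop = _reflect(sigma + scale * rng.standard_normal(), 0.0, upper)
                prop_ll = marginal_loglik(prop)
                if math.log(rng.uniform()) < prop_ll - current_ll:
                    sigma, current_ll = prop, prop_ll
                    accepted += 1
                window += 1
                if it < 0 and window == 25:
                    rate = accepted / window
                    scale *= math.exp(0.66 * (rate - 0.44))
                    scale = min(max(scale, 1e-6 * upper), 2.0 * upper)
                    accepted = 0
                    window = 0

            if it < 0:
                # the location block does not feed back into the collapsed
                # sigma update, so it is only drawn for recorded iterations
                continue

            # exact draw of the location block given sigma
            V = R + sigma**2 * G
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
            Vi_X = linalg.cho_solve(cf, X, check_finite=False)
            Lam = X.T @ Vi_X
            Lam[np.diag_indices_from(Lam)] += prior_prec
            Lam_cf = linalg.cho_factor(Lam, lower=True, check_finite=False)
            mean = linalg.cho_solve(Lam_cf, Vi_X.T @ y, check_finite=False)
            z = rng.standard_normal(n_loc)
            beta = mean + linalg.solve_triangular(
                Lam_cf[0].T, z, lower=False, check_finite=False
            )

            row = list(beta) + [sigma]
            if model.split is not None:
                d_ind = sum(
                    coef * beta[model.names.index(name)]
                    for name, coef in model.indirect_expression.items()
                )
                row.append(d_ind)
            if sample_delta:
                row.extend(_draw_deltas(model, beta, sigma, rng))
            all_draws[c, it, :] = row

    return PosteriorSamples(
        names=tuple(out_names),
        draws=all_draws,
        seed=seed,
        n_adapt=n_adapt,
        n_iter=n_iter,
    )


def _draw_deltas(model: Model, beta: np.ndarray, sigma: float, rng) -> List[float]:
    """Exact conditional draw of the per-study random effects."""
    out: List[float] = []
    for blk in model.blocks:
        resid = model.y[blk.obs_slice].copy()
        if blk.mu_col is not None:
            resid -= beta[blk.mu_col]
        R_b = model.R[blk.obs_slice, blk.obs_slice]
        prior_cov = max(sigma, 1e-8) ** 2 * blk.C0
        prior_mean = blk.W @ beta
        prior_prec = linalg.inv(prior_cov)
        Ri_L = linalg.solve(R_b, blk.L, assume_a="pos")
        prec = prior_prec + blk.L.T @ Ri_L
        cov = linalg.inv(prec)
        mean = cov @ (prior_prec @ prior_mean + Ri_L.T @ resid)
        out.extend(rng.multivariate_normal(mean, cov))
    return out


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-chain potential scale reduction factors with a pass threshold."""

    psrf: Dict[str, float]
    threshold: float
    passed: bool

    @property
    def failures(self) -> List[str]:
        return [k for k, v in self.psrf.items() if v >= self.threshold]


def gelman_rubin(samples: PosteriorSamples, threshold: float = 1.05) -> ConvergenceReport:
    """Split-chain Gelman-Rubin diagnostic for every recorded parameter."""
    if samples.n_chains < 2:
        raise NetworkError("the diagnostic requires at least 2 chains")
    n_iter = samples.draws.shape[1]
    if n_iter < 10:
        raise NetworkError("the diagnostic requires at least 10 draws per chain")
    half = n_iter // 2
    psrf: Dict[str, float] = {}
    for j, name in enumerate(samples.names):
        seqs = []
        for c in range(samples.n_chains):
            seqs.append(samples.draws[c, :half, j])
            seqs.append(samples.draws[c, half : 2 * half, j])
        seqs = np.asarray(seqs)
        n = seqs.shape[1]
        within = seqs.var(axis=1, ddof=1).mean()
        between_over_n = seqs.mean(axis=1).var(ddof=1)
        if within <= 1e-300:
            psrf[name] = 1.0
            continue
        var_hat = (n - 1) / n * within + between_over_n
        psrf[name] = float(np.sqrt(var_hat / within))
    passed = all(v < threshold for v in psrf.values())
    return ConvergenceReport(psrf=psrf, threshold=threshold, passed=passed)
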