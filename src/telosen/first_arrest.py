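"""Generation-dependent Bernoulli model of the first non-terminal arrest.

At each generation j a lineage that has not yet arrested does so with
probability p(j) (the discrete-time hazard). The generation X of the first
non-terminal arrest then has pmf

    P(X = k) = p(k) * prod_{j<k} (1 - p(j)).

Two hazard families are provided: a constant hazard (X geometric) and a
logistic hazard p(j) = 1 / (1 + exp(-(j - midpoint)/scale)), which grows
approximately exponentially for early generations while staying in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .lineages import LineageSet, annotate_arrests, filter_for_nonterminal_analysis
from .stats import GOFResult, chi2_gof, geometric_mle

__all__ = [
    "ConstantHazard",
    "LogisticHazard",
    "HazardEstimate",
    "first_arrest_pmf",
    "first_arrest_generations",
    "empirical_hazard",
    "fit_constant",
    "fit_logistic",
    "simulate_first_arrests",
    "gof_first_arrest",
    "sweep_threshold_D",
]


@dataclass(frozen=True)
class ConstantHazard:
    """Generation-independent arrest probability; X is geometric(p)."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")

    def hazard(self, j: int | np.ndarray) -> float | np.ndarray:
        j = np.asarray(j)
        out = np.full(j.shape, self.p, dtype=float)
        return float(out) if out.ndim == 0 else out

    @property
    def n_params(self) -> int:
        return 1


@dataclass(frozen=True)
class LogisticHazard:
    """Logistic hazard p(j) = 1 / (1 + exp(-(j - midpoint) / scale)).

    Strictly increasing in j, equals 1/2 at the midpoint, and approximates
    exponential growth exp((j - midpoint)/scale) when p(j) is small.
    """

    midpoint: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    def hazard(self, j: int | np.ndarray) -> float | np.ndarray:
        j = np.asarray(j, dtype=float)
        out = expit((j - self.midpoint) / self.scale)
        return float(out) if out.ndim == 0 else out

    @property
    def n_params(self) -> int:
        return 2


@dataclass(frozen=True)
class HazardEstimate:
    """Empirical discrete-time hazard: per retained generation j, the
    fraction of at-risk lineages whose first non-terminal arrest is at j."""

    generations: np.ndarray
    fractions: np.ndarray
    at_risk: np.ndarray


def first_arrest_pmf(hazard, k: int | np.ndarray) -> float | np.ndarray:
    """P(X = k) = p(k) * prod_{j=1}^{k-1} (1 - p(j))."""
    karr = np.atleast_1d(np.asarray(k, dtype=int))
    if np.any(karr < 1):
        raise ValueError("k must be >= 1")
    kmax = int(karr.max())
    js = np.arange(1, kmax + 1)
    p = np.asarray(hazard.hazard(js), dtype=float)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - p)])  # surv[j] = P(X > j)
    pmf_all = p * surv[:-1]
    out = pmf_all[karr - 1]
    return float(out[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else out


def first_arrest_generations(lineage_set: LineageSet, D: float) -> list[int]:
    """Generation of the first non-terminal long cycle for each lineage that
    has one (lineages without any non-terminal arrest are omitted)."""
    gens = []
    for lin in lineage_set:
        ann = annotate_arrests(lin, D)
        nt = ann.nonterminal_long_generations
        if nt:
            gens.append(nt[0])
    return gens


def _censor_generation(lin, ann) -> int:
    """Last generation at which the lineage could still have shown a *first*
    non-terminal arrest: the cycle before the terminal run if it died with
    one, else its final observed cycle."""
    term = ann.terminal_run
    if term is not None:
        return term.start_generation - 1
    return lin.n_cycles


def empirical_hazard(
    lineage_set: LineageSet, D: float, min_at_risk: int = 5
) -> HazardEstimate:
    """Empirical hazard of the first non-terminal arrest.

    For generation j the denominator counts lineages still at risk (no
    earlier non-terminal arrest, still observed and not yet in the terminal
    run at j); the numerator counts first arrests at j. Generations with at
    most ``min_at_risk`` lineages at risk are omitted.
    """
    if len(lineage_set) == 0:
        raise ValueError("empty lineage set")
    events: list[int] = []
    censors: list[int] = []
    for lin in lineage_set:
        ann = annotate_arrests(lin, D)
        nt = ann.nonterminal_long_generations
        if nt:
            events.append(nt[0])
        else:
            censors.append(_censor_generation(lin, ann))
    horizon = max(events + censors, default=0)
    gens, fracs, risks = [], [], []
    for j in range(1, horizon + 1):
        at_risk = sum(1 for e in events if e >= j) + sum(1 for c in censors if c >= j)
        if at_risk <= min_at_risk:
            continue
        arrested = sum(1 for e in events if e == j)
        gens.append(j)
        fracs.append(arrested / at_risk)
        risks.append(at_risk)
    return HazardEstimate(
        generations=np.asarray(gens, dtype=int),
        fractions=np.asarray(fracs, dtype=float),
        at_risk=np.asarray(risks, dtype=int),
    )


def fit_constant(first_arrests: Sequence[int]) -> ConstantHazard:
    """Constant-hazard fit: the geometric MLE of the arrest generations."""
    return ConstantHazard(p=geometric_mle(first_arrests))


def _fit_logistic_weighted_ls(est: HazardEstimate) -> tuple[LogisticHazard, float]:
    j = est.generations.astype(float)
    w = np.sqrt(est.at_risk.astype(float))
    y = est.fractions

    def resid(theta):
        mid, log_scale = theta
        scale = np.exp(log_scale)
        return w * (y - expit((j - mid) / scale))

    best = None
    mids = np.linspace(j.min(), j.max() + 0.5 * (j.max() - j.min() + 1), 8)
    for m0 in mids:
        for s0 in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
            try:
                sol = optimize.least_squares(
                    resid, x0=[m0, np.log(s0)], xtol=1e-12, ftol=1e-12, gtol=1e-12
                )
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("logistic fit did not converge from any start")
    mid, log_scale = best.x
    return LogisticHazard(midpoint=float(mid), scale=float(np.exp(log_scale))), float(
        2 * best.cost
    )


def _fit_logistic_mle(data: Sequence[int]) -> tuple[LogisticHazard, float]:
    x = np.asarray(list(data), dtype=int)

    def nll(theta):
        mid, log_scale = theta
        hz = LogisticHazard(midpoint=mid, scale=float(np.exp(log_scale)))
        pmf = first_arrest_pmf(hz, x)
        pmf = np.clip(np.atleast_1d(pmf), 1e-300, None)
        return -np.log(pmf).sum()

    best = None
    for m0 in np.linspace(x.min(), x.max(), 6):
        for s0 in (1.0, 4.0, 12.0):
            sol = optimize.minimize(
                nll, x0=[m0, np.log(s0)], method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
            )
            if best is None or sol.fun < best.fun:
                best = sol
    mid, log_scale = best.x
    return LogisticHazard(midpoint=float(mid), scale=float(np.exp(log_scale))), float(
        best.fun
    )


def fit_logistic(
    hazard_estimate: HazardEstimate | None = None,
    method: str = "weighted_ls",
    data: Sequence[int] | None = None,
) -> LogisticHazard:
    """Fit the logistic hazard.

    ``weighted_ls`` (default) minimises the at-risk-weighted squared error
    between the empirical hazard points and the logistic curve, mirroring a
    fit to the per-generation arrest frequencies. ``mle`` maximises the
    likelihood of the observed first-arrest generations under the chain pmf.
    Both use multi-start local optimisation.
    """
    if method == "weighted_ls":
        if hazard_estimate is None or hazard_estimate.generations.size < 3:
            raise ValueError("weighted_ls needs a hazard estimate with >= 3 points")
        if np.all(hazard_estimate.fractions == 0):
            raise ValueError("degenerate hazard estimate (all zero)")
        model, _ = _fit_logistic_weighted_ls(hazard_estimate)
        return model
    if method == "mle":
        if data is None or len(data) < 3:
            raise ValueError("mle needs >= 3 first-arrest observations")
        model, _ = _fit_logistic_mle(data)
        return model
    raise ValueError(f"unknown method {method!r}")


def simulate_first_arrests(
    hazard,
    n: int,
    rng: np.random.Generator | int | None = None,
    max_generation: int = 1000,
) -> np.ndarray:
    """Draw n i.i.d. first-arrest generations by sequential Bernoulli trials.

    Draws not triggered by ``max_generation`` are censored at
    ``max_generation + 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    js = np.arange(1, max_generation + 1)
    p = np.clip(np.asarray(hazard.hazard(js), dtype=float), 0.0, 1.0)
    u = rng.random((n, max_generation))
    hit = u < p[None, :]
    any_hit = hit.any(axis=1)
    gens = np.where(any_hit, hit.argmax(axis=1) + 1, max_generation + 1)
    return gens.astype(int)


def gof_first_arrest(
    generations: Sequence[int], model, n_fitted: int | None = None
) -> GOFResult:
    """Chi-square GOF of observed first-arrest generations against the model
    pmf; by default n_fitted is the model's own parameter count."""
    if n_fitted is None:
        n_fitted = model.n_params
    return chi2_gof(
        list(generations), lambda k: float(first_arrest_pmf(model, k)), n_fitted=n_fitted
    )


def sweep_threshold_D(
    lineage_set: LineageSet,
    D_values: Sequence[float],
    model_family: str = "logistic",
    min_at_risk: int = 5,
) -> pd.DataFrame:
    """Re-classify, refit and re-test the first-arrest model at each D.

    Returns a tidy table with one row per D: the fitted parameters, the GOF
    p-value and the number of first-arrest observations. Rows where the fit
    or test cannot be computed are flagged not-computable.
    """
    rows = []
    for D in D_values:
        row: dict = {"D": float(D), "computable": False, "n": 0, "p_value": np.nan}
        try:
            filtered = filter_for_nonterminal_analysis(lineage_set, D)
            gens = first_arrest_generations(filtered, D)
            row["n"] = len(gens)
            if not gens:
                rows.append(row)
                continue
            if model_family == "constant":
                model = fit_constant(gens)
                row["p_hat"] = model.p
            elif model_family == "logistic":
                est = empirical_hazard(filtered, D, min_at_risk=min_at_risk)
                model = fit_logistic(est)
                row["midpoint"] = model.midpoint
                row["scale"] = model.scale
            else:
                raise ValueError(f"unknown model family {model_family!r}")
            gof = gof_first_arrest(gens, model)
            row["p_value"] = gof.p_value
            row["chi2"] = gof.statistic
            row["df"] = gof.df
            row["computable"] = True
        except (ValueError, RuntimeError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)
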