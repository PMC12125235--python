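"""Monte Carlo harnesses for estimator comparison and prediction intervals.

The estimation study generates censored OMELRRSS samples at a fixed true
theta, applies the requested estimators (MLE, classical Bayes under SE/LINEX,
empirical Bayes under balanced losses) and reports, per estimator,

    AV  = mean estimate,
    ABE = mean absolute error |estimate - theta|,
    RAB = ABE / theta  (relative absolute bias).

The prediction study generates full samples, hides everything beyond the
descending rank s, builds the pivotal prediction interval for rank tau and
reports the coverage proportion (PC) and average interval width (AIW).

Sampling uses the exact marginal record-value sampler by default
(``sampler="stream"`` runs the literal scheme); the two are distributionally
identical.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import (LossConfig, PriorSpec, balanced_bayes_estimate,
                    bayes_estimate, empirical_bayes_estimate,
                    estimate_hyperparameter_b, posterior_summary)
from .ged import GEDParams
from .likelihood import mle_theta
from .prediction import PivotSpec, pivot_quantile, solve_pci
from .sampling import (CensoredSample, SampleSizeModel, SchemeConfig,
                       draw_sample_size, generate_melrrss,
                       sample_melrrss_marginal)

__all__ = [
    "EstSimConfig",
    "EstSimReport",
    "PredSimConfig",
    "PredSimReport",
    "run_estimation_study",
    "run_prediction_study",
    "summarize_estimates",
    "summarize_intervals",
]


@dataclass(frozen=True)
class EstSimConfig:
    true_theta: float
    lambda_: float
    prior_b: float
    scheme: SchemeConfig
    r: int
    s: int
    reps: int
    seed: int
    size_model: SampleSizeModel | None = None
    losses: tuple[LossConfig, ...] = (LossConfig("SE"),)
    weight_delta: float = 0.5
    estimators: tuple[str, ...] = ("mle", "bayes", "empirical_bayes")
    sampler: str = "marginal"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (self.true_theta > 0 and self.lambda_ > 0 and self.prior_b > 0):
            raise ValueError("true_theta, lambda_, prior_b must be positive")


@dataclass
class EstSimReport:
    metrics: dict          # name -> (AV, ABE, RAB)
    estimates: dict        # name -> per-rep array
    failures: dict         # name -> count


@dataclass(frozen=True)
class PredSimConfig:
    true_theta: float
    lambda_: float
    scheme: SchemeConfig
    s: int
    tau: int
    pi: float
    reps: int
    seed: int
    size_model: SampleSizeModel | None = None
    sampler: str = "marginal"


@dataclass
class PredSimReport:
    pc: float
    aiw: float
    widths: np.ndarray
    hits: np.ndarray
    psi: float


def summarize_estimates(estimates, true_theta: float):
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size == 0:
        raise ValueError("no estimates to summarize")
    av = float(np.mean(est))
    abe = float(np.mean(np.abs(est - true_theta)))
    return av, abe, abe / true_theta


def summarize_intervals(hits, widths):
    hits = np.asarray(hits, dtype=bool)
    widths = np.asarray(widths, dtype=float)
    if hits.size == 0:
        raise ValueError("no intervals to summarize")
    return float(np.mean(hits)), float(np.mean(widths))


def _one_sample(scheme, p, rng, sampler):
    if sampler == "stream":
        return generate_melrrss(scheme, p, rng)
    return sample_melrrss_marginal(scheme, p, rng)


def run_estimation_study(cfg: EstSimConfig) -> EstSimReport:
    rng = np.random.default_rng(cfg.seed)
    p = GEDParams(cfg.true_theta, cfg.lambda_)
    prior = PriorSpec(cfg.prior_b)
    names: list[str] = []
    if "mle" in cfg.estimators:
        names.append("mle")
    if "bayes" in cfg.estimators:
        names += [f"bayes_{l.family}" + (f"_c{l.c:g}" if "LINEX" in l.family else "")
                  for l in cfg.losses if l.family in ("SE", "LINEX")]
    if "empirical_bayes" in cfg.estimators:
        names += [f"eb_{l.family}" + (f"_c{l.c:g}" if "LINEX" in l.family else "")
                  for l in cfg.losses if l.family in ("BSE", "BLINEX")]
    store = {nm: np.full(cfg.reps, np.nan) for nm in names}
    fails = {nm: 0 for nm in names}

    for rep in range(cfg.reps):
        if cfg.size_model is not None and cfg.size_model.kind != "fixed":
            n = draw_sample_size(cfg.size_model, rng, at_least=cfg.s)
        else:
            n = cfg.scheme.n
        scheme = cfg.scheme.truncated(n)
        vals = _one_sample(scheme, p, rng, cfg.sampler)
        sample = CensoredSample(np.sort(vals), cfg.r, cfg.s, "ascending")
        mle = None
        try:
            mle = mle_theta(sample, scheme, cfg.lambda_, cfg.size_model)
            if "mle" in store:
                store["mle"][rep] = mle.theta
        except Exception:
            if "mle" in store:
                fails["mle"] += 1
        b_tilde = None
        for loss in cfg.losses:
            nm_b = f"bayes_{loss.family}" + (f"_c{loss.c:g}" if "LINEX" in loss.family else "")
            nm_e = f"eb_{loss.family}" + (f"_c{loss.c:g}" if "LINEX" in loss.family else "")
            try:
                if loss.family in ("SE", "LINEX") and nm_b in store:
                    store[nm_b][rep] = bayes_estimate(
                        sample, scheme, cfg.lambda_, prior, loss, cfg.size_model)
                elif loss.family in ("BSE", "BLINEX") and nm_e in store:
                    if b_tilde is None:
                        b_tilde, _ = estimate_hyperparameter_b(
                            sample, scheme, cfg.lambda_, cfg.size_model)
                    store[nm_e][rep] = empirical_bayes_estimate(
                        sample, scheme, cfg.lambda_, loss, cfg.size_model,
                        b_tilde=b_tilde, mle=mle)
            except Exception:
                fails[nm_b if loss.family in ("SE", "LINEX") else nm_e] = \
                    fails.get(nm_b if loss.family in ("SE", "LINEX") else nm_e, 0) + 1
    metrics = {nm: summarize_estimates(v, cfg.true_theta)
               for nm, v in store.items() if np.any(np.isfinite(v))}
    return EstSimReport(metrics=metrics, estimates=store, failures=fails)


def run_prediction_study(cfg: PredSimConfig) -> PredSimReport:
    rng = np.random.default_rng(cfg.seed)
    p = GEDParams(cfg.true_theta, cfg.lambda_)
    spec = PivotSpec(cfg.s, cfg.tau, cfg.scheme, cfg.size_model)
    psi = pivot_quantile(cfg.pi, spec, method="closed_form")
    hits = np.zeros(cfg.reps, dtype=bool)
    widths = np.zeros(cfg.reps)
    lam = cfg.lambda_
    for rep in range(cfg.reps):
        if cfg.size_model is not None and cfg.size_model.kind != "fixed":
            n = draw_sample_size(cfg.size_model, rng, at_least=cfg.tau)
        else:
            n = cfg.scheme.n
        scheme = cfg.scheme.truncated(n)
        vals = np.sort(_one_sample(scheme, p, rng, cfg.sampler))[::-1]
        z_s, z_tau = vals[cfg.s - 1], vals[cfg.tau - 1]
        base = -np.expm1(-lam * z_s)
        lower = -np.log1p(-base ** (psi + 1.0)) / lam
        hits[rep] = (lower < z_tau) and (z_tau <= z_s)
        widths[rep] = z_s - lower
    pc, aiw = summarize_intervals(hits, widths)
    return PredSimReport(pc=pc, aiw=aiw, widths=widths, hits=hits, psi=psi)
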