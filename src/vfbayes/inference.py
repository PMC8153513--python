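"""Bayesian importance-sampling estimation of fold properties from a GAW.

The posterior pi(chi | y) ~ pi(y | chi) pi_pri(chi) is explored with plain
importance sampling from the prior: draw an ensemble of parameter vectors
from independent uniform priors, simulate each, score it with the Gaussian
likelihood

    log pi(y | chi) = -||A_m - A_s||^2 / (2 sigma_e^2),

normalise the weights (log-sum-exp stabilised; a raw product of 600
Gaussian factors underflows double precision), and resample with
replacement in proportion to the weights.  Posterior means are the point
estimates and posterior standard deviations the uncertainty, both taken
over the resampled ensemble.

Unstable prior draws are part of the game -- the uniform boxes include
corners that do not oscillate or blow up the integrator -- so a failed
simulation simply carries zero weight and is counted, rather than
aborting the run.

Parameters are carried in the units their priors are quoted in (body and
ligament moduli in kPa, cover in Pa, viscosity in Poise) and converted to
SI only when a forward model is instantiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp

from .dynamics import simulate, DEFAULT_H_MS, DEFAULT_DURATION_MS
from .fe_core import MaterialProperties
from .geometry import build_default_geometry, triangulate
from .observation import (
    GAWSeries,
    compute_gaw,
    downsample,
    phase_align,
    trim_transient,
)

__all__ = [
    "PriorSpec",
    "Ensemble",
    "PosteriorSummary",
    "EstimateConfig",
    "TotalFailureError",
    "sample_prior",
    "props_from_sample",
    "props_to_sample",
    "log_likelihood",
    "importance_weights",
    "resample",
    "estimate",
    "welch_t",
    "sensitivity_sweep",
]


class TotalFailureError(RuntimeError):
    """Every ensemble member failed or scored zero likelihood."""


# Table-2 style prior boxes, in the units the bounds are quoted in.
_DEFAULT_BOUNDS = {
    "e_bdy_kpa": (9.0, 15.0),
    "e_cvr_pa": (250.0, 950.0),
    "e_lig_kpa": (0.5, 3.0),
    "p_sub_pa": (400.0, 1800.0),
    "rho_kgm3": (950.0, 1200.0),
    "eta_poise": (1.0, 7.0),
    "x0_mm": (7.4, 8.4),
}


@dataclass
class PriorSpec:
    """Independent uniform priors with fixed nu and p_sup.

    ``include_x0`` adds the medial-compression offset to the estimated set
    (off by default, matching the baseline no-compression analysis).
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    include_x0: bool = False
    nu: float = 0.4995
    p_sup: float = 0.0

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi and not (self.bounds[name][0] == self.bounds[name][1]):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
            if not lo <= hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def param_names(self) -> list[str]:
        names = ["e_bdy_kpa", "e_cvr_pa", "e_lig_kpa", "p_sub_pa", "rho_kgm3", "eta_poise"]
        if self.include_x0:
            names.append("x0_mm")
        return names

    def prior_sd(self) -> dict:
        """Standard deviation of each uniform prior, (hi - lo)/sqrt(12)."""
        return {
            n: (self.bounds[n][1] - self.bounds[n][0]) / np.sqrt(12.0)
            for n in self.param_names
        }


def sample_prior(spec: PriorSpec, n: int, seed: int) -> np.ndarray:
    """(n, d) independent uniform draws, one column per ``spec.param_names``."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    cols = []
    for name in spec.param_names:
        lo, hi = spec.bounds[name]
        cols.append(rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo))
    return np.column_stack(cols)


def props_from_sample(row, spec: PriorSpec) -> MaterialProperties:
    d = dict(zip(spec.param_names, row))
    return MaterialProperties(
        rho=d["rho_kgm3"],
        eta_poise=d["eta_poise"],
        e_bdy=d["e_bdy_kpa"] * 1e3,
        e_cvr=d["e_cvr_pa"],
        e_lig=d["e_lig_kpa"] * 1e3,
        nu=spec.nu,
        p_sub=d["p_sub_pa"],
        p_sup=spec.p_sup,
        x0_mm=d.get("x0_mm", 8.40),
    )


def props_to_sample(props: MaterialProperties, spec: PriorSpec) -> np.ndarray:
    """Ground-truth properties expressed in prior units (for error reports)."""
    d = {
        "e_bdy_kpa": props.e_bdy / 1e3,
        "e_cvr_pa": props.e_cvr,
        "e_lig_kpa": props.e_lig / 1e3,
        "p_sub_pa": props.p_sub,
        "rho_kgm3": props.rho,
        "eta_poise": props.eta_poise,
        "x0_mm": props.x0_mm,
    }
    return np.array([d[n] for n in spec.param_names])


# ---------------------------------------------------------------------------
# likelihood and weights


def log_likelihood(meas: GAWSeries, sim: GAWSeries, sigma_e: float = 1.0) -> float:
    """Unnormalised Gaussian log-density -||A_m - A_s||^2 / (2 sigma_e^2)."""
    if len(meas) != len(sim):
        raise ValueError(f"length mismatch: {len(meas)} vs {len(sim)}")
    r = meas.area - sim.area
    return float(-np.dot(r, r) / (2.0 * sigma_e**2))


def importance_weights(log_likelihoods) -> np.ndarray:
    """Normalised weights from log-likelihoods; -inf maps to weight zero."""
    ll = np.asarray(log_likelihoods, float)
    finite = np.isfinite(ll)
    if not np.any(finite):
        raise TotalFailureError("all ensemble members have zero likelihood")
    w = np.zeros_like(ll)
    shifted = ll[finite] - ll[finite].max()
    w[finite] = np.exp(shifted - logsumexp(shifted))
    return w


def resample(
    samples: np.ndarray, weights: np.ndarray, seed: int, size: int | None = None
) -> np.ndarray:
    """Multinomial resampling with replacement; returns row indices.

    ``size`` defaults to the ensemble size (the resampled multiset has the
    same cardinality as the prior ensemble).
    """
    rng = np.random.default_rng(seed)
    n = len(samples) if size is None else size
    return rng.choice(len(samples), size=n, replace=True, p=weights)


@dataclass
class Ensemble:
    samples: np.ndarray  # (n, d) prior draws in prior units
    param_names: list
    log_likelihoods: np.ndarray
    weights: np.ndarray
    resampled: np.ndarray  # index multiset, |resampled| = n
    seed: int
    failures: int

    @property
    def ess(self) -> float:
        """Effective sample size 1 / sum w^2."""
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class PosteriorSummary:
    mean: dict
    sd: dict
    relative_uncertainty: dict  # sd / mean
    ess: float
    failures: int
    n_ens: int
    config: dict
    ensemble: Ensemble | None = None

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "relative_uncertainty": self.relative_uncertainty,
            "ess": self.ess,
            "failures": self.failures,
            "n_ens": self.n_ens,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class EstimateConfig:
    n_ens: int = 2000
    seed: int = 0
    mesh_target: int = 205
    h_ms: float = DEFAULT_H_MS
    duration_ms: float = DEFAULT_DURATION_MS
    trim_ms: float = 250.0
    sigma_e: float = 1.0  # mm^2, chosen wide to whiten the likelihood
    workers: int = 1
    supraglottal_mode: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _score_sample(row, spec, config, mesh, meas) -> float:
    """Forward-simulate one prior draw and score it; -inf on failure."""
    props = props_from_sample(row, spec)
    result = simulate(
        props,
        mesh,
        duration_ms=config.duration_ms,
        h_ms=config.h_ms,
        catch_blowup=True,
        supraglottal_mode=config.supraglottal_mode,
    )
    if not result.ok:
        return -np.inf
    try:
        sim = trim_transient(
            downsample(compute_gaw(result), meas.fps), config.trim_ms
        )
        aligned = phase_align(sim, meas)
    except ValueError:
        return -np.inf
    n = len(aligned)
    if n < 2:
        return -np.inf
    meas_crop = GAWSeries(meas.t[:n], meas.area[:n], meas.fps)
    return log_likelihood(meas_crop, aligned, config.sigma_e)


def _evaluate(samples, spec, config, mesh, meas) -> np.ndarray:
    """Log-likelihood per sample; worker-count invariant by construction
    (each sample's work depends only on its row)."""
    if config.workers > 1:
        from joblib import Parallel, delayed

        lls = Parallel(n_jobs=config.workers, batch_size="auto")(
            delayed(_score_sample)(row, spec, config, mesh, meas) for row in samples
        )
        return np.array(lls)
    return np.array([_score_sample(row, spec, config, mesh, meas) for row in samples])


def _summarise(samples, names, lls, weights, resampled, seed, config) -> PosteriorSummary:
    res = samples[resampled]
    mean = {n: float(res[:, j].mean()) for j, n in enumerate(names)}
    sd = {n: float(res[:, j].std(ddof=0)) for j, n in enumerate(names)}
    rel = {n: sd[n] / mean[n] if mean[n] != 0 else np.inf for n in names}
    ens = Ensemble(
        samples=samples,
        param_names=list(names),
        log_likelihoods=lls,
        weights=weights,
        resampled=resampled,
        seed=seed,
        failures=int(np.sum(~np.isfinite(lls))),
    )
    return PosteriorSummary(
        mean=mean,
        sd=sd,
        relative_uncertainty=rel,
        ess=ens.ess,
        failures=ens.failures,
        n_ens=len(samples),
        config=config.as_dict() if hasattr(config, "as_dict") else dict(config),
        ensemble=ens,
    )


def estimate(
    meas: GAWSeries,
    spec: PriorSpec | None = None,
    config: EstimateConfig | None = None,
    mesh=None,
) -> PosteriorSummary:
    """Full importance-sampling estimate from a measured GAW.

    Deterministic for a fixed (config, seed) regardless of worker count.
    """
    spec = spec or PriorSpec()
    config = config or EstimateConfig()
    if mesh is None:
        mesh = triangulate(build_default_geometry(), config.mesh_target)
    samples = sample_prior(spec, config.n_ens, config.seed)
    lls = _evaluate(samples, spec, config, mesh, meas)
    weights = importance_weights(lls)
    resampled = resample(samples, weights, config.seed + 1)
    return _summarise(samples, spec.param_names, lls, weights, resampled, config.seed, config)


def welch_t(a: PosteriorSummary, b: PosteriorSummary, parameter: str) -> dict:
    """|mean_a - mean_b| / sqrt(sd_a^2 + sd_b^2) with a normal-approximation
    significance flag at 95% (the posterior samples carry no clean dof)."""
    for s in (a, b):
        if parameter not in s.mean:
            raise KeyError(f"parameter {parameter!r} missing from summary")
    denom = np.hypot(a.sd[parameter], b.sd[parameter])
    if denom == 0:
        raise ZeroDivisionError("zero combined standard deviation")
    t = abs(a.mean[parameter] - b.mean[parameter]) / denom
    return {"t": float(t), "significant_95": bool(t > 1.959963984540054)}


# ---------------------------------------------------------------------------
# sensitivity sweeps (ensemble size / time step / mesh density)


def sensitivity_sweep(
    meas: GAWSeries,
    spec: PriorSpec,
    axis: str,
    grid,
    config: EstimateConfig,
    truth: MaterialProperties,
) -> list[dict]:
    """Relative error and relative uncertainty along one numerical axis.

    For ``ensemble_size`` the likelihood evaluations of the largest grid
    point are reused: the first n draws of the full ensemble are a valid
    size-n ensemble from the same prior, so smaller points are free.
    Errors are percentage differences from the supplied truth, averaged
    and maximised across the estimated parameters.
    """
    truth_vec = props_to_sample(truth, spec)
    names = spec.param_names
    out = []

    def report(point, summary):
        means = np.array([summary.mean[n] for n in names])
        rel_err = 100.0 * np.abs(means - truth_vec) / np.abs(truth_vec)
        rel_unc = 100.0 * np.array([summary.relative_uncertainty[n] for n in names])
        return {
            axis: point,
            "avg_rel_error_pct": float(rel_err.mean()),
            "max_rel_error_pct": float(rel_err.max()),
            "avg_rel_uncertainty_pct": float(rel_unc.mean()),
            "max_rel_uncertainty_pct": float(rel_unc.max()),
            "ess": summary.ess,
            "failures": summary.failures,
            "summary": summary,
        }

    if axis == "ensemble_size":
        grid = sorted(int(g) for g in grid)
        n_max = grid[-1]
        cfg = EstimateConfig(**{**config.as_dict(), "n_ens": n_max})
        mesh = triangulate(build_default_geometry(), cfg.mesh_target)
        samples = sample_prior(spec, n_max, cfg.seed)
        lls = _evaluate(samples, spec, cfg, mesh, meas)
        for n in grid:
            w = importance_weights(lls[:n])
            idx = resample(samples[:n], w, cfg.seed + 1)
            summary = _summarise(samples[:n], names, lls[:n], w, idx, cfg.seed, cfg)
            out.append(report(n, summary))
    elif axis == "timestep":
        for h in grid:
            cfg = EstimateConfig(**{**config.as_dict(), "h_ms": float(h)})
            out.append(report(float(h), estimate(meas, spec, cfg)))
    elif axis == "mesh_density":
        for target in grid:
            cfg = EstimateConfig(**{**config.as_dict(), "mesh_target": int(target)})
            out.append(report(int(target), estimate(meas, spec, cfg)))
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    return out
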