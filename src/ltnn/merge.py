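"""Merging the refinement-network time with diffusion pseudotime.

The refinement regressor is trained only on origin/middle/end cells, whose
targets are drawn from state-specific normals — N(0.05, 0.1) for origin,
N(0.5, 0.1) for middle, N(0.95, 0.1) for end, clipped to [0, 1].  Its
predictions over all cells tend to be unimodal (normal-like), while
diffusion pseudotime follows a double-Weibull shape; the merged time
weights each cell's two times by the fitted pdf values,

    t_merged(i) = (f_dw(t_dpt(i)) * t_re(i) + f_n(t_re(i)) * t_dpt(i))
                  / (f_dw(t_dpt(i)) + f_n(t_re(i)))

with the double-Weibull fitted on the diffusion times and the normal on
the network times, so each pdf is evaluated at the sample it was fitted
on.  The merged value is a per-cell convex combination of the two inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .ann import RegressorSpec, TrainedRegressor, predict_time, train_regressor
from .io import ValidationError
from .states import StateAssignment

STATE_TARGET_PARAMS = {"origin": (0.05, 0.1), "middle": (0.5, 0.1), "end": (0.95, 0.1)}


@dataclass
class DistributionFit:
    """A fitted double-Weibull or normal distribution."""

    family: str                 # "dweibull" | "normal"
    shape: float | None         # dweibull only, > 0
    loc: float
    scale: float                # > 0
    loglik: float

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "dweibull":
            return stats.dweibull.pdf(x, self.shape, loc=self.loc, scale=self.scale)
        if self.family == "normal":
            return stats.norm.pdf(x, loc=self.loc, scale=self.scale)
        raise ValidationError(f"unknown family {self.family!r}")


def build_reann_targets(
    states: StateAssignment, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw seeded training targets for origin/middle/end cells.

    Returns (cell indices, targets); targets are clipped (not resampled)
    to [0, 1] so the draw stays reproducible.  Cells labeled other are
    excluded from training.
    """
    rng = np.random.default_rng(seed)
    idx_parts, tgt_parts = [], []
    for label, (mu, sd) in STATE_TARGET_PARAMS.items():
        idx = np.flatnonzero(states.state == label)
        if idx.size == 0:
            raise ValidationError(f"state set {label!r} is empty")
        idx_parts.append(idx)
        tgt_parts.append(np.clip(rng.normal(mu, sd, idx.size), 0.0, 1.0))
    return np.concatenate(idx_parts), np.concatenate(tgt_parts)


def train_reann(
    lsi_scores: np.ndarray,
    train_idx: np.ndarray,
    targets: np.ndarray,
    spec: RegressorSpec,
) -> tuple[TrainedRegressor, np.ndarray]:
    """Train the refinement regressor on the state cells, predict all cells.

    Returns the model and the [0, 1]-rescaled prediction over the full
    cell set.
    """
    model = train_regressor(lsi_scores[train_idx], targets, spec)
    return model, predict_time(model, lsi_scores)


def fit_normal(samples) -> DistributionFit:
    """Closed-form normal MLE: mean and population (1/n) standard deviation."""
    x = np.asarray(samples, dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("normal fit needs >= 2 distinct values (sigma > 0)")
    mu = float(x.mean())
    sd = float(x.std(ddof=0))
    ll = float(stats.norm.logpdf(x, mu, sd).sum())
    return DistributionFit(family="normal", shape=None, loc=mu, scale=sd, loglik=ll)


def fit_dweibull(samples) -> DistributionFit:
    """Numeric MLE of the double-Weibull (shape, location, scale).

    The symmetrized pdf (k/2)(|x-mu|/sigma)^(k-1) exp(-(|x-mu|/sigma)^k) is
    maximized with bounded L-BFGS-B from shape=2, loc=median, scale=sample
    standard deviation.
    """
    x = np.asarray(samples, dtype=float)
    if np.unique(x).size < 5:
        raise ValidationError("double-Weibull fit needs >= 5 distinct values")

    def nll(params):
        k, mu, sigma = params
        lp = stats.dweibull.logpdf(x, k, loc=mu, scale=sigma)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -float(lp.sum())

    x0 = np.array([2.0, float(np.median(x)), float(x.std(ddof=0))])
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(1e-6, None), (None, None), (1e-6, None)],
    )
    if not res.success and not np.isfinite(res.fun):
        raise ValidationError(f"double-Weibull MLE did not converge: {res.message}")
    k, mu, sigma = res.x
    return DistributionFit(
        family="dweibull", shape=float(k), loc=float(mu), scale=float(sigma),
        loglik=-float(res.fun),
    )


def merge_times(
    t_reann: np.ndarray,
    t_dpt: np.ndarray,
    fit_dw: DistributionFit,
    fit_n: DistributionFit,
    rescale: bool = True,
) -> np.ndarray:
    """Per-cell pdf-weighted convex combination of the two pseudotimes.

    ``fit_dw`` must be fitted on the diffusion-time sample and ``fit_n`` on
    the network-time sample.  When both pdf values underflow, equal weights
    are used.  By default the merged vector is min-max rescaled to [0, 1].
    """
    t_reann = np.asarray(t_reann, dtype=float)
    t_dpt = np.asarray(t_dpt, dtype=float)
    if t_reann.shape != t_dpt.shape:
        raise ValidationError(
            f"time vectors differ in length: {t_reann.shape} vs {t_dpt.shape}"
        )
    w_d = fit_dw.pdf(t_dpt)
    w_n = fit_n.pdf(t_reann)
    total = w_d + w_n
    under = total <= np.finfo(float).tiny
    w_d = np.where(under, 0.5, w_d)
    w_n = np.where(under, 0.5, w_n)
    total = w_d + w_n
    merged = (w_d * t_reann + w_n * t_dpt) / total
    if rescale:
        lo, hi = merged.min(), merged.max()
        if hi > lo:
            merged = (merged - lo) / (hi - lo)
    return merged
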