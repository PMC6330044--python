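"""Maximum-likelihood fitting of continuous trait-evolution models.

Four models are supported, each defined by a transform of the Brownian-motion
covariance matrix (see :func:`phyloniche.trees.transform_vcv`):

* ``bm``    — random walk at constant rate sigma2 from root state z0 (k = 2);
* ``ou``    — Ornstein-Uhlenbeck attraction toward an optimum with strength
  alpha (k = 3);
* ``eb``    — early burst, rate decaying exponentially through time with
  decay r <= 0 (k = 3);
* ``delta`` — Pagel's delta, node depths raised to delta; delta > 1
  concentrates change toward the tips (k = 3).

Model comparison uses the small-sample Akaike criterion,
``AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)``, and a four-way distinguishability
code on the AICc difference to the best model: ``e`` (< 2, equivalent), ``*``
([2, 7)), ``**`` ([7, 10)), ``***`` (>= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._gls import align_trait, ml_lnl
from .trees import Phylo, transform_vcv, vcv

__all__ = ["ModelFit", "ModelTable", "fit_model", "fit_all_models", "aicc",
           "rank_models", "delta_aic_category", "model_table", "fit_multi_optimum_ou"]

MODELS = ("bm", "ou", "eb", "delta")
_SHAPE_PARAM = {"ou": "alpha", "eb": "r", "delta": "delta"}


@dataclass
class ModelFit:
    model: str
    params: dict
    lnL: float
    k: int
    n: int
    aicc: float
    at_bound: bool = False


@dataclass
class ModelTable:
    fits: list[ModelFit]
    delta_aic: list[float] = field(default_factory=list)
    category: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, d, c in zip(self.fits, self.delta_aic, self.category):
            row = {"model": f.model, "lnL": f.lnL, "AICc": f.aicc, "k": f.k,
                   "dAIC": d, "category": c}
            row.update({k: v for k, v in f.params.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_aic_category(d: float) -> str:
    """Distinguishability code for an AICc difference to the best model."""
    if d < 2:
        return "e"
    if d < 7:
        return "*"
    if d < 10:
        return "**"
    return "***"


def _default_bounds(model: str, T: float) -> tuple[float, float]:
    if model == "ou":
        return (1e-8, 50.0 / T)
    if model == "eb":
        return (-10.0 / T, 0.0)
    if model == "delta":
        return (1e-3, 3.0)
    raise ValueError(model)


def fit_model(tree: Phylo, x, model: str, bounds: tuple[float, float] | None = None) -> ModelFit:
    """Fit one trait-evolution model by ML.

    The root state z0 and rate sigma2 are profiled in closed form (GLS) for
    any value of the shape parameter, which is then optimized by a fixed
    5-point start grid plus bounded refinement — the fit is deterministic.
    A shape estimate pinned at a bound is flagged via ``at_bound``, not an
    error (Pagel's delta saturates at its upper bound of 3 on real data).
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    xv = align_trait(tree, x)
    n = len(xv)
    C0 = vcv(tree)
    T = float(np.max(np.diag(C0.C)))
    k = 2 if model == "bm" else 3

    def _aicc(lnl: float) -> float:
        return aicc(lnl, k, n) if n > k + 1 else float("nan")

    if model == "bm":
        lnl, z0, s2 = ml_lnl(C0.C, xv)
        return ModelFit("bm", {"sigsq": s2, "z0": z0}, lnl, 2, n, _aicc(lnl))

    pname = _SHAPE_PARAM[model]
    lo, hi = bounds if bounds is not None else _default_bounds(model, T)

    def negll(theta: float) -> float:
        Ct = transform_vcv(C0, model, {pname if model != "lambda" else "lam": theta}, T=T).C
        return -ml_lnl(Ct, xv)[0]

    starts = np.linspace(lo, hi, 5)
    best_theta, best_f = None, np.inf
    for s0 in starts:
        a = max(lo, s0 - (hi - lo) / 4)
        b = min(hi, s0 + (hi - lo) / 4)
        if a >= b:
            continue
        res = minimize_scalar(negll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8})
        if res.fun < best_f:
            best_theta, best_f = float(res.x), float(res.fun)
    # also test the bounds themselves (saturating estimates)
    for edge in (lo, hi):
        f = negll(edge)
        if f < best_f:
            best_theta, best_f = float(edge), float(f)

    Ct = transform_vcv(C0, model, {pname: best_theta}, T=T).C
    lnl, z0, s2 = ml_lnl(Ct, xv)
    span = hi - lo
    at_bound = min(best_theta - lo, hi - best_theta) < 1e-6 * span
    params = {"sigsq": s2, "z0": z0, pname: best_theta}
    return ModelFit(model, params, lnl, k, n, _aicc(lnl), at_bound=at_bound)


def fit_all_models(tree: Phylo, x, models=MODELS) -> list[ModelFit]:
    return [fit_model(tree, x, m) for m in models]


def rank_models(fits: list[ModelFit]) -> ModelTable:
    """Sort fits by ascending AICc and attach dAIC and category codes."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to rank")
    fits = sorted(fits, key=lambda f: f.aicc)
    best = fits[0].aicc
    d = [f.aicc - best for f in fits]
    return ModelTable(fits=fits, delta_aic=d, category=[delta_aic_category(v) for v in d])


def model_table(tree: Phylo, traits: pd.DataFrame, models=MODELS) -> pd.DataFrame:
    """Fit and rank all models for every trait column; one long DataFrame."""
    frames = []
    for col in traits.columns:
        tab = rank_models(fit_all_models(tree, traits[col], models=models)).to_frame()
        tab.insert(0, "layer", col)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def fit_multi_optimum_ou(*args, **kwargs):
    """Reversible-jump multi-optima OU fitting (interface stub).

    A full treatment samples the number and placement of optimum shifts
    across branches (conditional-Poisson prior on shift count, at most one
    shift per branch) jointly with alpha, sigma2 and the per-regime optima by
    reversible-jump MCMC.  That machinery is deliberately not implemented
    here; single-optimum OU is available through :func:`fit_model`.
    """
    raise NotImplementedError(
        "multi-optima OU (reversible-jump MCMC) is out of scope; "
        "use fit_model(tree, x, 'ou') for the single-optimum model"
    )
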