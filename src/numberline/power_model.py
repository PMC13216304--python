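"""Cyclical power models of number-line placement with a unit-digit weight.

The placement of a two-digit number ``x = x_d + x_u`` (decade part ``x_d``,
unit digit ``x_u``) is modelled as a cyclical proportion judgment anchored
at the line's reference points, with the unit digit's contribution
compressed by a power weight δ:

    s = x_d + x_u ** δ
    y = (s − LB)**β / ((s − LB)**β + (UB − s)**β) · (UB − LB) + LB

* **one-cycle**: a single segment, LB = 0, UB = 100 (anchors at the ends);
* **two-cycle**: the midpoint is an additional anchor — targets ≤ 50 use
  LB = 0, UB = 50 and targets > 50 use LB = 50, UB = 100.

β > 0 is the index of curvature (β = 1: no cyclical bending); δ = 1 makes
the unit digit contribute veridically, δ < 1 is a left-digit bias (the
decade digit dominates).  A *language modifier* λ lets a comparison group
have its own effective unit weight, δ_eff = δ + λ·L with L = 0 for the
reference language and L = 1 for the comparison language; λ significantly
different from 0 is the evidence that the unit digit's contribution is
language specific.

Fitting is nonlinear least squares over group-level median placing
positions per target (targets > 20), with shared β and δ across groups.
Starting values are β = 1, δ = 1, λ = 0; β > 0 is enforced by optimising
log β, with natural-scale standard errors recovered by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trial_data import retained

__all__ = [
    "decompose", "predict_cyclical", "predict_two_cycle", "predict_one_cycle",
    "prepare_medians", "fit_language_pair", "fit_multi_language",
    "compare_cycles", "PowerModelFit",
]

#: Clamp margin for optimizer excursions pushing s past a segment boundary.
_EDGE = 1e-9

#: Convergence tolerance on the residual norm.
_TOL = 1e-10

_MAX_ITER = 500


def decompose(target):
    """Split two-digit targets into decade part and unit digit (28 → 20, 8)."""
    t = np.asarray(target)
    x_d = (t // 10) * 10
    x_u = t - x_d
    return x_d, x_u


def predict_cyclical(target, beta: float, delta_eff, cycles: str = "two"):
    """Predicted placing position(s) for target(s) under (β, δ_eff).

    ``delta_eff`` may be a scalar or an array aligned with ``target`` (used
    when languages differ in their effective unit weight).  Segment
    membership in the two-cycle model is decided by the *raw* target value;
    if the transformed value s = x_d + x_u**δ_eff falls outside its segment
    (possible only for δ_eff well above 1, i.e. optimizer excursions) it is
    clamped just inside the boundary.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if cycles not in ("one", "two"):
        raise ValueError("cycles must be 'one' or 'two'")
    t = np.asarray(target, dtype=float)
    x_d, x_u = decompose(t)
    s = x_d + np.power(x_u, delta_eff, where=x_u > 0, out=np.zeros_like(t))
    if cycles == "one":
        lb = np.zeros_like(t)
        ub = np.full_like(t, 100.0)
    else:
        upper = t > 50
        lb = np.where(upper, 50.0, 0.0)
        ub = np.where(upper, 100.0, 50.0)
    s = np.clip(s, lb + _EDGE, ub - _EDGE)
    a = np.power(s - lb, beta)
    b = np.power(ub - s, beta)
    y = a / (a + b) * (ub - lb) + lb
    return float(y) if np.ndim(target) == 0 else y


def predict_two_cycle(target, beta: float, delta: float = 1.0, lam: float = 0.0, L=0):
    """Two-cycle prediction with δ_eff = δ + λ·L (L: 0 reference, 1 comparison)."""
    return predict_cyclical(target, beta, delta + lam * np.asarray(L), cycles="two")


def predict_one_cycle(target, beta: float, delta: float = 1.0, lam: float = 0.0, L=0):
    """One-cycle prediction (single segment spanning the whole line)."""
    return predict_cyclical(target, beta, delta + lam * np.asarray(L), cycles="one")


# ---------------------------------------------------------------------------
# Model input: median placing positions
# ---------------------------------------------------------------------------

def prepare_medians(trials: pd.DataFrame, min_target: int = 21,
                    per_participant_first: bool = False) -> pd.DataFrame:
    """Median placing position per (language, target) for model fitting.

    Uses the median rather than the mean: each target draws eight responses
    per participant, so the median absorbs occasional stray touches without
    any response-level outlier trimming.  By default responses are pooled
    across all participants of a language (both orientations); with
    ``per_participant_first`` each participant contributes one median and
    the group value is the median of those.

    Teens are excluded (``min_target`` = 21): the model is built on targets
    above 20.  Targets with no retained responses are omitted.
    """
    df = retained(trials)
    df = df[df["target"] >= min_target]
    if per_participant_first:
        per = (df.groupby(["language", "target", "participant_id"])["placing_position"]
               .median().reset_index())
        med = per.groupby(["language", "target"])["placing_position"].median()
        n = df.groupby(["language", "target"])["placing_position"].size()
    else:
        g = df.groupby(["language", "target"])["placing_position"]
        med, n = g.median(), g.size()
    out = med.rename("median_position").reset_index()
    out["n_responses"] = n.to_numpy()
    x_d, x_u = decompose(out["target"].to_numpy())
    out["x_d"], out["x_u"] = x_d, x_u
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerModelFit:
    """Nonlinear-least-squares fit of a cyclical power model.

    ``params`` maps parameter name → (estimate, SE, t, p); t uses n − k
    residual degrees of freedom, p is two-sided.  ``bic`` is the Gaussian
    BIC n·ln(RSS/n) + k·ln(n).
    """

    params: dict[str, tuple[float, float, float, float]]
    rss: float
    n: int
    cycles: str
    reference: str
    languages: tuple[str, ...]
    converged: bool
    n_clamped: int = 0
    at_bound: tuple[str, ...] = ()
    message: str = ""
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def df_resid(self) -> int:
        return self.n - self.k

    @property
    def bic(self) -> float:
        from .inferential_stats import bic
        return bic(self.rss, self.n, self.k)

    def estimate(self, name: str) -> float:
        return self.params[name][0]

    def table(self) -> pd.DataFrame:
        """Estimates table: Parameter, Estimate, Std. Error, t value, Pr(>|t|)."""
        rows = [{"Parameter": name, "Estimate": est, "Std. Error": se,
                 "t value": t, "Pr(>|t|)": p}
                for name, (est, se, t, p) in self.params.items()]
        return pd.DataFrame(rows)


def _fit_core(targets: np.ndarray, medians: np.ndarray, indicators: np.ndarray,
              cycles: str, reference: str, languages: tuple[str, ...],
              lam_names: list[str]) -> PowerModelFit:
    """Shared least-squares machinery for pair and multi-language fits.

    ``indicators`` is (n, m): column j is the 0/1 indicator of the j-th
    comparison language (m = 1 for a pair fit).  Internal parameters are
    (log β, δ, λ_1 … λ_m); SEs are reported on the natural scale.
    """
    m = indicators.shape[1]

    def resid(theta):
        beta = np.exp(theta[0])
        delta_eff = theta[1] + indicators @ theta[2:]
        return predict_cyclical(targets, beta, delta_eff, cycles=cycles) - medians

    theta0 = np.concatenate([[0.0], [1.0], np.zeros(m)])  # beta=1, delta=1, lam=0
    # box bounds keep the optimizer off the x_u**delta_eff -> 0 plateau that
    # data with a large uniform shift would otherwise drive lambda into
    lo = np.concatenate([[np.log(1e-2)], [-5.0], np.full(m, -5.0)])
    hi = np.concatenate([[np.log(1e2)], [5.0], np.full(m, 5.0)])
    sol = optimize.least_squares(resid, theta0, method="trf", bounds=(lo, hi),
                                 xtol=_TOL, ftol=_TOL, gtol=_TOL,
                                 max_nfev=_MAX_ITER * (2 + m))
    if not sol.success:
        raise RuntimeError(f"power-model fit did not converge: {sol.message}")
    at_bound = [nm for nm, x, l, h in zip(["beta", "delta"] + lam_names,
                                          sol.x, lo, hi)
                if x - l < 1e-6 or h - x < 1e-6]

    n, k = len(targets), 2 + m
    rss = float(sol.fun @ sol.fun)
    sigma2 = rss / (n - k)
    JtJ = sol.jac.T @ sol.jac
    cov_internal = sigma2 * np.linalg.pinv(JtJ)
    # delta method: natural beta = exp(theta0'), gradient diag(beta, 1, ..., 1)
    beta = float(np.exp(sol.x[0]))
    grad = np.ones(k)
    grad[0] = beta
    cov = cov_internal * np.outer(grad, grad)
    estimates = np.concatenate([[beta], sol.x[1:]])
    ses = np.sqrt(np.diag(cov))
    tvals = estimates / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    names = ["beta", "delta"] + lam_names
    params = {nm: (float(estimates[i]), float(ses[i]), float(tvals[i]), float(pvals[i]))
              for i, nm in enumerate(names)}

    delta_eff = sol.x[1] + indicators @ sol.x[2:]
    n_clamped = _count_clamped(targets, delta_eff, cycles)
    preds = pd.DataFrame({"target": targets, "median_position": medians,
                          "predicted": predict_cyclical(targets, beta, delta_eff,
                                                        cycles=cycles)})
    return PowerModelFit(params=params, rss=rss, n=n, cycles=cycles,
                         reference=reference, languages=languages,
                         converged=bool(sol.success), n_clamped=n_clamped,
                         at_bound=tuple(at_bound),
                         message=sol.message, predictions=preds)


def _count_clamped(targets: np.ndarray, delta_eff, cycles: str) -> int:
    x_d, x_u = decompose(np.asarray(targets, dtype=float))
    s = x_d + np.power(x_u, delta_eff, where=x_u > 0, out=np.zeros_like(x_d, dtype=float))
    if cycles == "one":
        return int(np.sum((s < 0) | (s > 100)))
    upper = np.asarray(targets) > 50
    lb = np.where(upper, 50.0, 0.0)
    ub = np.where(upper, 100.0, 50.0)
    return int(np.sum((s < lb) | (s > ub)))


def fit_language_pair(medians: pd.DataFrame, reference: str, comparison: str | None = None,
                      cycles: str = "two") -> PowerModelFit:
    """Fit the model to two languages' medians with one language modifier.

    ``medians`` comes from :func:`prepare_medians` and must contain the
    reference language plus exactly one other (or name it explicitly).
    Shared β and δ; the comparison language's effective unit weight is
    δ + λ.  Requires ≥ 10 targets per language.
    """
    langs = sorted(medians["language"].unique())
    if reference not in langs:
        raise ValueError(f"reference language {reference!r} not in data ({langs})")
    if comparison is None:
        others = [l for l in langs if l != reference]
        if len(others) != 1:
            raise ValueError(f"specify the comparison language; found {others}")
        comparison = others[0]
    sub = medians[medians["language"].isin([reference, comparison])]
    for lang in (reference, comparison):
        if (sub["language"] == lang).sum() < 10:
            raise ValueError(f"need ≥ 10 targets for {lang!r}")
    L = (sub["language"] == comparison).to_numpy(dtype=float)[:, None]
    return _fit_core(sub["target"].to_numpy(dtype=float),
                     sub["median_position"].to_numpy(dtype=float),
                     L, cycles, reference, (reference, comparison), ["lambda"])


def fit_multi_language(medians: pd.DataFrame, reference: str,
                       cycles: str = "two") -> PowerModelFit:
    """Fit all languages jointly, one λ per non-reference language.

    With a single non-reference language this reduces exactly to
    :func:`fit_language_pair`.  λ parameters are named
    ``lambda_<language>``.
    """
    langs = sorted(medians["language"].unique())
    if reference not in langs:
        raise ValueError(f"reference language {reference!r} not in data ({langs})")
    others = [l for l in langs if l != reference]
    if not others:
        raise ValueError("need at least two languages")
    for lang in langs:
        if (medians["language"] == lang).sum() < 10:
            raise ValueError(f"need ≥ 10 targets for {lang!r}")
    L = np.column_stack([(medians["language"] == l).to_numpy(dtype=float)
                         for l in others])
    names = [f"lambda_{l}" for l in others]
    return _fit_core(medians["target"].to_numpy(dtype=float),
                     medians["median_position"].to_numpy(dtype=float),
                     L, cycles, reference, tuple([reference] + others), names)


def compare_cycles(medians: pd.DataFrame, reference: str,
                   comparison: str | None = None) -> dict:
    """BIC comparison of the one- vs two-cycle structure on the same data."""
    fits = {c: fit_language_pair(medians, reference, comparison, cycles=c)
            for c in ("one", "two")}
    bics = {c: f.bic for c, f in fits.items()}
    preferred = min(bics, key=bics.get)
    return {"fits": fits, "bic": bics, "preferred": preferred}
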