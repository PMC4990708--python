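"""Single-trait continuous-evolution models: BM, OU and EB.

The Brownian-motion likelihood is computed by the pruning (independent
contrasts) algorithm in O(n); Ornstein-Uhlenbeck and early-burst fits
profile a single shape parameter (pull strength alpha, rate-decay g) by
bounded 1-D optimisation with the Gaussian GLS root and ML rate solved in
closed form at each candidate value.

OU on a non-ultrametric tree uses the Hansen covariance with the root
state fixed (and equal to the optimum): fossil tips sit at different
depths, so the stationary OU covariance would be wrong.  EB rescales each
branch by the integral of exp(g * t) over the branch's time interval and
then reuses the BM machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo_io import TimeTree

__all__ = [
    "ModelFitResult",
    "MissingTraitError",
    "bm_loglik",
    "fit_model",
    "compare_models",
    "phylo_covariance",
]

LN_2PI = math.log(2.0 * math.pi)


class MissingTraitError(ValueError):
    """Some tips have no trait value."""


@dataclass
class ModelFitResult:
    """Maximum-likelihood fit of one model to one trait."""

    model: str
    log_likelihood: float
    n_parameters: int
    aic: float
    aicc: float
    parameters: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    degenerate: bool = False
    delta_aic: float | None = None


def _check_traits(tree: TimeTree, traits: dict[str, float]) -> None:
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise MissingTraitError(f"no trait value for taxa: {missing}")


def _pruning_pass(
    tree: TimeTree, traits: dict[str, float], lengths: dict[int, float]
) -> tuple[float, float, float, float]:
    """Single post-order peel with unit rate.

    Returns (root_mean, root_var, logdet_C0, q_contrasts) where C0 is the
    tip covariance at sigma2 = 1 built from `lengths`, root_mean is the GLS
    root estimate, root_var = (1' C0^-1 1)^-1, and q_contrasts is the
    GLS sum of squares about root_mean.
    """
    mu: dict[int, float] = {}
    var: dict[int, float] = {}
    logdet = 0.0
    q = 0.0
    for nid in tree.postorder():
        node = tree.node(nid)
        if node.is_tip:
            mu[nid] = traits[node.label]  # type: ignore[index]
            var[nid] = 0.0
            continue
        # fold children pairwise; exact for any out-degree
        m, v = None, None
        for cid in node.children:
            mc, vc = mu[cid], var[cid] + lengths[cid]
            if m is None:
                m, v = mc, vc
            else:
                s = v + vc
                logdet += math.log(s)
                q += (m - mc) ** 2 / s
                m = (m * vc + mc * v) / s
                v = v * vc / s
        mu[nid], var[nid] = m, v  # type: ignore[assignment]
    root = tree.root_id
    root_var = var[root]
    logdet += math.log(root_var)
    return mu[root], root_var, logdet, q


def _branch_lengths(tree: TimeTree) -> dict[int, float]:
    return {
        nid: tree.duration(nid) for nid in tree.preorder() if nid != tree.root_id
    }


def bm_loglik(
    tree: TimeTree, traits: dict[str, float], sigma2: float, root_state: float
) -> float:
    """Log density of tip values under Brownian motion.

    Tips are jointly normal with mean `root_state` and covariance
    sigma2 times the shared root-to-MRCA path-length matrix; evaluated by
    the pruning algorithm in O(n).
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    _check_traits(tree, traits)
    n = tree.n_tips
    root_mean, root_var, logdet, q = _pruning_pass(tree, traits, _branch_lengths(tree))
    q += (root_mean - root_state) ** 2 / root_var
    return -0.5 * (n * LN_2PI + logdet + n * math.log(sigma2) + q / sigma2)


def phylo_covariance(tree: TimeTree) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tip labels, shared-path-length matrix T_a, and tip depths.

    T_a[i, j] is the duration of the path shared by tips i and j (their
    MRCA's depth); the diagonal is each tip's own depth.  This is the BM
    covariance at sigma2 = 1.
    """
    labels = tree.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ta = np.zeros((n, n))
    depths = tree.depths()
    tipsets: dict[int, list[int]] = {}
    for nid in tree.postorder():
        node = tree.node(nid)
        if node.is_tip:
            i = idx[node.label]  # type: ignore[index]
            tipsets[nid] = [i]
            ta[i, i] = depths[nid]
            continue
        groups = [tipsets.pop(c) for c in node.children]
        d = depths[nid]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        ta[i, j] = ta[j, i] = d
        tipsets[nid] = [i for g in groups for i in g]
    tip_depths = np.array([ta[i, i] for i in range(n)])
    return labels, ta, tip_depths


def _gls_profile(V: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """GLS root, ML sigma2 and profile logL for covariance sigma2 * V."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return math.nan, math.nan, -math.inf
    Vi_x = np.linalg.solve(V, x)
    Vi_1 = np.linalg.solve(V, np.ones(n))
    root = float(x @ Vi_1 / (np.ones(n) @ Vi_1))
    resid = x - root
    q = float(resid @ np.linalg.solve(V, resid))
    if q <= 0:
        return root, 0.0, math.inf
    sigma2 = q / n
    ll = -0.5 * (n * LN_2PI + logdet + n * math.log(sigma2) + n)
    return root, sigma2, ll


def _ou_covariance(ta: np.ndarray, depths: np.ndarray, alpha: float) -> np.ndarray:
    """Hansen covariance at sigma2 = 1, root state fixed at the optimum."""
    dsum = depths[:, None] + depths[None, :]
    return np.exp(-alpha * (dsum - 2.0 * ta)) * (1.0 - np.exp(-2.0 * alpha * ta)) / (
        2.0 * alpha
    )


def _eb_lengths(tree: TimeTree, g: float) -> dict[int, float]:
    """Branch lengths rescaled for an exponentially decaying rate exp(g t)."""
    depths = tree.depths()
    out = {}
    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        t1 = depths[nid]
        t0 = t1 - tree.duration(nid)
        if abs(g) < 1e-12:
            out[nid] = t1 - t0
        else:
            out[nid] = (math.exp(g * t1) - math.exp(g * t0)) / g
    return out


def _fit_bm(tree: TimeTree, traits: dict[str, float]) -> ModelFitResult:
    n = tree.n_tips
    root_mean, root_var, logdet, q = _pruning_pass(tree, traits, _branch_lengths(tree))
    if q <= 1e-12 * max(1, n):
        # all tip values (effectively) identical: sigma2 on the boundary
        return ModelFitResult(
            model="BM",
            log_likelihood=math.inf,
            n_parameters=2,
            aic=-math.inf,
            aicc=-math.inf,
            parameters={"sigma2": 0.0, "root_state": root_mean, "sigma2_reml": 0.0},
            degenerate=True,
        )
    sigma2 = q / n
    ll = -0.5 * (n * LN_2PI + logdet + n * math.log(sigma2) + n)
    k = 2
    return ModelFitResult(
        model="BM",
        log_likelihood=ll,
        n_parameters=k,
        aic=2 * k - 2 * ll,
        aicc=2 * k - 2 * ll + 2 * k * (k + 1) / max(n - k - 1, 1),
        parameters={
            "sigma2": sigma2,
            "root_state": root_mean,
            "sigma2_reml": q / (n - 1),
        },
    )


def _fit_ou(
    tree: TimeTree, traits: dict[str, float], fixed_alpha: float | None = None
) -> ModelFitResult:
    labels, ta, depths = phylo_covariance(tree)
    x = np.array([traits[t] for t in labels])
    tmax = float(depths.max())

    def profile(alpha: float) -> tuple[float, float, float]:
        return _gls_profile(_ou_covariance(ta, depths, alpha), x)

    converged = True
    if fixed_alpha is not None:
        alpha = fixed_alpha
    else:
        lo, hi = 1e-8, 50.0 / tmax
        res = minimize_scalar(
            lambda a: -profile(a)[2], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        alpha = float(res.x)
        converged = bool(res.success)
    root, sigma2, ll = profile(alpha)
    k = 3
    return ModelFitResult(
        model="OU",
        log_likelihood=ll,
        n_parameters=k,
        aic=2 * k - 2 * ll,
        aicc=2 * k - 2 * ll + 2 * k * (k + 1) / max(tree.n_tips - k - 1, 1),
        parameters={"sigma2": sigma2, "root_state": root, "alpha": alpha},
        converged=converged,
        degenerate=sigma2 == 0.0,
    )


def _fit_eb(
    tree: TimeTree, traits: dict[str, float], fixed_decay: float | None = None
) -> ModelFitResult:
    n = tree.n_tips
    tmax = max(tree.depths().values())

    def profile(g: float) -> tuple[float, float, float, float]:
        root_mean, root_var, logdet, q = _pruning_pass(tree, traits, _eb_lengths(tree, g))
        if q <= 0:
            return root_mean, 0.0, math.inf, q
        sigma2 = q / n
        ll = -0.5 * (n * LN_2PI + logdet + n * math.log(sigma2) + n)
        return root_mean, sigma2, ll, q

    converged = True
    if fixed_decay is not None:
        g = fixed_decay
    else:
        g_min = math.log(1e-6) / tmax
        res = minimize_scalar(
            lambda g_: -profile(g_)[2], bounds=(g_min, 0.0), method="bounded",
            options={"xatol": 1e-10},
        )
        g = float(res.x)
        converged = bool(res.success)
    root, sigma2, ll, q = profile(g)
    k = 3
    return ModelFitResult(
        model="EB",
        log_likelihood=ll,
        n_parameters=k,
        aic=2 * k - 2 * ll,
        aicc=2 * k - 2 * ll + 2 * k * (k + 1) / max(n - k - 1, 1),
        parameters={"sigma2": sigma2, "root_state": root, "decay": g},
        converged=converged,
        degenerate=sigma2 == 0.0,
    )


def fit_model(
    tree: TimeTree,
    traits: dict[str, float],
    model: str,
    *,
    fixed_alpha: float | None = None,
    fixed_decay: float | None = None,
) -> ModelFitResult:
    """Fit one of BM, OU or EB by maximum likelihood.

    `fixed_alpha` / `fixed_decay` pin the shape parameter instead of
    profiling it (useful for limit checks: OU with alpha -> 0 and EB with
    decay 0 both reduce to BM).
    """
    _check_traits(tree, traits)
    model = model.upper()
    if model == "BM":
        return _fit_bm(tree, traits)
    if model == "OU":
        return _fit_ou(tree, traits, fixed_alpha)
    if model == "EB":
        return _fit_eb(tree, traits, fixed_decay)
    raise ValueError(f"unknown model {model!r}; expected BM, OU or EB")


def compare_models(
    tree: TimeTree, traits: dict[str, float], models: list[str] = ("BM", "OU", "EB")
) -> list[ModelFitResult]:
    """Fit several models and rank them by AIC (ascending, best first)."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    fits = [fit_model(tree, traits, m) for m in models]
    fits.sort(key=lambda f: f.aic)
    best = fits[0].aic
    for f in fits:
        f.delta_aic = f.aic - best
    return fits


def fits_to_frame(fits: list[ModelFitResult]):
    """Serialise fit results as a tidy table (one row per model)."""
    import pandas as pd

    rows = []
    for f in fits:
        row = {
            "model": f.model,
            "k": f.n_parameters,
            "logLik": f.log_likelihood,
            "AIC": f.aic,
            "AICc": f.aicc,
            "dAIC": f.delta_aic,
            "converged": f.converged,
            "degenerate": f.degenerate,
        }
        row.update(f.parameters)
        rows.append(row)
    return pd.DataFrame(rows)
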