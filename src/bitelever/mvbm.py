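"""Multiple-variance Brownian motion: Bayesian ancestral states and
branch-specific rate multipliers.

Model
-----
Along each branch b (duration t_b, Myr) the trait takes a Gaussian step

    x_child | x_parent ~ Normal(x_parent, sigma2 * r_b * t_b)

with a base rate sigma2 (ln-units^2 / Myr) and a dimensionless multiplier
r_b per branch.  Priors: ln r_b ~ Normal(0, nu^2) independently per
branch, sigma2 ~ InverseGamma(shape, scale), flat prior on the root
state.  nu = 0 pins every multiplier at 1 and the model collapses to
single-rate BM, which the closed-form GLS root verifies.

Sampler
-------
Metropolis-within-Gibbs:

* node states — Gibbs.  Conditional on everything else each internal
  node is normal with precision-weighted mean over its incident
  branches.  Because a parent and child always have opposite depth
  parity, the tree is two-colorable and each color class is updated as
  one vectorised draw; this is exactly one-at-a-time Gibbs, just batched.
* sigma2 — Gibbs from its conjugate inverse-gamma full conditional.
* ln r_b — vectorised random-walk Metropolis (each branch's likelihood
  term involves only its own increment, so proposals are accepted
  independently per branch).

All randomness flows through a single numpy Generator seeded from the
config, so identical config implies bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_io import TimeTree
from .trait_models import _check_traits, _fit_bm

__all__ = ["MvbmConfig", "MvbmPosterior", "mvbm_mcmc", "posterior_node_table"]


@dataclass
class MvbmConfig:
    """Settings for the mvBM sampler.

    The defaults are desk-scale (a hundred thousand sweeps runs in
    seconds on one core); production analyses simply raise `iterations`.
    """

    iterations: int = 100_000
    burn_in: float = 0.2
    thin: int = 10
    seed: int = 0
    rate_prior_sd: float = 1.0  # nu; 0 pins all multipliers at 1
    sigma2_prior_shape: float = 0.5
    sigma2_prior_scale: float = 0.5
    proposal_sd: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.burn_in < 1.0):
            raise ValueError("burn_in must be in (0, 1)")
        if self.thin < 1 or self.iterations < self.thin:
            raise ValueError("need iterations >= thin >= 1")
        if self.rate_prior_sd < 0:
            raise ValueError("rate_prior_sd must be >= 0")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")


@dataclass
class MvbmPosterior:
    """Thinned post-burn-in posterior summaries and chains."""

    node_ids: np.ndarray          # (N,) preorder node ids
    parent_ids: np.ndarray        # (N,) parent id, -1 for root
    durations: np.ndarray         # (N,) branch duration, nan for root
    is_tip: np.ndarray            # (N,) bool
    labels: list[str | None]

    state_mean: np.ndarray        # (N,)
    state_sd: np.ndarray
    state_ci: np.ndarray          # (N, 2) 2.5 / 97.5 percentiles

    rate_mult_mean: np.ndarray    # (N,) nan for root
    rate_mult_sd: np.ndarray
    rate_mult_ci: np.ndarray      # (N, 2)
    eff_rate_mean: np.ndarray     # sigma2 * r_b summaries
    eff_rate_sd: np.ndarray
    eff_rate_ci: np.ndarray

    sigma2_mean: float
    sigma2_ci: tuple[float, float]

    state_chain: np.ndarray       # (n_samples, N)
    rate_mult_chain: np.ndarray   # (n_samples, N) column 0 (root) = nan
    sigma2_chain: np.ndarray      # (n_samples,)

    diagnostics: dict = field(default_factory=dict)
    config: MvbmConfig | None = None


def _ess(chain: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(chain)[None, :]))


def mvbm_mcmc(
    tree: TimeTree, traits: dict[str, float], config: MvbmConfig
) -> MvbmPosterior:
    """Sample ancestral states and branch rate multipliers.

    Tip states are data and are never altered; internal states, the base
    rate sigma2 and (when nu > 0) the per-branch multipliers are sampled.
    """
    _check_traits(tree, traits)
    rng = np.random.default_rng(config.seed)

    order = list(tree.preorder())
    pos = {nid: i for i, nid in enumerate(order)}
    N = len(order)
    parent = np.array(
        [pos[tree.parent(n)] if tree.parent(n) is not None else -1 for n in order]
    )
    dur = np.array(
        [tree.duration(n) if tree.parent(n) is not None else np.nan for n in order]
    )
    tip_mask = np.array([tree.is_tip(n) for n in order])
    labels = [tree.node(n).label for n in order]

    # edges indexed by child position (root excluded)
    ec = np.flatnonzero(parent >= 0)
    ep = parent[ec]
    t = dur[ec]
    B = len(ec)

    # two-coloring by topological depth parity
    depth_edges = np.zeros(N, dtype=int)
    for i in range(1, N):
        depth_edges[i] = depth_edges[parent[i]] + 1
    internal = ~tip_mask
    colors = [internal & (depth_edges % 2 == p) for p in (0, 1)]

    # init: tips at data, internal states by post-order child averages
    x = np.zeros(N)
    for i, nid in enumerate(order):
        if tip_mask[i]:
            x[i] = traits[labels[i]]  # type: ignore[index]
    for nid in tree.postorder():
        i = pos[nid]
        if not tip_mask[i]:
            kids = [pos[c] for c in tree.children(nid)]
            x[i] = float(np.mean(x[kids]))

    bm = _fit_bm(tree, traits)
    sigma2 = max(bm.parameters["sigma2"], 1e-12)
    logr = np.zeros(B)
    nu = config.rate_prior_sd
    a0, b0 = config.sigma2_prior_shape, config.sigma2_prior_scale

    if not np.isfinite(x).all() or not math.isfinite(sigma2):
        raise ValueError("non-finite state at initialization")

    n_burn = int(config.iterations * config.burn_in)
    keep_iters = range(n_burn, config.iterations, config.thin)
    n_keep = len(keep_iters)
    keep_set = set(keep_iters)

    state_chain = np.empty((n_keep, N))
    mult_chain = np.empty((n_keep, B))
    sigma2_chain = np.empty(n_keep)

    accepts = 0
    proposals = 0
    k = 0
    for it in range(config.iterations):
        dx = x[ec] - x[ep]

        # --- multipliers: vectorised random-walk Metropolis on ln r ---
        if nu > 0:
            prop = logr + config.proposal_sd * rng.standard_normal(B)
            var_cur = sigma2 * np.exp(logr) * t
            var_new = sigma2 * np.exp(prop) * t
            dx2 = dx * dx
            log_ratio = (
                -0.5 * (np.log(var_new) + dx2 / var_new)
                + 0.5 * (np.log(var_cur) + dx2 / var_cur)
                - 0.5 * (prop**2 - logr**2) / nu**2
            )
            acc = np.log(rng.uniform(size=B)) < log_ratio
            logr[acc] = prop[acc]
            accepts += int(acc.sum())
            proposals += B

        r = np.exp(logr)

        # --- sigma2: conjugate inverse-gamma Gibbs ---
        s = float(np.sum(dx * dx / (r * t)))
        shape = a0 + 0.5 * B
        scale = b0 + 0.5 * s
        sigma2 = scale / rng.gamma(shape)

        # --- node states: two-color vectorised Gibbs ---
        w = 1.0 / (sigma2 * r * t)
        for mask in colors:
            num = np.zeros(N)
            prec = np.zeros(N)
            wx_c = w * x[ec]
            wx_p = w * x[ep]
            np.add.at(num, ep, wx_c)
            np.add.at(num, ec, wx_p)
            np.add.at(prec, ep, w)
            np.add.at(prec, ec, w)
            z = rng.standard_normal(N)
            x[mask] = num[mask] / prec[mask] + z[mask] / np.sqrt(prec[mask])

        if it in keep_set:
            dxk = x[ec] - x[ep]
            log_joint = (
                -0.5 * np.sum(np.log(2 * np.pi * sigma2 * r * t) + dxk**2 / (sigma2 * r * t))
                - (a0 + 1) * math.log(sigma2)
                - b0 / sigma2
            )
            if nu > 0:
                log_joint += -0.5 * float(np.sum(logr**2)) / nu**2
            if not math.isfinite(log_joint):
                raise FloatingPointError(f"non-finite log joint at iteration {it}")
            state_chain[k] = x
            mult_chain[k] = r
            sigma2_chain[k] = sigma2
            k += 1

    assert k == n_keep

    def summarize(chain: np.ndarray):
        mean = chain.mean(axis=0)
        sd = chain.std(axis=0, ddof=1) if len(chain) > 1 else np.zeros(chain.shape[1])
        ci = np.percentile(chain, [2.5, 97.5], axis=0).T
        return mean, sd, ci

    st_mean, st_sd, st_ci = summarize(state_chain)
    # tips are data and never sampled; echo them exactly rather than
    # through the summation round-off of a column mean
    st_mean[tip_mask] = x[tip_mask]
    st_sd[tip_mask] = 0.0
    st_ci[tip_mask, 0] = x[tip_mask]
    st_ci[tip_mask, 1] = x[tip_mask]
    mult_full = np.full((n_keep, N), np.nan)
    mult_full[:, ec] = mult_chain
    mu_mean = np.full(N, np.nan)
    mu_sd = np.full(N, np.nan)
    mu_ci = np.full((N, 2), np.nan)
    mu_mean[ec], mu_sd[ec], mu_ci[ec] = summarize(mult_chain)
    eff_chain = mult_chain * sigma2_chain[:, None]
    ef_mean = np.full(N, np.nan)
    ef_sd = np.full(N, np.nan)
    ef_ci = np.full((N, 2), np.nan)
    ef_mean[ec], ef_sd[ec], ef_ci[ec] = summarize(eff_chain)

    acc_frac = accepts / proposals if proposals else float("nan")
    root_chain = state_chain[:, 0]
    diagnostics = {
        "acceptance_fraction": acc_frac,
        "n_samples": n_keep,
        "ess_root_state": _ess(root_chain),
        "ess_sigma2": _ess(sigma2_chain),
    }
    if proposals and not (0.1 <= acc_frac <= 0.6):
        diagnostics["warning"] = (
            f"multiplier acceptance fraction {acc_frac:.3f} outside [0.1, 0.6]; "
            "consider tuning proposal_sd"
        )

    node_ids = np.array(order)
    parent_ids = np.array(
        [tree.parent(n) if tree.parent(n) is not None else -1 for n in order]
    )
    return MvbmPosterior(
        node_ids=node_ids,
        parent_ids=parent_ids,
        durations=dur,
        is_tip=tip_mask,
        labels=labels,
        state_mean=st_mean,
        state_sd=st_sd,
        state_ci=st_ci,
        rate_mult_mean=mu_mean,
        rate_mult_sd=mu_sd,
        rate_mult_ci=mu_ci,
        eff_rate_mean=ef_mean,
        eff_rate_sd=ef_sd,
        eff_rate_ci=ef_ci,
        sigma2_mean=float(sigma2_chain.mean()),
        sigma2_ci=(
            float(np.percentile(sigma2_chain, 2.5)),
            float(np.percentile(sigma2_chain, 97.5)),
        ),
        state_chain=state_chain,
        rate_mult_chain=mult_full,
        sigma2_chain=sigma2_chain,
        diagnostics=diagnostics,
        config=config,
    )


def posterior_node_table(posterior: MvbmPosterior, tree: TimeTree) -> pd.DataFrame:
    """Per-node summary table keyed by stable node id.

    Columns: label, parent id, branch duration, state posterior summaries
    and (for non-root nodes) rate-multiplier and effective-rate summaries.
    """
    expected = list(tree.preorder())
    if list(posterior.node_ids) != expected:
        raise ValueError("posterior was not computed on this tree (node ids differ)")
    df = pd.DataFrame(
        {
            "node_id": posterior.node_ids,
            "label": [l if l is not None else "" for l in posterior.labels],
            "parent_id": posterior.parent_ids,
            "duration_myr": posterior.durations,
            "is_tip": posterior.is_tip,
            "state_mean": posterior.state_mean,
            "state_sd": posterior.state_sd,
            "state_lo": posterior.state_ci[:, 0],
            "state_hi": posterior.state_ci[:, 1],
            "rate_mult_mean": posterior.rate_mult_mean,
            "rate_mult_sd": posterior.rate_mult_sd,
            "rate_mult_lo": posterior.rate_mult_ci[:, 0],
            "rate_mult_hi": posterior.rate_mult_ci[:, 1],
            "eff_rate_mean": posterior.eff_rate_mean,
            "eff_rate_sd": posterior.eff_rate_sd,
            "eff_rate_lo": posterior.eff_rate_ci[:, 0],
            "eff_rate_hi": posterior.eff_rate_ci[:, 1],
        }
    )
    return df.set_index("node_id")
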