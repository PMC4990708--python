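"""Per-branch signed rates for two traits, RMA fit, and the six
evolutionary tradeoff scenarios.

Each non-root branch gets a signed rate for both traits: the change in
posterior-mean ln state from parent to child, divided by the branch
duration (ln-units / Myr).  The reduced-major-axis line through the
(rate_hw, rate_rap) cloud is the isometry reference; a branch's residual
is its vertical offset from that line.  Sign of each rate and sign of
the residual place the branch in one of six tradeoff scenarios:

  AI       both traits increasing, RAP faster than the RMA line predicts
  DI       both increasing, RAP slower
  SEP_POS  RAP increasing while body size shrinks (or holds)
  DD       both decreasing, RAP more slowly
  AD       both decreasing, RAP faster
  SEP_NEG  RAP decreasing while body size grows (or holds)
  ISO      on the line (within tolerance) or no change at all
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mvbm import MvbmPosterior
from .phylo_io import TimeTree

__all__ = [
    "SCENARIOS",
    "RmaFit",
    "PaintResult",
    "branch_rates",
    "rma_fit",
    "classify_branches",
    "paint_tree",
    "scenario_probabilities",
    "plot_rate_space",
]

SCENARIOS = ("AI", "DI", "SEP_POS", "DD", "AD", "SEP_NEG", "ISO")

DEFAULT_TOLERANCE = 1e-9  # ln-units / Myr; exact ties occur only in fixtures


@dataclass
class RmaFit:
    """Reduced-major-axis line y = slope * x + intercept.

    slope = sign(r) * sd(y) / sd(x); the fit is symmetric in the sense
    slope(x, y) * slope(y, x) = 1 whenever r != 0.
    """

    slope: float
    intercept: float
    r: float
    n: int


def branch_rates(
    posterior_rap: MvbmPosterior, posterior_hw: MvbmPosterior, tree: TimeTree
) -> pd.DataFrame:
    """One row per non-root node: signed ln-state deltas and rates.

    Columns: node_id (index), parent_id, label, duration_myr, delta_rap,
    delta_hw, rate_rap, rate_hw.  Scenario assignment comes later.
    """
    for post in (posterior_rap, posterior_hw):
        if list(post.node_ids) != list(tree.preorder()):
            raise ValueError("posterior and tree node sets do not match")
    rows = []
    pos = {nid: i for i, nid in enumerate(posterior_rap.node_ids)}
    for nid in tree.preorder():
        pid = tree.parent(nid)
        if pid is None:
            continue
        i, j = pos[nid], pos[pid]
        t = tree.duration(nid)
        d_rap = posterior_rap.state_mean[i] - posterior_rap.state_mean[j]
        d_hw = posterior_hw.state_mean[i] - posterior_hw.state_mean[j]
        rows.append(
            {
                "node_id": nid,
                "parent_id": pid,
                "label": tree.node(nid).label or "",
                "duration_myr": t,
                "delta_rap": d_rap,
                "delta_hw": d_hw,
                "rate_rap": d_rap / t,
                "rate_hw": d_hw / t,
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


def branch_rates_from_tables(rap: pd.DataFrame, hw: pd.DataFrame) -> pd.DataFrame:
    """Branch rates from two posterior node tables (as written to disk).

    Both frames must be indexed by node_id with parent_id, duration_myr
    and state_mean columns describing the same tree.
    """
    if not rap.index.equals(hw.index):
        raise ValueError("node tables index different node sets")
    rows = []
    for nid in rap.index:
        pid = int(rap.loc[nid, "parent_id"])
        if pid < 0:
            continue
        t = float(rap.loc[nid, "duration_myr"])
        d_rap = float(rap.loc[nid, "state_mean"] - rap.loc[pid, "state_mean"])
        d_hw = float(hw.loc[nid, "state_mean"] - hw.loc[pid, "state_mean"])
        rows.append(
            {
                "node_id": nid,
                "parent_id": pid,
                "label": rap.loc[nid, "label"] if "label" in rap.columns else "",
                "duration_myr": t,
                "delta_rap": d_rap,
                "delta_hw": d_hw,
                "rate_rap": d_rap / t,
                "rate_hw": d_hw / t,
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


def rma_fit(x: np.ndarray, y: np.ndarray) -> RmaFit:
    """Closed-form reduced-major-axis regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sx = float(np.std(x))
    sy = float(np.std(y))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in x or y: RMA line undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return RmaFit(slope=slope, intercept=intercept, r=r, n=len(x))


def _classify_point(u: float, v: float, resid: float, tol: float) -> str:
    """u = rate_hw (body size), v = rate_rap (lever arm)."""
    if u > 0 and v > 0:
        if resid > tol:
            return "AI"
        if resid < -tol:
            return "DI"
        return "ISO"
    if u <= 0 and v > 0:
        return "SEP_POS"
    if u < 0 and v < 0:
        if resid > tol:
            return "DD"
        if resid < -tol:
            return "AD"
        return "ISO"
    if u >= 0 and v < 0:
        return "SEP_NEG"
    return "ISO"  # v == 0 (including u = v = 0)


def classify_branches(
    records: pd.DataFrame, fit: RmaFit, tolerance: float = DEFAULT_TOLERANCE
) -> pd.DataFrame:
    """Assign one of the six scenarios (plus ISO) to every branch.

    Adds `rma_residual` (vertical offset of rate_rap from the RMA line)
    and `scenario` columns; returns a new frame.
    """
    out = records.copy()
    u = out["rate_hw"].to_numpy()
    v = out["rate_rap"].to_numpy()
    resid = v - (fit.slope * u + fit.intercept)
    out["rma_residual"] = resid
    out["scenario"] = [
        _classify_point(ui, vi, ri, tolerance) for ui, vi, ri in zip(u, v, resid)
    ]
    return out


@dataclass
class PaintResult:
    """Scenario-painted tree plus summary census."""

    newick: str                      # scenario annotated as [&scenario=..]
    census: dict[str, int]           # scenario -> branch count
    ai_run_by_tip: dict[str, int]    # tip label -> contiguous root-ward AI run
    longest_ai_run: tuple[str | None, int]


def paint_tree(tree: TimeTree, records: pd.DataFrame) -> PaintResult:
    """Annotate branches with their scenario and census the labels.

    The AI-run diagnostic counts, for each tip, how many consecutive
    branches are labeled AI walking root-ward starting from the tip's own
    branch — the "continuous accelerated-increase trend" leading to a
    living taxon.
    """
    if "scenario" not in records.columns or records["scenario"].isna().any():
        raise ValueError("records must be classified before painting")
    scen = records["scenario"].to_dict()
    expected = set(tree.preorder()) - {tree.root_id}
    if set(records.index) != expected:
        raise ValueError("records do not cover the tree's branches")

    annotations = {nid: f"scenario={scen[nid]}" for nid in scen}
    newick = tree.to_newick(annotations=annotations)
    census = dict(Counter(records["scenario"]))

    runs: dict[str, int] = {}
    for tid in tree.tips():
        label = tree.node(tid).label
        run = 0
        nid: int | None = tid
        while nid is not None and nid != tree.root_id and scen[nid] == "AI":
            run += 1
            nid = tree.parent(nid)
        runs[label] = run  # type: ignore[index]
    if runs and max(runs.values()) > 0:
        best_tip = min(t for t, n in runs.items() if n == max(runs.values()))
        longest = (best_tip, max(runs.values()))
    else:
        longest = (None, 0)
    return PaintResult(
        newick=newick, census=census, ai_run_by_tip=runs, longest_ai_run=longest
    )


def scenario_probabilities(
    posterior_rap: MvbmPosterior,
    posterior_hw: MvbmPosterior,
    tree: TimeTree,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Per-branch scenario probabilities from paired posterior draws.

    For each retained MCMC sample the branch rates are recomputed, the
    RMA line refit, and every branch classified; the table reports the
    fraction of draws assigning each label.
    """
    for post in (posterior_rap, posterior_hw):
        if list(post.node_ids) != list(tree.preorder()):
            raise ValueError("posterior and tree node sets do not match")
    n_draws = min(len(posterior_rap.state_chain), len(posterior_hw.state_chain))
    order = list(tree.preorder())
    pos = {nid: i for i, nid in enumerate(order)}
    child_ids = [nid for nid in order if tree.parent(nid) is not None]
    ci = np.array([pos[n] for n in child_ids])
    pi = np.array([pos[tree.parent(n)] for n in child_ids])
    t = np.array([tree.duration(n) for n in child_ids])

    counts = {nid: Counter() for nid in child_ids}
    for k in range(n_draws):
        v = (posterior_rap.state_chain[k, ci] - posterior_rap.state_chain[k, pi]) / t
        u = (posterior_hw.state_chain[k, ci] - posterior_hw.state_chain[k, pi]) / t
        try:
            fit = rma_fit(u, v)
        except ValueError:
            continue
        resid = v - (fit.slope * u + fit.intercept)
        for nid, ui, vi, ri in zip(child_ids, u, v, resid):
            counts[nid][_classify_point(ui, vi, ri, tolerance)] += 1
    rows = []
    for nid in child_ids:
        total = sum(counts[nid].values()) or 1
        row = {"node_id": nid}
        row.update({s: counts[nid][s] / total for s in SCENARIOS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("node_id")


def plot_rate_space(records: pd.DataFrame, fit: RmaFit, path: str) -> None:
    """Scatter of the (rate_hw, rate_rap) plane colored by scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "AI": "deeppink",
        "DI": "plum",
        "SEP_POS": "orange",
        "DD": "skyblue",
        "AD": "navy",
        "SEP_NEG": "teal",
        "ISO": "gray",
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for s in SCENARIOS:
        sub = records[records["scenario"] == s]
        if len(sub):
            ax.scatter(sub["rate_hw"], sub["rate_rap"], s=18, label=s, color=colors[s])
    xs = np.linspace(records["rate_hw"].min(), records["rate_hw"].max(), 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, "k--", lw=1, label="RMA")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("head-width rate (ln mm / Myr)")
    ax.set_ylabel("RAP rate (ln mm / Myr)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
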