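"""Ten-stage trajectories of relative lever-arm growth, ontogenetic and
evolutionary, and their comparison.

Both trajectories track the same quantity — the ratio of ln(RAP length)
to ln(head width), both in mm — across ten sequential stages.  For an
ontogenetic series the stages are equal-width bins of ln(HW) between the
sample minimum and maximum (an equal-count option exists); for an
evolutionary series they are node-depth bins along the ancestor chain of
a focal tip, earliest ancestors in stage 1 and the living taxon in stage
10.  An inflection is the interior stage with the largest absolute
second difference of stage means; heterochrony is "inverted" when the
ontogenetic inflection precedes the evolutionary one.

Note the units matter: ln(RAP)/ln(HW) is a quotient of logarithms, so
re-expressing measurements in centimetres changes its level (though not
the inversion pattern).  The package convention is millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageTrajectory",
    "TrajectoryComparison",
    "ontogeny_trajectory",
    "evolution_trajectory",
    "compare_trajectories",
    "plot_trajectories",
]

FLATNESS_THRESHOLD = 1e-6  # max |second difference| below which no inflection


@dataclass
class StageTrajectory:
    """Mean trait-ratio per stage for one series."""

    kind: str                    # "ontogeny" or "evolution"
    n_stages: int
    mean_ratio: np.ndarray       # (n_stages,), nan for empty stages
    n_in_bin: np.ndarray         # (n_stages,) int
    bin_bounds: np.ndarray       # (n_stages, 2); ln(HW) bounds or chain ranks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": np.arange(1, self.n_stages + 1),
                "kind": self.kind,
                "mean_ratio": self.mean_ratio,
                "n_in_bin": self.n_in_bin,
                "bin_lo": self.bin_bounds[:, 0],
                "bin_hi": self.bin_bounds[:, 1],
            }
        )


@dataclass
class TrajectoryComparison:
    """Stage-wise difference and inflection timing of two trajectories."""

    n_stages: int
    ratio_difference: np.ndarray        # evolution - ontogeny, per stage
    inflection_evolution: int | None    # stage 2..n-1, or None if flat
    inflection_ontogeny: int | None
    inversion: bool                     # ontogenetic inflection earlier


def _ratio(ln_rap: np.ndarray, ln_hw: np.ndarray, convention: str) -> np.ndarray:
    if convention == "log-quotient":
        if np.any(ln_hw == 0):
            raise ValueError(
                "ln(HW) = 0 (head width exactly 1 mm): ratio undefined"
            )
        return ln_rap / ln_hw
    if convention == "log-ratio":
        return ln_rap - ln_hw
    raise ValueError(f"unknown ratio convention {convention!r}")


def ontogeny_trajectory(
    series: pd.DataFrame,
    n_stages: int = 10,
    ratio: str = "log-quotient",
    binning: str = "width",
) -> StageTrajectory:
    """Bin an ontogenetic series into body-size stages.

    `series` needs rap_mm and hw_mm columns.  Stages are equal-width
    intervals of ln(HW) spanning the observed range (binning="width"),
    or equal-count quantile bins (binning="count").  The per-stage value
    is the mean of ln(rap)/ln(hw) over specimens in the bin.
    """
    if len(series) == 0:
        raise ValueError("empty ontogeny series")
    ln_hw = np.log(series["hw_mm"].to_numpy(dtype=float))
    ln_rap = np.log(series["rap_mm"].to_numpy(dtype=float))
    ratios = _ratio(ln_rap, ln_hw, ratio)

    lo, hi = float(ln_hw.min()), float(ln_hw.max())
    if binning == "width":
        if hi == lo:
            edges = np.linspace(lo - 0.5, lo + 0.5, n_stages + 1)
        else:
            edges = np.linspace(lo, hi, n_stages + 1)
    elif binning == "count":
        edges = np.quantile(ln_hw, np.linspace(0, 1, n_stages + 1))
    else:
        raise ValueError(f"unknown binning {binning!r}")
    # right-inclusive top bin so the largest specimen lands in stage n
    stage = np.clip(np.searchsorted(edges, ln_hw, side="right") - 1, 0, n_stages - 1)

    mean_ratio = np.full(n_stages, np.nan)
    n_in_bin = np.zeros(n_stages, dtype=int)
    for s in range(n_stages):
        mask = stage == s
        n_in_bin[s] = int(mask.sum())
        if n_in_bin[s]:
            mean_ratio[s] = float(ratios[mask].mean())
    bounds = np.column_stack([edges[:-1], edges[1:]])
    return StageTrajectory("ontogeny", n_stages, mean_ratio, n_in_bin, bounds)


def evolution_trajectory(
    chain_states_rap: np.ndarray,
    chain_states_hw: np.ndarray,
    n_stages: int = 10,
    ratio: str = "log-quotient",
) -> StageTrajectory:
    """Bin an ancestor chain of ln states into node-depth stages.

    Chains are root-first and end at the focal tip.  Entry k of m
    (1-based) maps to stage ceil(n_stages * k / m): the earliest
    ancestors fall in stage 1 and the tip always in stage n_stages.
    """
    rap = np.asarray(chain_states_rap, dtype=float)
    hw = np.asarray(chain_states_hw, dtype=float)
    if len(rap) != len(hw):
        raise ValueError("RAP and HW chains differ in length")
    m = len(rap)
    if m < 2:
        raise ValueError("need at least 2 chain entries")
    ratios = _ratio(rap, hw, ratio)
    ks = np.arange(1, m + 1)
    stage = np.ceil(n_stages * ks / m).astype(int) - 1  # 0-based

    mean_ratio = np.full(n_stages, np.nan)
    n_in_bin = np.zeros(n_stages, dtype=int)
    for s in range(n_stages):
        mask = stage == s
        n_in_bin[s] = int(mask.sum())
        if n_in_bin[s]:
            mean_ratio[s] = float(ratios[mask].mean())
    bounds = np.column_stack(
        [
            [ks[stage == s].min() if (stage == s).any() else np.nan for s in range(n_stages)],
            [ks[stage == s].max() if (stage == s).any() else np.nan for s in range(n_stages)],
        ]
    )
    return StageTrajectory("evolution", n_stages, mean_ratio, n_in_bin, bounds)


def _inflection(traj: StageTrajectory, threshold: float) -> int | None:
    """Interior stage with the largest |second difference| of stage means.

    Ties break to the earliest stage; a maximum below `threshold` means
    the trajectory is flat (or linear) and has no inflection.  Second
    differences are only defined where the stage and both neighbours are
    nonempty.
    """
    y = traj.mean_ratio
    best_stage, best_val = None, -1.0
    for s in range(1, traj.n_stages - 1):
        window = y[s - 1 : s + 2]
        if np.isnan(window).any():
            continue
        d2 = abs(window[2] - 2 * window[1] + window[0])
        if d2 > best_val + 1e-15:
            best_stage, best_val = s + 1, d2  # report 1-based stage
    if best_stage is None or best_val < threshold:
        return None
    return best_stage


def compare_trajectories(
    evo: StageTrajectory,
    onto: StageTrajectory,
    flatness_threshold: float = FLATNESS_THRESHOLD,
) -> TrajectoryComparison:
    """Stage-wise difference, inflection stages, and the inversion flag.

    The inversion flag is True when the ontogenetic inflection falls at
    an earlier stage than the evolutionary one — early developmental
    acceleration mirrored by late evolutionary acceleration.
    """
    if evo.n_stages != onto.n_stages:
        raise ValueError("trajectories have different stage counts")
    for traj in (evo, onto):
        if int((traj.n_in_bin > 0).sum()) < 3:
            raise ValueError(f"{traj.kind} trajectory has fewer than 3 nonempty stages")
    diff = evo.mean_ratio - onto.mean_ratio
    ie = _inflection(evo, flatness_threshold)
    io = _inflection(onto, flatness_threshold)
    inversion = ie is not None and io is not None and io < ie
    return TrajectoryComparison(
        n_stages=evo.n_stages,
        ratio_difference=diff,
        inflection_evolution=ie,
        inflection_ontogeny=io,
        inversion=inversion,
    )


def plot_trajectories(
    onto: StageTrajectory, evo: StageTrajectory, path: str
) -> None:
    """Two-line stage plot: solid ontogeny, dashed evolution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = np.arange(1, onto.n_stages + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(stages, onto.mean_ratio, "-o", color="black", label="ontogeny")
    ax.plot(stages, evo.mean_ratio, "--s", color="gray", label="evolution")
    ax.set_xlabel("stage")
    ax.set_ylabel("mean ln(RAP) / ln(HW)")
    ax.set_xticks(stages)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
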