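"""Synthetic inputs with known truth: Yule time trees, trait data under
(mv)BM, biphasic allometric ontogenies, and ancestor-chain series.

Every generator is a pure function of its parameters and seed.  Defaults
are sized to the study system they emulate: 36-taxon trees (the number
of suchian fossils with complete lever-arm and head-width data) and a
34-specimen *Alligator* developmental series spanning hatchling to large
adult head widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_io import TimeTree

__all__ = [
    "SimTruth",
    "simulate_tree",
    "simulate_mvbm",
    "simulate_ontogeny",
    "simulate_evolution_chain",
]


@dataclass
class SimTruth:
    """Ground truth recorded by a simulation."""

    node_states: dict[int, float] = field(default_factory=dict)
    multipliers: dict[int, float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.node_states)
        return pd.DataFrame(
            {
                "node_id": ids,
                "true_state": [self.node_states[i] for i in ids],
                "true_multiplier": [self.multipliers.get(i, np.nan) for i in ids],
            }
        ).set_index("node_id")


def simulate_tree(
    n_tips: int,
    birth_rate: float = 0.02,
    seed: int = 0,
    fossil_fraction: float = 0.0,
) -> TimeTree:
    """Yule (pure-birth) time tree with `n_tips` terminal taxa.

    Speciation happens at rate `birth_rate` per lineage per Myr; the tree
    is grown until `n_tips` lineages exist, then extended by one final
    exponential waiting time so terminal branches are nonzero.  With
    `fossil_fraction` > 0 that share of tips (rounded) have their
    terminal branch truncated at a uniform random height, producing a
    non-ultrametric tree like a fossil-rich phylogeny.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # protos mutate in place: [label, pending duration, children]
    first: list = [None, 0.0, []]
    second: list = [None, 0.0, []]
    active: list[list] = [first, second]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for lin in active:
            lin[1] += wait
        i = int(rng.integers(len(active)))
        a: list = [None, 0.0, []]
        b: list = [None, 0.0, []]
        active[i][2] = [a, b]
        active.pop(i)
        active.extend([a, b])
    final = rng.exponential(1.0 / (birth_rate * n_tips))
    for lin in active:
        lin[1] += final

    width = len(str(n_tips))
    for k, lin in enumerate(active):
        lin[0] = f"t{k + 1:0{width}d}"

    n_fossil = int(round(fossil_fraction * n_tips))
    if n_fossil:
        chosen = rng.choice(len(active), size=n_fossil, replace=False)
        for i in chosen:
            active[i][1] *= float(rng.uniform(0.05, 0.95))

    root: list = [None, None, [first, second]]
    return TimeTree.from_proto(root)


def simulate_mvbm(
    tree: TimeTree,
    sigma2: float,
    root_state: float,
    multipliers: float | dict[int, float] = 1.0,
    seed: int = 0,
) -> tuple[dict[str, float], SimTruth]:
    """Simulate a trait along the tree under (multiple-variance) BM.

    Each branch adds a Normal(0, sigma2 * r_b * t_b) increment, with the
    branch's multiplier r_b taken from `multipliers` (scalar applied
    everywhere, or a {node_id: r} mapping defaulting to 1).  Returns the
    tip values keyed by label and a :class:`SimTruth` holding every
    node's true state and every branch's multiplier.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if np.isscalar(multipliers):
        mult_map = {
            nid: float(multipliers)  # type: ignore[arg-type]
            for nid in tree.preorder()
            if nid != tree.root_id
        }
    else:
        mult_map = {
            nid: float(multipliers.get(nid, 1.0))  # type: ignore[union-attr]
            for nid in tree.preorder()
            if nid != tree.root_id
        }
    if any(r < 0 for r in mult_map.values()):
        raise ValueError("multipliers must be positive")

    rng = np.random.default_rng(seed)
    states: dict[int, float] = {tree.root_id: float(root_state)}
    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        var = sigma2 * mult_map[nid] * tree.duration(nid)
        parent_state = states[tree.parent(nid)]  # preorder: parent is done
        states[nid] = parent_state + math.sqrt(var) * float(rng.standard_normal())

    tips = {tree.node(t).label: states[t] for t in tree.tips()}
    truth = SimTruth(
        node_states=states,
        multipliers=mult_map,
        parameters={"sigma2": sigma2, "root_state": root_state},
        seed=seed,
    )
    return tips, truth  # type: ignore[return-value]


def simulate_ontogeny(
    n: int = 34,
    hw_range_mm: tuple[float, float] = (20.0, 300.0),
    a1: float = 0.08,
    b1: float = 1.4,
    b2: float = 0.9,
    breakpoint_hw_mm: float = 40.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Biphasic log-log allometric developmental series.

    ln(rap) = ln(a1) + b1 * ln(hw) below the breakpoint, continuing with
    slope b2 above it (continuous at the break); b1 > 1 > b2 encodes
    early positive allometry followed by deceleration.  Specimens are
    placed evenly in ln(HW) across the range — a size-structured sample
    deliberately spanning hatchling to adult — with multiplicative
    (ln-scale additive Normal) noise on RAP only.  Total length is
    back-computed from HW with a fixed proportionality so the series
    carries a plausible 28-364 cm span.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("allometric slopes must be positive")
    lo, hi = hw_range_mm
    if not (lo < breakpoint_hw_mm < hi):
        raise ValueError("breakpoint must lie inside hw_range_mm")
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    rng = np.random.default_rng(seed)

    ln_hw = np.linspace(math.log(lo), math.log(hi), n)
    ln_bp = math.log(breakpoint_hw_mm)
    ln_a1 = math.log(a1)
    ln_rap = np.where(
        ln_hw <= ln_bp,
        ln_a1 + b1 * ln_hw,
        ln_a1 + b1 * ln_bp + b2 * (ln_hw - ln_bp),
    )
    ln_rap = ln_rap + noise_sd * rng.standard_normal(n)

    hw = np.exp(ln_hw)
    # head width is ~1/12 of total length in this size range (mm -> cm)
    total_length_cm = hw * 12.0 / 10.0
    return pd.DataFrame(
        {
            "specimen": [f"s{k + 1:02d}" for k in range(n)],
            "total_length_cm": total_length_cm,
            "rap_mm": np.exp(ln_rap),
            "hw_mm": hw,
        }
    )


def simulate_evolution_chain(
    m: int = 15,
    accel_depth: float = 0.8,
    base_ln_rap: float = 3.0,
    base_ln_hw: float = 4.5,
    hw_drift: float = 0.4,
    rap_jump: float = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestor-chain ln states with a late acceleration in RAP.

    The chain runs root-first with `m` entries.  ln(HW) drifts linearly
    by `hw_drift` over the whole chain; ln(RAP) keeps the ratio
    ln(RAP)/ln(HW) constant for entries at relative depth <= accel_depth
    and then rises linearly so the ratio gains `rap_jump` by the tip —
    conserved relative lever-arm length for most of history, accelerating
    only near the present.
    """
    if m < 2:
        raise ValueError("need m >= 2")
    if not (0.0 < accel_depth < 1.0):
        raise ValueError("accel_depth must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, m + 1)
    rel = ks / m
    ln_hw = base_ln_hw + hw_drift * (ks - 1) / (m - 1)
    base_ratio = base_ln_rap / base_ln_hw
    n_late = int(np.sum(rel > accel_depth))
    ratio = np.full(m, base_ratio)
    if n_late:
        steps = np.arange(1, n_late + 1) / n_late
        ratio[m - n_late :] = base_ratio + rap_jump * steps
    ln_rap = ratio * ln_hw + noise_sd * rng.standard_normal(m)
    return ln_rap, ln_hw
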