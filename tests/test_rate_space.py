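"""Branch rates, RMA fit, scenario classification and tree painting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bitelever import classify_branches, paint_tree, parse_newick, rma_fit
from bitelever.mvbm import MvbmConfig, mvbm_mcmc
from bitelever.rate_space import (
    SCENARIOS,
    RmaFit,
    _classify_point,
    branch_rates,
    branch_rates_from_tables,
)
from bitelever.synthetic import simulate_mvbm, simulate_tree


def _records(points, fit=None):
    """Build a minimal classified-record frame from (u, v) rate points."""
    df = pd.DataFrame(
        {
            "parent_id": 0,
            "duration_myr": 1.0,
            "delta_rap": [v for _, v in points],
            "delta_hw": [u for u, _ in points],
            "rate_rap": [v for _, v in points],
            "rate_hw": [u for u, _ in points],
        },
        index=pd.Index(range(1, len(points) + 1), name="node_id"),
    )
    return df


class TestBranchRates:
    def test_delta_and_rate_arithmetic(self):
        tree = parse_newick("(A:0.5,B:1);")
        config = MvbmConfig(iterations=1000, thin=2, seed=0, rate_prior_sd=0.0)
        post_rap = mvbm_mcmc(tree, {"A": 2.0, "B": 0.0}, config)
        post_hw = mvbm_mcmc(tree, {"A": 1.0, "B": 1.0}, config)
        rec = branch_rates(post_rap, post_hw, tree)
        assert len(rec) == tree.n_nodes - 1
        a = rec.loc[tree.tip_id("A")]
        root_mean = post_rap.state_mean[0]
        assert a["delta_rap"] == pytest.approx(2.0 - root_mean)
        assert a["rate_rap"] == pytest.approx((2.0 - root_mean) / 0.5)
        # HW trait constant: all deltas exactly 0 would need an exact root,
        # but the B branch of RAP: duration 1 means rate == delta
        b = rec.loc[tree.tip_id("B")]
        assert b["rate_rap"] == pytest.approx(b["delta_rap"])

    def test_mismatched_posteriors_rejected(self, cherry, three_tip):
        config = MvbmConfig(iterations=500, thin=1, seed=1)
        p2 = mvbm_mcmc(cherry, {"A": 0.0, "B": 1.0}, config)
        with pytest.raises(ValueError):
            branch_rates(p2, p2, three_tip)

    def test_from_tables_matches_inmemory(self):
        from bitelever.mvbm import posterior_node_table

        tree = simulate_tree(8, seed=2)
        ta, _ = simulate_mvbm(tree, 0.2, 0.0, seed=3)
        tb, _ = simulate_mvbm(tree, 0.2, 0.0, seed=4)
        config = MvbmConfig(iterations=2000, thin=4, seed=5)
        pa = mvbm_mcmc(tree, ta, config)
        pb = mvbm_mcmc(tree, tb, config)
        direct = branch_rates(pa, pb, tree)
        via_tables = branch_rates_from_tables(
            posterior_node_table(pa, tree), posterior_node_table(pb, tree)
        )
        pd.testing.assert_frame_equal(
            direct[["rate_rap", "rate_hw"]], via_tables[["rate_rap", "rate_hw"]]
        )


class TestRma:
    def test_identity_line(self):
        fit = rma_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        fit = rma_fit([0, 1, 2, 3], [1, 3, 4, 8])
        assert fit.slope == pytest.approx(math.sqrt(26 / 5), abs=1e-10)
        assert fit.intercept == pytest.approx(4 - math.sqrt(26 / 5) * 1.5, abs=1e-10)

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            rma_fit([1, 1, 1], [0, 1, 2])

    def test_negative_correlation_gives_negative_slope(self):
        fit = rma_fit([0, 1, 2, 3], [3, 2.5, 1, 0])
        assert fit.slope < 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_slope_symmetry(self, seed):
        """slope(x, y) * slope(y, x) = 1 whenever r != 0."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        assert rma_fit(x, y).slope * rma_fit(y, x).slope == pytest.approx(1.0)


SEVEN_POINTS = [
    ((0.2, 0.9), "AI"),
    ((0.5, 0.2), "DI"),
    ((-0.3, 0.4), "SEP_POS"),
    ((-0.8, -0.2), "DD"),
    ((-0.2, -0.9), "AD"),
    ((0.3, -0.4), "SEP_NEG"),
    ((0.4, 0.4), "ISO"),  # placed exactly on the unit line
]


class TestClassification:
    def test_seven_point_fixture(self):
        """One point per scenario, classified against the identity line."""
        fit = RmaFit(slope=1.0, intercept=0.0, r=1.0, n=7)
        records = _records([p for p, _ in SEVEN_POINTS])
        out = classify_branches(records, fit, tolerance=1e-9)
        assert list(out["scenario"]) == [label for _, label in SEVEN_POINTS]

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for u, v in rng.normal(size=(500, 2)):
            resid = v - u
            label = _classify_point(u, v, resid, 1e-9)
            assert label in SCENARIOS

    def test_negation_antisymmetry(self):
        """Negating both rate vectors (and refitting) swaps AI/AD, DI/DD,
        SEP_POS/SEP_NEG and fixes ISO."""
        swap = {"AI": "AD", "AD": "AI", "DI": "DD", "DD": "DI",
                "SEP_POS": "SEP_NEG", "SEP_NEG": "SEP_POS", "ISO": "ISO"}
        rng = np.random.default_rng(1)
        u = rng.normal(size=1000)
        v = 0.8 * u + rng.normal(size=1000)
        fit = rma_fit(u, v)
        fit_neg = rma_fit(-u, -v)
        for ui, vi in zip(u, v):
            a = _classify_point(ui, vi, vi - (fit.slope * ui + fit.intercept), 1e-9)
            b = _classify_point(
                -ui, -vi, -vi - (fit_neg.slope * -ui + fit_neg.intercept), 1e-9
            )
            assert b == swap[a]


class TestPaint:
    def _classified(self, tree, labels):
        records = _records([(0.1, 0.1)] * (tree.n_nodes - 1))
        records.index = pd.Index(
            [n for n in tree.preorder() if n != tree.root_id], name="node_id"
        )
        records["scenario"] = [labels[n] for n in records.index]
        return records

    def test_all_iso_census(self, balanced_four):
        labels = {n: "ISO" for n in balanced_four.preorder()
                  if n != balanced_four.root_id}
        res = paint_tree(balanced_four, self._classified(balanced_four, labels))
        assert res.census == {"ISO": balanced_four.n_nodes - 1}
        assert res.longest_ai_run == (None, 0)

    def test_ai_run_along_chain(self, caterpillar_five):
        from bitelever import ancestor_chain

        tree = caterpillar_five
        chain = ancestor_chain(tree, "A")  # root + 3 internals + tip
        labels = {n: "ISO" for n in tree.preorder() if n != tree.root_id}
        for n in chain[1:]:  # all 4 branches on the path to A
            labels[n] = "AI"
        res = paint_tree(tree, self._classified(tree, labels))
        assert res.ai_run_by_tip["A"] == 4
        assert res.longest_ai_run == ("A", 4)
        assert "scenario=AI" in res.newick

    def test_census_conserves_branches(self, caterpillar_five):
        tree = caterpillar_five
        rng = np.random.default_rng(3)
        labels = {
            n: SCENARIOS[rng.integers(len(SCENARIOS))]
            for n in tree.preorder() if n != tree.root_id
        }
        res = paint_tree(tree, self._classified(tree, labels))
        assert sum(res.census.values()) == tree.n_nodes - 1

    def test_unclassified_rejected(self, balanced_four):
        records = _records([(0.1, 0.1)] * (balanced_four.n_nodes - 1))
        records.index = pd.Index(
            [n for n in balanced_four.preorder() if n != balanced_four.root_id],
            name="node_id",
        )
        with pytest.raises(ValueError, match="classified"):
            paint_tree(balanced_four, records)


class TestEnrichment:
    def test_fast_rap_lineage_is_ai_enriched(self):
        """Accelerated directional RAP increase (with mild HW increase)
        along one tip's ancestor chain enriches that chain for AI labels.

        A pure variance multiplier cannot do this — its increments have
        random sign — so the lineage effect is simulated as positive
        jumps on the chain branches on top of BM noise."""
        from bitelever import ancestor_chain

        tree = simulate_tree(36, seed=60, fossil_fraction=0.3)
        tip = tree.tip_labels[0]
        chain = ancestor_chain(tree, tip)
        chain_branches = set(chain[1:])
        rap, _ = simulate_mvbm(tree, 0.02, 3.0, seed=61)
        hw, _ = simulate_mvbm(tree, 0.02, 4.5, seed=62)
        # every tip descending from a chain branch inherits its jump;
        # jumps scale with branch duration so they are true rate shifts
        # well above the BM rate noise sd(sqrt(sigma2 / t))
        for branch in chain_branches:
            below = {branch}
            stack = [branch]
            while stack:
                for c in tree.children(stack.pop()):
                    below.add(c)
                    stack.append(c)
            t_b = tree.duration(branch)
            for t in tree.tips():
                if t in below:
                    lab = tree.node(t).label
                    rap[lab] += 0.10 * t_b
                    hw[lab] += 0.04 * t_b
        config = MvbmConfig(iterations=20_000, thin=10, seed=63)
        post_rap = mvbm_mcmc(tree, rap, config)
        post_hw = mvbm_mcmc(tree, hw, MvbmConfig(iterations=20_000, thin=10, seed=64))
        rec = branch_rates(post_rap, post_hw, tree)
        fit = rma_fit(rec["rate_hw"].to_numpy(), rec["rate_rap"].to_numpy())
        rec = classify_branches(rec, fit)
        on_chain = rec.loc[sorted(chain_branches)]
        off_chain = rec.drop(index=sorted(chain_branches))
        frac_on = (on_chain["scenario"] == "AI").mean()
        frac_off = (off_chain["scenario"] == "AI").mean()
        assert frac_on > frac_off
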