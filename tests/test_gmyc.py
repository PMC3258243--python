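import dataclasses
import math

import numpy as np
import pytest

import barcodelim as bl
from barcodelim.gmyc import (
    _candidate_arrays,
    _fit_null,
    _optimize_candidate,
    branching_schedule,
)


class TestBranchingSchedule:
    def test_three_tip_example(self, toy_tree):
        sch = branching_schedule(toy_tree)
        np.testing.assert_allclose(sch.ages, [2.0, 1.0])
        np.testing.assert_allclose(sch.x, [1.0, 1.0])
        assert sch.x.sum() == pytest.approx(sch.root_age)

    def test_tied_ages_get_distinct_jitter(self):
        tree = bl.read_newick_string("((a:1,b:1):2,(c:1,d:1):2);")
        sch = branching_schedule(tree)
        assert len(np.unique(sch.ages)) == 3
        assert np.all(np.diff(sch.ages) < 0)

    def test_lineage_bookkeeping_counts(self):
        tree, _ = bl.simulate_gmyc_tree(8, 3, 1.0, 0.02, seed=2)
        sch = branching_schedule(tree)
        # k-th interval has k+1 lineages: total events = tips - 1
        assert sch.n_events == tree.n_tips - 1
        assert sch.x.sum() == pytest.approx(sch.root_age)
        # parent events are strictly older
        for k in range(1, sch.n_events):
            assert sch.parent[k] < k

    def test_too_few_tips_rejected(self):
        tree = bl.read_newick_string("(a:1,b:1);")
        with pytest.raises(bl.ValidationError):
            branching_schedule(tree)


def reference_loglik(tree, threshold, lam1, p1, lam2, p2):
    """Independent likelihood evaluation by explicit tree traversal.

    Walks the intervals between successive node ages, counting for each
    interval the lineages that originate above the threshold and, for every
    crossing lineage, the lineages of its subtree, with no shared code with
    the production implementation.
    """
    nodes = sorted(
        tree.tree.preorder_internal_node_iter(), key=lambda n: -n.age
    )
    ages = [n.age for n in nodes] + [0.0]

    def crossing_ancestor(node):
        anc = node
        while anc.parent_node is not None and anc.parent_node.age < threshold:
            anc = anc.parent_node
        return anc

    lnl = 0.0
    for i in range(len(nodes)):
        top, bottom = ages[i], ages[i + 1]
        mid = (top + bottom) / 2
        # lineages alive at time mid = edges spanning mid
        alive = [
            n
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
            and n.parent_node.age > mid >= n.age
        ]
        # Species (diversification) lineages: crossing edges still unbranched
        # below the threshold, plus one per crossing lineage whose subtree
        # has already started branching -- the species persists while its
        # gene copies coalesce.
        unbranched = sum(1 for n in alive if n.parent_node.age > threshold)
        ent: dict[int, int] = {}
        for n in alive:
            if n.parent_node.age <= threshold:
                key = id(crossing_ancestor(n))
                ent[key] = ent.get(key, 0) + 1
        n_div = unbranched + len(ent)
        s = sum((c * (c - 1)) ** p2 for c in ent.values())
        b = lam1 * n_div**p1 + lam2 * s
        lnl += math.log(b) - b * (top - bottom)
    return lnl


class TestLoglik:
    def test_two_interval_hand_value(self, toy_tree):
        sch = branching_schedule(toy_tree)
        # interval 1: 2 diversification lineages, rate 2, wait 1;
        # interval 2: 2 crossing lineages, one entity of 2, rate 2+2=4, wait 1
        expected = (math.log(2) - 2.0) + (math.log(4) - 4.0)
        assert bl.gmyc_loglik(sch, 1.5, 1, 1, 1, 1) == pytest.approx(expected)

    def test_threshold_above_root_reduces_to_single_process(self, toy_tree):
        sch = branching_schedule(toy_tree)
        lam2, p2 = 0.7, 1.3
        val = bl.gmyc_loglik(sch, 5.0, 1e-12, 1.0, lam2, p2)
        n = np.array([2.0, 3.0])
        b = lam2 * (n * (n - 1)) ** p2
        expected = float(np.sum(np.log(b)) - np.dot(b, sch.x))
        assert val == pytest.approx(expected, rel=1e-6)

    def test_invariant_under_tip_relabeling(self):
        t1 = bl.read_newick_string("((a:0.1,b:0.1):1.9,(c:0.2,d:0.2):1.8);")
        t2 = bl.read_newick_string("((d:0.1,c:0.1):1.9,(b:0.2,a:0.2):1.8);")
        for thr in (0.15, 0.5, 1.85):
            assert bl.gmyc_loglik(
                branching_schedule(t1), thr, 1.0, 1.0, 2.0, 1.0
            ) == pytest.approx(
                bl.gmyc_loglik(branching_schedule(t2), thr, 1.0, 1.0, 2.0, 1.0)
            )

    def test_matches_independent_traversal_oracle(self):
        tree, _ = bl.simulate_gmyc_tree(4, 3, 1.0, 0.05, seed=9)
        sch = branching_schedule(tree)
        ages = sch.ages
        rng = np.random.default_rng(0)
        for _ in range(12):
            thr = float(rng.uniform(1e-3, ages[0] * 0.99))
            lam1, lam2 = rng.uniform(0.2, 3, size=2)
            p1, p2 = rng.uniform(0.2, 2, size=2)
            got = bl.gmyc_loglik(sch, thr, lam1, p1, lam2, p2)
            want = reference_loglik(tree, thr, lam1, p1, lam2, p2)
            assert got == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize(
        "override",
        [
            {"threshold_age": -1.0},
            {"lam1": 0.0},
            {"lam2": -2.0},
            {"p1": 11.0},
            {"p2": -0.5},
        ],
    )
    def test_domain_errors(self, toy_tree, override):
        sch = branching_schedule(toy_tree)
        params = {"threshold_age": 1.0, "lam1": 1.0, "p1": 1.0,
                  "lam2": 1.0, "p2": 1.0}
        params.update(override)
        with pytest.raises(ValueError):
            bl.gmyc_loglik(sch, **params)


@pytest.fixture(scope="module")
def fitted():
    tree, truth = bl.simulate_gmyc_tree(12, 4, 1.0, 0.02, seed=4)
    return bl.gmyc_fit(tree), truth


class TestFit:
    def test_recovers_species_partition(self, fitted):
        result, truth = fitted
        assert result.n_entities == 12
        assert (
            result.entities.relabel_canonical().assignment
            == truth.relabel_canonical().assignment
        )

    def test_nesting_and_confidence_set(self, fitted):
        result, _ = fitted
        assert result.lnl_max >= result.lnl_null
        lo, hi = result.entity_ci
        assert lo <= result.n_entities <= hi
        assert result.n_singletons <= result.n_entities

    def test_profile_covers_all_candidates(self, fitted):
        result, _ = fitted
        # E - 1 midpoints plus the null configuration
        assert len(result.profile) == 12 * 4 - 1 - 1 + 1
        assert result.profile.n_entities.min() == 1

    def test_entities_form_valid_partition(self, fitted):
        result, truth = fitted
        assert result.entities.specimen_ids() == truth.specimen_ids()
        assert all(result.entities.groups().values())

    def test_significant_structure_detected(self, fitted):
        result, _ = fitted
        assert result.p_value < 0.05
        # df=3 reference is the more conservative of the two conventions
        assert result.p_value >= result.p_value_df2

    def test_parameter_recovery_on_model_simulated_waits(self):
        """Waiting times redrawn from the model at known rates are fit back
        to within a factor of two (large schedule, fixed seed)."""
        tree, _ = bl.simulate_gmyc_tree(40, 4, 1.0, 0.02, seed=7)
        sch = branching_schedule(tree)
        m = 39  # true threshold configuration: all species events above
        lam1_true, lam2_true = 1.0, 25.0
        ndiv, old_c, new_c = _candidate_arrays(sch, m)
        s = np.cumsum(np.where(new_c > 0, new_c, 0) - np.where(old_c > 0, old_c, 0))
        b = lam1_true * ndiv + lam2_true * s
        rng = np.random.default_rng(3)
        sch2 = dataclasses.replace(sch, x=rng.exponential(1.0 / b))
        _, theta = _optimize_candidate(sch2, m)
        lam1, p1, lam2, p2 = np.exp(theta[0]), theta[1], np.exp(theta[2]), theta[3]
        assert 0.5 <= lam1 / lam1_true <= 2.0
        assert 0.5 <= lam2 / lam2_true <= 2.0
        assert abs(p1 - 1.0) < 0.75 and abs(p2 - 1.0) < 0.75

    def test_null_fit_matches_grid(self, toy_tree):
        lnl, lam, p = _fit_null(branching_schedule(toy_tree))
        grid = max(
            bl.gmyc_loglik(branching_schedule(toy_tree), 5.0, 1e-12, 1.0, la, pp)
            for la in np.geomspace(0.01, 10, 60)
            for pp in np.linspace(0.0, 3, 40)
        )
        assert lnl >= grid - 1e-3


class TestExpandEntities:
    def test_empty_collapse_is_identity(self, toy_tree):
        result = _fake_result(bl.Partition({"a": "a", "b": "a", "c": "c"}, "gmyc"))
        coll = bl.HaplotypeCollapse(kept_ids=("a", "b", "c"), removed={})
        assert bl.expand_entities(result, coll).assignment == result.entities.assignment

    def test_removed_specimen_joins_representative(self, toy_tree):
        result = _fake_result(bl.Partition({"a": "a", "c": "c"}, "gmyc"))
        coll = bl.HaplotypeCollapse(kept_ids=("a", "c"), removed={"a": ("b",)})
        out = bl.expand_entities(result, coll)
        assert out.assignment["b"] == "a"
        assert out.n_groups == result.entities.n_groups

    def test_missing_representative_is_error(self, toy_tree):
        result = _fake_result(bl.Partition({"a": "a"}, "gmyc"))
        coll = bl.HaplotypeCollapse(kept_ids=("z",), removed={"z": ("b",)})
        with pytest.raises(bl.ValidationError):
            bl.expand_entities(result, coll)


def _fake_result(entities: bl.Partition) -> bl.GMYCResult:
    import pandas as pd

    return bl.GMYCResult(
        threshold_age=1.0, lambda1=1.0, p1=1.0, lambda2=1.0, p2=1.0,
        lnl_max=0.0, lnl_null=0.0, lr=0.0, p_value=1.0, p_value_df2=1.0,
        entities=entities, n_entities=entities.n_groups,
        n_singletons=0, entity_ci=(1, 1), profile=pd.DataFrame(),
    )
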