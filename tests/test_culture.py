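import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sociont.config import override, preset
from sociont.culture import (ExpressionTally, boost_factor,
                             express_traditions, complexity, invent,
                             resolve_institutions, social_learning_step)

from conftest import bare_world, manual_community


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive claim-allocation search.
# A performance may claim a downward-closed subset of its tree's components
# (parent before child), each component expression claimed at most
# tally[component] times in total.  The oracle enumerates all joint
# allocations to find (a) the greedy outcome under every processing order
# and (b) the allocation maximizing total realized complexity.


def _closed_subsets(comps, parent):
    """All subsets of components closed under 'parent present'."""
    out = []
    for r in range(len(comps) + 1):
        for sub in itertools.combinations(comps, r):
            s = set(sub)
            if all(parent[c] not in comps or parent[c] in s for c in s):
                out.append(s)
    return out


def greedy_sequential(tally, comps, parent, order):
    """Literal sequential greedy: each performance claims top-down, one
    expression per reachable component, availability permitting."""
    avail = dict(tally)
    results = []
    for _ in order:
        claimed = set()
        for c in comps:   # comps listed parents-first
            parent_ok = parent[c] not in comps or parent[c] in claimed
            if parent_ok and avail.get(c, 0) > 0:
                avail[c] -= 1
                claimed.add(c)
        results.append(1 + len(claimed))
    return sorted(results)


def optimal_allocation(tally, comps, parent, n_perf):
    """Exhaustive search over joint feasible allocations, maximizing total
    realized complexity."""
    subsets = _closed_subsets(comps, parent)
    best = 0
    for combo in itertools.product(subsets, repeat=n_perf):
        usage = {}
        for s in combo:
            for c in s:
                usage[c] = usage.get(c, 0) + 1
        if all(usage.get(c, 0) <= tally.get(c, 0) for c in comps):
            best = max(best, n_perf + sum(len(s) for s in combo))
    return best


def build_tree(world, shape):
    """shape: list of parent indices (-1 = apex) in addition order."""
    igut = world.registry.apex_by_target["igut"]
    slots = []
    for p in shape:
        parent_slot = igut if p == -1 else slots[p]
        slots.append(world.registry.add_component(parent_slot, 0))
    return igut, slots


def run_resolver(world, com, tally_spec, igut):
    counts = np.zeros(world.registry.width, dtype=np.int32)
    for slot, c in tally_spec.items():
        counts[slot] = c
    # attribute apex expressions to the first agents
    alleles = np.zeros((com.n, world.registry.width), dtype=bool)
    alleles[:counts[igut], igut] = True
    tally = ExpressionTally(counts, alleles)
    perfs = resolve_institutions(tally, world.registry, com, world.rng)
    if igut not in perfs:
        return []
    _, realized, full = perfs[igut]
    return sorted(int(r) for r in realized), full


class TestResolution:
    def _world(self, n=6):
        cfg = override(preset("BASE"), grid_size=(24, 24))
        w = bare_world(cfg)
        com = manual_community(w, ages=[20] * n)
        return w, com

    def test_lone_apex_always_full(self):
        w, com = self._world()
        igut = w.registry.apex_by_target["igut"]
        realized, full = run_resolver(w, com, {igut: 1}, igut)
        assert realized == [1] and full.all()

    def test_two_sibling_components_split_claims(self):
        # two apex expressions over components c1 (1 expr) and c2 (2 exprs):
        # realized multiset must be {3, 2} whatever the order
        w, com = self._world()
        igut, (c1, c2) = self._two_siblings(w)
        realized, _ = run_resolver(w, com, {igut: 2, c1: 1, c2: 2}, igut)
        assert realized == [2, 3]

    def _two_siblings(self, w):
        igut, slots = build_tree(w, [-1, -1])
        return igut, slots

    def test_chain_requires_parent_claimed(self):
        # c2 below c1; c1 unexpressed -> c2 unreachable
        w, com = self._world()
        igut, (c1, c2) = build_tree(w, [-1, 0])
        realized, full = run_resolver(w, com, {igut: 1, c2: 1}, igut)
        assert realized == [1]
        assert not full.all()   # c2 is present in community but unclaimed

    def test_complexity_is_locus_count(self):
        w, _ = self._world()
        igut, slots = build_tree(w, [-1, 0])
        assert complexity(w.registry, igut) == 3
        basic = w.registry.apex_by_target["basic"]
        assert complexity(w.registry, basic) == 1

    @pytest.mark.parametrize("shape,counts", [
        ([-1, -1], (2, 1, 2)),
        ([-1, 0], (2, 1, 2)),
        ([-1, -1, 0], (3, 2, 1, 2)),
        ([-1, 0, 1], (3, 2, 2, 1)),
        ([-1, -1, -1], (2, 1, 1, 3)),
    ])
    def test_greedy_matches_sequential_oracle_all_orders(self, shape, counts):
        """The closed-form resolver equals the literal sequential greedy
        under every processing order, and stays within the oracle optimum."""
        w, com = self._world()
        igut, slots = build_tree(w, shape)
        n_a = counts[0]
        tally_spec = {igut: n_a}
        tally_spec.update({s: c for s, c in zip(slots, counts[1:])})
        realized, _ = run_resolver(w, com, tally_spec, igut)

        parent = {}
        for s, p in zip(slots, shape):
            parent[s] = igut if p == -1 else slots[p]
        tally_d = {s: c for s, c in zip(slots, counts[1:])}
        expected = greedy_sequential(tally_d, slots, parent, range(n_a))
        assert realized == expected
        opt = optimal_allocation(tally_d, slots, parent, n_a)
        assert sum(realized) <= opt
        assert sum(realized) >= 0.9 * opt

    def test_tally_conservation(self):
        w, com = self._world()
        igut, slots = build_tree(w, [-1, 0, 0])
        counts = np.zeros(w.registry.width, dtype=np.int32)
        counts[igut] = 3
        for s, c in zip(slots, (2, 1, 4)):
            counts[s] = c
        alleles = np.zeros((com.n, w.registry.width), dtype=bool)
        alleles[:3, igut] = True
        tally = ExpressionTally(counts.copy(), alleles)
        resolve_institutions(tally, w.registry, com, w.rng)
        claimed = com.last_claimed
        assert np.all(claimed <= counts)
        # initial = remaining + claimed, with remaining = counts - claimed
        assert np.all((counts - claimed) + claimed == counts)
        assert np.all(claimed >= 0)


class TestExpression:
    def _setup(self, allele_sets):
        cfg = override(preset("BASE"), grid_size=(24, 24))
        w = bare_world(cfg)
        igut = w.registry.apex_by_target["igut"]
        a = w.registry.add_component(igut, 0)
        b = w.registry.add_component(a, 0)
        names = {"A": a, "B": b}
        com = manual_community(w, ages=[20] * len(allele_sets))
        com.ensure_width(w.registry.width)
        for i, held in enumerate(allele_sets):
            for nm in held:
                com.alleles_view[i, names[nm]] = True
        return w, com, names

    def test_tally_counts_every_allele_once(self):
        w, com, names = self._setup([{"A"}, {"A", "B"}, set()])
        tally = express_traditions(com, w.cfg)
        assert tally.counts[names["A"]] == 2
        assert tally.counts[names["B"]] == 1

    def test_empty_community_empty_tally(self):
        w, com, _ = self._setup([set(), set()])
        tally = express_traditions(com, w.cfg)
        assert tally.total == 0

    def test_expression_cost_conservation(self):
        # 3 agents x 2 alleles each at cost c -> total debit 6c
        w, com, _ = self._setup([{"A", "B"}] * 3)
        before = com.energy.sum()
        express_traditions(com, w.cfg)
        debit = before - com.energy.sum()
        assert debit == pytest.approx(6 * w.cfg.allele_expression_cost)

    def test_counter_matches_attribution(self):
        w, com, names = self._setup([{"A"}, {"A", "B"}, {"B"}])
        tally = express_traditions(com, w.cfg)
        for slot in (names["A"], names["B"]):
            assert tally.counts[slot] == len(tally.expressers(slot))


class TestSocialLearning:
    def _single_locus_world(self, n_carriers, n_naive, slr):
        # one observation per agent per update: the per-opportunity contract
        cfg = override(preset("BASE"), grid_size=(24, 24), slr=slr,
                       observation_rate=1.0, conformity_exponent=0.0)
        w = bare_world(cfg, targets=("igut",))
        igut = w.registry.apex_by_target["igut"]
        com = manual_community(w, ages=[20] * (n_carriers + n_naive))
        com.ensure_width(w.registry.width)
        com.alleles_view[:n_carriers, igut] = True
        return w, com, igut

    def test_zero_rate_never_learns(self):
        w, com, igut = self._single_locus_world(3, 3, slr=0)
        for _ in range(50):
            tally = express_traditions(com, w.cfg)
            ops, succ, _ = social_learning_step(tally, com, {}, w.cfg,
                                                w.registry, w.rng)
            assert succ == 0

    def test_holder_never_a_candidate(self):
        w, com, igut = self._single_locus_world(4, 0, slr=999)
        tally = express_traditions(com, w.cfg)
        ops, succ, _ = social_learning_step(tally, com, {}, w.cfg,
                                            w.registry, w.rng)
        assert ops == 0 and succ == 0

    def test_binomial_complement_probability(self):
        """One naive observer of a universally expressed single locus has
        per-update success p, so P(learned within 3 updates) =
        1-(1-p)^3 = 0.142625 at p = 0.05."""
        n_rep = 4000
        hits = 0
        for rep in range(n_rep):
            w, com, igut = self._single_locus_world(3, 1, slr=50)
            w.rng = np.random.default_rng(1000 + rep)
            learned = False
            for _ in range(3):
                tally = express_traditions(com, w.cfg)
                _, succ, _ = social_learning_step(tally, com, {}, w.cfg,
                                                  w.registry, w.rng)
                if succ:
                    learned = True
                    break
            hits += learned
        p_expected = 0.142625
        sd = np.sqrt(p_expected * (1 - p_expected) / n_rep)
        assert abs(hits / n_rep - p_expected) < 3 * sd

    def test_monotone_in_slr_common_random_numbers(self):
        counts = []
        for slr in (10, 40, 160):
            w, com, igut = self._single_locus_world(6, 12, slr=slr)
            w.rng = np.random.default_rng(77)
            tally = express_traditions(com, w.cfg)
            _, succ, _ = social_learning_step(tally, com, {}, w.cfg,
                                              w.registry, w.rng)
            counts.append(succ)
        assert counts[0] <= counts[1] <= counts[2]

    def test_at_most_one_allele_per_locus(self):
        w, com, igut = self._single_locus_world(2, 10, slr=900)
        for _ in range(30):
            tally = express_traditions(com, w.cfg)
            social_learning_step(tally, com, {}, w.cfg, w.registry, w.rng)
        assert com.alleles_view[:, igut].dtype == bool
        assert com.alleles_view.sum() <= com.n * w.registry.width


class TestBoostFactor:
    def _cfg(self, **kw):
        return override(preset("COEVO_BOOST"), **kw)

    def test_no_boost_without_performance(self):
        assert boost_factor(None, 10.0, self._cfg()) == 1.0

    def test_direct_evaluation(self):
        # multiplier grows with institutional depth beyond the apex
        cfg = self._cfg(boost_coefficient=0.1, genetics_enabled=True)
        assert boost_factor(4, 10.0, cfg) == pytest.approx(1.3)

    def test_lone_apex_confers_nothing(self):
        cfg = self._cfg(boost_coefficient=0.1)
        assert boost_factor(1, 10.0, cfg) == pytest.approx(1.0)

    def test_capacity_cap_binds(self):
        cfg = self._cfg(boost_coefficient=0.1, genetics_enabled=True)
        assert boost_factor(4, 2.0, cfg) == pytest.approx(1.1)

    def test_uncapped_without_genetics(self):
        cfg = self._cfg(boost_coefficient=0.1)
        assert boost_factor(12, 2.0, cfg) == pytest.approx(2.1)

    def test_decoupled_capacity_has_no_effect(self):
        cfg = self._cfg(boost_coefficient=0.1, genetics_enabled=True,
                        cognition_decoupled=True)
        assert boost_factor(12, 2.0, cfg) == pytest.approx(2.1)


class TestInvention:
    def _world(self, n=12, rate=1.0):
        cfg = override(preset("BASE"), grid_size=(24, 24),
                       invention_rate=rate)
        w = bare_world(cfg)
        com = manual_community(w, ages=[20] * n)
        com.ensure_width(w.registry.width)
        return w, com

    def test_zero_rate_no_inventions(self):
        w, com = self._world(rate=0.0)
        assert invent(com, w.registry, w.cfg, w.rng, 1) == []

    def test_apex_holder_extends_own_tree(self):
        w, com = self._world(n=1, rate=1.0)
        igut = w.registry.apex_by_target["igut"]
        com.alleles_view[0, igut] = True
        events = invent(com, w.registry, w.cfg, w.rng, 1)
        assert len(events) == 1
        _, slot = events[0]
        assert w.registry.loci[slot].kind == "component"
        assert w.registry.apex_root[slot] == igut
        assert complexity(w.registry, igut) == 2
        assert com.alleles_view[0, slot]

    def test_naive_agent_acquires_apex(self):
        w, com = self._world(n=1, rate=1.0)
        events = invent(com, w.registry, w.cfg, w.rng, 1)
        _, slot = events[0]
        assert w.registry.loci[slot].kind == "apex"
        assert com.alleles_view[0, slot]

    def test_binomial_mean_rate(self):
        n, rate, reps = 300, 0.05, 40
        total = 0
        for rep in range(reps):
            w, com = self._world(n=n, rate=rate)
            w.rng = np.random.default_rng(rep)
            total += len(invent(com, w.registry, w.cfg, w.rng, 1))
        mean = total / reps
        sd = np.sqrt(n * rate * (1 - rate) / reps)
        assert abs(mean - n * rate) < 3 * sd


@settings(max_examples=40, deadline=None)
@given(counts=st.lists(st.integers(0, 4), min_size=1, max_size=4),
       n_a=st.integers(1, 3),
       data=st.data())
def test_resolution_matches_oracle_property(counts, n_a, data):
    """Randomized chains/stars: closed-form resolver equals the literal
    sequential greedy for every instance."""
    cfg = override(preset("BASE"), grid_size=(24, 24))
    w = bare_world(cfg)
    shape = [data.draw(st.sampled_from([-1] + list(range(i)) if i else [-1]),
                       label=f"parent{i}") for i in range(len(counts))]
    igut, slots = build_tree(w, shape)
    com = manual_community(w, ages=[20] * max(n_a, 1))
    com.ensure_width(w.registry.width)
    tally_spec = {igut: n_a}
    tally_spec.update({s: c for s, c in zip(slots, counts)})
    realized, _ = run_resolver(w, com, tally_spec, igut)
    parent = {}
    for s, p in zip(slots, shape):
        parent[s] = igut if p == -1 else slots[p]
    tally_d = {s: c for s, c in zip(slots, counts)}
    expected = greedy_sequential(tally_d, slots, parent, range(n_a))
    assert realized == expected
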