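"""Trajectories, interpolation, lineage nesting, Muller decomposition and
the cross-host Mantel comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gutevolve.io_formats import IsolateRecord
from gutevolve.lineage_dynamics import (FOUNDER, Lineage, LineageTree,
                                        TrajectorySeries,
                                        compare_host_dynamics,
                                        interpolate_trajectory, mantel_test,
                                        muller_decompose, nest_lineages,
                                        snp_frequencies)
from gutevolve.variant_core import (AMBIGUOUS, DERIVED, GenotypeMatrix,
                                    SnpRecord)


def _snp(j):
    return SnpRecord(snp_id=f"s{j}", replicon_id="chr", pos=10 * (j + 1),
                     ref_allele="A", alt_allele="G", mutation_class="A:T>G:C")


def _gm(calls, isolates):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(isolates=isolates,
                          snps=[_snp(j) for j in range(calls.shape[1])],
                          calls=calls)


class TestSnpFrequencies:
    def _meta(self, days):
        return [IsolateRecord(f"i{k}", "human", "h1", d)
                for k, d in enumerate(days)]

    def test_min_isolate_threshold_drops_rare_snps(self):
        # SNP derived in 3 isolates total, threshold 4 -> dropped
        calls = np.zeros((6, 2), dtype=np.int8)
        calls[:3, 0] = DERIVED
        calls[:4, 1] = DERIVED
        gm = _gm(calls, [f"i{k}" for k in range(6)])
        out = snp_frequencies(gm, self._meta([3] * 6), min_isolates=4)
        assert [t.label for t in out] == ["s1"]

    def test_ambiguous_isolates_excluded_from_denominator(self):
        # day with 5 isolates: 2 derived, 1 ambiguous -> 2/4 = 0.5
        calls = np.array([[DERIVED], [DERIVED], [AMBIGUOUS], [0], [0],
                          [DERIVED], [DERIVED]], dtype=np.int8)
        meta = self._meta([7, 7, 7, 7, 7, 14, 14])
        gm = _gm(calls, [f"i{k}" for k in range(7)])
        out = snp_frequencies(gm, meta, min_isolates=4)
        series = out[0]
        assert series.freqs[list(series.days).index(7)] == pytest.approx(0.5)

    def test_default_scenario_retains_all_22(self, default_sim,
                                             called_default):
        _, truth, data = default_sim
        _, gm, _ = called_default
        out = snp_frequencies(gm, data.records, min_isolates=4)
        assert len(out) == 22


class TestInterpolation:
    def test_flat_zero_observations(self):
        s = TrajectorySeries("x", [0, 28], [0.0, 0.0])
        _, curve = interpolate_trajectory(s)
        assert (curve == 0).all()

    def test_passes_through_and_bounded(self):
        s = TrajectorySeries("x", [3, 7], [0.2, 0.8])
        grid, curve = interpolate_trajectory(s, grid_step=0.25)
        assert curve[0] == pytest.approx(0.2)
        assert curve[-1] == pytest.approx(0.8)
        assert ((curve >= 0) & (curve <= 1)).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_monotone_observations_give_monotone_curve(self, values):
        values = sorted(values)
        days = np.arange(len(values), dtype=float) * 5
        _, curve = interpolate_trajectory(
            TrajectorySeries("x", days, np.array(values)))
        assert (np.diff(curve) >= -1e-12).all()

    def test_single_observation_constant_with_warning(self):
        with pytest.warns(UserWarning, match="single observation"):
            grid, curve = interpolate_trajectory(
                TrajectorySeries("x", [7], [0.4]))
        assert list(curve) == [0.4]


class TestNesting:
    def _chain_gm(self):
        # s0 in 6 isolates, s0+s1 in 4, s0+s1+s2 in 2: a nested chain
        calls = np.zeros((8, 3), dtype=np.int8)
        calls[:6, 0] = DERIVED
        calls[2:6, 1] = DERIVED
        calls[4:6, 2] = DERIVED
        return _gm(calls, [f"i{k}" for k in range(8)])

    def test_chain_recovered_with_nested_names(self):
        tree = nest_lineages(self._chain_gm())
        names = set(tree.nodes) - {FOUNDER}
        assert names == {"E1", "E1-A", "E1-A-1"}
        assert tree.nodes["E1-A-1"].parent == "E1-A"
        assert tree.nodes["E1-A"].snp_ids == {"s0", "s1"}

    def test_disjoint_sets_become_siblings(self):
        calls = np.zeros((8, 3), dtype=np.int8)
        calls[:6, 0] = DERIVED
        calls[:3, 1] = DERIVED
        calls[3:6, 2] = DERIVED
        tree = nest_lineages(_gm(calls, [f"i{k}" for k in range(8)]))
        assert tree.nodes["E1-A"].parent == "E1"
        assert tree.nodes["E1-B"].parent == "E1"

    def test_irreconcilable_conflict_raises(self):
        # two SNPs with heavily overlapping but non-nested carrier sets
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:6, 0] = DERIVED
        calls[3:9, 1] = DERIVED
        with pytest.raises(ValueError, match="curation"):
            nest_lineages(_gm(calls, [f"i{k}" for k in range(10)]),
                          nesting_tolerance=0.10)

    def test_simulated_tree_topology_recovered(self, default_sim,
                                               called_default):
        _, truth, data = default_sim
        _, gm, _ = called_default
        tree = nest_lineages(gm, data.records)
        pos2true = {(s.replicon_id, s.pos): s.snp_id for s in truth.snps}

        def remap(fs):
            return frozenset(pos2true[(x.rsplit(":", 1)[0],
                                       int(x.rsplit(":", 1)[1]))] for x in fs)
        got = {(remap(a), remap(b) if b else None) for a, b in tree.topology()}
        assert got == truth.topology()


class TestMuller:
    def _tree(self, raw):
        nodes = {
            FOUNDER: Lineage(FOUNDER, frozenset(), frozenset(), None, ["P"]),
            "P": Lineage("P", frozenset({"s0"}), frozenset(), FOUNDER,
                         ["C1", "C2"]),
            "C1": Lineage("C1", frozenset({"s0", "s1"}), frozenset(), "P"),
            "C2": Lineage("C2", frozenset({"s0", "s2"}), frozenset(), "P"),
        }
        freq = pd.DataFrame(raw, index=[14]).rename_axis("day")
        return LineageTree(nodes=nodes, frequencies=freq)

    def test_parent_minus_children(self):
        m = muller_decompose(self._tree(
            {FOUNDER: [1.0], "P": [0.8], "C1": [0.3], "C2": [0.3]}))
        m = m.set_index("lineage")["exclusive_freq"]
        assert m["P"] == pytest.approx(0.2)
        assert m["C1"] == pytest.approx(0.3)   # leaves keep raw

    def test_clamped_to_zero_when_children_exceed_parent(self):
        m = muller_decompose(self._tree(
            {FOUNDER: [1.0], "P": [0.8], "C1": [0.5], "C2": [0.4]}))
        assert m.set_index("lineage")["exclusive_freq"]["P"] == 0.0

    def test_idempotent_on_leafified_output(self):
        tree = self._tree({FOUNDER: [1.0], "P": [0.8], "C1": [0.3],
                           "C2": [0.3]})
        first = muller_decompose(tree)
        wide = first.pivot(index="day", columns="lineage",
                           values="exclusive_freq")
        leaf_nodes = {n: Lineage(n, frozenset(), frozenset(), None)
                      for n in wide.columns}
        second = muller_decompose(LineageTree(nodes=leaf_nodes,
                                              frequencies=wide))
        merged = first.merge(second, on=["day", "lineage"])
        assert np.allclose(merged["exclusive_freq_x"],
                           merged["exclusive_freq_y"])

    def test_conservation_on_simulation(self, default_sim, called_default):
        _, truth, data = default_sim
        _, gm, _ = called_default
        tree = nest_lineages(gm, data.records)
        m = muller_decompose(tree)
        sums = m.groupby("day")["exclusive_freq"].sum()
        assert (sums <= 1 + 1e-9).all()

    def test_estimated_frequencies_near_truth(self, default_sim,
                                              called_default):
        cfg, truth, data = default_sim
        _, gm, _ = called_default
        # pooled derived fraction per (snp, day) vs pooled truth frequency
        meta = {r.isolate_id: r for r in data.records}
        pos2true = {(s.replicon_id, s.pos): s.snp_id for s in truth.snps}
        ok = total = 0
        for j, snp in enumerate(gm.snps):
            true_id = pos2true[(snp.replicon_id, snp.pos)]
            carriers = {n for n, l in truth.lineages.items()
                        if true_id in l.all_snp_ids}
            for day in cfg.days:
                idx = [i for i, iso in enumerate(gm.isolates)
                       if meta[iso].day == day]
                col = gm.calls[idx, j]
                n_ok = (col != AMBIGUOUS).sum()
                if n_ok == 0:
                    continue
                est = (col == DERIVED).sum() / n_ok
                truth_f = np.mean([occ.loc[day, sorted(carriers)].sum()
                                   for occ in truth.occupancy.values()])
                se = np.sqrt(max(truth_f * (1 - truth_f), 1e-4) / n_ok)
                total += 1
                ok += abs(est - truth_f) <= 3 * se
        assert ok / total >= 0.90


class TestMantel:
    def _traj(self, seed=None):
        rng = np.random.default_rng(seed)
        days = [3, 7, 14, 21, 28]
        data = (rng.random((5, 6)) > 0.5).astype(float)
        return pd.DataFrame(data, index=days,
                            columns=[f"s{j}" for j in range(6)])

    def test_identical_trajectories_r_one(self):
        t = self._traj(1)
        r, p = compare_host_dynamics(t, t.copy(), n_permutations=999, seed=0)
        assert r == pytest.approx(1.0)

    def test_shuffled_trajectories_not_significant(self):
        rng = np.random.default_rng(5)
        t1 = self._traj(2)
        t2 = pd.DataFrame(rng.permutation(self._traj(3).to_numpy()),
                          index=t1.index, columns=t1.columns)
        r, p = compare_host_dynamics(t1, t2, n_permutations=999, seed=0)
        assert p > 0.05 or abs(r) < 0.5

    def test_r_invariant_to_consistent_relabeling(self):
        t1, t2 = self._traj(7), self._traj(8)
        r1, _ = compare_host_dynamics(t1, t2, n_permutations=99, seed=0)
        perm = [4, 0, 3, 1, 2]
        t1p = t1.iloc[perm].set_index(t1.index)
        t2p = t2.iloc[perm].set_index(t2.index)
        r2, _ = compare_host_dynamics(t1p, t2p, n_permutations=99, seed=0)
        assert r1 == pytest.approx(r2)

    def test_degenerate_matrix_undefined(self):
        t = pd.DataFrame(np.ones((4, 3)), index=[3, 7, 14, 21],
                         columns=["a", "b", "c"])
        r, p = compare_host_dynamics(t, t, n_permutations=99, seed=0)
        assert np.isnan(r) and np.isnan(p)

    def test_matches_skbio_mantel(self):
        # independent cross-check of the seeded implementation
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(13)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.normal(0, 0.05, a.shape)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        b = np.abs(b)
        r_ours, _ = mantel_test(a, b, n_permutations=99, seed=1)
        r_skbio, _, _ = sk_mantel(SkDM(a), SkDM(b), permutations=0)
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-12)
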