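import numpy as np
import pytest

from densfam.alignments import Region
from densfam.metaclusters import (
    Metacluster,
    MetaclusteringParams,
    _members_of,
    assign_to_metaclusters,
    export_seed_set,
    filter_member_regions,
    merge_metaclusters,
    metacluster_distance,
    metacluster_peaks,
    primary_cluster_distance,
    primary_cluster_distance_matrix,
    reduce_and_cap_members,
)
from densfam.primary import PrimaryCluster

from conftest import make_alignment
from _oracles import brute_cluster_distance, brute_merge_components, brute_metacluster_dpc

PARAMS = MetaclusteringParams()


def make_cluster(cid, query_id, members):
    """members: list of (search_id, sstart, send)."""
    alns = [
        make_alignment(query_id, sid, (1, 100), (ss, se))
        for sid, ss, se in members
    ]
    return PrimaryCluster(cluster_id=cid, query_id=query_id,
                          peak=alns[0], members=alns)


def random_clusters(rng, n_clusters, n_search=20, max_members=8):
    out = []
    for c in range(n_clusters):
        k = int(rng.integers(1, max_members + 1))
        members = []
        for _ in range(k):
            sid = f"S{int(rng.integers(n_search))}"
            ss = int(rng.integers(1, 300))
            members.append((sid, ss, ss + int(rng.integers(20, 120))))
        out.append(make_cluster(f"Q{c}/p0", f"Q{c}", members))
    return out


class TestPrimaryClusterDistance:
    def test_identical_clusters_have_distance_zero(self):
        members = [("X", 1, 100), ("Y", 50, 150), ("Z", 10, 90)]
        c = make_cluster("a", "Q1", members)
        c0 = make_cluster("b", "Q2", members)
        assert primary_cluster_distance(c, c0, PARAMS.mu_d) == 0.0

    def test_no_shared_search_sequence_means_distance_one(self):
        c = make_cluster("a", "Q1", [("X", 1, 100)])
        c0 = make_cluster("b", "Q2", [("Y", 1, 100)])
        assert primary_cluster_distance(c, c0, PARAMS.mu_d) == 1.0

    def test_matching_caps_pair_count_at_min_size(self):
        c = make_cluster("a", "Q1", [("X", 1, 100)])
        c0 = make_cluster("b", "Q2", [("X", 1, 100), ("X", 5, 104)])
        # both of c0's regions qualify against c's single region, but the
        # one-to-one matching counts at most one pair: D = 1 - 1/1 = 0
        assert primary_cluster_distance(c, c0, PARAMS.mu_d) == 0.0

    def test_symmetric(self, rng):
        clusters = random_clusters(rng, 12)
        for _ in range(30):
            i, j = rng.integers(0, len(clusters), 2)
            a, b = clusters[int(i)], clusters[int(j)]
            assert primary_cluster_distance(a, b, 0.2) == pytest.approx(
                primary_cluster_distance(b, a, 0.2)
            )

    def test_matrix_agrees_with_pairwise(self, rng):
        clusters = random_clusters(rng, 15)
        dist = primary_cluster_distance_matrix(clusters, PARAMS.mu_d)
        for i in range(len(clusters)):
            for j in range(len(clusters)):
                if i == j:
                    continue
                expected = primary_cluster_distance(
                    clusters[i], clusters[j], PARAMS.mu_d
                )
                assert dist[i, j] == pytest.approx(expected)

    def test_empty_cluster_rejected(self):
        c = make_cluster("a", "Q1", [("X", 1, 100)])
        empty = PrimaryCluster("b", "Q2", peak=c.members[0], members=[])
        with pytest.raises(ValueError):
            primary_cluster_distance(c, empty)


class TestMetaclusterPeaks:
    def test_overlapping_trio_plus_isolated(self):
        members = [("X", 1, 100), ("Y", 1, 100)]
        trio = [make_cluster(f"t{i}", f"Q{i}", members) for i in range(3)]
        isolated = make_cluster("iso", "Q9", [("Z", 1, 100)])
        clusters = trio + [isolated]
        peaks, rho, delta = metacluster_peaks(clusters, PARAMS)
        assert list(rho) == [2, 2, 2, 0]
        assert peaks == [trio[0]]  # designated maximum of the tied trio
        assert delta[3] == 1.0  # isolated, but rho 0 keeps it off the peak list

    def test_far_pair_yields_no_peaks(self):
        # D = 1 between them (no shared search sequence) >= mu2 = 0.9
        a = make_cluster("a", "Q1", [("X", 1, 100)])
        b = make_cluster("b", "Q2", [("Y", 1, 100)])
        peaks, rho, _ = metacluster_peaks([a, b], PARAMS)
        assert peaks == [] and list(rho) == [0, 0]

    def test_single_cluster_is_not_a_peak(self):
        c = make_cluster("a", "Q1", [("X", 1, 100)])
        peaks, rho, delta = metacluster_peaks([c], PARAMS)
        assert peaks == [] and rho[0] == 0 and delta[0] == 1.0


class TestAssignToMetaclusters:
    def test_nearest_peak_wins_and_peak_joins_itself(self):
        shared = [("X", 1, 100), ("Y", 1, 100), ("W", 1, 100)]
        group1 = [make_cluster(f"g{i}", f"Q{i}", shared) for i in range(3)]
        other = [make_cluster(f"h{i}", f"R{i}", [("Z", 1, 100), ("V", 1, 100)])
                 for i in range(3)]
        clusters = group1 + other
        peaks, _, _ = metacluster_peaks(clusters, PARAMS)
        mcs = assign_to_metaclusters(clusters, peaks, PARAMS)
        assert len(mcs) == 2
        assert set(map(id, mcs[0].primary_clusters)) == set(map(id, group1))
        assert set(map(id, mcs[1].primary_clusters)) == set(map(id, other))
        # member regions are the search regions of all member alignments
        assert mcs[0].size == sum(c.n_c for c in group1)

    def test_cluster_far_from_all_peaks_discarded(self):
        shared = [("X", 1, 100), ("Y", 1, 100)]
        group = [make_cluster(f"g{i}", f"Q{i}", shared) for i in range(3)]
        loner = make_cluster("lone", "Q9", [("Z", 1, 100)])
        clusters = group + [loner]
        peaks, _, _ = metacluster_peaks(clusters, PARAMS)
        mcs = assign_to_metaclusters(clusters, peaks, PARAMS)
        assigned = {id(c) for mc in mcs for c in mc.primary_clusters}
        assert id(loner) not in assigned


class TestMergeMetaclusters:
    def _mc(self, mc_id, clusters):
        return Metacluster(mc_id=mc_id, primary_clusters=clusters,
                           members=_members_of(clusters))

    def test_identical_metaclusters_merge(self):
        members = [("X", 1, 100), ("Y", 1, 100)]
        a = self._mc("MC1", [make_cluster("a", "Q1", members)])
        b = self._mc("MC2", [make_cluster("b", "Q2", members)])
        assert len(merge_metaclusters([a, b], PARAMS)) == 1

    def test_distant_metaclusters_stay_separate(self):
        a = self._mc("MC1", [make_cluster("a", "Q1", [("X", 1, 100)])])
        b = self._mc("MC2", [make_cluster("b", "Q2", [("Y", 1, 100)])])
        assert len(merge_metaclusters([a, b], PARAMS)) == 2

    def test_transitive_chain_merges_into_one(self):
        params = MetaclusteringParams(merge_threshold=0.9)
        dists = {
            ("A", "B"): 0.5, ("B", "A"): 0.5,
            ("B", "C"): 0.5, ("C", "B"): 0.5,
            ("A", "C"): 0.95, ("C", "A"): 0.95,
        }
        mcs = [
            self._mc(x, [make_cluster(x.lower(), f"Q{x}", [(x, 1, 100)])])
            for x in "ABC"
        ]
        dist_fn = lambda c, c0: dists.get((c.query_id[1], c0.query_id[1]), 0.0)
        merged = merge_metaclusters(mcs, params, dist_fn=dist_fn)
        assert len(merged) == 1 and merged[0].n_mc == 3

    def test_printed_factor_doubles_the_mean(self):
        a = self._mc("MC1", [make_cluster("a", "Q1", [("X", 1, 100)])])
        b = self._mc("MC2", [make_cluster("b", "Q2", [("X", 200, 300)])])
        plain = metacluster_distance(a, b, PARAMS)
        doubled = metacluster_distance(
            a, b, MetaclusteringParams(printed_merge_factor=True)
        )
        assert doubled == min(2 * plain, 1.0)


class TestFilterMemberRegions:
    def _mc(self, members):
        pc = make_cluster("a", "Q1", members)
        return Metacluster("MC1", [pc], members=_members_of([pc]))

    def test_overlapping_pair_retained(self):
        mc = self._mc([("X", 10, 100), ("X", 12, 102)])
        assert filter_member_regions(mc, PARAMS).size == 2

    def test_lone_region_removed(self):
        mc = self._mc([("X", 10, 100), ("X", 12, 102), ("Y", 1, 50)])
        out = filter_member_regions(mc, PARAMS)
        assert {m.seq_id for m in out.members} == {"X"}

    def test_disjoint_same_sequence_pair_removed(self):
        mc = self._mc([("X", 1, 100), ("X", 300, 400)])
        assert filter_member_regions(mc, PARAMS).size == 0

    def test_every_retained_region_keeps_a_retained_partner(self, rng):
        from densfam.primary import region_distance

        members = []
        for _ in range(60):
            sid = f"S{int(rng.integers(8))}"
            ss = int(rng.integers(1, 200))
            members.append((sid, ss, ss + int(rng.integers(20, 100))))
        out = filter_member_regions(self._mc(members), PARAMS)
        for m in out.members:
            partners = [
                o for o in out.members
                if o is not m and o.seq_id == m.seq_id
                and region_distance(o.region, m.region) < PARAMS.mu_d
            ]
            assert partners


class TestReduceAndCap:
    def _mc(self, n, seq="X"):
        members = [(f"{seq}{i}", 1, 100) for i in range(n)]
        pc = make_cluster("a", "Q1", members)
        return Metacluster("MC1", [pc], members=_members_of([pc]))

    def test_min_size_keeps_120(self):
        assert reduce_and_cap_members(self._mc(120)).size == 120

    def test_min_size_drops_99(self):
        assert reduce_and_cap_members(self._mc(99)) is None

    def test_cap_is_seeded_and_reproducible(self):
        params = MetaclusteringParams(member_cap=5000, rng_seed=42)
        mc = self._mc(6000)
        a = reduce_and_cap_members(mc, params=params)
        b = reduce_and_cap_members(mc, params=params)
        assert a.size == 5000
        assert [m.region for m in a.members] == [m.region for m in b.members]

    def test_identity_reduction_drops_duplicates(self):
        sequences = {"X0": "M" + "ACDEFGHIKLMNPQRSTVWY" * 5}
        members = [("X0", 2, 101), ("X0", 2, 101), ("X0", 2, 101)]
        pc = make_cluster("a", "Q1", members)
        mc = Metacluster("MC1", [pc], members=_members_of([pc]))
        params = MetaclusteringParams(min_size=1)
        out = reduce_and_cap_members(mc, sequences, params)
        assert out.size == 1

    def test_missing_sequence_is_an_error(self):
        mc = self._mc(3)
        with pytest.raises(KeyError, match="X1"):
            reduce_and_cap_members(mc, {"X0": "A" * 200},
                                   MetaclusteringParams(min_size=1))


class TestExportSeedSet:
    def _mc_with_sequences(self, specs):
        members = [(sid, s, e) for sid, s, e in specs]
        pc = make_cluster("a", "Q1", members)
        return Metacluster("MC1", [pc], members=_members_of([pc]))

    def test_subsequences_and_headers(self, rng):
        seqs = {
            f"X{i}": "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)
            )
            for i in range(3)
        }
        mc = self._mc_with_sequences([("X0", 5, 60), ("X1", 20, 110), ("X2", 1, 90)])
        records = export_seed_set(mc, seqs, MetaclusteringParams())
        assert [r.id for r in records] == ["X0/5-60", "X1/20-110", "X2/1-90"]
        assert str(records[0].seq) == seqs["X0"][4:60]

    def test_exact_duplicates_collapse(self):
        seqs = {"X0": "ACDEFGHIKL" * 10, "X1": "ACDEFGHIKL" * 10}
        mc = self._mc_with_sequences([("X0", 1, 100), ("X1", 1, 100)])
        records = export_seed_set(mc, seqs, MetaclusteringParams())
        assert len(records) == 1

    def test_seed_cap(self, rng):
        seqs = {}
        specs = []
        for i in range(60):
            seqs[f"X{i}"] = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
            specs.append((f"X{i}", 1, 100))
        mc = self._mc_with_sequences(specs)
        params = MetaclusteringParams(seed_cap=40, rng_seed=1)
        records = export_seed_set(mc, seqs, params)
        assert len(records) == 40

    def test_region_outside_sequence_is_an_error(self):
        seqs = {"X0": "A" * 50}
        mc = self._mc_with_sequences([("X0", 1, 100)])
        with pytest.raises(ValueError, match="exceeds"):
            export_seed_set(mc, seqs, MetaclusteringParams())


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_distances_densities_peaks_assignment(self, seed):
        rng = np.random.default_rng(seed)
        clusters = random_clusters(rng, int(rng.integers(4, 25)))
        d_oracle, rho_o, delta_o, peaks_o, assign_o = brute_metacluster_dpc(
            clusters, PARAMS.mu_d, PARAMS.mu2
        )
        dist = primary_cluster_distance_matrix(clusters, PARAMS.mu_d)
        for i in range(len(clusters)):
            for j in range(len(clusters)):
                assert dist[i, j] == pytest.approx(d_oracle[i][j])
        peaks, rho, delta = metacluster_peaks(clusters, PARAMS, dist=dist)
        assert list(rho) == rho_o
        assert list(delta) == pytest.approx(delta_o)
        assert [clusters.index(p) for p in peaks] == peaks_o
        mcs = assign_to_metaclusters(clusters, peaks, PARAMS, dist=dist)
        mine = {}
        for mc in mcs:
            for pc in mc.primary_clusters:
                mine[clusters.index(pc)] = mc.mc_id
        theirs = {}
        for i, p in assign_o.items():
            if p is not None:
                theirs[i] = f"MC{peaks_o.index(p) + 1}"
        assert mine == theirs

    def test_merge_components_match_oracle(self, rng):
        clusters = random_clusters(rng, 18, n_search=6)
        dist = primary_cluster_distance_matrix(clusters, PARAMS.mu_d)
        peaks, _, _ = metacluster_peaks(clusters, PARAMS, dist=dist)
        if not peaks:
            pytest.skip("random draw produced no peaks")
        mcs = assign_to_metaclusters(clusters, peaks, PARAMS, dist=dist)
        row = {id(c): i for i, c in enumerate(clusters)}
        merged = merge_metaclusters(
            mcs, PARAMS, dist_fn=lambda a, b: float(dist[row[id(a)], row[id(b)]])
        )
        mc_sets = [[row[id(c)] for c in mc.primary_clusters] for mc in mcs]
        comps = brute_merge_components(mc_sets, dist.tolist(), PARAMS.merge_threshold)
        merged_sets = sorted(
            (
                frozenset(
                    next(k for k, s in enumerate(mc_sets) if row[id(c)] in s)
                    for c in mc.primary_clusters
                )
                for mc in merged
            ),
            key=sorted,
        )
        assert merged_sets == comps
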