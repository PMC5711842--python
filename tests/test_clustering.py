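import itertools
import math
import random

import numpy as np
import pytest

from segscreen.clustering import (
    ClusterAssignment,
    Dendrogram,
    Merge,
    average_linkage,
    cluster_profiles,
    cluster_vectors_from_table,
    cut_clusters,
    distance_matrix,
    select_pulse_candidates,
    to_newick,
)
from segscreen.errors import InsufficientDataError, ValidationError
from segscreen.model import PhenotypicVector

from conftest import build_record, build_table, build_vector


def brute_force_average_linkage(dist):
    """Reference agglomerator: recompute mean inter-cluster distance from the
    raw leaf-pair matrix at every step (no Lance-Williams update)."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    ids = {i: i for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [dist[i, j] for i in clusters[a] for j in clusters[b]]
            )
            key = (d, min(clusters[a]), min(clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((ids[a], ids[b], float(d), len(clusters[a] | clusters[b])))
        clusters[a] = clusters[a] | clusters[b]
        ids[a] = next_id
        del clusters[b], ids[b]
        next_id += 1
    return merges


class TestDistanceMatrix:
    def test_identical_vectors_distance_zero(self):
        v = build_vector(seg=(3, 2, 0, 0, 1, 0))
        labels, dist, _ = distance_matrix({"a": v, "b": v})
        assert dist[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        v1 = build_vector(morph=(0, 3, 0, 3, 0, 3), seg=(0, 3, 0, 3, 0, 3))
        v2 = build_vector(morph=(3, 0, 3, 0, 3, 0), seg=(3, 0, 3, 0, 3, 0))
        _, dist, _ = distance_matrix({"a": v1, "b": v2})
        assert dist[0, 1] == pytest.approx(2.0)

    def test_matches_entrywise_oracle(self):
        rng = random.Random(5)
        vectors = {}
        while len(vectors) < 4:
            scores = [rng.randint(0, 3) for _ in range(12)]
            if len(set(scores)) > 1:
                vectors[f"v{len(vectors)}"] = PhenotypicVector(tuple(scores))
        labels, dist, _ = distance_matrix(vectors)

        def pearson(x, y):
            n = len(x)
            mx, my = sum(x) / n, sum(y) / n
            num = sum((a - mx) * (b - my) for a, b in zip(x, y))
            den = math.sqrt(
                sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
            )
            return num / den

        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i == j:
                    continue
                expected = 1 - pearson(
                    list(vectors[li].scores), list(vectors[lj].scores)
                )
                assert dist[i, j] == pytest.approx(expected)

    def test_constant_vectors_excluded(self):
        v = build_vector(seg=(3, 2, 0, 0, 1, 0))
        flat = build_vector()
        labels, dist, excluded = distance_matrix({"a": v, "b": flat, "c": v})
        assert excluded == ["b"]
        assert labels == ["a", "c"]

    def test_too_few_nonconstant(self):
        with pytest.raises(InsufficientDataError):
            distance_matrix({"a": build_vector(), "b": build_vector()})


class TestAverageLinkage:
    def test_two_leaves(self):
        dist = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = average_linkage(dist, ["A", "B"])
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(0.4)

    def test_three_leaves_hand_case(self):
        # d(AB)=0.1, d(AC)=d(BC)=1.0: merge A,B first, then with C at 1.0
        dist = np.array(
            [[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        dend = average_linkage(dist, ["A", "B", "C"])
        assert dend.merges[0].height == pytest.approx(0.1)
        assert {dend.merges[0].node_a, dend.merges[0].node_b} == {0, 1}
        assert dend.merges[1].height == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(120):
            n = int(rng.integers(2, 8))
            raw = rng.random((n, n))
            dist = (raw + raw.T) / 2
            np.fill_diagonal(dist, 0.0)
            dend = average_linkage(dist)
            expected = brute_force_average_linkage(dist)
            got = [
                (m.node_a, m.node_b, m.height, m.size) for m in dend.merges
            ]
            for (ga, gb, gh, gs), (ea, eb, eh, es) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh)
                assert gs == es

    def test_heights_monotone(self):
        rng = np.random.default_rng(3)
        raw = rng.random((10, 10))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        dend = average_linkage(dist)
        heights = [m.height for m in dend.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            average_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_row_order_invariance_via_label_sorting(self):
        v1 = build_vector(seg=(3, 3, 0, 0, 0, 0))
        v2 = build_vector(seg=(3, 2, 0, 0, 0, 0))
        v3 = build_vector(morph=(2, 2, 0, 0, 0, 0), seg=(0, 0, 1, 1, 0, 0))
        forward = dict([("a", v1), ("b", v2), ("c", v3)])
        backward = dict([("c", v3), ("b", v2), ("a", v1)])
        la, da, _ = distance_matrix(forward)
        lb, db, _ = distance_matrix(backward)
        assert la == lb
        assert np.allclose(da, db)
        ma = average_linkage(da, la).merges
        mb = average_linkage(db, lb).merges
        assert ma == mb


class TestCutClusters:
    def planted_two_block(self):
        v1 = build_vector(seg=(3, 3, 3, 0, 0, 0))
        v2 = build_vector(morph=(0, 0, 0, 1, 1, 1))
        vectors = {f"x{i}": v1 for i in range(3)}
        vectors.update({f"y{i}": v2 for i in range(3)})
        return vectors

    def test_two_block_recovery(self):
        labels, dist, _ = distance_matrix(self.planted_two_block())
        dend = average_linkage(dist, labels)
        assign = cut_clusters(dend, cutoff_correlation=0.6)
        groups = {}
        for lab, cid in assign.assignment.items():
            groups.setdefault(cid, set()).add(lab)
        assert sorted(groups.values(), key=len) == sorted(
            [{"x0", "x1", "x2"}, {"y0", "y1", "y2"}], key=len
        )

    def test_all_similar_gives_one_cluster(self):
        v = build_vector(seg=(3, 3, 0, 0, 0, 0))
        vectors = {f"v{i}": v for i in range(4)}
        labels, dist, _ = distance_matrix(vectors)
        assign = cut_clusters(average_linkage(dist, labels), 0.6)
        assert len(assign.cluster_ids()) == 1

    def test_all_dissimilar_gives_singletons(self):
        vectors = {
            "a": build_vector(seg=(3, 0, 0, 0, 0, 0), morph=(0, 3, 0, 0, 3, 0)),
            "b": build_vector(seg=(0, 3, 0, 3, 0, 0), morph=(3, 0, 0, 0, 0, 0)),
            "c": build_vector(seg=(0, 0, 3, 0, 0, 3), morph=(0, 0, 3, 0, 0, 0)),
        }
        labels, dist, _ = distance_matrix(vectors)
        assert (dist[np.triu_indices(3, 1)] > 0.4).all()
        assign = cut_clusters(average_linkage(dist, labels), 0.6)
        assert len(assign.cluster_ids()) == 3

    def test_cutoff_extremes(self):
        labels, dist, _ = distance_matrix(self.planted_two_block())
        dend = average_linkage(dist, labels)
        everything = cut_clusters(dend, cutoff_correlation=-1.0)
        assert len(everything.cluster_ids()) == 1
        with pytest.raises(ValidationError):
            cut_clusters(dend, cutoff_correlation=1.5)


class TestClusterProfiles:
    def build_planted_table(self):
        records = []
        # direct segmentation cluster: strong seg, clean morphology
        for i in range(4):
            records.append(
                build_record(f"A{i}", 10.0, "wt_A", seg=(0, 3, 3, 0, 3, 0))
            )
        # secondary tail cluster: S and tail-shape (T) dominant
        for i in range(4):
            records.append(
                build_record(
                    f"B{i}", 10.0, "wt_A",
                    morph=(0, 0, 0, 0, 0, 2), seg=(3, 0, 0, 0, 0, 2),
                )
            )
        # seg + morph cluster
        for i in range(4):
            records.append(
                build_record(
                    f"C{i}", 10.0, "wt_A",
                    morph=(3, 3, 2, 3, 2, 3), seg=(0, 2, 2, 2, 2, 0),
                )
            )
        # all-low cluster
        for i in range(4):
            records.append(
                build_record(
                    f"D{i}", 10.0, "wt_A", morph=(1, 0, 0, 0, 0, 0),
                    seg=(0, 1, 0, 0, 0, 0),
                )
            )
        return build_table(records)

    def assignment_for(self, table):
        vectors = cluster_vectors_from_table(table)
        labels, dist, excluded = distance_matrix(vectors)
        dend = average_linkage(dist, labels)
        assign = cut_clusters(dend, 0.6)
        assign.excluded_constant = excluded
        return assign

    def test_planted_labels(self):
        table = self.build_planted_table()
        profiles = cluster_profiles(self.assignment_for(table), table)
        by_member = {}
        for p in profiles:
            for m in p.members:
                by_member[m.split("@")[0]] = p.label
        assert by_member["A0"] == "first_class"
        assert by_member["B0"] == "secondary_tail"
        assert by_member["C0"] == "seg_plus_morph"
        assert by_member["D0"] == "other"

    def test_all_zero_treatments_not_clustered(self):
        table = build_table(
            [build_record("C1"), build_record("C2", seg=(3, 3, 0, 0, 0, 0))]
        )
        vectors = cluster_vectors_from_table(table)
        assert set(vectors) == {table.records[1].treatment_id} | {
            t for t in vectors if not t.startswith("C1")
        }


class TestPlantedClassAgreement:
    def test_adjusted_rand_at_least_090_with_low_noise(self):
        import numpy as np
        from sklearn.metrics import adjusted_rand_score

        from segscreen.model import ScreenTable
        from segscreen.simulate import CompoundProfile, SimConfig, simulate_treatment

        cfg = SimConfig(seed=0, noise_sd=0.1, lethality_scale=0.0)
        prototypes = {
            "A": dict(compound_class="direct_seg",
                      seg_pattern=("BD", "AD", "TD"), seg_effect=2.8,
                      activity_threshold=1.0, toxicity_threshold=np.inf,
                      morph_effect=0.0),
            "B": dict(compound_class="secondary_tail",
                      seg_pattern=("S", "BS"), seg_effect=2.9,
                      activity_threshold=1.0, toxicity_threshold=1.0,
                      morph_effect=2.0, morph_pattern=("T",)),
            "C": dict(compound_class="seg_plus_morph",
                      seg_pattern=("PD", "TD", "AD", "BD"), seg_effect=2.0,
                      activity_threshold=1.0, toxicity_threshold=1.0,
                      morph_effect=2.8),
        }
        rng = np.random.default_rng(3)
        records, truth_class = [], {}
        for name, kwargs in prototypes.items():
            for i in range(12):
                profile = CompoundProfile(compound_id=f"{name}{i:02d}", **kwargs)
                rec, _ = simulate_treatment(profile, 10.0, "wt_A", cfg, rng)
                records.append(rec)
                truth_class[rec.treatment_id] = name
        table = ScreenTable(records=tuple(records))
        vectors = cluster_vectors_from_table(table)
        labels, dist, _ = distance_matrix(vectors)
        assign = cut_clusters(average_linkage(dist, labels), 0.6)
        ari = adjusted_rand_score(
            [truth_class[lab] for lab in labels],
            [assign.assignment[lab] for lab in labels],
        )
        assert ari >= 0.9


class TestSelectPulseCandidates:
    def assignment_and_profiles(self):
        table = TestClusterProfiles().build_planted_table()
        assign = TestClusterProfiles().assignment_for(table)
        return assign, cluster_profiles(assign, table), table

    def test_whole_cluster_when_k_equals_size(self):
        assign, profiles, table = self.assignment_and_profiles()
        picked = select_pulse_candidates(
            assign, profiles, "seg_plus_morph", 4, seed=0, table=table
        )
        assert picked == ["C0", "C1", "C2", "C3"]

    def test_deterministic_per_seed(self):
        assign, profiles, table = self.assignment_and_profiles()
        a = select_pulse_candidates(assign, profiles, "seg_plus_morph", 2, 7, table)
        b = select_pulse_candidates(assign, profiles, "seg_plus_morph", 2, 7, table)
        assert a == b

    def test_k_too_large(self):
        assign, profiles, table = self.assignment_and_profiles()
        with pytest.raises(ValidationError):
            select_pulse_candidates(assign, profiles, "seg_plus_morph", 9, 0, table)

    def test_uniformity_over_pairs(self):
        assign, profiles, table = self.assignment_and_profiles()
        counts = {}
        n_draws = 3000
        for seed in range(n_draws):
            pair = tuple(
                select_pulse_candidates(
                    assign, profiles, "seg_plus_morph", 2, seed, table
                )
            )
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 6
        p = 1 / 6
        se = math.sqrt(p * (1 - p) * n_draws)
        for pair, c in counts.items():
            assert abs(c - n_draws * p) <= 3.5 * se, (pair, c)


class TestNewick:
    def test_two_leaves(self):
        dend = Dendrogram(labels=("A", "B"), merges=(Merge(0, 1, 0.2, 2),))
        assert to_newick(dend) == "(A:0.1,B:0.1);"

    def test_single_leaf(self):
        dend = Dendrogram(labels=("A",), merges=())
        assert to_newick(dend) == "A;"

    def test_round_trip_reproduces_merge_heights(self):
        import dendropy

        rng = np.random.default_rng(11)
        raw = rng.random((6, 6))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"L{i}" for i in range(6)]
        dend = average_linkage(dist, labels)
        tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}

        # cophenetic distance between two leaves = height of their first
        # common merge; patristic distance on the exported tree equals it
        n = dend.n_leaves
        member_sets = {i: {i} for i in range(n)}
        for k, m in enumerate(dend.merges):
            merged = member_sets[m.node_a] | member_sets[m.node_b]
            for i in member_sets[m.node_a]:
                for j in member_sets[m.node_b]:
                    expected = m.height
                    got = pdm.patristic_distance(
                        taxa[labels[i]], taxa[labels[j]]
                    )
                    assert got == pytest.approx(expected, abs=1e-6)
            member_sets[n + k] = merged
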