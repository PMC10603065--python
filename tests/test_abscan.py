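"""Distance matrices, elbow epsilon, density clustering and AbScan iterations."""

import random

import numpy as np
import pytest

import edlib

from abselect.abscan import (
    NOISE,
    AbScanClusterer,
    IdentityClusterer,
    OpticsParams,
    TraditionalClonotyper,
    abscan_cluster,
    density_cluster,
    elbow_epsilon,
    identity_cluster,
    pairwise_distance_matrix,
    traditional_clonotype,
)
from abselect.annotation import AA20
from conftest import make_clone
from oracles import (
    canonical_partition,
    clonotype_components,
    density_reachability_components,
    knee_by_chord,
    levenshtein_dp,
)


def _random_seqs(rng, n, lo=4, hi=10):
    return ["".join(rng.choice(AA20) for _ in range(rng.randint(lo, hi)))
            for _ in range(n)]


class TestDistances:
    def test_identity_distance_zero(self):
        D = pairwise_distance_matrix(["ARDYW", "ARDYW"])
        assert D[0, 1] == 0

    def test_classic_example(self):
        D = pairwise_distance_matrix(["kitten", "sitting"])
        assert D[0, 1] == 3 == levenshtein_dp("kitten", "sitting")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(0)
        pairs = [(a, b) for a, b in zip(_random_seqs(rng, 1000), _random_seqs(rng, 1000))]
        for a, b in pairs:
            assert edlib.align(a, b)["editDistance"] == levenshtein_dp(a, b)

    def test_symmetry_and_zero_diagonal(self):
        rng = random.Random(1)
        seqs = _random_seqs(rng, 12)
        D = pairwise_distance_matrix(seqs)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_matrix([])


def _matrix_from_kdist(kdist):
    """A diagonal block layout whose sorted 2-NN distances equal ``kdist``."""
    # pairs of points at the target distance, blocks far apart
    n = len(kdist)
    big = 1000.0
    D = np.full((2 * n, 2 * n), big)
    for i, d in enumerate(kdist):
        D[2 * i, 2 * i + 1] = D[2 * i + 1, 2 * i] = d
    np.fill_diagonal(D, 0.0)
    return D


class TestElbowEpsilon:
    def test_knee_at_jump(self):
        # 2-NN distance list [1]*6 + [9]: knee sits on the plateau end
        D = _matrix_from_kdist([1, 1, 1, 1, 1, 1, 9])
        kd = np.sort(np.sort(D, axis=1)[:, 1])  # core distance at min_pts=2
        assert kd[knee_by_chord(kd)] == 1.0  # knee sits on the plateau, not the jump
        eps = elbow_epsilon(D, k=2)
        assert eps == 1.0

    def test_linear_curve_ties_break_to_first(self):
        kd = np.arange(1, 8, dtype=float)
        assert knee_by_chord(kd) == 0
        D = _matrix_from_kdist(list(kd))
        assert elbow_epsilon(D, k=2) == 1.0

    def test_two_points_fallback_is_their_distance(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert elbow_epsilon(D) == 3.0

    def test_degenerate_all_zero_uses_fallback(self):
        D = np.zeros((4, 4))
        assert elbow_epsilon(D, fallback_eps=0.5) == 0.5

    def test_floored_at_smallest_positive_distance(self):
        D = _matrix_from_kdist([2.0, 2.0, 2.0, 2.0])
        assert elbow_epsilon(D, k=2) >= 2.0


class TestDensityCluster:
    def test_two_distant_groups(self):
        D = np.full((6, 6), 100.0)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        labels = density_cluster(D, OpticsParams(eps_opt=1.0, max_eps=10.0))
        assert len(set(labels)) == 2 and NOISE not in labels
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4], labels[5]}) == 1

    def test_all_identical_single_cluster(self):
        labels = density_cluster(np.zeros((5, 5)), OpticsParams(eps_opt=1.0))
        assert set(labels) == {0}

    def test_isolated_point_is_noise(self):
        D = np.zeros((4, 4))
        D[3, :] = D[:, 3] = 50.0
        D[3, 3] = 0.0
        labels = density_cluster(D, OpticsParams(eps_opt=1.0, max_eps=10.0))
        assert labels[3] == NOISE and set(labels[:3]) == {0}

    def test_matches_reachability_oracle_on_separated_instances(self):
        """Exact agreement with brute-force density-reachability components
        on random instances of tight groups plus isolated points."""
        rng = random.Random(7)
        max_eps = 3.0
        for _ in range(150):
            seqs = []
            for _ in range(rng.randint(1, 3)):
                proto = "".join(rng.choice(AA20) for _ in range(rng.randint(12, 16)))
                for _ in range(rng.randint(2, 4)):
                    s = list(proto)
                    if rng.random() < 0.5:
                        s[rng.randrange(len(s))] = rng.choice(AA20)
                    seqs.append("".join(s))
            for _ in range(rng.randint(0, 2)):
                seqs.append("".join(rng.choice(AA20) for _ in range(rng.randint(12, 16))))
            seqs = seqs[:10]
            if len(seqs) < 2:
                continue
            D = pairwise_distance_matrix(seqs)
            labels = density_cluster(D, OpticsParams(eps_opt=max_eps / 2, max_eps=max_eps))
            oracle = density_reachability_components(D, max_eps)
            assert canonical_partition(labels) == canonical_partition(oracle)

    def test_consistent_with_reachability_on_random_instances(self):
        """On arbitrary random instances: clusters stay within max_eps
        components, unreachable points are noise, and eps_opt-connected
        points always co-cluster."""
        rng = random.Random(1)
        for _ in range(150):
            n = rng.randint(3, 10)
            seqs = _random_seqs(rng, n, 4, 8)
            D = pairwise_distance_matrix(seqs)
            max_eps = rng.choice([2.0, 3.0, 4.0])
            labels = density_cluster(
                D, OpticsParams(eps_opt=max_eps / 2, max_eps=max_eps))
            comp = density_reachability_components(D, max_eps)
            core_comp = density_reachability_components(D, max_eps / 2)
            for c in set(labels) - {NOISE}:
                assert len({comp[i] for i in range(n) if labels[i] == c}) == 1
            for i in range(n):
                if comp[i] == -1:
                    assert labels[i] == NOISE
                for j in range(n):
                    if core_comp[i] != -1 and core_comp[i] == core_comp[j]:
                        assert labels[i] == labels[j] != NOISE

    def test_deterministic(self):
        rng = random.Random(3)
        D = pairwise_distance_matrix(_random_seqs(rng, 15))
        p = OpticsParams(eps_opt=2.0, max_eps=4.0)
        assert np.array_equal(density_cluster(D, p), density_cluster(D, p))


class TestAbScan:
    def _families(self, toy_scaffold):
        protos = ["ARDYWGQGHFKL", "SSGYLMNPQRTV", "KKTEPWFCHDIA"]
        clones = []
        for i, proto in enumerate(protos):
            variant = proto[:-1] + ("A" if proto[-1] != "A" else "G")
            clones.append(make_clone(toy_scaffold, clone_id=f"f{i}a",
                                     HCDR3=proto, counts={"p": 40}))
            clones.append(make_clone(toy_scaffold, clone_id=f"f{i}b",
                                     HCDR3=variant, counts={"p": 20}))
        return clones

    def test_three_families_three_clusters(self, toy_scaffold):
        assignments = abscan_cluster(self._families(toy_scaffold), "HCDR3")
        ids = {a.roi_value: a.cluster_id for a in assignments}
        assert all(cid is not None for cid in ids.values())
        assert len(set(ids.values())) == 3
        # variants share their prototype's cluster
        assert ids["ARDYWGQGHFKL"] == ids["ARDYWGQGHFKA"]

    def test_abundant_distinct_singleton_rescued_by_count(self, toy_scaffold):
        clones = self._families(toy_scaffold)
        clones.append(make_clone(toy_scaffold, clone_id="lone",
                                 HCDR3="W" * 25, counts={"p": 2}))
        assignments = abscan_cluster(clones, "HCDR3")
        lone = next(a for a in assignments if a.roi_value == "W" * 25)
        assert lone.status == "rescued_count"
        assert lone.cluster_id is not None

    def test_count1_singleton_without_match_discarded(self, toy_scaffold):
        clones = self._families(toy_scaffold)
        clones.append(make_clone(toy_scaffold, clone_id="lone",
                                 HCDR3="W" * 25, counts={"p": 1}))
        assignments = abscan_cluster(clones, "HCDR3")
        lone = next(a for a in assignments if a.roi_value == "W" * 25)
        assert lone.status == "discarded_noise"
        assert lone.cluster_id is None

    def test_count1_noise_with_identity_match_rescued(self, toy_scaffold):
        clones = self._families(toy_scaffold)
        # singleton one substitution away from an abundant family (11/12 = 92%)
        clones.append(make_clone(toy_scaffold, clone_id="nbr",
                                 HCDR3="WRDYWGQGHFKL", counts={"p": 1}))
        # keep it out of OPTICS range by clustering only abundant seeds
        assignments = abscan_cluster(
            clones, "HCDR3", iteration_schedule=(5.0, 0.0),
        )
        ids = {a.roi_value: a for a in assignments}
        nbr = ids["WRDYWGQGHFKL"]
        assert nbr.status in ("member", "rescued_identity")
        assert nbr.cluster_id == ids["ARDYWGQGHFKL"].cluster_id

    def test_partition_unique_ids_and_permutation_stable(self, toy_scaffold):
        clones = self._families(toy_scaffold)
        a1 = abscan_cluster(clones, "HCDR3")
        a2 = abscan_cluster(list(reversed(clones)), "HCDR3")
        as_map = lambda a: {x.roi_value: x.cluster_id for x in a}
        assert as_map(a1) == as_map(a2)
        values = [x.roi_value for x in a1]
        assert len(values) == len(set(values))

    def test_equals_identity_when_all_far_apart_and_counted(self, toy_scaffold):
        # a tight pair anchors the elbow at 1 (max_eps 10); the singletons sit
        # beyond max_eps of everything and carry count >= 2
        protos = ["AAAAAAAAAAAA", "W" * 25, "H" * 40, "P" * 55]
        clones = [make_clone(toy_scaffold, clone_id=f"c{i}", HCDR3=p,
                             counts={"p": 5}) for i, p in enumerate(protos)]
        clones.append(make_clone(toy_scaffold, clone_id="pair",
                                 HCDR3="AAAAAAAAAAAG", counts={"p": 5}))
        abscan = {a.roi_value: a.cluster_id for a in abscan_cluster(clones, "HCDR3")}
        ident = {a.roi_value: a.cluster_id for a in identity_cluster(clones, "HCDR3")}
        assert all(cid is not None for cid in abscan.values())
        assert canonical_partition([abscan[p] for p in protos]) == \
            canonical_partition([ident[p] for p in protos])

    def test_empty_input(self):
        assert abscan_cluster([], "HCDR3") == []

    def test_schedule_validation(self, toy_scaffold):
        with pytest.raises(ValueError, match="decreasing"):
            AbScanClusterer(iteration_schedule=(0.001, 0.01, 0.0)).fit(["A"])
        with pytest.raises(ValueError, match="end at 0"):
            AbScanClusterer(iteration_schedule=(0.01, 0.001)).fit(["A"])


class TestClonotyping:
    def test_875_percent_identity_splits_at_90(self):
        t = TraditionalClonotyper(identity=0.90)
        labels = t.fit_predict(["ARDYWGQG", "ARDYWGQS"])
        assert labels[0] != labels[1]

    def test_same_roi_different_scaffold_split(self):
        t = TraditionalClonotyper()
        labels = t.fit_predict(["ARDYWGQGHF", "ARDYWGQGHA"],
                               scaffolds=["vh1", "vh2"])
        assert labels[0] != labels[1]

    def test_length_mismatch_always_splits(self):
        t = TraditionalClonotyper(identity=0.1)
        labels = t.fit_predict(["ARDYWGQGH", "ARDYWGQGHF"])
        assert labels[0] != labels[1]

    def test_single_linkage_chains(self):
        # a-b identical at 90%, b-c at 90%, a-c below: still one clonotype
        vals = ["AAAAAAAAAA", "AAAAAAAAAW", "AAAAAAAAWW"]
        labels = TraditionalClonotyper(identity=0.90).fit_predict(vals)
        assert len(set(labels)) == 1

    def test_matches_bruteforce_graph(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(2, 12)
            base = "".join(rng.choice(AA20) for _ in range(10))
            vals, scaffs = [], []
            seen = set()
            for _ in range(n):
                s = list(base)
                for _ in range(rng.randint(0, 3)):
                    s[rng.randrange(10)] = rng.choice(AA20)
                s = "".join(s)
                if s in seen:
                    continue
                seen.add(s)
                vals.append(s)
                scaffs.append(rng.choice(["v1", "v2"]))
            if len(vals) < 2:
                continue
            got = TraditionalClonotyper().fit_predict(vals, scaffolds=scaffs)
            oracle = clonotype_components(vals, scaffs, 0.90)
            assert canonical_partition(list(got)) == canonical_partition(oracle)


class TestIdentityCluster:
    def test_distinct_strings_distinct_clusters(self, toy_scaffold):
        clones = [make_clone(toy_scaffold, clone_id=f"c{i}", HCDR3=f"ARDYWGQGH{c}")
                  for i, c in enumerate("FLYWA")]
        assignments = identity_cluster(clones, "HCDR3")
        assert len({a.cluster_id for a in assignments}) == 5

    def test_shared_string_across_populations_single_cluster(self, toy_scaffold):
        a = make_clone(toy_scaffold, clone_id="a", counts={"p1": 2})
        b = make_clone(toy_scaffold, clone_id="b", LCDR1="QSIAAY", counts={"p2": 3})
        assignments = identity_cluster([a, b], "HCDR3")
        assert len(assignments) == 1  # identical HCDR3 condensed to one value


def test_cluster_method_nesting_on_error_inflated_data(small_campaign):
    """identity >= clonotype >= abscan cluster counts on noisy reads."""
    from abselect.pipeline import run_pipeline
    from abselect.simulate import EARLY, LATE

    reads = small_campaign.reads[EARLY] + small_campaign.reads[LATE]
    res = run_pipeline(reads, small_campaign.barcodes, small_campaign.scaffolds)
    n_ident = len({a.cluster_id for a in identity_cluster(res.clones, "HCDR3")})
    n_clono = len({a.cluster_id for a in traditional_clonotype(res.clones, "HCDR3")})
    n_abscan = res.clusterer.n_clusters_
    assert n_ident >= n_clono >= n_abscan
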