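import pytest

from mznet import (
    AttributionSummary,
    ConsensusNode,
    MolecularNetwork,
    SampleRecord,
    attribute_groups,
    flag_media_nodes,
    genus_stats,
    mass_bins,
    neutral_loss_annotate,
    rarefaction,
    strain_specificity,
)
from mznet.cohort_stats import per_strain_average, percent, round_half_up


def node(node_id, samples, precursor=500.0):
    """Minimal node with one member per listed sample."""
    return ConsensusNode(
        node_id=node_id,
        precursor_mz=precursor,
        peaks=(),
        member_spectrum_ids=[f"{node_id}:{s}" for s in samples],
        sample_presence={s: 1 for s in samples},
        strain_presence=set(samples),
    )


META = [
    SampleRecord("a1", "a1", "Antarctica", "Bacillus", False),
    SampleRecord("a2", "a2", "Antarctica", "Kocuria", False),
    SampleRecord("s1", "s1", "Scotland", "Bacillus", False),
    SampleRecord("s2", "s2", "Scotland", "Streptomyces", False),
    SampleRecord("b1", "b1", "", "unknown", True),
]


class TestRounding:
    def test_half_up(self):
        assert round_half_up(64.25, 1) == 64.3
        assert round_half_up(64.24, 1) == 64.2
        assert round_half_up(7.8134, 1) == 7.8

    def test_percent(self):
        assert percent(278, 3558) == 7.8
        assert percent(0, 0) == 0.0


class TestMediaFlagging:
    def test_blank_only_node_is_media(self):
        net = MolecularNetwork(nodes=[node(0, ["b1"])], edges=[])
        assert flag_media_nodes(net, META) == {0}

    def test_strain_only_node_is_not_media(self):
        net = MolecularNetwork(nodes=[node(0, ["a1", "s1"])], edges=[])
        assert flag_media_nodes(net, META) == set()

    def test_single_blank_member_dominates(self):
        net = MolecularNetwork(nodes=[node(0, ["b1", "a1", "a2", "s1"])], edges=[])
        assert flag_media_nodes(net, META) == {0}

    def test_min_blank_members_configurable(self):
        net = MolecularNetwork(nodes=[node(0, ["b1", "a1"])], edges=[])
        assert flag_media_nodes(net, META, min_blank_members=2) == set()


class TestAttribution:
    def test_exclusive_shared_media_partition(self):
        nodes = [
            node(0, ["a1"]),            # Antarctica-exclusive
            node(1, ["a1", "a2"]),      # Antarctica-exclusive
            node(2, ["s1"]),            # Scotland-exclusive
            node(3, ["a1", "s1"]),      # shared
            node(4, ["b1", "a1"]),      # media
        ]
        net = MolecularNetwork(nodes=nodes, edges=[])
        summary = attribute_groups(net, META)
        assert summary.total_nodes == 5
        assert summary.media_nodes == 1
        assert summary.per_group_exclusive == {"Antarctica": 2, "Scotland": 1}
        assert summary.shared_all_groups == 1
        # conservation: media + exclusive + shared == total
        assert (
            summary.media_nodes
            + sum(summary.per_group_exclusive.values())
            + summary.shared_all_groups
            == summary.total_nodes
        )
        assert summary.fractions["Antarctica"] == 40.0
        assert summary.fractions["exclusive_union"] == 60.0

    def test_single_group_cohort_has_no_shared(self):
        meta = [r for r in META if r.group != "Scotland"]
        nodes = [node(0, ["a1"]), node(1, ["a1", "a2"])]
        summary = attribute_groups(MolecularNetwork(nodes=nodes, edges=[]), meta)
        assert summary.shared_all_groups == 0
        assert summary.per_group_exclusive == {"Antarctica": 2}

    def test_unknown_group_is_an_error(self):
        meta = META + [SampleRecord("x1", "x1", "", "Bacillus", False)]
        net = MolecularNetwork(nodes=[node(0, ["x1"])], edges=[])
        with pytest.raises(ValueError, match="x1"):
            attribute_groups(net, meta)

    def test_group_label_permutation_invariance(self):
        nodes = [node(0, ["a1"]), node(1, ["s1"]), node(2, ["a1", "s1"])]
        net = MolecularNetwork(nodes=nodes, edges=[])
        swapped = [
            SampleRecord(r.sample_id, r.strain_id,
                         {"Antarctica": "Scotland", "Scotland": "Antarctica"}.get(r.group, r.group),
                         r.genus, r.is_blank)
            for r in META
        ]
        a = attribute_groups(net, META)
        b = attribute_groups(net, swapped)
        assert a.per_group_exclusive["Antarctica"] == b.per_group_exclusive["Scotland"]
        assert a.shared_all_groups == b.shared_all_groups

    def test_from_counts_builds_percentages(self):
        summary = AttributionSummary.from_counts(
            per_group_exclusive={"A": 30, "B": 50}, shared=10, media=10
        )
        assert summary.total_nodes == 100
        assert summary.fractions == {
            "A": 30.0, "B": 50.0, "shared": 10.0, "media": 10.0,
            "exclusive_union": 80.0,
        }


class TestStrainSpecificity:
    def test_all_single_strain(self):
        nodes = [node(i, [s]) for i, s in enumerate(["a1", "a2", "s1"])]
        spec = strain_specificity(MolecularNetwork(nodes=nodes, edges=[]), META)
        assert spec.fraction_single_strain == 100.0
        assert spec.histogram == {1: 3}

    def test_histogram_conserves_non_media_nodes(self):
        nodes = [
            node(0, ["a1"]),
            node(1, ["a1", "s1"]),
            node(2, ["a1", "a2", "s1"]),
            node(3, ["b1"]),
        ]
        spec = strain_specificity(MolecularNetwork(nodes=nodes, edges=[]), META)
        assert sum(spec.histogram.values()) == 3
        assert spec.histogram == {1: 1, 2: 1, 3: 1}
        assert spec.fraction_single_strain == 25.0  # of all 4 nodes


class TestMassBins:
    def test_single_bin_concentration(self):
        nodes = [node(i, ["a1"], precursor=200.0) for i in range(10)]
        summary = mass_bins(MolecularNetwork(nodes=nodes, edges=[]))
        assert summary.bins[0][2] == 10
        assert summary.bins[0][3] == 100.0

    def test_upper_edge_inclusive(self):
        nodes = [node(0, ["a1"], 300.0), node(1, ["a1"], 300.5), node(2, ["a1"], 301.0)]
        summary = mass_bins(MolecularNetwork(nodes=nodes, edges=[]))
        assert summary.bins[0][2] == 1    # 300.0 -> 149-300
        assert summary.bins[1][2] == 2    # 300.5 and 301.0 -> 301-500

    def test_overflow_warned_and_counted(self):
        nodes = [node(0, ["a1"], 100.0), node(1, ["a1"], 200.0)]
        with pytest.warns(UserWarning):
            summary = mass_bins(MolecularNetwork(nodes=nodes, edges=[]))
        assert summary.overflow == 1

    def test_random_nodes_match_bruteforce(self, rng):
        precs = rng.uniform(150, 2558, 200)
        nodes = [node(i, ["a1"], float(p)) for i, p in enumerate(precs)]
        summary = mass_bins(MolecularNetwork(nodes=nodes, edges=[]))
        uppers = [300.0, 500.0, 1000.0, 2558.0]
        expected = [0, 0, 0, 0]
        for p in precs:
            for b, hi in enumerate(uppers):
                if p <= hi:
                    expected[b] += 1
                    break
        assert [b[2] for b in summary.bins] == expected


class TestGenusStats:
    def test_averages_and_counts(self):
        nodes = [
            node(0, ["a1"]),          # Bacillus
            node(1, ["a1", "s1"]),    # Bacillus x2 strains
            node(2, ["a2"]),          # Kocuria
        ]
        summary = genus_stats(MolecularNetwork(nodes=nodes, edges=[]), META)
        bac = summary.per_genus["Bacillus"]
        assert bac.strain_count == 2
        assert bac.node_count == 2
        assert bac.avg_per_strain == 1.0
        assert summary.per_genus["Kocuria"].node_count == 1
        assert summary.per_genus["Streptomyces"].node_count == 0

    def test_cross_genus_counts_three_or_more(self):
        nodes = [
            node(0, ["a1", "a2"]),          # 2 genera: not crossing
            node(1, ["a1", "a2", "s2"]),    # 3 genera: crossing
        ]
        summary = genus_stats(MolecularNetwork(nodes=nodes, edges=[]), META)
        assert summary.cross_genus_count == 1
        relaxed = genus_stats(
            MolecularNetwork(nodes=nodes, edges=[]), META, cross_genus_min=2
        )
        assert relaxed.cross_genus_count == 2

    def test_single_genus_cohort_never_crosses(self):
        meta = [SampleRecord(s, s, "G", "Bacillus", False) for s in ("x", "y", "z")]
        nodes = [node(0, ["x", "y", "z"])]
        summary = genus_stats(MolecularNetwork(nodes=nodes, edges=[]), meta)
        assert summary.cross_genus_count == 0

    def test_per_strain_average_rounding(self):
        assert per_strain_average(1349, 21) == 64.2
        assert per_strain_average(156, 2) == 78.0
        assert per_strain_average(0, 0) == 0.0


class TestRarefaction:
    def test_single_sample_point(self):
        curve = rarefaction({"s1": {1, 2, 3}}, n_permutations=5, seed=0)
        assert curve.points == ((1, 3.0, 0.0),)

    def test_identical_samples_flat_curve(self):
        curve = rarefaction({f"s{i}": {1, 2} for i in range(5)}, 20, seed=1)
        assert [m for _, m, _ in curve.points] == [2.0] * 5
        assert all(sd == 0.0 for _, _, sd in curve.points)

    def test_disjoint_samples_linear_curve(self):
        clusters = {f"s{i}": {10 * i + j for j in range(4)} for i in range(6)}
        curve = rarefaction(clusters, 10, seed=2)
        assert [m for _, m, _ in curve.points] == [4.0 * k for k in range(1, 7)]

    def test_mean_non_decreasing(self, small_run):
        from mznet.cohort_stats import sample_cluster_map

        curve = rarefaction(sample_cluster_map(small_run["net"]), 50, seed=3)
        means = [m for _, m, _ in curve.points]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_invalid_permutations(self):
        with pytest.raises(ValueError):
            rarefaction({"s1": {1}}, n_permutations=0)


class TestNeutralLoss:
    def test_carbonyl_loss_assignment(self):
        # antimycin-type fragment pair: loss of CO (27.99491 Da)
        out = neutral_loss_annotate([(265.081, 237.08704)], tol_da=0.005)
        assert out[0][3] == "CO"
        assert out[0][2] == pytest.approx(27.99396, abs=1e-5)

    def test_exact_water_loss(self):
        out = neutral_loss_annotate([(300.0, 281.98944)], tol_da=0.005)
        assert out[0][3] == "H2O"

    def test_unassigned_when_no_loss_matches(self):
        out = neutral_loss_annotate([(300.0, 250.0)], tol_da=0.005)
        assert out[0][3] == "unassigned"

    def test_extensible_loss_table(self):
        out = neutral_loss_annotate(
            [(400.0, 300.0)], tol_da=0.01, losses={"X": 100.0}
        )
        assert out[0][3] == "X"
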