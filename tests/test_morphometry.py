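"""SWC parsing, segment decomposition, the seven variables, timecourses."""

import numpy as np
import pytest

from pannpc import synth
from pannpc.morphometry import (
    DENDRITE_TYPE,
    SOMA_TYPE,
    MorphometricRecord,
    NeuronMorphology,
    Node,
    centrifugal_order,
    compute_metrics,
    crosssection_tests,
    read_spine_csv,
    read_swc,
    records_frame,
    segment_decomposition,
    timecourse_regression,
    write_spine_csv,
    write_swc,
)
from pannpc.presets import get_preset


def chain(*lengths, start_id=2, parent=1, x0=0.0):
    """Straight dendrite chain along +x with the given edge lengths."""
    nodes = []
    x = x0
    nid = start_id
    for L in lengths:
        x += L
        nodes.append(Node(nid, DENDRITE_TYPE, x, 0.0, 0.0, 0.5, parent))
        parent = nid
        nid += 1
    return nodes


def worked_example_tree():
    """Two trees: a bifurcated 10+(5,5) um tree and a single 20 um neurite."""
    soma = Node(1, SOMA_TYPE, 0.0, 0.0, 0.0, 5.0, -1)
    n2 = Node(2, DENDRITE_TYPE, 10.0, 0.0, 0.0, 0.5, 1)   # order-1 segment, 10 um
    n3 = Node(3, DENDRITE_TYPE, 10.0, 5.0, 0.0, 0.5, 2)   # daughter, 5 um
    n4 = Node(4, DENDRITE_TYPE, 10.0, -5.0, 0.0, 0.5, 2)  # daughter, 5 um
    n5 = Node(5, DENDRITE_TYPE, -20.0, 0.0, 0.0, 0.5, 1)  # second tree, 20 um
    return NeuronMorphology(
        nodes=[soma, n2, n3, n4, n5], soma_area=100.0, species="human"
    )


class TestSwcIO:
    def test_three_node_chain(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
        m = read_swc(p)
        assert m.root.id == 1
        assert len(m.nodes) == 3

    def test_parent_after_child_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 3\n3 3 20 0 0 1 1\n")
        with pytest.raises(ValueError, match="precede"):
            read_swc(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n2 3 20 0 0 1 1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_swc(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "mal.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 ten 0 0 1 1\n")
        with pytest.raises(ValueError, match=":2"):
            read_swc(p)

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_identity_on_generated_trees(self, tmp_path, seed):
        preset = get_preset("chimpanzee")
        m, _, _ = synth.gen_morphology(preset, week=3, seed=seed)
        path = tmp_path / f"n{seed}.swc"
        write_swc(m, path)
        back = read_swc(path)
        assert [n.id for n in back.nodes] == [n.id for n in m.nodes]
        assert [n.parent for n in back.nodes] == [n.parent for n in m.nodes]
        for a, b in zip(m.nodes, back.nodes):
            assert (a.x, a.y, a.z) == pytest.approx((b.x, b.y, b.z), rel=1e-5)

    def test_spine_sidecar_round_trip(self, tmp_path):
        spines = {1: 3, 2: 0, 4: 7}
        p = tmp_path / "spines.csv"
        write_spine_csv(spines, p)
        assert read_spine_csv(p) == spines


class TestCentrifugalOrder:
    def test_single_unbranched_neurite(self):
        m = NeuronMorphology(
            nodes=[Node(1, SOMA_TYPE, 0, 0, 0, 5, -1), *chain(10.0, 10.0)]
        )
        segs = centrifugal_order(m)
        assert len(segs) == 1
        assert segs[0].order == 1
        assert segs[0].length == pytest.approx(20.0)

    def test_one_bifurcation_orders_1_2_2(self):
        m = worked_example_tree()
        segs = centrifugal_order(m)
        by_first = {s.node_ids[0]: s.order for s in segs}
        assert by_first[2] == 1
        assert by_first[3] == 2 and by_first[4] == 2
        assert by_first[5] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_orders_equal_branch_count_oracle(self, seed):
        m, _, _ = synth.gen_morphology(get_preset("chimpanzee"), week=4, seed=seed)
        segs = segment_decomposition(m)
        children = m.children_map()
        parents = {n.id: n.parent for n in m.nodes}
        soma_ids = {n.id for n in m.nodes if n.type == SOMA_TYPE}

        def oracle_order(first_node):
            # walk to the soma counting branch points passed
            order = 1
            cur = parents[first_node]
            while cur not in soma_ids:
                if len(children.get(cur, [])) >= 2:
                    order += 1
                cur = parents[cur]
            return order

        for s in segs:
            assert s.order == oracle_order(s.node_ids[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_segments_partition_dendrite_nodes(self, seed):
        m, _, _ = synth.gen_morphology(get_preset("human"), week=7, seed=seed)
        segs = segment_decomposition(m)
        all_ids = [nid for s in segs for nid in s.node_ids]
        dendrite_ids = [n.id for n in m.nodes if n.type == DENDRITE_TYPE]
        assert sorted(all_ids) == sorted(dendrite_ids)


class TestMetrics:
    def test_worked_example_values(self):
        m = worked_example_tree()
        segs = segment_decomposition(m)
        spine_per_um = 8 / 40
        spines = {}
        remaining = 8
        for s in segs:  # deterministic 8 spines total
            k = round(spine_per_um * s.length)
            spines[s.segment_id] = min(k, remaining)
            remaining -= spines[s.segment_id]
        rec = compute_metrics(m, spines)
        assert rec.TDL == pytest.approx(40.0)
        assert rec.TREE == 2
        assert rec.DSC == 4
        assert rec.MSL == pytest.approx(10.0)
        assert rec.DSN == 8
        assert rec.DSD == pytest.approx(0.2)
        assert rec.SOMA == pytest.approx(100.0)

    def test_no_dendrites(self):
        m = NeuronMorphology(nodes=[Node(1, SOMA_TYPE, 0, 0, 0, 5, -1)], soma_area=50.0)
        rec = compute_metrics(m, {})
        assert rec.TDL == 0.0 and rec.DSD == 0.0 and rec.DSC == 0

    def test_spines_without_dendrite_rejected(self):
        m = NeuronMorphology(nodes=[Node(1, SOMA_TYPE, 0, 0, 0, 5, -1)])
        with pytest.raises(ValueError):
            compute_metrics(m, {1: 3})

    def test_unknown_segment_reference_rejected(self):
        m = worked_example_tree()
        with pytest.raises(ValueError, match="unknown segments"):
            compute_metrics(m, {99: 1})

    @pytest.mark.parametrize("seed", range(25))
    def test_identities_and_edge_sum_oracle(self, seed):
        preset = get_preset("chimpanzee" if seed % 2 else "human")
        m, spines, _ = synth.gen_morphology(preset, week=3 + (seed % 5), seed=seed)
        rec = compute_metrics(m, spines)
        assert rec.MSL * rec.DSC == pytest.approx(rec.TDL, abs=1e-9)
        assert rec.DSD * rec.TDL == pytest.approx(rec.DSN, abs=1e-9)
        assert rec.DSC >= rec.TREE
        # independent oracle: TDL = sum over dendrite nodes of edge to parent
        pos = {n.id: np.array([n.x, n.y, n.z]) for n in m.nodes}
        parents = {n.id: n.parent for n in m.nodes}
        oracle = sum(
            np.linalg.norm(pos[n.id] - pos[parents[n.id]])
            for n in m.nodes
            if n.type == DENDRITE_TYPE
        )
        assert rec.TDL == pytest.approx(oracle, abs=1e-6)

    def test_rigid_motion_invariance_and_scaling(self):
        m, spines, _ = synth.gen_morphology(get_preset("human"), week=6, seed=3)
        rec = compute_metrics(m, spines)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = [
            Node(n.id, n.type, *(R @ np.array([n.x, n.y, n.z]) + 5.0), n.radius, n.parent)
            for n in m.nodes
        ]
        rec2 = compute_metrics(NeuronMorphology(nodes=moved), spines)
        assert rec2.TDL == pytest.approx(rec.TDL, rel=1e-9)
        scaled = [
            Node(n.id, n.type, 2 * n.x, 2 * n.y, 2 * n.z, n.radius, n.parent)
            for n in m.nodes
        ]
        rec3 = compute_metrics(NeuronMorphology(nodes=scaled), spines)
        assert rec3.TDL == pytest.approx(2 * rec.TDL, rel=1e-9)


def make_records(spec):
    """spec: list of (species, week, variable values dict)."""
    out = []
    for i, (sp, wk, vals) in enumerate(spec):
        out.append(
            MorphometricRecord(
                SOMA=vals.get("SOMA", 100.0),
                TDL=vals.get("TDL", 100.0),
                TREE=3,
                DSC=4,
                MSL=vals.get("TDL", 100.0) / 4,
                DSN=vals.get("DSN", 10),
                DSD=vals.get("DSN", 10) / vals.get("TDL", 100.0),
                species=sp,
                weeks_pst=wk,
                cell_id=f"c{i}",
            )
        )
    return out


class TestTimecourse:
    def test_exact_linear_dsn(self):
        recs = make_records(
            [("human", w, {"DSN": int(7 * w)}) for w in (1, 2, 4, 6, 8) for _ in range(3)]
        )
        res = timecourse_regression(recs, "DSN")
        assert res.slope == pytest.approx(7.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_variable(self):
        recs = make_records([("human", w, {"TDL": 50.0}) for w in (1, 2, 4)])
        res = timecourse_regression(recs, "TDL")
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_needs_two_timepoints(self):
        recs = make_records([("human", 2, {}) for _ in range(5)])
        with pytest.raises(ValueError):
            timecourse_regression(recs, "TDL")

    def test_slope_coverage_on_noisy_data(self, rng):
        # 95% CI of the OLS slope covers the truth in >= 93/100 replicates
        from scipy.stats import t as tdist

        hits = 0
        weeks = np.repeat([1, 2, 4, 6, 8], 6)
        for _ in range(100):
            y = 12.0 * weeks + rng.normal(0, 20, len(weeks))
            res = timecourse_regression(
                make_records(
                    [("human", w, {"TDL": v}) for w, v in zip(weeks, y)]
                ),
                "TDL",
            )
            resid = y - (res.slope * weeks + res.intercept)
            se = np.sqrt(
                (resid @ resid)
                / (len(weeks) - 2)
                / ((weeks - weeks.mean()) @ (weeks - weeks.mean()))
            )
            tcrit = tdist.ppf(0.975, len(weeks) - 2)
            if abs(res.slope - 12.0) <= tcrit * se:
                hits += 1
        assert hits >= 93


class TestCrosssection:
    def test_identical_species_all_p_one(self):
        spec = []
        for w in (1, 2, 4):
            for sp in ("human", "chimpanzee"):
                spec += [(sp, w, {"TDL": v}) for v in (90.0, 100.0, 110.0)]
        results = crosssection_tests(make_records(spec), "TDL")
        species_tests = [r for r in results if "-vs-" in r.contrast and "@wk" in r.contrast]
        cross = [r for r in species_tests if "human-vs-chimpanzee" in r.contrast]
        assert cross and all(r.p == pytest.approx(1.0) for r in cross)

    def test_single_neuron_timepoint_skipped(self):
        spec = [("human", 1, {"TDL": 100.0})] + [
            ("chimpanzee", 1, {"TDL": v}) for v in (90.0, 95.0)
        ]
        results = crosssection_tests(make_records(spec), "TDL")
        assert any("skipped_insufficient_n" in r.flags for r in results)

    def test_planted_crossover_flips_sign(self, rng):
        # chimp ahead early, human ahead late
        spec = []
        for sp, early, late in (("human", 40.0, 200.0), ("chimpanzee", 80.0, 120.0)):
            for w, mu in ((2, early), (8, late)):
                spec += [(sp, w, {"TDL": mu + rng.normal(0, 5)}) for _ in range(8)]
        results = crosssection_tests(
            make_records(spec), "TDL", species_pair=("human", "chimpanzee")
        )
        by_week = {
            r.contrast: r.effect
            for r in results
            if "human-vs-chimpanzee" in r.contrast
        }
        assert by_week["TDL:human-vs-chimpanzee@wk2"] < 0
        assert by_week["TDL:human-vs-chimpanzee@wk8"] > 0

    def test_adjusted_p_never_below_raw(self):
        spec = []
        for w in (1, 2):
            for sp in ("human", "chimpanzee"):
                spec += [(sp, w, {"TDL": 100.0 + w * (sp == "human") * 10}) for _ in range(4)]
        results = crosssection_tests(make_records(spec), "TDL")
        for r in results:
            if r.p_adjusted is not None and np.isfinite(r.p):
                assert r.p_adjusted >= r.p
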