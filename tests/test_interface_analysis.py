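import numpy as np
import pytest

from pocketdyn.interface_analysis import (
    HBondCriteria,
    SubPocketDefinition,
    define_subpockets,
    hbond_occupancy,
    merge_definitions,
    pocket_average,
)
from pocketdyn.synthetic_data import PocketPlan, gen_interface_ensemble
from pocketdyn.trajectory_io import FrameEnsemble, ResidueID, Topology

from oracles import brute_force_pockets


def complex_from_atoms(atoms):
    """Build a single-frame complex; atoms = [(chain, resnum, name, element, xyz)]."""
    atom_names, elements, res_index, residues, coords = [], [], [], [], []
    index = {}
    for chain, num, name, el, xyz in atoms:
        rid = ResidueID(chain, num, "", "GLY")
        if rid not in index:
            index[rid] = len(residues)
            residues.append(rid)
        atom_names.append(name)
        elements.append(el)
        res_index.append(index[rid])
        coords.append(xyz)
    topo = Topology(np.array(atom_names, dtype=object), np.array(elements, dtype=object),
                    np.array(res_index), residues)
    return FrameEnsemble(topo, np.asarray(coords, dtype=float)[None])


class TestDefineSubpockets:
    @pytest.fixture
    def toy(self):
        # peptide residues P1/P2 on chain P; one protease residue 3.4 Å from
        # the P1 atom and 3.6 Å from the P2 atom
        return complex_from_atoms([
            ("P", 1, "CA", "C", [0.0, 0.0, 0.0]),
            ("P", 2, "CA", "C", [0.2, 0.0, 0.0]),
            ("E", 10, "CA", "C", [3.6, 0.0, 0.0]),
            ("E", 11, "CA", "C", [50.0, 0.0, 0.0]),
        ])

    @pytest.fixture
    def position_map(self):
        return {ResidueID("P", 1): "P1", ResidueID("P", 2): "P2"}

    def test_cutoff_boundary(self, toy, position_map):
        pockets = define_subpockets(toy, "P", position_map, cutoff=3.5)
        assert pockets.pockets["S1"] == set()
        assert pockets.pockets["S2"] == {ResidueID("E", 10)}

    def test_degenerate_cutoff_all_empty_flagged(self, toy, position_map, caplog):
        with caplog.at_level("WARNING"):
            pockets = define_subpockets(toy, "P", position_map, cutoff=0.1)
        assert all(not resis for resis in pockets.pockets.values())
        assert "S1" in pockets.empty_pockets and "S2" in pockets.empty_pockets

    def test_absent_peptide_residue_hard_error(self, toy):
        with pytest.raises(ValueError, match="absent"):
            define_subpockets(toy, "P", {ResidueID("P", 9): "P1"})

    def test_matches_brute_force_scan(self):
        plans = {"S1": PocketPlan(2, 1, 2, 0.5), "S3": PocketPlan(1, 2, 0, 0.0),
                 "S6": PocketPlan(1, 0, 1, 1.0)}
        gen = gen_interface_ensemble(plans, n_frames=3, seed=21)
        pockets = define_subpockets(gen.ensemble, gen.peptide_chain, gen.position_map)
        topo = gen.ensemble.topology
        oracle = brute_force_pockets(
            gen.ensemble.coordinates[0], topo.atom_residue_index, topo.residues,
            None, gen.peptide_chain, gen.position_map, 3.5)
        for lab, resis in oracle.items():
            assert pockets.pockets[lab] == resis
        # and the generator's planted truth agrees
        for lab in plans:
            assert pockets.pockets[lab] == gen.pockets_truth.pockets[lab]

    def test_rigid_motion_invariance(self):
        gen = gen_interface_ensemble({"S1": PocketPlan(1, 1, 1, 1.0)}, 2, seed=4)
        before = define_subpockets(gen.ensemble, gen.peptide_chain, gen.position_map)
        t = np.radians(37.0)
        rot = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        moved = FrameEnsemble(gen.ensemble.topology,
                              gen.ensemble.coordinates @ rot.T + [5.0, -3.0, 8.0])
        after = define_subpockets(moved, gen.peptide_chain, gen.position_map)
        assert before.pockets == after.pockets


class TestMergeDefinitions:
    def pockets(self, **kwargs):
        return SubPocketDefinition(
            pockets={lab: {ResidueID("E", n) for n in nums} for lab, nums in kwargs.items()},
            source_complexes=["x"])

    def test_idempotence(self):
        a = self.pockets(S1={1, 2, 3}, S2={4})
        merged = merge_definitions(a, a)
        assert merged.pockets == a.pockets

    def test_disjoint_union(self):
        a = self.pockets(S1={1, 2, 3})
        b = self.pockets(S1={4, 5})
        assert len(merge_definitions(a, b).pockets["S1"]) == 5

    def test_overlap_set_arithmetic(self):
        sa, sb = {1, 2, 3, 4}, {3, 4, 5}
        a, b = self.pockets(S1=sa), self.pockets(S1=sb)
        merged = merge_definitions(a, b).pockets["S1"]
        assert len(merged) == len(sa) + len(sb) - len(sa & sb)
        assert merged == {ResidueID("E", n) for n in sa | sb}

    def test_label_mismatch_hard_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            merge_definitions(self.pockets(S1={1}), self.pockets(S2={1}))


def hbond_toy(no_distance, deviation_deg):
    """Single protease N-H donor vs peptide O acceptor at given geometry.

    The N-H bond is tilted off the N→O axis until the D-H···A angle deviates
    from linearity by exactly ``deviation_deg`` (solved by bisection).
    """
    n_pos = np.array([0.0, 0.0, 0.0])
    o_pos = np.array([no_distance, 0.0, 0.0])

    def deviation_of(alpha):
        h = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        v1, v2 = n_pos - h, o_pos - h
        angle = np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        return 180.0 - angle

    lo, hi = 0.0, np.radians(85.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if deviation_of(mid) < deviation_deg:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    h_pos = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    ens = complex_from_atoms([
        ("E", 1, "N", "N", n_pos),
        ("E", 1, "H", "H", h_pos),
        ("E", 1, "CA", "C", [-1.5, 0.0, 0.0]),
        ("P", 1, "O", "O", o_pos),
        ("P", 1, "C", "C", [no_distance + 1.2, 0.0, 0.0]),
    ])
    pockets = SubPocketDefinition(pockets={"S1": {ResidueID("E", 1)}})
    return ens, pockets


class TestHbondOccupancy:
    @pytest.mark.parametrize(
        "distance, deviation, expected",
        [
            (2.9, 0.0, 1.0),  # ideal collinear geometry
            (3.1, 0.0, 0.0),  # distance cutoff
            (2.8, 50.0, 0.0),  # angle cutoff
            (2.8, 40.0, 1.0),
        ],
    )
    def test_threshold_classification(self, distance, deviation, expected):
        ens, pockets = hbond_toy(distance, deviation)
        table = hbond_occupancy(ens, pockets, "P")
        assert table.value_by_pocket["S1"] == pytest.approx(expected)

    def test_no_polar_hydrogens_hard_error(self):
        ens = complex_from_atoms([
            ("E", 1, "N", "N", [0.0, 0.0, 0.0]),
            ("P", 1, "O", "O", [2.9, 0.0, 0.0]),
        ])
        pockets = SubPocketDefinition(pockets={"S1": {ResidueID("E", 1)}})
        with pytest.raises(ValueError, match="protonated"):
            hbond_occupancy(ens, pockets, "P")

    def test_monotone_in_criteria(self):
        plans = {"S1": PocketPlan(1, 0, 3, 0.7), "S6": PocketPlan(1, 0, 1, 0.4)}
        gen = gen_interface_ensemble(plans, 500, seed=8)
        loose = hbond_occupancy(gen.ensemble, gen.pockets_truth, gen.peptide_chain,
                                HBondCriteria(3.5, 60.0))
        default = hbond_occupancy(gen.ensemble, gen.pockets_truth, gen.peptide_chain)
        strict = hbond_occupancy(gen.ensemble, gen.pockets_truth, gen.peptide_chain,
                                 HBondCriteria(2.5, 20.0))
        for lab in plans:
            assert loose.value_by_pocket[lab] >= default.value_by_pocket[lab]
            assert default.value_by_pocket[lab] >= strict.value_by_pocket[lab]

    def test_planted_fraction_recovered(self):
        m = 5000
        gen = gen_interface_ensemble({"S2": PocketPlan(0, 0, 1, 0.6)}, m, seed=13)
        table = hbond_occupancy(gen.ensemble, gen.pockets_truth, gen.peptide_chain)
        assert table.value_by_pocket["S2"] == pytest.approx(0.6, abs=1.0 / np.sqrt(m))


class TestPocketAverage:
    def test_single_residue_pocket(self):
        pockets = SubPocketDefinition(pockets={"S1": {ResidueID("E", 1)}})
        table = pocket_average({ResidueID("E", 1): 7.5}, pockets)
        assert table.value_by_pocket["S1"] == 7.5

    def test_arithmetic_mean(self):
        pockets = SubPocketDefinition(
            pockets={"S1": {ResidueID("E", 10), ResidueID("E", 20), ResidueID("E", 30)}})
        metric = {ResidueID("E", 10): 1.0, ResidueID("E", 20): 2.0, ResidueID("E", 30): 6.0}
        assert pocket_average(metric, pockets).value_by_pocket["S1"] == pytest.approx(3.0)

    def test_matches_explicit_loop(self, rng):
        residues = [ResidueID("E", n) for n in range(1, 21)]
        metric = {r: float(v) for r, v in zip(residues, rng.normal(size=20))}
        pockets = SubPocketDefinition(pockets={
            "S1": set(residues[:7]), "S2": set(residues[5:12]), "S3": set(residues[12:])})
        table = pocket_average(metric, pockets)
        for lab, resis in pockets.pockets.items():
            total, count = 0.0, 0
            for r in resis:
                total += metric[r]
                count += 1
            assert table.value_by_pocket[lab] == pytest.approx(total / count, rel=1e-12)

    def test_mean_within_min_max(self, rng):
        residues = [ResidueID("E", n) for n in range(12)]
        metric = {r: float(v) for r, v in zip(residues, rng.normal(size=12))}
        pockets = SubPocketDefinition(pockets={"S1": set(residues[:5]), "S2": set(residues[5:])})
        table = pocket_average(metric, pockets)
        for lab, resis in pockets.pockets.items():
            vals = [metric[r] for r in resis]
            assert min(vals) <= table.value_by_pocket[lab] <= max(vals)

    def test_uncovered_pocket_flagged_not_zero(self, caplog):
        pockets = SubPocketDefinition(
            pockets={"S1": {ResidueID("E", 1)}, "S2": {ResidueID("E", 2)}})
        with caplog.at_level("WARNING"):
            table = pocket_average({ResidueID("E", 1): 3.0}, pockets)
        assert np.isnan(table.value_by_pocket["S2"])
        assert table.missing_pockets == ["S2"]
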