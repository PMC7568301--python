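"""Structure parsing and geometry: planted features, rigid invariance."""

import numpy as np
import pandas as pd
import pytest

from hydrolase_duo.structure import (
    ParseError,
    Structure,
    distance_stats,
    find_disulfides,
    read_models,
    read_structure,
    residue_min_distance,
    trajectory_distances,
    triad_geometry,
    write_structure,
)
from hydrolase_duo.synth import (
    ToyStructureSpec,
    gen_distance_models,
    gen_distance_trajectory,
    gen_toy_structure,
)


class TestReadWrite:
    def test_round_trip_preserves_atoms(self, toy_structure):
        text = write_structure(toy_structure)
        back = read_structure(text)
        assert back.n_atoms == toy_structure.n_atoms
        a = toy_structure.atoms.sort_values("serial")
        b = back.atoms.sort_values("serial")
        assert list(a["name"]) == list(b["name"])
        assert np.allclose(a[["x", "y", "z"]].to_numpy(),
                           b[["x", "y", "z"]].to_numpy(), atol=1.5e-3)

    def test_model_selection_from_multimodel_file(self):
        models = gen_distance_models(n_frames=3, seed=1)
        text = write_structure(models)
        st2 = read_structure(text, model=2)
        assert st2.model_id == 2
        assert st2.n_atoms == 2
        with pytest.raises(KeyError, match="model 9"):
            read_structure(text, model=9)

    def test_highest_occupancy_altloc_kept_tie_breaks_to_a(self):
        pdb = "\n".join([
            "ATOM      1  CA AALA A   1      0.000   0.000   0.000  0.60 10.00           C",
            "ATOM      2  CA BALA A   1      1.000   0.000   0.000  0.40 10.00           C",
            "ATOM      3  CB BALA A   1      2.000   0.000   0.000  0.50 10.00           C",
            "ATOM      4  CB AALA A   1      3.000   0.000   0.000  0.50 10.00           C",
            "END",
        ])
        st = read_structure(pdb)
        ca = st.atoms[st.atoms["name"] == "CA"]
        cb = st.atoms[st.atoms["name"] == "CB"]
        assert len(ca) == 1 and ca.iloc[0]["x"] == 0.0  # higher occupancy
        assert len(cb) == 1 and cb.iloc[0]["altloc"] == "A"  # tie -> 'A'

    def test_garbage_content_raises_parse_error(self):
        with pytest.raises(ParseError):
            read_structure("ATOM this is not fixed width\nbroken\n")

    def test_clashing_serials_rejected_on_write(self, toy_structure):
        atoms = toy_structure.atoms.copy()
        atoms.loc[atoms.index[1], "serial"] = atoms.iloc[0]["serial"]
        with pytest.raises(ValueError, match="serial"):
            write_structure(Structure(atoms=atoms))

    def test_empty_feature_spec_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            ToyStructureSpec(disulfide_distances=(), triad=False, linkage=False)


class TestDisulfides:
    def test_planted_pairs_detected_exactly(self, toy_structure):
        bonds = find_disulfides(toy_structure)
        assert len(bonds) == 5
        assert [(b.cys_a[1], b.cys_b[1]) for b in bonds] == \
            toy_structure.planted_disulfides
        assert all(b.distance == pytest.approx(2.05, abs=1e-6) for b in bonds)

    def test_cutoff_boundary_is_strict_less_equal(self):
        st = gen_toy_structure(ToyStructureSpec(disulfide_distances=(2.31,),
                                                triad=False, linkage=False))
        assert find_disulfides(st, cutoff=2.3) == []
        assert len(find_disulfides(st, cutoff=2.31)) == 1

    def test_each_cysteine_in_at_most_one_bond(self):
        # three colinear CYS SG atoms 2.0 apart: greedy pairing keeps one bond
        rows = []
        for i, x in enumerate((0.0, 2.0, 4.0), start=1):
            rows.append((2 * i - 1, "CB", "C", "", 1.0, "CYS", i, "A", x, 1.5, 0.0))
            rows.append((2 * i, "SG", "S", "", 1.0, "CYS", i, "A", x, 0.0, 0.0))
        st = Structure(atoms=pd.DataFrame(
            rows, columns=["serial", "name", "element", "altloc", "occupancy",
                           "resname", "resseq", "chain", "x", "y", "z"]))
        bonds = find_disulfides(st, cutoff=2.3)
        assert len(bonds) == 1
        seen = [b.cys_a for b in bonds] + [b.cys_b for b in bonds]
        assert len(seen) == len(set(seen))

    def test_cysteine_without_sg_warned_and_skipped(self):
        rows = [(1, "CB", "C", "", 1.0, "CYS", 1, "A", 0.0, 0.0, 0.0)]
        st = Structure(atoms=pd.DataFrame(
            rows, columns=["serial", "name", "element", "altloc", "occupancy",
                           "resname", "resseq", "chain", "x", "y", "z"]))
        with pytest.warns(UserWarning, match="no SG"):
            assert find_disulfides(st) == []


class TestTriad:
    def test_planted_geometry_reported_to_two_decimals(self, toy_structure):
        ser, his, asp = toy_structure.planted_triad
        tg = triad_geometry(toy_structure, ("A", ser), ("A", his), ("A", asp))
        assert tg.ser_og_his_ne2 == 2.80
        assert tg.his_nd1_asp_od == 2.70
        assert tg.ser_his_bonded and tg.his_asp_bonded

    def test_stretched_triad_flagged_not_bonded(self):
        st = gen_toy_structure(ToyStructureSpec(disulfide_distances=(),
                                                ser_og_his_ne2=6.0, linkage=False))
        ser, his, asp = st.planted_triad
        tg = triad_geometry(st, ("A", ser), ("A", his), ("A", asp))
        assert tg.ser_og_his_ne2 == 6.0
        assert not tg.ser_his_bonded

    def test_wrong_residue_type_rejected(self, toy_structure):
        ser, his, asp = toy_structure.planted_triad
        with pytest.raises(TypeError, match="expected SER"):
            triad_geometry(toy_structure, ("A", his), ("A", his), ("A", asp))


class TestMinDistance:
    def test_planted_main_chain_linkage(self, toy_structure):
        tyr, ala = toy_structure.planted_linkage
        d, pair = residue_min_distance(toy_structure, ("A", tyr), ("A", ala),
                                       "main-chain")
        assert d == 2.90
        assert pair == ("O", "N")

    def test_self_distance_rejected(self, toy_structure):
        tyr, _ = toy_structure.planted_linkage
        with pytest.raises(ValueError, match="undefined"):
            residue_min_distance(toy_structure, ("A", tyr), ("A", tyr))

    def test_unknown_selector_rejected(self, toy_structure):
        tyr, ala = toy_structure.planted_linkage
        with pytest.raises(ValueError, match="subset"):
            residue_min_distance(toy_structure, ("A", tyr), ("A", ala), "backbone")


class TestRigidInvariance:
    def test_all_distance_operations_invariant(self, toy_structure, rigid_transform):
        rot, trans = rigid_transform
        moved = toy_structure.transformed(rot, trans)
        moved.planted_triad = toy_structure.planted_triad
        bonds_a = find_disulfides(toy_structure)
        bonds_b = find_disulfides(moved)
        assert [b.distance for b in bonds_a] == pytest.approx(
            [b.distance for b in bonds_b], abs=1e-9)
        ser, his, asp = toy_structure.planted_triad
        ta = triad_geometry(toy_structure, ("A", ser), ("A", his), ("A", asp))
        tb = triad_geometry(moved, ("A", ser), ("A", his), ("A", asp))
        assert ta.ser_og_his_ne2 == tb.ser_og_his_ne2
        tyr, ala = toy_structure.planted_linkage
        da, _ = residue_min_distance(toy_structure, ("A", tyr), ("A", ala), "main-chain")
        db, _ = residue_min_distance(moved, ("A", tyr), ("A", ala), "main-chain")
        assert da == db

    def test_min_distance_symmetric_in_arguments(self, toy_structure):
        tyr, ala = toy_structure.planted_linkage
        da, _ = residue_min_distance(toy_structure, ("A", tyr), ("A", ala))
        db, _ = residue_min_distance(toy_structure, ("A", ala), ("A", tyr))
        assert da == db


class TestDistanceStats:
    def test_normal_trace_moments_recovered(self):
        series = gen_distance_trajectory(mean=2.0, sd=0.2, n_frames=10_000, seed=4)
        stats = distance_stats(series)
        assert stats.mean == pytest.approx(2.0, abs=0.01)
        assert stats.sd == pytest.approx(0.2, abs=0.01)
        assert stats.occupancy == 1.0  # all frames well under 3.5 Å

    def test_constant_series_zero_sd_binary_occupancy(self):
        stats = distance_stats(np.full(100, 4.0))
        assert stats.sd == 0.0
        assert stats.occupancy == 0.0
        assert distance_stats(np.full(100, 2.0)).occupancy == 1.0

    def test_threshold_below_minimum_gives_zero_occupancy(self):
        series = gen_distance_trajectory(mean=2.0, sd=0.05, n_frames=500, seed=1)
        assert distance_stats(series, threshold=1.0).occupancy == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            distance_stats(np.array([2.0]))

    def test_trajectory_pair_distances_from_multimodel(self):
        models = gen_distance_models(mean=2.0, sd=0.2, n_frames=400, seed=9)
        text = write_structure(models)
        series = trajectory_distances(read_models(text), (("A", 1), "OG"),
                                      (("A", 2), "NE2"))
        stats = distance_stats(series)
        assert stats.mean == pytest.approx(2.0, abs=0.05)
        assert stats.sd == pytest.approx(0.2, abs=0.05)
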