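"""Fragment extraction, torsion profiles, clustering, spans, surveys."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import slimdock as sd
from slimdock.fragments import (
    ClusterConfig,
    DihedralProfile,
    Fragment,
    backbone_dihedrals,
    cluster_fragments,
    dihedral_distance,
    endpoint_span,
    extract_fragments,
    filter_by_span,
    mn_phosphate_survey,
    pairwise_dihedral_distances,
    select_reference,
)
from slimdock.synthetic import build_peptide, gen_conformer_library

from conftest import dbscan_oracle


def _extended(n):
    return np.tile([-139.0, 135.0, 180.0], (n, 1))


def _anchor_fragment(oe, nh):
    """Marked-atoms-only pseudo fragment for span arithmetic."""
    return Fragment(
        "pseudo", "A", "1", "2", "ER", 0, 2,
        np.empty((0, 4, 3)), np.empty((0, 3)),
        marked_atoms={"GLU_OE": np.asarray(oe, float), "ARG_NH": np.asarray(nh, float)},
    )


class TestExtraction:
    def test_core_motif_with_flanks(self):
        st_ = build_peptide(_extended(6), "AHPRVG")
        frags = extract_fragments([st_], "xHPRVx")
        assert len(frags) == 1
        f = frags[0]
        assert f.sequence == "AHPRVG"
        assert (f.core_start, f.core_end) == (1, 5)
        assert "ARG_NH" in f.marked_atoms

    def test_terminal_motif_without_flank_excluded(self):
        st_ = build_peptide(_extended(5), "HPRVG")  # motif starts at the terminus
        assert extract_fragments([st_], "xHPRVx") == []

    def test_missing_backbone_atom_rejects_fragment(self):
        st_ = build_peptide(_extended(6), "AHPRVG")
        chain = st_[0]["A"]
        res = chain[2]
        for i in range(len(res)):
            if res[i].name == "CA":
                del res[i]
                break
        assert extract_fragments([st_], "xHPRVx") == []

    def test_chain_break_rejects_fragment(self):
        st_ = build_peptide(_extended(6), "AHPRVG")
        for atom in st_[0]["A"][3]:
            atom.pos = type(atom.pos)(atom.pos.x + 50, atom.pos.y, atom.pos.z)
        assert extract_fragments([st_], "xHPRVx") == []


class TestDihedrals:
    def test_builder_roundtrip_exact(self):
        rng = np.random.default_rng(11)
        n = 8
        dih = np.column_stack(
            [
                rng.uniform(-179, 180, n),
                rng.uniform(-179, 180, n),
                rng.uniform(120, 180, n) * rng.choice([-1, 1], n),
            ]
        )
        st_ = build_peptide(dih, "AEAHPRVA")
        frag = extract_fragments([st_], "xEAHPRVx")[0]
        prof = backbone_dihedrals(frag)
        got = prof.angles()
        want = dih.copy()
        want[0, 0] = np.nan
        want[-1, 1:] = np.nan
        mask = ~np.isnan(want)
        from slimdock.geometry import circular_difference

        assert np.max(circular_difference(got[mask], want[mask])) < 1e-6

    def test_terminal_angles_undefined(self):
        st_ = build_peptide(_extended(4), "AHPR")
        prof = backbone_dihedrals(extract_fragments([st_], "xHPR")[0])
        assert np.isnan(prof.phi[0])
        assert np.isnan(prof.psi[-1]) and np.isnan(prof.omega[-1])

    def test_cis_omega_recovered(self):
        dih = _extended(4)
        dih[:, 2] = 0.0  # cis peptide bonds
        st_ = build_peptide(dih, "AHPR")
        prof = backbone_dihedrals(extract_fragments([st_], "xHPR")[0])
        assert abs(prof.omega[0]) < 1e-6

    def test_profile_invariant_under_rigid_motion(self):
        st_ = build_peptide(_extended(6), "AHPRVG")
        frag = extract_fragments([st_], "xHPRVx")[0]
        prof = backbone_dihedrals(frag)
        rng = np.random.default_rng(3)
        from slimdock.geometry import RigidTransform
        from slimdock.synthetic import _random_rotation

        moved = frag.transformed(
            RigidTransform(_random_rotation(rng), rng.uniform(-30, 30, 3))
        )
        prof2 = backbone_dihedrals(moved)
        for a, b in ((prof.phi, prof2.phi), (prof.psi, prof2.psi), (prof.omega, prof2.omega)):
            mask = ~np.isnan(a)
            from slimdock.geometry import circular_difference

            assert np.max(circular_difference(a[mask], b[mask])) < 1e-6


class TestDihedralDistance:
    def _profile(self, arr):
        arr = np.asarray(arr, float)
        return DihedralProfile(arr[:, 0], arr[:, 1], arr[:, 2])

    def test_identity_and_single_angle(self):
        a = self._profile([[10, 20, 180], [30, 40, 180]])
        assert dihedral_distance(a, a, core_only=False) == 0.0
        b = self._profile([[10, 50, 180], [30, 40, 180]])
        assert dihedral_distance(a, b, core_only=False) == pytest.approx(30.0)

    def test_circular_wrap(self):
        a = self._profile([[179.0, 0, 180]])
        b = self._profile([[-179.0, 0, 180]])
        assert dihedral_distance(a, b, core_only=False) == pytest.approx(2.0)

    def test_no_comparable_pair_is_error(self):
        a = DihedralProfile(np.array([np.nan]), np.array([np.nan]), np.array([np.nan]))
        with pytest.raises(ValueError):
            dihedral_distance(a, a, core_only=False)

    @given(st.integers(0, 2_000))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        profs = [
            self._profile(rng.uniform(-180, 180, (3, 3))) for _ in range(3)
        ]
        a, b, c = profs
        dab = dihedral_distance(a, b, core_only=False)
        dba = dihedral_distance(b, a, core_only=False)
        dac = dihedral_distance(a, c, core_only=False)
        dcb = dihedral_distance(c, b, core_only=False)
        assert dab == pytest.approx(dba)
        assert 0.0 <= dab <= 180.0
        assert dab <= dac + dcb + 1e-9  # max of circular metrics


class TestClustering:
    def test_planted_clusters_recovered(self):
        centers = [
            np.tile([-60.0, -45.0, 180.0], (6, 1)),
            np.tile([-139.0, 135.0, 180.0], (6, 1)),
        ]
        structures, truth = gen_conformer_library(centers, 6, 5.0, "AHPRVA", seed=1)
        frags = extract_fragments(structures, "xHPRVx")
        assert len(frags) == 12
        profiles = [backbone_dihedrals(f) for f in frags]
        labels = cluster_fragments(frags, profiles, ClusterConfig(eps=30.0, min_pts=3))
        true_labels = [m["cluster"] for m in truth.records["members"]]
        assert set(labels) == {0, 1}
        assert adjusted_rand_score(true_labels, labels) == 1.0

    def test_identical_fragments_one_cluster(self):
        st_ = build_peptide(_extended(6), "AHPRVG")
        frags = extract_fragments([st_], "xHPRVx") * 5
        profiles = [backbone_dihedrals(f) for f in frags]
        labels = cluster_fragments(frags, profiles, ClusterConfig(eps=30, min_pts=3))
        assert set(labels) == {0}

    def test_isolated_fragment_is_noise(self):
        centers = [np.tile([-60.0, -45.0, 180.0], (6, 1))]
        structures, _ = gen_conformer_library(centers, 1, 0.0, "AHPRVA", seed=2)
        frags = extract_fragments(structures, "xHPRVx")
        profiles = [backbone_dihedrals(f) for f in frags]
        labels = cluster_fragments(frags, profiles, ClusterConfig(eps=30, min_pts=3))
        assert list(labels) == [-1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ClusterConfig(eps=-1.0)
        with pytest.raises(ValueError):
            ClusterConfig(min_pts=0)

    def test_matches_definitional_oracle(self):
        """DBSCAN labels agree with the neighborhoods/core/connectivity definition."""
        rng = np.random.default_rng(9)
        profs = [
            DihedralProfile(*rng.uniform(-180, 180, (3, 4)))
            for _ in range(40)
        ]
        frags = [None] * len(profs)
        D = pairwise_dihedral_distances(profs, core_only=False)
        eps, min_pts = 90.0, 4
        labels = cluster_fragments(
            ["f"] * len(profs), profs, ClusterConfig(eps, min_pts), core_only=False
        )
        core, components = dbscan_oracle(D, eps, min_pts)
        # core points: exactly one component each, labels consistent
        comp_of = {}
        for k, comp in enumerate(components):
            for i in comp:
                comp_of[i] = k
        for i in range(len(profs)):
            if core[i]:
                assert labels[i] != -1
                # same component <=> same sklearn label
                for j in range(len(profs)):
                    if core[j]:
                        assert (comp_of[i] == comp_of[j]) == (labels[i] == labels[j])
            elif labels[i] != -1:
                # border point: must neighbor a core point carrying its label
                ok = any(
                    core[j] and labels[j] == labels[i] and D[i, j] <= eps
                    for j in range(len(profs))
                )
                assert ok
            else:
                # noise: no core point within eps
                assert not any(core[j] and D[i, j] <= eps for j in range(len(profs)))


class TestReferenceSelection:
    def _frag(self, fid, resolution):
        return Fragment(
            fid, "A", "1", "6", "AHPRVG", 1, 5,
            np.zeros((6, 4, 3)), np.zeros((6, 3)), resolution=resolution,
        )

    def test_best_resolution_in_largest_cluster(self):
        frags = [self._frag(f"s{i}", r) for i, r in enumerate([2.0, 1.75, 2.5, 3.0])]
        labels = np.array([0, 0, 0, -1])
        assert select_reference(labels, frags).resolution == 1.75

    def test_equal_size_tie_broken_by_resolution_then_id(self):
        frags = [
            self._frag("a1", 2.0), self._frag("a2", 2.2),
            self._frag("b1", 1.6), self._frag("b2", 2.9),
        ]
        labels = np.array([0, 0, 1, 1])
        assert select_reference(labels, frags).structure_id == "b1"

    def test_missing_resolution_ranks_last(self):
        frags = [self._frag("nmr", None), self._frag("xray", 2.8)]
        labels = np.array([0, 0])
        assert select_reference(labels, frags).structure_id == "xray"

    def test_all_noise_is_error(self):
        with pytest.raises(ValueError):
            select_reference(np.array([-1, -1]), [self._frag("a", 2.0)] * 2)


class TestSpan:
    def test_min_pair_distance(self):
        f = _anchor_fragment([[0, 0, 0], [1, 0, 0]], [[20, 0, 0], [21, 0, 0]])
        assert endpoint_span(f) == pytest.approx(19.0)
        assert endpoint_span(f, mode="max") == pytest.approx(21.0)

    def test_coincident_atoms(self):
        f = _anchor_fragment([[1, 1, 1]], [[1, 1, 1]])
        assert endpoint_span(f) == 0.0

    def test_missing_marked_atoms_is_error(self):
        f = _anchor_fragment([[0, 0, 0]], [[1, 0, 0]])
        del f.marked_atoms["ARG_NH"]
        with pytest.raises(ValueError):
            endpoint_span(f)

    def test_filter_boundary_inclusive_and_order_preserving(self):
        frags = [
            _anchor_fragment([[0, 0, 0]], [[s, 0, 0]]) for s in (15.0, 20.0, 25.0)
        ]
        kept = filter_by_span(frags, 20.0)
        assert [endpoint_span(f) for f in kept] == [20.0, 25.0]
        assert filter_by_span(frags, 0.0) == frags
        assert filter_by_span(kept, 20.0) == kept  # idempotent


class TestSurvey:
    def _structure(self, name, mn_positions, oxy_positions):
        import gemmi

        st_ = gemmi.Structure()
        st_.name = name
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i, pos in enumerate(mn_positions):
            res = gemmi.Residue()
            res.name = "MN"
            res.seqid = gemmi.SeqId(100 + i, " ")
            atom = gemmi.Atom()
            atom.name = "MN"
            atom.element = gemmi.Element("Mn")
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
            chain.add_residue(res)
        res = gemmi.Residue()
        res.name = "PO4"
        res.seqid = gemmi.SeqId(200, " ")
        for j, pos in enumerate(oxy_positions):
            atom = gemmi.Atom()
            atom.name = f"O{j + 1}"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st_.add_model(model)
        return st_

    def test_shortest_distance_per_ion(self):
        st_ = self._structure(
            "one", [[0, 0, 0]],
            [[2.1, 0, 0], [0, 2.6, 0], [0, 0, 3.0], [3.3, 0, 0]],
        )
        result = mn_phosphate_survey([st_])
        assert result.per_ion[0][1] == pytest.approx(2.1)

    def test_mean_and_population_sd(self):
        st_ = self._structure(
            "two", [[0, 0, 0], [10, 0, 0]],
            [[2.0, 0, 0], [10, 2.8, 0]],
        )
        result = mn_phosphate_survey([st_])
        assert result.mean == pytest.approx(2.4)
        assert result.sd == pytest.approx(0.4)  # population convention

    def test_structures_without_pair_skipped(self):
        good = self._structure("good", [[0, 0, 0]], [[2.2, 0, 0]])
        bad = self._structure("bad", [], [[2.2, 0, 0]])
        with pytest.warns(UserWarning, match="skipped"):
            result = mn_phosphate_survey([good, bad])
        assert result.skipped == ["bad"]
        with pytest.raises(ValueError):
            mn_phosphate_survey([bad])
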