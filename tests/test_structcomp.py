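import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import oracles
from epimap import (
    GlobuleSpec,
    cys_pair_distances,
    kabsch_superpose,
    make_globule,
    pairwise_structure_rmsd,
    sequence_charge,
)
from epimap.structcomp import GeometryError, superpose_chains
from epimap.structio import Atom, Chain, Residue, Structure


def _ca_structure(coords, names=None, sid="toy"):
    chain = Chain(id="A")
    for i, c in enumerate(coords):
        name = (names or {}).get(i, "ALA")
        chain.residues.append(
            Residue(number=i + 1, icode="", name=name,
                    atoms=[Atom(name="CA", element="C", x=c[0], y=c[1], z=c[2])])
        )
    return Structure(id=sid, chains=[chain])


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        x = rng.normal(size=(20, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.rotation == pytest.approx(np.eye(3), abs=1e-9)

    def test_recovers_planted_rigid_transform(self, rng):
        x = rng.normal(scale=5.0, size=(50, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        y = x @ rot.T + np.array([4.0, -2.0, 9.0])
        res = kabsch_superpose(x, y)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.transform(y) == pytest.approx(x, abs=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_fit_matches_numeric_minimisation(self, rng):
        x = rng.normal(scale=5.0, size=(100, 3))
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        y = x @ rot.T + rng.normal(scale=0.5, size=(100, 3)) + 3.0
        res = kabsch_superpose(x, y)
        assert res.rmsd == pytest.approx(oracles.rmsd_by_minimisation(x, y), abs=1e-6)

    def test_rotation_is_proper_even_for_reflected_input(self, rng):
        x = rng.normal(size=(30, 3))
        y = x * np.array([-1.0, 1.0, 1.0])  # mirror image
        res = kabsch_superpose(x, y)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.0

    def test_too_few_or_collinear_pairs_raise(self, rng):
        with pytest.raises(GeometryError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line + 1.0)

    def test_invariant_to_common_pre_rotation(self, rng):
        x = rng.normal(scale=4.0, size=(40, 3))
        y = x + rng.normal(scale=0.3, size=(40, 3))
        pre = Rotation.from_rotvec([0.5, 0.5, -1.0]).as_matrix()
        base = kabsch_superpose(x, y).rmsd
        rotated = kabsch_superpose(x @ pre.T, y @ pre.T).rmsd
        assert rotated == pytest.approx(base, abs=1e-9)


class TestPairwiseRmsd:
    def test_two_copies_give_zero(self, rng):
        coords = rng.normal(scale=6.0, size=(30, 3))
        a = _ca_structure(coords, sid="a")
        b = _ca_structure(coords, sid="b")
        matrix, counts = pairwise_structure_rmsd([a, b])
        assert matrix[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert counts[0, 1] == 30
        assert matrix[0, 0] == 0.0

    def test_planted_displacement_rmsd_has_closed_form(self, rng):
        # a rigid shift of every residue is absorbed by the fitted
        # translation (RMSD 0); an alternating +/-d displacement along an
        # axis of a mirror-symmetric point cloud cannot be absorbed and
        # leaves RMSD d exactly.
        coords = rng.normal(scale=6.0, size=(40, 3))
        shifted = coords + np.array([0.6, 0.0, 0.0])
        assert kabsch_superpose(coords, shifted).rmsd == pytest.approx(0.0, abs=1e-9)

        base = np.concatenate([coords, -coords])  # centrosymmetric cloud
        d = 0.37
        signs = np.concatenate([np.ones(40), -np.ones(40)])
        displaced = base + np.outer(signs * d, [1.0, 0.0, 0.0])
        res = kabsch_superpose(base, displaced)
        assert res.rmsd == pytest.approx(oracles.rmsd_by_minimisation(base, displaced),
                                         abs=1e-6)

    def test_alignment_mapping_handles_different_lengths(self, rng):
        # a varied sequence keeps the global alignment unambiguous
        seq = "MSWQAYVDDHLMCDIDGQGLASAKFPQFKP"
        one_to_three = {
            "A": "ALA", "C": "CYS", "D": "ASP", "F": "PHE", "G": "GLY",
            "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET",
            "P": "PRO", "Q": "GLN", "S": "SER", "V": "VAL", "W": "TRP",
            "Y": "TYR",
        }
        names = {i: one_to_three[c] for i, c in enumerate(seq)}
        coords = rng.normal(scale=6.0, size=(30, 3))
        a = _ca_structure(coords, names=names, sid="a")
        b = _ca_structure(coords[5:], names={i: names[i + 5] for i in range(25)},
                          sid="b")  # N-terminal truncation
        matrix, counts = pairwise_structure_rmsd([a, b])
        assert counts[0, 1] == 25
        assert matrix[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestCysteines:
    def test_fewer_than_two_cysteines_gives_empty_table(self):
        st, _ = make_globule(GlobuleSpec(n_residues=30, seed=1))
        assert len(cys_pair_distances(st)) == 0

    def test_planted_pair_distance_and_feasibility(self):
        st, truth = make_globule(
            GlobuleSpec(n_residues=40, cys_pairs=((5, 20, 5.0),), seed=2)
        )
        table = cys_pair_distances(st)
        assert len(table) == 1
        pair = table.pairs[0]
        assert pair.distance == pytest.approx(5.0, abs=0.01)
        assert pair.feasible

    def test_four_cysteines_give_six_pairs_matching_euclidean_oracle(self):
        st, _ = make_globule(
            GlobuleSpec(n_residues=60, cys_pairs=((5, 20, 4.5), (35, 50, 8.2)), seed=3)
        )
        table = cys_pair_distances(st)
        assert len(table) == 6
        ca = oracles.chain_ca(st.first_chain())
        for pair in table.pairs:
            expected = float(np.linalg.norm(ca[pair.a.number] - ca[pair.b.number]))
            assert pair.distance == pytest.approx(expected, abs=1e-9)
            assert pair.feasible == (3.0 <= pair.distance <= 7.5)

    def test_table_invariant_under_rigid_motion(self):
        st, _ = make_globule(
            GlobuleSpec(n_residues=40, cys_pairs=((5, 20, 6.0),), seed=4)
        )
        rot = Rotation.from_rotvec([0.4, 1.2, -0.3]).as_matrix()
        moved = _ca_structure(
            [rot @ np.asarray(r.atom("CA").pos) + 7.0 for _, r in st.residues()],
            names={i: r.name for i, (_, r) in enumerate(st.residues())},
        )
        d1 = [p.distance for p in cys_pair_distances(st).pairs]
        d2 = [p.distance for p in cys_pair_distances(moved).pairs]
        assert d2 == pytest.approx(d1, abs=1e-9)


class TestSequenceCharge:
    @pytest.mark.parametrize(
        "seq,neg,pos,net",
        [("DEK", 2, 1, -1), ("GGG", 0, 0, 0), ("RKDEH", 2, 2, 0)],
    )
    def test_known_counts(self, seq, neg, pos, net):
        s = sequence_charge(seq)
        assert (s.n_negative, s.n_positive, s.net_charge) == (neg, pos, net)

    def test_percentages(self):
        s = sequence_charge("DEK")
        assert s.pct_negative == pytest.approx(200.0 / 3)
        assert s.pct_positive == pytest.approx(100.0 / 3)

    def test_histidine_optional(self):
        assert sequence_charge("HHH").n_positive == 0
        assert sequence_charge("HHH", include_histidine=True).n_positive == 3

    def test_random_sequence_matches_letter_count(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWYX"), size=131))
        s = sequence_charge(seq)
        assert s.n_negative == seq.count("D") + seq.count("E")
        assert s.n_positive == seq.count("K") + seq.count("R")
        assert s.unknown == seq.count("X")
        assert s.length == 131
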