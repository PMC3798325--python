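import numpy as np
import pytest

import oracles
from epimap import (
    EpitopeParams,
    GlobuleSpec,
    SasaConfig,
    compute_exposures,
    expand_members,
    fill_single_gaps,
    make_globule,
    merge_centers,
    predict_epitopes,
    select_centers,
)
from epimap.conf_epitope import GeometryError, parameter_sweep
from epimap.sasa import ResidueExposure
from epimap.structio import Atom, Chain, Residue, ResidueRef, Structure


def _chain(positions, names=None):
    """Single chain of Cα-only residues at the given coordinates."""
    chain = Chain(id="A")
    for i, pos in enumerate(positions):
        name = (names or {}).get(i, "ALA")
        chain.residues.append(
            Residue(number=i + 1, icode="", name=name,
                    atoms=[Atom(name="CA", element="C", x=pos[0], y=pos[1], z=pos[2])])
        )
    return chain


def _exposures(chain, rel_by_number):
    return [
        ResidueExposure(
            ref=ResidueRef("A", r.number, "", r.name),
            absolute=rel_by_number[r.number],
            reference=100.0,
            relative=rel_by_number[r.number],
        )
        for r in chain.residues
    ]


def _refs(chain, numbers):
    by_num = {r.number: r for r in chain.residues}
    return {ResidueRef("A", n, "", by_num[n].name) for n in numbers}


class TestSelectCenters:
    def test_no_residue_above_threshold_gives_empty_set(self):
        chain = _chain([(i * 4.0, 0, 0) for i in range(5)])
        exp = _exposures(chain, {n: 50.0 for n in range(1, 6)})
        assert select_centers(exp) == set()

    def test_threshold_is_strict(self):
        chain = _chain([(i * 4.0, 0, 0) for i in range(3)])
        exp = _exposures(chain, {1: 80.0, 2: 75.0, 3: 74.0})
        assert select_centers(exp) == _refs(chain, {1})

    def test_planted_protruding_residues_are_exactly_recovered(self):
        spec = GlobuleSpec(n_residues=60, protruding=(5, 18, 30, 44, 57), seed=11)
        st, truth = make_globule(spec)
        exposures = compute_exposures(st, SasaConfig(n_points=480))
        centers = select_centers(exposures)
        assert {c.number for c in centers} == set(truth.protruding_resnums)


class TestMergeCenters:
    def test_pair_below_merge_radius_combines(self):
        chain = _chain([(0, 0, 0), (4.9, 0, 0)])
        groups = merge_centers(_refs(chain, {1, 2}), chain)
        assert len(groups) == 1

    def test_pair_above_merge_radius_stays_apart(self):
        chain = _chain([(0, 0, 0), (5.1, 0, 0)])
        groups = merge_centers(_refs(chain, {1, 2}), chain)
        assert len(groups) == 2

    def test_single_linkage_chains_transitively(self):
        chain = _chain([(0, 0, 0), (4.0, 0, 0), (8.0, 0, 0)])
        groups = merge_centers(_refs(chain, {1, 2, 3}), chain)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_missing_calpha_raises_geometry_error(self):
        chain = _chain([(0, 0, 0), (4, 0, 0)])
        chain.residues[1].atoms = [Atom(name="CB", element="C", x=4, y=0, z=0)]
        with pytest.raises(GeometryError):
            merge_centers(_refs(chain, {1, 2}), chain)


class TestExpandMembers:
    def test_lone_center_expands_to_itself(self):
        chain = _chain([(0, 0, 0), (20.0, 0, 0)])
        exp = _exposures(chain, {1: 80.0, 2: 80.0})
        members = expand_members(sorted(_refs(chain, {1})), exp, chain)
        assert members == _refs(chain, {1})

    @pytest.mark.parametrize("dist,included", [(9.0, True), (11.0, False)])
    def test_expansion_radius_is_strict(self, dist, included):
        chain = _chain([(0, 0, 0), (dist, 0, 0)])
        exp = _exposures(chain, {1: 80.0, 2: 30.0})
        members = expand_members(sorted(_refs(chain, {1})), exp, chain)
        assert (ResidueRef("A", 2, "", "ALA") in members) == included

    def test_member_threshold_is_strict(self):
        chain = _chain([(0, 0, 0), (5.0, 0, 0)])
        exp = _exposures(chain, {1: 80.0, 2: 20.0})
        members = expand_members(sorted(_refs(chain, {1})), exp, chain)
        assert ResidueRef("A", 2, "", "ALA") not in members


class TestFillSingleGaps:
    def test_single_gap_filled(self):
        chain = _chain([(i * 4.0, 0, 0) for i in range(7)])
        members = fill_single_gaps(_refs(chain, {5, 7}), chain)
        assert {m.number for m in members} == {5, 6, 7}

    def test_double_gap_untouched(self):
        chain = _chain([(i * 4.0, 0, 0) for i in range(8)])
        members = fill_single_gaps(_refs(chain, {5, 8}), chain)
        assert {m.number for m in members} == {5, 8}

    def test_random_member_sets_match_scan_oracle(self, rng):
        chain = _chain([(i * 4.0, 0, 0) for i in range(30)])
        order = [r.number for r in chain.residues]
        for _ in range(50):
            nums = set(rng.choice(order, size=10, replace=False).tolist())
            got = {m.number for m in fill_single_gaps(_refs(chain, nums), chain)}
            expected = set(nums)
            for k in range(1, len(order) - 1):
                if order[k] not in nums and order[k - 1] in nums and order[k + 1] in nums:
                    expected.add(order[k])
            assert got == expected


class TestPredictEpitopes:
    def test_no_protruding_residues_gives_empty_table(self):
        st, _ = make_globule(GlobuleSpec(n_residues=40, seed=1))
        exposures = compute_exposures(st, SasaConfig(n_points=240))
        table = predict_epitopes(st, exposures)
        assert len(table) == 0

    def test_two_remote_plants_give_two_epitopes(self):
        st, truth = make_globule(GlobuleSpec(n_residues=60, protruding=(10, 40), seed=21))
        exposures = compute_exposures(st, SasaConfig(n_points=480))
        table = predict_epitopes(st, exposures)
        assert len(table) == 2
        assert [c.number for row in table for c in row.centers] == truth.protruding_resnums

    def test_pipeline_equals_composed_oracles_on_globules(self):
        for seed in range(5):
            st, _ = make_globule(
                GlobuleSpec(n_residues=60, protruding=(3, 12, 25, 41, 55), seed=seed)
            )
            exposures = compute_exposures(st, SasaConfig(n_points=240))
            rel = {e.ref.number: e.relative for e in exposures}
            expected = oracles.epitopes_brute(st.first_chain(), rel)
            table = predict_epitopes(st, exposures)
            got = [
                (
                    frozenset(c.number for c in row.centers),
                    frozenset(m.number for m in row.members),
                )
                for row in table
            ]
            assert got == expected

    def test_determinism(self):
        st, _ = make_globule(GlobuleSpec(n_residues=50, protruding=(7, 30), seed=4))
        exposures = compute_exposures(st, SasaConfig(n_points=240))
        t1 = predict_epitopes(st, exposures)
        t2 = predict_epitopes(st, exposures)
        assert [(r.centers, sorted(r.members)) for r in t1] == [
            (r.centers, sorted(r.members)) for r in t2
        ]

    def test_center_sets_of_distinct_epitopes_are_disjoint(self):
        st, _ = make_globule(
            GlobuleSpec(n_residues=80, protruding=(5, 6, 30, 31, 60), seed=8)
        )
        exposures = compute_exposures(st, SasaConfig(n_points=240))
        table = predict_epitopes(st, exposures)
        seen = set()
        for row in table:
            assert not (set(row.centers) & seen)
            seen |= set(row.centers)

    def test_member_threshold_and_radius_monotonicity(self):
        st, _ = make_globule(GlobuleSpec(n_residues=60, protruding=(10, 40), seed=13))
        exposures = compute_exposures(st, SasaConfig(n_points=240))
        base = predict_epitopes(st, exposures, EpitopeParams())
        loose_member = predict_epitopes(
            st, exposures, EpitopeParams(member_threshold=10.0)
        )
        wide_radius = predict_epitopes(
            st, exposures, EpitopeParams(expansion_radius=12.0)
        )
        for b, lm, wr in zip(base, loose_member, wide_radius):
            assert set(b.members) <= set(lm.members)
            assert set(b.members) <= set(wr.members)

    def test_provenance_tags_are_recorded(self):
        st, _ = make_globule(GlobuleSpec(n_residues=60, protruding=(20,), seed=6))
        exposures = compute_exposures(st, SasaConfig(n_points=480))
        row = predict_epitopes(st, exposures).rows[0]
        tags = set(row.provenance.values())
        assert "center" in tags and "proximity" in tags
        for c in row.centers:
            assert row.provenance[c] == "center"


def test_parameter_sweep_reports_grid():
    st, _ = make_globule(GlobuleSpec(n_residues=50, protruding=(10, 35), seed=3))
    exposures = compute_exposures(st, SasaConfig(n_points=240))
    grid = [EpitopeParams(), EpitopeParams(distance_basis="min_heavy_atom")]
    report = parameter_sweep(st, {"default": exposures}, grid)
    assert len(report) == 2
    assert {r["distance_basis"] for r in report} == {"calpha", "min_heavy_atom"}
    assert all(r["n_epitopes"] >= 1 for r in report)
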