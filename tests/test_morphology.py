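"""Geometry: the artificial-neuron builder, edits and path distances."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efneuron.errors import MorphologyError, ParameterError
from efneuron.morphology import (ArtificialNeuronParams, MorphologyTree, Point2D,
                                 SectionSpec, apply_bend, build_artificial_neuron,
                                 path_distance_from_soma, remove_dendrites)


class TestBuilder:
    def test_default_cell_has_14_sections(self, default_tree):
        assert len(default_tree) == 14
        kinds = [s.kind for s in default_tree.sections]
        assert kinds.count("soma") == 1
        assert kinds.count("axon") == 1
        assert kinds.count("dend_proximal") == 4
        assert kinds.count("dend_distal") == 8

    def test_soma_centered_axon_down_dendrites_up(self, default_tree):
        soma = default_tree.root
        assert soma.center == Point2D(0.0, 0.0)
        assert default_tree.section("axon").distal.y < soma.proximal.y
        for sec in default_tree.dendritic_sections():
            assert sec.center.y > 0

    def test_removing_all_dendrites_leaves_soma_and_axon(self, default_params):
        params = default_params.with_(
            removed_dendrites=frozenset(range(1, 13)))
        tree = build_artificial_neuron(params)
        assert sorted(s.id for s in tree.sections) == ["axon", "soma"]

    def test_removal_reduces_cable_by_removed_lengths(self, default_tree,
                                                      default_params):
        total = default_tree.total_dendritic_length()
        removed = {"dend12", "dend3"}  # a distal leaf and a proximal subtree
        sub = {"dend3"} | {c.id for c in default_tree.children("dend3")}
        expected_loss = sum(default_tree.section(s).length for s in removed | sub)
        pruned = build_artificial_neuron(
            default_params.with_(removed_dendrites=frozenset(removed)))
        assert pruned.total_dendritic_length() == pytest.approx(total - expected_loss)

    def test_builder_is_pure(self, default_params):
        a = build_artificial_neuron(default_params)
        b = build_artificial_neuron(default_params)
        for sa, sb in zip(a.sections, b.sections):
            assert sa == sb

    def test_distal_dendrites_attach_to_proximal_blocks(self, default_tree):
        # contiguous numbering: dend7/dend8 are daughters of dend2
        assert default_tree.section("dend7").parent == "dend2"
        assert default_tree.section("dend8").parent == "dend2"

    @pytest.mark.parametrize("field,value", [
        ("soma_diameter", -1.0), ("axon_length", 0.0),
        ("dend_bend_angle", 91.0), ("n_dendrites", -1),
    ])
    def test_invalid_params_name_the_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            ArtificialNeuronParams(**{field: value})

    @pytest.mark.parametrize("n,n_prox", [(0, 0), (3, 1), (6, 2), (12, 4), (15, 5)])
    def test_dendrite_count_split(self, n, n_prox):
        tree = build_artificial_neuron(ArtificialNeuronParams(n_dendrites=n))
        kinds = [s.kind for s in tree.sections]
        assert kinds.count("dend_proximal") == n_prox
        assert kinds.count("dend_distal") == n - n_prox
        tree.validate()

    def test_terminal_sections_only_when_branched_or_bent(self):
        plain = build_artificial_neuron(ArtificialNeuronParams())
        assert not any(s.kind == "axon_terminal" for s in plain.sections)
        branched = build_artificial_neuron(
            ArtificialNeuronParams(n_axon_terminals=3))
        assert sum(s.kind == "axon_terminal" for s in branched.sections) == 3
        bent = build_artificial_neuron(
            ArtificialNeuronParams(axon_terminal_branch_angle=30.0))
        assert sum(s.kind == "axon_terminal" for s in bent.sections) == 1

    def test_every_built_tree_validates(self):
        for kw in ({}, {"axon_bend_angle": 45.0}, {"dend_bifurcation_angle": 60.0},
                   {"n_axon_terminals": 4, "axon_terminal_branch_angle": 20.0},
                   {"n_dendrites": 9, "dend_bend_angle": 30.0}):
            build_artificial_neuron(ArtificialNeuronParams(**kw)).validate()


class TestApplyBend:
    def test_zero_angle_is_identity(self, default_tree):
        bent = apply_bend(default_tree, "dend1", 0.0)
        assert bent.section("dend1") == default_tree.section("dend1")

    def test_right_angle_makes_section_horizontal(self, default_tree):
        bent = apply_bend(default_tree, "dend2", 90.0)
        sec = bent.section("dend2")
        # dend2 starts 5 degrees off vertical; after a further 90 degree
        # rotation away from y its y-extent equals the original x-extent
        orig = default_tree.section("dend2")
        dy = abs(sec.distal.y - sec.proximal.y)
        assert dy == pytest.approx(abs(orig.distal.x - orig.proximal.x), abs=1e-9)

    @given(angle=st.floats(0.0, 90.0), section=st.sampled_from(
        ["axon", "dend1", "dend3", "dend8"]))
    def test_bend_preserves_lengths_and_connectivity(self, default_tree,
                                                     angle, section):
        bent = apply_bend(default_tree, section, angle)
        bent.validate()
        for sec in default_tree.sections:
            new = bent.section(sec.id)
            assert new.length == pytest.approx(sec.length, rel=1e-9)
            assert new.diameter == sec.diameter

    def test_unknown_section_and_bad_angle(self, default_tree):
        with pytest.raises(MorphologyError):
            apply_bend(default_tree, "nope", 10.0)
        with pytest.raises(ParameterError):
            apply_bend(default_tree, "axon", 120.0)


class TestPathDistance:
    def test_soma_midpoint_is_origin(self, default_tree):
        assert path_distance_from_soma(default_tree, "soma", 0.5) == 0.0

    def test_axon_tip(self, default_tree):
        # half soma (5) + axon (50)
        assert path_distance_from_soma(default_tree, "axon", 1.0) == pytest.approx(55.0)

    def test_distal_dendrite_tip(self, default_tree):
        # half soma (5) + proximal (8) + distal (2)
        assert path_distance_from_soma(default_tree, "dend5", 1.0) == pytest.approx(15.0)

    def test_unknown_section(self, default_tree):
        with pytest.raises(MorphologyError):
            path_distance_from_soma(default_tree, "dend99", 0.5)


class TestTreeInvariants:
    def test_duplicate_ids_rejected(self):
        s = SectionSpec("soma", "soma", Point2D(0, -5), Point2D(0, 5), 10.0)
        with pytest.raises(MorphologyError):
            MorphologyTree([s, s])

    def test_detached_section_rejected(self):
        soma = SectionSpec("soma", "soma", Point2D(0, -5), Point2D(0, 5), 10.0)
        floater = SectionSpec("axon", "axon", Point2D(3, 3), Point2D(3, -40),
                              2.0, parent="soma", attach_end="proximal")
        with pytest.raises(MorphologyError, match="coincide"):
            MorphologyTree([soma, floater]).validate()

    def test_two_roots_rejected(self):
        a = SectionSpec("soma", "soma", Point2D(0, -5), Point2D(0, 5), 10.0)
        b = SectionSpec("soma2", "soma", Point2D(9, -5), Point2D(9, 5), 10.0)
        with pytest.raises(MorphologyError):
            MorphologyTree([a, b]).root

    def test_remove_non_dendrite_rejected(self, default_tree):
        with pytest.raises(MorphologyError):
            remove_dendrites(default_tree, ["axon"])
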