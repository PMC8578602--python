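import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import brute_force_align
from mirenrich.alignment import (
    AlignParams,
    AlignmentMap,
    assign_c2_subtype,
    cluster_by_identity,
    global_align,
    identity_and_similarity,
    kabsch_superpose,
    segmented_align,
    structure_align,
)
from mirenrich.io_formats import CalphaTrace, DomainRecord
from mirenrich.synthetic_data import SyntheticFamilySpec, generate_template, _helix_coords

SIMPLE = AlignParams(matrix=None, match=1.0, mismatch=-1.0, gap_open=2.0, gap_extend=1.0)


def _record(pid, seq, coords=None):
    trace = None
    if coords is not None:
        trace = CalphaTrace(
            list(range(1, len(seq) + 1)), seq, np.asarray(coords, float),
            seq_positions=list(range(1, len(seq) + 1)),
        )
    return DomainRecord(pid, "BAR", seq, (1, len(seq)), structure=trace)


class TestGlobalAlign:
    def test_identical_sequences(self):
        amap = global_align("ACDK", "ACDK")
        assert amap.pairs == [(1, 1), (2, 2), (3, 3), (4, 4)]
        assert amap.identity_pct == 100.0

    def test_overhang_matches_enumeration(self):
        amap = global_align("KKACDE", "ACDE", SIMPLE)
        score, pairs = brute_force_align(
            "KKACDE", "ACDE", SIMPLE.score_fn(), 2.0, 1.0
        )
        assert amap.score == pytest.approx(score)
        assert amap.pairs == pairs

    def test_blosum_gapless_score_is_sum_of_entries(self):
        # for KAC vs KEC the gapless shape beats either single-gap shape
        params = AlignParams()  # BLOSUM62, 10/0.5
        amap = global_align("KAC", "KEC", params)
        fn = params.score_fn()
        expected = fn("K", "K") + fn("A", "E") + fn("C", "C")
        assert amap.score == pytest.approx(expected)
        assert amap.pairs == [(1, 1), (2, 2), (3, 3)]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            global_align("", "ACDK")

    def test_score_equals_enumeration_on_random_battery(self):
        rng = np.random.default_rng(42)
        alphabet = "ACDEK"
        for _ in range(60):
            a = "".join(alphabet[i] for i in rng.integers(0, 5, rng.integers(1, 7)))
            b = "".join(alphabet[i] for i in rng.integers(0, 5, rng.integers(1, 7)))
            go, ge = float(rng.integers(0, 5)), float(rng.integers(0, 3))
            params = AlignParams(matrix=None, gap_open=go, gap_extend=ge)
            amap = global_align(a, b, params)
            score, pairs = brute_force_align(a, b, params.score_fn(), go, ge)
            assert amap.score == pytest.approx(score), (a, b, go, ge)
            assert amap.pairs == pairs, (a, b, go, ge)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AlignmentMap([(1, 2), (2, 2)], 0.0, 0.0, 0.0, 2)


class TestIdentitySimilarity:
    def test_identical_tenmers(self):
        amap = global_align("ACDEFGHIKL", "ACDEFGHIKL")
        assert identity_and_similarity(amap, "ACDEFGHIKL", "ACDEFGHIKL") == (100.0, 100.0)

    def test_half_matches_negative_rest(self):
        # gapless: 5 matches, 5 negative-scoring substitutions
        a, b = "KKKKKWWWWW", "KKKKKDDDDD"
        amap = global_align(a, b)
        ident, sim = identity_and_similarity(amap, a, b)
        assert ident == 50.0
        assert sim == 50.0

    def test_internal_gap_counts_in_denominator(self):
        # hand-built 6-column alignment: 5 pairs (all matches) + 1 gap column
        amap = AlignmentMap([(1, 1), (2, 2), (3, 4), (4, 5), (5, 6)], 0, 0, 0, 6)
        seq_a, seq_b = "KLMNP", "KLXMNP"
        ident, _ = identity_and_similarity(amap, seq_a, seq_b)
        assert ident == pytest.approx(100.0 * 5 / 6)  # 5 matching pairs / 6 columns

    def test_terminal_overhang_excluded(self):
        a, b = "KKKKACDE", "ACDE"
        amap = global_align(a, b, SIMPLE)
        ident, _ = identity_and_similarity(amap, a, b, SIMPLE)
        assert ident == 100.0  # the 4-residue overhang is terminal


class TestKabsch:
    def test_self_superposition(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts + [5.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.translation, [5.0, 0.0, 0.0], atol=1e-8)

    def test_rmsd_matches_scipy_on_noised_rotation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        rot = Rotation.random(rng=3)
        b = rot.apply(a) + rng.normal(scale=0.2, size=(4, 3)) + [1.0, -2.0, 0.5]
        sup = kabsch_superpose(a, b)
        # independent minimization: scipy's orthogonal Procrustes on the
        # centered point sets
        ac, bc = a - a.mean(0), b - b.mean(0)
        _, rssd = Rotation.align_vectors(bc, ac)
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        base = kabsch_superpose(a, b).rmsd
        rot = Rotation.random(rng=5).as_matrix()
        shift = np.array([3.0, -7.0, 2.0])
        moved = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift).rmsd
        assert moved == pytest.approx(base, abs=1e-8)

    def test_reflection_corrected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(6, 3))
        b = a * [-1.0, 1.0, 1.0]  # mirrored
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestStructureAlign:
    @pytest.fixture()
    def helix_template(self):
        spec = SyntheticFamilySpec(
            family="BAR", domain_length=120, seed=3, with_structures=True,
            mir_intervals=[(20, 60)]
        )
        return generate_template(spec).record

    def test_self_alignment_pairs_everything(self, helix_template):
        amap = structure_align(helix_template, helix_template)
        assert len(amap.pairs) == 120
        assert amap.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_noised_copy_keeps_most_pairs(self, helix_template):
        rng = np.random.default_rng(7)
        rot = Rotation.random(rng=8)
        coords = rot.apply(helix_template.structure.coords) + rng.normal(
            scale=0.5, size=(120, 3)
        )
        target = _record("noised", helix_template.sequence, coords)
        amap = structure_align(helix_template, target)
        assert len(amap.pairs) >= 0.95 * 120
        assert amap.rmsd < 1.5

    def test_displaced_segment_dropped(self, helix_template):
        # last 20 residues displaced 30 A: the residual filter must keep
        # only the consistent segment
        coords = helix_template.structure.coords.copy()
        coords[100:] += [30.0, 0.0, 0.0]
        target = _record("twoseg", helix_template.sequence, coords)
        amap = structure_align(helix_template, target)
        paired = {a for a, _ in amap.pairs}
        assert paired <= set(range(1, 101))
        assert len(paired) >= 20  # still a reliable superposition
        assert amap.rmsd < 5.0

    def test_too_few_pairs_errors(self):
        a = _record("a", "ACDEFGHIKL", _helix_coords(10))
        with pytest.raises(ValueError, match="unreliable"):
            structure_align(a, a)


class TestSegmentedAlign:
    @pytest.fixture()
    def hinge_pair(self):
        spec = SyntheticFamilySpec(
            family="BAR", domain_length=100, seed=9, with_structures=True,
            mir_intervals=[(20, 60)]
        )
        template = generate_template(spec).record
        coords = template.structure.coords.copy()
        # rotate the second half 25 degrees about the hinge point
        hinge = coords[49]
        rot = Rotation.from_euler("y", 25, degrees=True)
        coords[50:] = rot.apply(coords[50:] - hinge) + hinge
        target = _record("hinged", template.sequence, coords)
        return template, target

    def test_single_segment_equals_unsegmented(self):
        spec = SyntheticFamilySpec(
            family="BAR", domain_length=80, seed=10, with_structures=True,
            mir_intervals=[(20, 60)]
        )
        template = generate_template(spec).record
        whole = structure_align(template, template)
        seg = segmented_align(template, template, [(1, 80)])
        assert seg.pairs == whole.pairs

    def test_hinge_per_segment_rmsd_beats_global(self, hinge_pair):
        template, target = hinge_pair
        glob = structure_align(template, target)
        seg = segmented_align(template, target, [(1, 50), (51, 100)])
        assert all(r < glob.rmsd for r in seg.segment_rmsds)
        assert len(seg.pairs) > len(glob.pairs)

    def test_overlapping_segments_error(self, hinge_pair):
        template, target = hinge_pair
        with pytest.raises(ValueError, match="overlap"):
            segmented_align(template, target, [(1, 60), (50, 100)])

    def test_empty_segments_error(self, hinge_pair):
        template, target = hinge_pair
        with pytest.raises(ValueError, match="empty"):
            segmented_align(template, target, [])


class TestClustering:
    def test_identical_sequences_cluster(self):
        t = _record("t", "ACDEFGHIKLMNPQRSTVWY" * 3)
        m = _record("m", t.sequence)
        cluster, excluded = cluster_by_identity([m], t)
        assert [r.protein_id for r in cluster] == ["t", "m"]
        assert excluded == []

    def test_shuffled_sequence_excluded(self):
        rng = np.random.default_rng(12)
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        t = _record("t", seq)
        shuffled = "".join(rng.permutation(list(seq)))
        m = _record("m", shuffled)
        cluster, excluded = cluster_by_identity([m], t)
        assert [r.protein_id for r in cluster] == ["t"]
        assert [r.protein_id for r, _ in excluded] == ["m"]

    def test_single_linkage_chains_through_intermediate(self):
        # A ~60% to template, B ~60% to A but <50% to template
        rng = np.random.default_rng(13)
        spec = SyntheticFamilySpec(
            family="BAR", domain_length=120, seed=14, target_identity_pct=60.0,
            indel_rate=0.0, mir_intervals=[(20, 60)],
        )
        from mirenrich.synthetic_data import generate_template, mutate_homolog

        template = generate_template(spec)
        a_rec, _ = mutate_homolog(template, spec, 0)
        # mutate A again to get B: ~60% of A, ~36% of template
        from dataclasses import replace

        from mirenrich.region_annotation import RegionAnnotation
        from mirenrich.region_annotation import TemplateDefinition

        a_template = TemplateDefinition(
            a_rec, RegionAnnotation((1, len(a_rec.sequence)), [(20, 60)])
        )
        b_rec, _ = mutate_homolog(a_template, replace(spec, seed=99), 1)
        b_rec = DomainRecord("B", "BAR", b_rec.sequence, b_rec.domain_range)
        a_rec = DomainRecord("A", "BAR", a_rec.sequence, a_rec.domain_range)

        linked, excluded_linked = cluster_by_identity([a_rec, b_rec], template.record)
        assert {r.protein_id for r in linked} == {"A", "B", template.record.protein_id}
        strict, excluded_strict = cluster_by_identity(
            [a_rec, b_rec], template.record, mode="template"
        )
        assert {r.protein_id for r, _ in excluded_strict} == {"B"}


class TestC2Subtype:
    @pytest.fixture()
    def templates(self):
        sa = SyntheticFamilySpec(family="C2", domain_length=130, seed=21, mir_intervals=[(10, 40)])
        sb = SyntheticFamilySpec(family="C2", domain_length=130, seed=22, mir_intervals=[(10, 40)])
        return generate_template(sa).record, generate_template(sb).record

    def test_template_assigns_to_itself(self, templates):
        ta, tb = templates
        assert assign_c2_subtype(ta, ta, tb) == "C2A-like"

    def test_low_complexity_is_degenerate(self, templates):
        ta, tb = templates
        rec = _record("low", "GS" * 65)
        assert assign_c2_subtype(rec, ta, tb) == "degenerate"

    def test_mutant_of_b_goes_to_b(self, templates):
        ta, tb = templates
        from mirenrich.region_annotation import RegionAnnotation, TemplateDefinition
        from mirenrich.synthetic_data import mutate_homolog

        tdef = TemplateDefinition(tb, RegionAnnotation((1, 130), [(10, 40)]))
        spec = SyntheticFamilySpec(
            family="C2", domain_length=130, seed=23, target_identity_pct=70.0,
            mir_intervals=[(10, 40)]
        )
        rec, _ = mutate_homolog(tdef, spec, 0)
        assert assign_c2_subtype(rec, ta, tb) == "C2B-like"

    def test_exact_tie_warns_and_assigns_a(self, templates):
        ta, tb = templates
        with pytest.warns(UserWarning, match="tie"):
            assert assign_c2_subtype(ta, ta, ta) == "C2A-like"
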