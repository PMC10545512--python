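"""Screening rules: oracles, trivial arithmetic cases, sensitivity/specificity."""

import numpy as np
import pytest

from cineqc.biomarkers import BiomarkerSet
from cineqc.core_io import BG, ED, ES, LVBP, MYO, RVBP
from cineqc.phantom import (
    DEFECT_KINDS,
    default_defect,
    generate_phantom,
    inject_defect,
    random_phantom_spec,
)
from cineqc.screening import (
    ScreeningConfig,
    apply_correction_plan,
    check_coverage,
    check_external_components,
    check_frame_completeness,
    check_gaps,
    check_anatomy_relations,
    check_sv_discordance,
    check_volume_plausibility,
    connected_components,
    find_duplicates,
    run_qa_gt,
    run_qc_post,
)
from .conftest import make_stack


def flood_fill_components(mask_2d):
    """Brute-force 8-connectivity flood fill; independent oracle."""
    mask = np.asarray(mask_2d, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack_ = [(r0, c0)]
                seen[r0, c0] = True
                comp = []
                while stack_:
                    r, c = stack_.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack_.append((rr, cc))
                comps.append(frozenset(comp))
    return set(comps)


class TestConnectedComponents:
    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            grid = (rng.random((8, 8)) < 0.4).astype(np.int16)  # LVBP mask
            stack = make_stack(grid[None, :, :])
            got = {
                frozenset((int(r), int(c)) for _, r, c in comp.voxels)
                for comp in connected_components(stack, LVBP, "per_slice_2d")
            }
            assert got == flood_fill_components(grid == 1)

    def test_single_disc_is_one_component(self):
        grid = np.zeros((1, 16, 16), dtype=np.int16)
        yy, xx = np.mgrid[:16, :16]
        grid[0][(yy - 8) ** 2 + (xx - 8) ** 2 <= 16] = LVBP
        comps = connected_components(make_stack(grid), LVBP)
        assert len(comps) == 1

    def test_3d_mode_joins_face_adjacent_slices_only(self):
        vox = np.zeros((3, 5, 5), dtype=np.int16)
        vox[0, 1, 1] = vox[1, 1, 1] = LVBP  # face-adjacent across slices
        vox[2, 3, 3] = LVBP  # diagonal across slices: separate in 3D mode
        comps = connected_components(make_stack(vox), LVBP, "stack_3d")
        assert sorted(c.size for c in comps) == [1, 2]
        assert len(connected_components(make_stack(vox), LVBP, "per_slice_2d")) == 3


class TestIndividualRules:
    def test_completeness_passes_with_both_phases(self, reference_study):
        study, _ = reference_study
        assert check_frame_completeness(study) == []

    def test_completeness_excludes_missing_and_empty_phases(self, reference_study):
        study, _ = reference_study
        missing = inject_defect(study, default_defect("missing_phase"))
        entries = check_frame_completeness(missing)
        assert [e.severity for e in entries] == ["exclude"]
        assert entries[0].phase_tag == ES
        empty = study.copy()
        empty.stacks[ES].voxels[:] = BG
        entries = check_frame_completeness(empty)
        assert [e.severity for e in entries] == ["exclude"]

    def test_coverage_extent_arithmetic(self):
        cfg = ScreeningConfig()
        vox = np.zeros((10, 12, 12), dtype=np.int16)
        vox[:8, 3:9, 3:9] = LVBP  # 8 slices x 10 mm = 80 mm >= 40 mm
        vox[7, 3:9, 3:9] = 0
        vox[7, 5, 5] = LVBP  # tapered apex: small most-apical area
        assert check_coverage(make_stack(vox), cfg) == []
        vox = np.zeros((10, 12, 12), dtype=np.int16)
        vox[:3, 3:9, 3:9] = LVBP  # 30 mm < 40 mm
        vox[2, 3:9, 3:9] = 0
        vox[2, 5, 5] = LVBP
        entries = check_coverage(make_stack(vox), cfg)
        assert [e.rule_id for e in entries] == ["coverage_extent"]

    def test_coverage_apex_truncation_flag(self):
        # constant-area column: most-apical slice area equals the max -> flag
        vox = np.zeros((8, 12, 12), dtype=np.int16)
        vox[:6, 4:9, 4:9] = LVBP
        entries = check_coverage(make_stack(vox), ScreeningConfig())
        assert "coverage_apex" in [e.rule_id for e in entries]

    def test_gap_flagged_only_strictly_between_segmented_slices(self):
        vox = np.zeros((8, 8, 8), dtype=np.int16)
        for s in (2, 3, 5):
            vox[s, 3:5, 3:5] = LVBP
        entries = check_gaps(make_stack(vox))
        assert [(e.rule_id, e.location) for e in entries] == [("gap", "slice 4")]
        vox[4, 3:5, 3:5] = LVBP
        assert check_gaps(make_stack(vox)) == []

    def test_anatomy_clean_annulus_passes(self, reference_study):
        study, _ = reference_study
        assert check_anatomy_relations(study.stacks[ED]) == []

    def test_myocardial_hole_breaches_ring(self, reference_study):
        study, _ = reference_study
        holed = inject_defect(study, default_defect("myocardial_hole"))
        rules = {e.rule_id for e in check_anatomy_relations(holed.stacks[ED])}
        assert rules == {"myo_ring_breach"}

    def test_zero_thickness_septum_flags_contact(self):
        vox = np.zeros((1, 16, 16), dtype=np.int16)
        vox[0, 6:10, 6:10] = LVBP
        vox[0, 5, 5:11] = MYO
        vox[0, 6:10, 5] = MYO
        vox[0, 10, 5:11] = MYO
        vox[0, 6:10, 10] = RVBP  # RV column directly adjacent to LVBP
        rules = [e.rule_id for e in check_anatomy_relations(make_stack(vox))]
        assert "lvbp_rvbp_contact" in rules

    def test_sv_discordance_threshold_cases(self):
        cfg = ScreeningConfig()

        def bm(lvsv, rvsv):
            return BiomarkerSet(LVEDV=100 + lvsv, LVESV=100, LVM=100,
                                RVEDV=100 + rvsv, RVESV=100)

        assert len(check_sv_discordance(bm(60, 40), cfg)) == 1  # 40% > 25%
        assert check_sv_discordance(bm(60, 55), cfg) == []  # 8.7%
        assert check_sv_discordance(bm(60, 60), cfg) == []  # identical SVs
        assert len(check_sv_discordance(bm(-5, 60), cfg)) == 1  # implausible

    def test_volume_plausibility_bounds(self):
        cfg = ScreeningConfig()
        ok = BiomarkerSet(LVEDV=150, LVESV=60, LVM=120, RVEDV=150, RVESV=60)
        assert check_volume_plausibility(ok, cfg) == []
        big = BiomarkerSet(LVEDV=900, LVESV=60, LVM=120, RVEDV=150, RVESV=60)
        assert [e.location for e in check_volume_plausibility(big, cfg)] == ["LVEDV"]
        light = BiomarkerSet(LVEDV=150, LVESV=60, LVM=10, RVEDV=150, RVESV=60)
        assert [e.location for e in check_volume_plausibility(light, cfg)] == ["LVM"]


class TestExternalComponents:
    def test_clean_phantom_has_empty_plan(self, reference_study):
        study, _ = reference_study
        entries, plan = check_external_components(study, ScreeningConfig())
        assert entries == [] and plan == []

    def test_stray_blob_flagged_and_planned_exactly(self, study_factory):
        study, _ = study_factory(31)
        bad = inject_defect(study, default_defect("stray_component", size=50))
        entries, plan = check_external_components(bad, ScreeningConfig())
        assert len(entries) == 1 and len(plan) == 1
        assert plan[0].size == 50
        fixed, corrected = apply_correction_plan(bad, plan)
        assert np.array_equal(fixed.stacks[ED].voxels, study.stacks[ED].voxels)
        assert [e.severity for e in corrected] == ["corrected"]
        assert "correction" in corrected[0].detail

    def test_tiny_components_removed_silently(self, study_factory):
        study, _ = study_factory(32)
        bad = inject_defect(study, default_defect("stray_component", size=2))
        entries, plan = check_external_components(bad, ScreeningConfig())
        assert entries == [] and len(plan) == 1 and plan[0].flagged is False

    def test_equal_components_tie_break_is_deterministic(self):
        vox = np.zeros((1, 12, 12), dtype=np.int16)
        vox[0, 1:3, 1:3] = LVBP  # 4 voxels, min index (0,1,1)
        vox[0, 8:10, 8:10] = LVBP  # 4 voxels, min index (0,8,8)
        from cineqc.core_io import CineStudy

        study = CineStudy(study_id="tie", stacks={ED: make_stack(vox)})
        for _ in range(3):
            entries, plan = check_external_components(study, ScreeningConfig())
            assert len(plan) == 1
            assert tuple(plan[0].voxels[0]) == (0, 8, 8)  # lowest-index comp kept


class TestDuplicates:
    def test_distinct_phantoms_have_no_duplicates(self, study_factory):
        cohort = [study_factory(s)[0] for s in range(40, 43)]
        assert find_duplicates(cohort) == []

    def test_copied_stack_flags_both_studies(self, study_factory):
        a, _ = study_factory(44)
        b, _ = study_factory(45)
        b_dup = inject_defect(b, default_defect("duplicate_of"), source_study=a)
        hits = find_duplicates([a, b_dup])
        assert len(hits) == 1
        a_id, b_id, entry = hits[0]
        assert {a_id, b_id} == {a.study_id, b_dup.study_id}
        assert a.study_id in entry.location and b_dup.study_id in entry.location

    def test_empty_stacks_are_not_duplicates(self):
        from cineqc.core_io import CineStudy

        empty = np.zeros((2, 4, 4), dtype=np.int16)
        a = CineStudy(study_id="a", stacks={ED: make_stack(empty)})
        b = CineStudy(study_id="b", stacks={ED: make_stack(empty.copy())})
        assert find_duplicates([a, b]) == []


class TestEntryPoints:
    def test_clean_cohort_yields_no_flags_or_exclusions(self, study_factory):
        cohort = [study_factory(s)[0] for s in range(50, 60)]
        reports, exclusion = run_qa_gt(cohort)
        assert exclusion == []
        assert all(len(r) == 0 for r in reports.values())

    def test_missing_phase_study_is_excluded(self, study_factory):
        good, _ = study_factory(61)
        bad = inject_defect(study_factory(62)[0], default_defect("missing_phase"))
        _, exclusion = run_qa_gt([good, bad])
        assert exclusion == [bad.study_id]

    @pytest.mark.parametrize("kind", DEFECT_KINDS)
    def test_each_defect_triggers_its_designed_rule(self, kind):
        for seed in range(5):
            study, _ = generate_phantom(random_phantom_spec(700 + seed))
            defect = default_defect(kind, seed=seed)
            if kind == "duplicate_of":
                src, _ = generate_phantom(random_phantom_spec(800 + seed))
                bad = inject_defect(study, defect, source_study=src)
                reports, _ = run_qa_gt([bad, src])
            else:
                bad = inject_defect(study, defect)
                reports, _ = run_qa_gt([bad])
            assert defect.target_rule in reports[bad.study_id].rule_ids()

    def test_qa_never_modifies_ground_truth(self, study_factory):
        study, _ = study_factory(63)
        bad = inject_defect(study, default_defect("stray_component"))
        before = {t: s.voxels.copy() for t, s in bad.stacks.items()}
        run_qa_gt([bad])
        for tag, vox in before.items():
            assert np.array_equal(bad.stacks[tag].voxels, vox)

    def test_qc_corrects_stray_and_is_idempotent(self, study_factory):
        study, _ = study_factory(64)
        bad = inject_defect(study, default_defect("stray_component"))
        fixed, report = run_qc_post(bad, apply_corrections=True)
        assert any(e.severity == "corrected" for e in report.entries)
        for tag in study.stacks:
            assert np.array_equal(fixed.stacks[tag].voxels, study.stacks[tag].voxels)
        fixed2, report2 = run_qc_post(fixed, apply_corrections=True)
        assert len(report2) == 0
        for tag in study.stacks:
            assert np.array_equal(fixed2.stacks[tag].voxels, fixed.stacks[tag].voxels)

    def test_complex_issues_flagged_but_never_modified(self, study_factory):
        study, _ = study_factory(65)
        holed = inject_defect(study, default_defect("myocardial_hole"))
        out, report = run_qc_post(holed, apply_corrections=True)
        assert "myo_ring_breach" in report.rule_ids()
        for tag in holed.stacks:
            assert np.array_equal(out.stacks[tag].voxels, holed.stacks[tag].voxels)

    def test_corrections_change_only_planned_voxels(self, study_factory):
        study, _ = study_factory(66)
        bad = inject_defect(study, default_defect("stray_component", size=50))
        _, plan = check_external_components(bad, ScreeningConfig())
        fixed, _ = apply_correction_plan(bad, plan)
        diff = bad.stacks[ED].voxels != fixed.stacks[ED].voxels
        planned = np.zeros_like(diff)
        vox = plan[0].voxels
        planned[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        assert np.array_equal(diff, planned)
        assert np.array_equal(bad.stacks[ES].voxels, fixed.stacks[ES].voxels)

    def test_reports_are_deterministic_and_sorted(self, study_factory):
        study, _ = study_factory(67)
        bad = inject_defect(study, default_defect("mid_stack_gap"))
        r1, _ = run_qa_gt([bad])
        r2, _ = run_qa_gt([bad])
        e1 = [(e.rule_id, e.phase_tag, e.location) for e in r1[bad.study_id].entries]
        e2 = [(e.rule_id, e.phase_tag, e.location) for e in r2[bad.study_id].entries]
        assert e1 == e2 == sorted(e1)
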