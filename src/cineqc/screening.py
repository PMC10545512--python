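"""Rule-based QA/QC for segmentation stacks.

Two entry points share one set of checks:

* :func:`run_qa_gt` — ground-truth quality assurance over a cohort.  Ground
  truth is never modified: rules flag (or exclude, for incomplete studies)
  and flagged studies are listed for manual review.
* :func:`run_qc_post` — post-analysis quality control of model outputs for
  one study.  Simple errors (components disconnected from the heart) can be
  corrected automatically; complex issues (gaps, anatomy breaches,
  implausible volumes, stroke-volume discordance) are flagged only.

Connectivity conventions: SAX stacks are thick and anisotropic, so checks
are per-slice 2D with 8-neighbour connectivity unless stated; only the
heart-component check is 3D, adding face adjacency across slices.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .biomarkers import BiomarkerSet, compute_biomarkers
from .core_io import BG, CineStudy, ED, ES, FlagEntry, FlagReport, LVBP, MYO, RVBP, LabelStack
from .errors import CineQCError, IncompleteStudyError

__all__ = [
    "ScreeningConfig",
    "Component",
    "CorrectionAction",
    "connected_components",
    "check_frame_completeness",
    "check_coverage",
    "check_gaps",
    "check_anatomy_relations",
    "check_external_components",
    "check_volume_plausibility",
    "check_sv_discordance",
    "find_duplicates",
    "apply_correction_plan",
    "run_qa_gt",
    "run_qc_post",
]

_STRUCT_2D = np.ones((3, 3), dtype=bool)  # in-plane 8-connectivity
_STRUCT_3D = np.zeros((3, 3, 3), dtype=bool)  # + face adjacency across slices
_STRUCT_3D[1] = True
_STRUCT_3D[0, 1, 1] = _STRUCT_3D[2, 1, 1] = True

_LABEL_NAMES = {LVBP: "LVBP", MYO: "MYO", RVBP: "RVBP"}


@dataclass
class ScreeningConfig:
    """Thresholds of the plausibility rules.

    The stroke-volume discordance threshold is the one clinical screens key
    on (relative LV/RV SV difference over their mean > 25%); the remaining
    defaults are package choices, all configurable.
    """

    sv_discordance_fraction: float = 0.25
    volume_ranges_ml: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LVEDV": (20.0, 800.0),
            "LVESV": (10.0, 700.0),
            "RVEDV": (20.0, 800.0),
            "RVESV": (10.0, 700.0),
            "LVM": (20.0, 500.0),
        }
    )
    min_lv_extent_mm: float = 40.0
    apical_area_fraction_max: float = 0.5
    min_component_voxels: int = 2
    papillary_mode: str = "include"  # biomarker computation inside QA/QC

    def __post_init__(self) -> None:
        if not 0 < self.sv_discordance_fraction <= 1:
            raise ValueError("sv_discordance_fraction must be in (0, 1]")
        if not 0 < self.apical_area_fraction_max <= 1:
            raise ValueError("apical_area_fraction_max must be in (0, 1]")
        if self.min_lv_extent_mm <= 0 or self.min_component_voxels < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Component:
    """A maximal connected set of same-label voxels."""

    voxels: np.ndarray  # (n, 3) int indices (slice, row, col)
    slice_index: int | None = None  # set for per-slice components

    @property
    def size(self) -> int:
        return len(self.voxels)

    @property
    def min_index(self) -> tuple[int, int, int]:
        i = np.lexsort((self.voxels[:, 2], self.voxels[:, 1], self.voxels[:, 0]))[0]
        return tuple(int(v) for v in self.voxels[i])


@dataclass
class CorrectionAction:
    """Planned deletion of one external component."""

    phase_tag: str
    voxels: np.ndarray  # (n, 3) indices
    flagged: bool  # False => silent noise removal (<= min_component_voxels)

    @property
    def size(self) -> int:
        return len(self.voxels)


def connected_components(
    stack: LabelStack, label: int, mode: str = "per_slice_2d"
) -> list[Component]:
    """Connected components of one label, sorted by size desc then position.

    ``per_slice_2d``: 8-connectivity within each slice, none across slices.
    ``stack_3d``: additionally face adjacency between adjacent slices.
    """
    mask = stack.voxels == label
    comps: list[Component] = []
    if mode == "per_slice_2d":
        for s in range(stack.n_slices):
            lab, n = ndimage.label(mask[s], structure=_STRUCT_2D)
            for cid in range(1, n + 1):
                rr, cc = np.nonzero(lab == cid)
                vox = np.column_stack([np.full_like(rr, s), rr, cc])
                comps.append(Component(voxels=vox, slice_index=s))
    elif mode == "stack_3d":
        lab, n = ndimage.label(mask, structure=_STRUCT_3D)
        for cid in range(1, n + 1):
            ss, rr, cc = np.nonzero(lab == cid)
            comps.append(Component(voxels=np.column_stack([ss, rr, cc])))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    comps.sort(key=lambda c: (-c.size, c.min_index))
    return comps


# ---------------------------------------------------------------------------
# Individual checks
# ---------------------------------------------------------------------------


def _required_phases(study: CineStudy) -> list[str]:
    declared: list[str] = []
    for key in ("lv_phases", "rv_phases"):
        if study.meta.get(key):
            declared.extend(str(t) for t in study.meta[key])
    return sorted(set(declared)) if declared else [ED, ES]


def check_frame_completeness(study: CineStudy) -> list[FlagEntry]:
    """Exclude studies missing (or having empty) ED/ES segmentations."""
    entries = []
    for phase in _required_phases(study):
        stack = study.stacks.get(phase)
        if stack is None:
            entries.append(
                FlagEntry(
                    "frame_completeness", "exclude", phase, "stack",
                    f"phase {phase} not segmented",
                )
            )
        elif not np.any(stack.voxels != BG):
            entries.append(
                FlagEntry(
                    "frame_completeness", "exclude", phase, "stack",
                    f"phase {phase} segmentation is empty",
                )
            )
    return entries


def check_coverage(stack: LabelStack, config: ScreeningConfig) -> list[FlagEntry]:
    """Base-to-apex coverage of the LV: extent and apical truncation."""
    entries = []
    lv_slices = stack.slices_with(LVBP)
    extent = len(lv_slices) * stack.slice_spacing
    if extent < config.min_lv_extent_mm:
        entries.append(
            FlagEntry(
                "coverage_extent", "flag", stack.phase_tag, "stack",
                f"segmented LV extent {extent:.0f} mm < {config.min_lv_extent_mm:.0f} mm",
            )
        )
    if len(lv_slices) >= 1:
        areas = (stack.voxels[lv_slices] == LVBP).sum(axis=(1, 2))
        frac = areas[-1] / areas.max()
        if frac > config.apical_area_fraction_max:
            entries.append(
                FlagEntry(
                    "coverage_apex", "flag", stack.phase_tag,
                    f"slice {int(lv_slices[-1])}",
                    f"most-apical LVBP area is {100 * frac:.0f}% of the maximum "
                    f"slice area (apex likely truncated)",
                )
            )
    return entries


def check_gaps(stack: LabelStack) -> list[FlagEntry]:
    """Non-segmented slices strictly between segmented ones, per label."""
    entries = []
    for label in (LVBP, MYO, RVBP):
        present = stack.slices_with(label)
        if len(present) < 2:
            continue
        missing = sorted(set(range(int(present[0]), int(present[-1]) + 1)) - set(present.tolist()))
        for s in missing:
            entries.append(
                FlagEntry(
                    "gap", "flag", stack.phase_tag, f"slice {s}",
                    f"{_LABEL_NAMES[label]} absent between segmented slices",
                )
            )
    return entries


def check_anatomy_relations(stack: LabelStack) -> list[FlagEntry]:
    """Ventricle/myocardium relationship checks, per slice.

    (a) myocardial-ring breach: on any slice containing LV blood pool, an
    8-connected in-plane path of non-myocardium voxels from the blood pool
    to the image border (a broken or absent ring);
    (b) direct LVBP/RVBP contact (zero-thickness septum).
    """
    entries = []
    for s in range(stack.n_slices):
        plane = stack.voxels[s]
        lv = plane == LVBP
        if not lv.any():
            continue
        passable = plane != MYO
        lab, _ = ndimage.label(passable, structure=_STRUCT_2D)
        lv_comps = np.unique(lab[lv])
        border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        if np.intersect1d(lv_comps, border[border > 0]).size:
            entries.append(
                FlagEntry(
                    "myo_ring_breach", "flag", stack.phase_tag, f"slice {s}",
                    "LV blood pool reaches the image border without crossing "
                    "myocardium (broken or missing ring)",
                )
            )
        rv = plane == RVBP
        if rv.any() and np.any(ndimage.binary_dilation(lv, structure=_STRUCT_2D) & rv):
            entries.append(
                FlagEntry(
                    "lvbp_rvbp_contact", "flag", stack.phase_tag, f"slice {s}",
                    "LV and RV blood pools are directly adjacent (no septal wall)",
                )
            )
    return entries


def check_external_components(
    study: CineStudy, config: ScreeningConfig
) -> tuple[list[FlagEntry], list[CorrectionAction]]:
    """Foreground components disconnected from the heart, with deletion plan.

    Per phase, the largest 3D foreground component (ties: lexicographically
    smallest minimum index) is the heart; every other component enters the
    correction plan.  Components larger than ``min_component_voxels`` are
    flagged; smaller ones are silent noise.
    """
    entries: list[FlagEntry] = []
    plan: list[CorrectionAction] = []
    for phase in sorted(study.stacks):
        stack = study.stacks[phase]
        mask = stack.voxels != BG
        if not mask.any():
            entries.append(
                FlagEntry(
                    "external_component", "flag", phase, "stack",
                    "no foreground voxels",
                )
            )
            continue
        lab, n = ndimage.label(mask, structure=_STRUCT_3D)
        comps = []
        for cid in range(1, n + 1):
            ss, rr, cc = np.nonzero(lab == cid)
            comps.append(Component(voxels=np.column_stack([ss, rr, cc])))
        comps.sort(key=lambda c: (-c.size, c.min_index))
        for comp in comps[1:]:
            flagged = comp.size > config.min_component_voxels
            plan.append(CorrectionAction(phase_tag=phase, voxels=comp.voxels, flagged=flagged))
            if flagged:
                entries.append(
                    FlagEntry(
                        "external_component", "flag", phase,
                        f"component@{comp.min_index}",
                        f"{comp.size} foreground voxel(s) disconnected from the heart",
                    )
                )
    return entries, plan


def apply_correction_plan(
    study: CineStudy, plan: Iterable[CorrectionAction]
) -> tuple[CineStudy, list[FlagEntry]]:
    """Delete planned components from a copy of `study`; report corrections."""
    out = study.copy()
    entries = []
    for action in plan:
        vox = action.voxels
        out.stacks[action.phase_tag].voxels[vox[:, 0], vox[:, 1], vox[:, 2]] = BG
        entries.append(
            FlagEntry(
                "external_component", "corrected", action.phase_tag,
                f"component@{Component(vox).min_index}",
                f"deleted {action.size} voxel(s) by external-component correction",
            )
        )
    return out, entries


def check_volume_plausibility(
    biomarkers: BiomarkerSet, config: ScreeningConfig
) -> list[FlagEntry]:
    """Flag biomarkers outside their configured plausibility intervals."""
    entries = []
    values = biomarkers.as_dict()
    for name, (lo, hi) in sorted(config.volume_ranges_ml.items()):
        v = values[name]
        if not lo <= v <= hi:
            unit = "g" if name == "LVM" else "mL"
            entries.append(
                FlagEntry(
                    "volume_range", "flag", "", name,
                    f"{name} = {v:.1f} {unit} outside [{lo:.0f}, {hi:.0f}] {unit}",
                )
            )
    return entries


def check_sv_discordance(
    biomarkers: BiomarkerSet, config: ScreeningConfig
) -> list[FlagEntry]:
    """LV/RV stroke-volume discordance (flag-only, never corrected)."""
    lvsv, rvsv = biomarkers.LVSV, biomarkers.RVSV
    if lvsv <= 0 or rvsv <= 0:
        return [
            FlagEntry(
                "sv_discordance", "flag", "", "SV",
                f"non-positive stroke volume (LVSV {lvsv:.1f} mL, RVSV {rvsv:.1f} mL)",
            )
        ]
    frac = abs(lvsv - rvsv) / ((lvsv + rvsv) / 2.0)
    if frac > config.sv_discordance_fraction:
        return [
            FlagEntry(
                "sv_discordance", "flag", "", "SV",
                f"LV/RV stroke-volume difference {100 * frac:.0f}% of their mean "
                f"exceeds {100 * config.sv_discordance_fraction:.0f}% "
                f"(LVSV {lvsv:.1f} mL, RVSV {rvsv:.1f} mL)",
            )
        ]
    return []


def find_duplicates(cohort: list[CineStudy]) -> list[tuple[str, str, FlagEntry]]:
    """Identical non-empty stacks across the cohort (within and across studies).

    Returns ``(study_id_a, study_id_b, entry)`` triples so callers can file
    the flag under both studies.  Empty stacks are completeness failures,
    not duplicates, and are skipped.
    """
    digests: dict[str, list[tuple[str, str, LabelStack]]] = {}
    for study in cohort:
        for phase in sorted(study.stacks):
            stack = study.stacks[phase]
            if not np.any(stack.voxels != BG):
                continue
            h = hashlib.sha1(
                stack.voxels.tobytes() + repr(stack.voxels.shape).encode()
            ).hexdigest()
            digests.setdefault(h, []).append((study.study_id, phase, stack))
    out = []
    for group in digests.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a_id, a_phase, a = group[i]
                b_id, b_phase, b = group[j]
                if np.array_equal(a.voxels, b.voxels):  # digest then exact check
                    entry = FlagEntry(
                        "duplicate", "flag", a_phase,
                        f"{a_id}:{a_phase} ~ {b_id}:{b_phase}",
                        "identical voxel content in two stacks",
                    )
                    out.append((a_id, b_id, entry))
    return out


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------


def _biomarker_checks(
    study: CineStudy, config: ScreeningConfig
) -> list[FlagEntry]:
    try:
        bm = compute_biomarkers(study, papillary_mode=config.papillary_mode)
    except (IncompleteStudyError, CineQCError):
        return []  # completeness rules already cover unusable studies
    return check_volume_plausibility(bm, config) + check_sv_discordance(bm, config)


def run_qa_gt(
    cohort: list[CineStudy], config: ScreeningConfig | None = None
) -> tuple[dict[str, FlagReport], list[str]]:
    """Ground-truth quality assurance over a cohort (flag/exclude only).

    Runs completeness, coverage, gaps, anatomy relations, external
    components (flag-only: ground truth is never auto-modified), volume
    plausibility, SV discordance, and cohort-wide duplicate detection.
    Returns per-study reports and the exclusion list (studies with any
    ``exclude`` entry); all other flagged studies are candidates for manual
    review.
    """
    config = config or ScreeningConfig()
    reports = {s.study_id: FlagReport(study_id=s.study_id) for s in cohort}
    for study in cohort:
        rep = reports[study.study_id]
        rep.extend(check_frame_completeness(study))
        for phase in sorted(study.stacks):
            stack = study.stacks[phase]
            rep.extend(check_coverage(stack, config))
            rep.extend(check_gaps(stack))
            rep.extend(check_anatomy_relations(stack))
        entries, _ = check_external_components(study, config)
        rep.extend(entries)
        rep.extend(_biomarker_checks(study, config))
    for a_id, b_id, entry in find_duplicates(cohort):
        reports[a_id].entries.append(entry)
        if b_id != a_id:
            reports[b_id].entries.append(entry)
    for rep in reports.values():
        rep.sort()
    exclusion = sorted(
        sid for sid, rep in reports.items() if rep.has_severity("exclude")
    )
    return reports, exclusion


def run_qc_post(
    study: CineStudy,
    config: ScreeningConfig | None = None,
    apply_corrections: bool = False,
) -> tuple[CineStudy, FlagReport]:
    """Post-analysis QC of one (model-output) study, optionally auto-corrected.

    Runs gaps, anatomy relations, external components, volume plausibility
    and SV discordance.  With ``apply_corrections`` the external-component
    deletion plan is executed and biomarker checks re-run on the corrected
    study; all other issues are flagged but never modified.
    """
    config = config or ScreeningConfig()
    report = FlagReport(study_id=study.study_id)
    for phase in sorted(study.stacks):
        stack = study.stacks[phase]
        report.extend(check_gaps(stack))
        report.extend(check_anatomy_relations(stack))
    entries, plan = check_external_components(study, config)
    report.extend(entries)
    out = study
    if apply_corrections and plan:
        out, corrected_entries = apply_correction_plan(study, plan)
        report.extend(corrected_entries)
    report.extend(_biomarker_checks(out, config))
    report.sort()
    return out, report
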