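"""Synthetic SAX cine phantom with analytically known biomarkers.

The phantom is a stacked-disc voxelization of simple solids of revolution:

* LV blood pool: half-ellipsoid of revolution, endocardial radius profile
  ``r(z) = r_base * sqrt(1 - (z/L)^2)`` from base (z = 0, slice 0) to apex
  (z = L, the long-axis extent).
* LV myocardium: closed annulus of constant wall thickness ``w`` around the
  blood pool on every LV slice.
* RV blood pool: crescent — an annular sector of thickness ``t`` and angular
  extent ``theta`` that shares its inner (septal) border with the epicardium,
  so ventricle/myocardium adjacency rules are exercised realistically.
* Papillary muscles: spheres inside a blood pool that are *labelled* as
  blood (inclusion protocol) but *drawn* at myocardial intensity, giving the
  bimodal in-mask histogram that Otsu-based exclusion relies on.

A voxel is foreground iff its center lies inside the continuous solid, so
closed-form volumes of the solids are unbiased oracles for the voxel-count
volumes; discretization error shrinks with the spacing.  Intensities are
per-tissue means plus seeded Gaussian noise (bright-blood bSSFP contrast).
The same seed always reproduces the same study bit-for-bit.

:func:`inject_defect` produces every annotation-error class the screening
rules are designed to catch, as a minimal modification of a deep copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .biomarkers import MYO_DENSITY_G_PER_ML, BiomarkerSet
from .core_io import BG, CANONICAL_LABELS, CineStudy, ED, ES, LVBP, MYO, RVBP, LabelStack
from .errors import DefectError, PhantomSpecError

__all__ = [
    "LVPhaseGeom",
    "RVPhaseGeom",
    "PapillaryInclusion",
    "IntensityLevels",
    "PhantomSpec",
    "DefectSpec",
    "DEFECT_TARGET_RULE",
    "DEFECT_KINDS",
    "analytic_truth",
    "generate_phantom",
    "inject_defect",
    "default_phantom_spec",
    "random_phantom_spec",
    "default_defect",
]


@dataclass(frozen=True)
class LVPhaseGeom:
    """LV endocardial geometry for one phase: basal radius and long-axis extent."""

    base_radius_mm: float
    extent_mm: float

    def radius_at(self, z_mm: np.ndarray | float) -> np.ndarray:
        """Endocardial radius at depth z below the base plane (0 beyond apex)."""
        z = np.asarray(z_mm, dtype=float)
        frac = np.clip(1.0 - (z / self.extent_mm) ** 2, 0.0, None)
        return np.where(z < self.extent_mm, self.base_radius_mm * np.sqrt(frac), 0.0)


@dataclass(frozen=True)
class RVPhaseGeom:
    """RV crescent for one phase: wall-hugging annular sector."""

    thickness_mm: float
    angular_extent_deg: float
    extent_mm: float
    orientation_deg: float = 180.0  # sector center; 180 = septal side


@dataclass(frozen=True)
class PapillaryInclusion:
    """A spherical papillary muscle placed fractionally inside a chamber.

    Position is given relative to the chamber's own per-phase geometry
    (``z_frac`` of the long-axis extent; ``r_frac`` of the local endocardial
    radius for LV, of the crescent thickness for RV) so the same inclusion
    stays inside the cavity at both ED and ES.
    """

    chamber: str = "LV"  # LV | RV
    z_frac: float = 0.3
    r_frac: float = 0.5
    angle_deg: float = 90.0
    radius_mm: float = 6.0
    phases: tuple[str, ...] = (ED, ES)


@dataclass(frozen=True)
class IntensityLevels:
    """bSSFP-like tissue intensities (arbitrary units) and noise level."""

    blood_mean: float = 300.0
    myo_mean: float = 100.0
    background_mean: float = 60.0
    noise_sd: float = 5.0


@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic study.

    ``seed`` fully determines the generated voxels and intensities.
    """

    study_id: str = "phantom"
    n_slices: int = 12
    grid: tuple[int, int] = (96, 96)
    spacing_mm: tuple[float, float, float] = (1.4, 1.4, 8.0)  # (row, col, slice)
    lv: dict[str, LVPhaseGeom] = field(
        default_factory=lambda: {
            ED: LVPhaseGeom(28.0, 90.0),
            ES: LVPhaseGeom(21.0, 70.0),
        }
    )
    wall_thickness_mm: dict[str, float] = field(
        default_factory=lambda: {ED: 8.0, ES: 11.0}
    )
    rv: dict[str, RVPhaseGeom] = field(
        default_factory=lambda: {
            ED: RVPhaseGeom(13.53, 200.0, 76.5),
            ES: RVPhaseGeom(8.30, 200.0, 59.5),
        }
    )
    papillary: list[PapillaryInclusion] = field(
        default_factory=lambda: [
            PapillaryInclusion("LV", 0.30, 0.50, 100.0, 6.0),
            PapillaryInclusion("LV", 0.45, 0.40, 250.0, 6.0),
        ]
    )
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    seed: int = 0
    meta: dict = field(
        default_factory=lambda: {
            "disease_group": "healthy",
            "scanner_vendor": "synthetic",
            "scanner_model": "phantom-1",
            "field_strength_T": 1.5,
        }
    )

    def validate(self) -> None:
        rs, cs, ss = self.spacing_mm
        if min(rs, cs, ss) <= 0:
            raise PhantomSpecError(f"non-positive spacing {self.spacing_mm}")
        half = (min(self.grid) - 1) / 2.0 * min(rs, cs)
        for phase in (ED, ES):
            geom, w, rvg = self.lv[phase], self.wall_thickness_mm[phase], self.rv[phase]
            if geom.base_radius_mm <= 0 or geom.extent_mm <= 0 or w <= 0:
                raise PhantomSpecError(f"{phase}: non-positive LV geometry")
            if w >= geom.base_radius_mm:
                raise PhantomSpecError(
                    f"{phase}: wall thickness {w} mm >= basal radius "
                    f"{geom.base_radius_mm} mm (self-intersecting geometry)"
                )
            if rvg.thickness_mm <= 0 or not 0 < rvg.angular_extent_deg <= 360:
                raise PhantomSpecError(f"{phase}: invalid RV crescent {rvg}")
            if rvg.extent_mm > geom.extent_mm:
                raise PhantomSpecError(
                    f"{phase}: RV extent {rvg.extent_mm} mm exceeds LV extent"
                )
            reach = geom.base_radius_mm + w + rvg.thickness_mm
            if reach > half - 2.0:
                raise PhantomSpecError(
                    f"{phase}: geometry (radial reach {reach:.1f} mm) does not fit "
                    f"the {self.grid} grid at spacing {self.spacing_mm}"
                )
            if self.n_slices * ss < geom.extent_mm:
                raise PhantomSpecError(
                    f"{phase}: stack ({self.n_slices} x {ss} mm) shorter than the "
                    f"LV extent {geom.extent_mm} mm"
                )
        for pap in self.papillary:
            for phase in pap.phases:
                self._pap_center(pap, phase)  # raises if it does not fit

    def _pap_center(self, pap: PapillaryInclusion, phase: str):
        """(zc, yc, xc) in mm of an inclusion center; validates containment."""
        geom = self.lv[phase]
        if pap.chamber == "LV":
            zc = pap.z_frac * geom.extent_mm
            rho = pap.r_frac * float(geom.radius_at(zc))
            lo = max(zc - pap.radius_mm, 0.0)
            hi = min(zc + pap.radius_mm, geom.extent_mm)
            r_min = float(min(geom.radius_at(lo), geom.radius_at(hi)))
            if rho + pap.radius_mm > r_min or zc - pap.radius_mm < 0 or hi < zc + pap.radius_mm:
                raise PhantomSpecError(
                    f"papillary inclusion does not fit inside LV cavity at {phase}"
                )
        elif pap.chamber == "RV":
            rvg = self.rv[phase]
            zc = pap.z_frac * rvg.extent_mm
            r_in = float(geom.radius_at(zc)) + self.wall_thickness_mm[phase]
            rho = r_in + pap.r_frac * rvg.thickness_mm
            if (
                pap.r_frac * rvg.thickness_mm < pap.radius_mm
                or (1 - pap.r_frac) * rvg.thickness_mm < pap.radius_mm
            ):
                raise PhantomSpecError(
                    f"papillary inclusion does not fit inside RV crescent at {phase}"
                )
        else:
            raise PhantomSpecError(f"unknown chamber {pap.chamber!r}")
        a = math.radians(pap.angle_deg)
        return zc, rho * math.sin(a), rho * math.cos(a)


# ---------------------------------------------------------------------------
# Closed-form volumes of the continuous solids
# ---------------------------------------------------------------------------


def _ellipse_arc_integral(upper: float, extent: float) -> float:
    """integral_0^min(upper, L) sqrt(1 - (z/L)^2) dz, closed form."""
    u = min(upper, extent) / extent
    return extent / 2.0 * (math.asin(u) + u * math.sqrt(max(0.0, 1.0 - u * u)))


def _lv_blood_volume_mm3(geom: LVPhaseGeom) -> float:
    # integral of pi r^2 (1 - z^2/L^2) over [0, L]
    return 2.0 / 3.0 * math.pi * geom.base_radius_mm**2 * geom.extent_mm


def _myo_volume_mm3(geom: LVPhaseGeom, wall: float) -> float:
    # annulus: pi * integral (2 w r(z) + w^2) dz over [0, L]
    int_r = geom.base_radius_mm * _ellipse_arc_integral(geom.extent_mm, geom.extent_mm)
    return math.pi * (2.0 * wall * int_r + wall**2 * geom.extent_mm)


def _rv_volume_mm3(geom: LVPhaseGeom, wall: float, rvg: RVPhaseGeom) -> float:
    # annular sector: 0.5 theta * integral ((r_epi + t)^2 - r_epi^2) dz
    theta = math.radians(rvg.angular_extent_deg)
    int_repi = (
        geom.base_radius_mm * _ellipse_arc_integral(rvg.extent_mm, geom.extent_mm)
        + wall * rvg.extent_mm
    )
    t = rvg.thickness_mm
    return 0.5 * theta * (2.0 * t * int_repi + t**2 * rvg.extent_mm)


def analytic_truth(spec: PhantomSpec) -> BiomarkerSet:
    """Ground-truth biomarkers from the continuous geometry (papillary in blood)."""
    vols = {}
    for phase in (ED, ES):
        geom, w, rvg = spec.lv[phase], spec.wall_thickness_mm[phase], spec.rv[phase]
        vols[phase] = {
            "lv": _lv_blood_volume_mm3(geom) / 1000.0,
            "myo": _myo_volume_mm3(geom, w) / 1000.0,
            "rv": _rv_volume_mm3(geom, w, rvg) / 1000.0,
        }
    return BiomarkerSet(
        LVEDV=vols[ED]["lv"],
        LVESV=vols[ES]["lv"],
        LVM=vols[ED]["myo"] * MYO_DENSITY_G_PER_ML,
        RVEDV=vols[ED]["rv"],
        RVESV=vols[ES]["rv"],
        provenance={"analytic": True, "papillary_excluded": False},
    )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _phase_masks(spec: PhantomSpec, phase: str):
    """Boolean masks (lv, myo, rv, papillary) for one phase, voxel-center rule."""
    rows, cols = spec.grid
    rs, cs, ss = spec.spacing_mm
    z = (np.arange(spec.n_slices) + 0.5) * ss
    y = (np.arange(rows) - (rows - 1) / 2.0) * rs
    x = (np.arange(cols) - (cols - 1) / 2.0) * cs
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    d = np.sqrt(yy**2 + xx**2)  # in-plane distance from the LV long axis

    geom, wall, rvg = spec.lv[phase], spec.wall_thickness_mm[phase], spec.rv[phase]
    r_endo = geom.radius_at(z)[:, None, None]
    in_lv_slices = (z < geom.extent_mm)[:, None, None]
    lv = in_lv_slices & (d <= r_endo)
    myo = in_lv_slices & (d > r_endo) & (d <= r_endo + wall)

    ang = np.degrees(np.arctan2(yy, xx))
    dang = np.abs((ang - rvg.orientation_deg + 180.0) % 360.0 - 180.0)
    in_rv_slices = (z < rvg.extent_mm)[:, None, None]
    r_epi = r_endo + wall
    rv = (
        in_rv_slices
        & (dang <= rvg.angular_extent_deg / 2.0)
        & (d > r_epi)
        & (d <= r_epi + rvg.thickness_mm)
    )

    pap = np.zeros_like(lv)
    for inc in spec.papillary:
        if phase not in inc.phases:
            continue
        zc, yc, xc = spec._pap_center(inc, phase)
        sphere = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= inc.radius_mm**2
        pap |= sphere & (lv if inc.chamber == "LV" else rv)
    return lv, myo, rv, pap


def generate_phantom(spec: PhantomSpec) -> tuple[CineStudy, BiomarkerSet]:
    """Voxelize a spec into a CineStudy plus its analytic ground truth.

    Papillary inclusions are labelled as blood (inclusion-protocol ground
    truth) but drawn at myocardial intensity; their per-phase voxel counts
    are recorded under ``study.meta["papillary_truth"]``.
    """
    spec.validate()
    rs, cs, ss = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)
    lev = spec.intensity_levels
    stacks: dict[str, LabelStack] = {}
    intensities: dict[str, np.ndarray] = {}
    pap_truth: dict[str, dict[str, int]] = {}
    for phase in (ED, ES):  # fixed order so the seed stream is reproducible
        lv, myo, rv, pap = _phase_masks(spec, phase)
        labels = np.zeros((spec.n_slices, *spec.grid), dtype=np.int16)
        labels[lv] = LVBP
        labels[myo] = MYO
        labels[rv] = RVBP
        intensity = np.full(labels.shape, lev.background_mean, dtype=np.float64)
        intensity[lv | rv] = lev.blood_mean
        intensity[myo | pap] = lev.myo_mean
        if lev.noise_sd > 0:
            intensity += rng.normal(0.0, lev.noise_sd, size=intensity.shape)
        stacks[phase] = LabelStack(
            voxels=labels,
            in_plane_spacing=(rs, cs),
            slice_spacing=ss,
            label_map=dict(CANONICAL_LABELS),
            phase_tag=phase,
        )
        intensities[phase] = intensity
        pap_truth[phase] = {
            "LV": int((pap & lv).sum()),
            "RV": int((pap & rv).sum()),
        }
    meta = dict(spec.meta)
    meta.update(
        {
            "lv_phases": [ED, ES],
            "rv_phases": [ED, ES],
            "papillary_truth": pap_truth,
            "seed": spec.seed,
        }
    )
    study = CineStudy(
        study_id=spec.study_id, stacks=stacks, intensities=intensities, meta=meta
    )
    return study, analytic_truth(spec)


# ---------------------------------------------------------------------------
# Study-condition generators
# ---------------------------------------------------------------------------


def default_phantom_spec(seed: int = 0, study_id: str = "phantom", **overrides) -> PhantomSpec:
    """The fixed reference phantom (healthy adult-sized heart)."""
    return replace(PhantomSpec(study_id=study_id, seed=seed), **overrides)


def random_phantom_spec(
    seed: int,
    study_id: str | None = None,
    spacing_mm: tuple[float, float, float] = (1.4, 1.4, 8.0),
    grid: tuple[int, int] = (96, 96),
    n_slices: int = 12,
    papillary: Optional[list[PapillaryInclusion]] = None,
) -> PhantomSpec:
    """A physiologically plausible random phantom, fully determined by `seed`.

    Sampling ranges emulate a healthy-to-mildly-dilated adult cohort: LV
    basal endocardial radius 24-29 mm, LV extent 80-95 mm, EF 50-65%, wall
    7-9 mm (ED) with 2-4 mm systolic thickening, RVEDV 85-105% of LVEDV and
    RVSV within +/-8% of LVSV (the RV crescent thickness is solved from the
    target volume in closed form).
    """
    rng = np.random.default_rng(seed)
    r_ed = rng.uniform(24.0, 29.0)
    l_ed = rng.uniform(80.0, 95.0)
    ef = rng.uniform(0.50, 0.65)
    lvedv = _lv_blood_volume_mm3(LVPhaseGeom(r_ed, l_ed))
    l_es = 0.78 * l_ed
    lvesv = (1.0 - ef) * lvedv
    r_es = math.sqrt(3.0 * lvesv / (2.0 * math.pi * l_es))
    w_ed = rng.uniform(7.0, 9.0)
    w_es = w_ed + rng.uniform(2.0, 4.0)

    theta = rng.uniform(190.0, 220.0)
    rvedv = lvedv * rng.uniform(0.85, 1.05)
    rvsv = (lvedv - lvesv) * (1.0 + rng.uniform(-0.08, 0.08))
    rvesv = rvedv - rvsv

    def solve_thickness(geom: LVPhaseGeom, wall: float, l_rv: float, target: float) -> float:
        th = math.radians(theta)
        a = geom.base_radius_mm * _ellipse_arc_integral(l_rv, geom.extent_mm) + wall * l_rv
        # 0.5*th*(l_rv t^2 + 2 a t) = target
        disc = (th * a) ** 2 + 2.0 * th * l_rv * target
        return (-th * a + math.sqrt(disc)) / (th * l_rv)

    lv_geom = {ED: LVPhaseGeom(r_ed, l_ed), ES: LVPhaseGeom(r_es, l_es)}
    rv_geom = {}
    for phase, wall, target in ((ED, w_ed, rvedv), (ES, w_es, rvesv)):
        l_rv = 0.85 * lv_geom[phase].extent_mm
        t = solve_thickness(lv_geom[phase], wall, l_rv, target)
        rv_geom[phase] = RVPhaseGeom(t, theta, l_rv)

    if papillary is None:
        papillary = [
            PapillaryInclusion("LV", 0.28, 0.45, 100.0, 4.5),
            PapillaryInclusion("LV", 0.45, 0.40, 250.0, 4.5),
        ]
    spec = PhantomSpec(
        study_id=study_id or f"phantom-{seed:05d}",
        n_slices=n_slices,
        grid=grid,
        spacing_mm=spacing_mm,
        lv=lv_geom,
        wall_thickness_mm={ED: w_ed, ES: w_es},
        rv=rv_geom,
        papillary=papillary,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

#: screening rule each defect kind is designed to trigger
DEFECT_TARGET_RULE: dict[str, str] = {
    "missing_phase": "frame_completeness",
    "dropped_basal_slices": "coverage_extent",
    "dropped_apical_slices": "coverage_apex",
    "mid_stack_gap": "gap",
    "stray_component": "external_component",
    "myocardial_hole": "myo_ring_breach",
    "oversize_scale": "volume_range",
    "undersize_scale": "volume_range",
    "sv_discordance": "sv_discordance",
    "duplicate_of": "duplicate",
    "absent_class": "myo_ring_breach",
}

DEFECT_KINDS = tuple(DEFECT_TARGET_RULE)


@dataclass(frozen=True)
class DefectSpec:
    """A named annotation defect with parameters and the rule it must trigger."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_TARGET_RULE:
            raise DefectError(f"unknown defect kind {self.kind!r}")

    @property
    def target_rule(self) -> str:
        return DEFECT_TARGET_RULE[self.kind]


def default_defect(kind: str, seed: int = 0, **params) -> DefectSpec:
    """A DefectSpec with parameters strong enough to trigger its rule."""
    defaults: dict[str, dict] = {
        "missing_phase": {"phase": ES},
        "dropped_basal_slices": {"k": 6, "phase": ES},
        "dropped_apical_slices": {"k": 5, "phase": ED},
        "mid_stack_gap": {"n_gap": 2, "phase": ED},
        "stray_component": {"label": LVBP, "size": 50, "phase": ED},
        "myocardial_hole": {"arc_deg": 40.0, "phase": ED, "center_angle_deg": 0.0},
        "oversize_scale": {"factor": 2.0},
        "undersize_scale": {"factor": 0.4},
        "sv_discordance": {"factor": 2.5},
        "duplicate_of": {"phase": ED},
        "absent_class": {"class_name": "MYO", "phase": ES},
    }
    merged = {**defaults[kind], **params}
    return DefectSpec(kind=kind, params=merged, seed=seed)


def _zero_slices(stack: LabelStack, slices) -> None:
    stack.voxels[list(slices)] = BG


def inject_defect(
    study: CineStudy, defect: DefectSpec, source_study: CineStudy | None = None
) -> CineStudy:
    """Return a deep copy of `study` with one defect applied minimally.

    ``duplicate_of`` requires `source_study` (the study whose stack is
    copied in).  Raises :class:`DefectError` when the defect cannot be
    applied to this study.
    """
    out = study.copy()
    p = defect.params
    kind = defect.kind

    def stack_for(phase: str) -> LabelStack:
        if phase not in out.stacks:
            raise DefectError(f"{kind}: study has no phase {phase!r}")
        return out.stacks[phase]

    if kind == "missing_phase":
        phase = p["phase"]
        stack_for(phase)
        del out.stacks[phase]
        out.intensities.pop(phase, None)

    elif kind in ("dropped_basal_slices", "dropped_apical_slices"):
        stack = stack_for(p["phase"])
        k = int(p["k"])
        lv_slices = stack.slices_with(LVBP)
        if k >= len(lv_slices):
            raise DefectError(f"{kind}: cannot drop {k} of {len(lv_slices)} LV slices")
        chosen = lv_slices[:k] if kind == "dropped_basal_slices" else lv_slices[-k:]
        _zero_slices(stack, chosen)

    elif kind == "mid_stack_gap":
        stack = stack_for(p["phase"])
        if "slices" in p:
            gap = [int(s) for s in p["slices"]]
        else:
            lv_slices = stack.slices_with(LVBP)
            n_gap = int(p.get("n_gap", 2))
            if len(lv_slices) < n_gap + 2:
                raise DefectError("mid_stack_gap: too few segmented slices")
            mid = len(lv_slices) // 2
            gap = list(lv_slices[mid : mid + n_gap])
        interior = set(range(int(stack.slices_with(LVBP)[0]) + 1, int(stack.slices_with(LVBP)[-1])))
        if not set(gap) <= interior:
            raise DefectError(f"mid_stack_gap: slices {gap} are not interior")
        _zero_slices(stack, gap)

    elif kind == "stray_component":
        stack = stack_for(p["phase"])
        size = int(p["size"])
        n_slices, rows, cols = stack.voxels.shape
        width = max(4, math.ceil(math.sqrt(size)))
        height = math.ceil(size / width)
        sl = int(p.get("slice", 0))
        r0, c0 = int(p.get("row", 2)), int(p.get("col", 2))
        if r0 + height + 1 >= rows or c0 + width + 1 >= cols:
            raise DefectError("stray_component: block does not fit the grid")
        # the block plus a 1-voxel margin must be background (8/face-disjoint)
        lo_s, hi_s = max(sl - 1, 0), min(sl + 2, n_slices)
        region = stack.voxels[lo_s:hi_s, r0 - 1 : r0 + height + 1, c0 - 1 : c0 + width + 1]
        if np.any(region != BG):
            raise DefectError("stray_component: target region touches the heart")
        flat = np.arange(size)
        rr = r0 + flat // width
        cc = c0 + flat % width
        stack.voxels[sl, rr, cc] = int(p.get("label", LVBP))

    elif kind == "myocardial_hole":
        stack = stack_for(p["phase"])
        arc = float(p.get("arc_deg", 40.0))
        center = float(p.get("center_angle_deg", 0.0))
        rows, cols = stack.voxels.shape[1:]
        y = (np.arange(rows) - (rows - 1) / 2.0)[:, None]
        x = (np.arange(cols) - (cols - 1) / 2.0)[None, :]
        ang = np.degrees(np.arctan2(y * stack.in_plane_spacing[0], x * stack.in_plane_spacing[1]))
        in_arc = np.abs((ang - center + 180.0) % 360.0 - 180.0) <= arc / 2.0
        myo = stack.voxels == MYO
        hole = myo & in_arc[None, :, :]
        if not hole.any():
            raise DefectError("myocardial_hole: arc removes no myocardium")
        stack.voxels[hole] = BG

    elif kind in ("oversize_scale", "undersize_scale"):
        factor = float(p["factor"])
        if factor <= 0 or (kind == "oversize_scale") != (factor > 1.0):
            raise DefectError(f"{kind}: inapplicable factor {factor}")
        for stack in out.stacks.values():
            stack.in_plane_spacing = (
                stack.in_plane_spacing[0] * factor,
                stack.in_plane_spacing[1] * factor,
            )
            stack.slice_spacing *= factor

    elif kind == "sv_discordance":
        factor = float(p["factor"])
        stack = stack_for(p.get("phase", ES))
        mask = stack.voxels == RVBP
        n0 = int(mask.sum())
        if n0 == 0:
            raise DefectError("sv_discordance: no RV blood pool at ES")
        target = int(round(factor * n0))
        if factor > 1.0:
            # grow the crescent in-plane into background until the target count
            grow_struct = np.zeros((3, 3, 3), dtype=bool)
            grow_struct[1] = True
            for _ in range(10_000):
                if int(mask.sum()) >= target:
                    break
                ring = ndimage.binary_dilation(mask, structure=grow_struct) & (
                    stack.voxels == BG
                )
                if not ring.any():
                    raise DefectError("sv_discordance: no room to grow the RV")
                mask |= ring
            stack.voxels[mask] = RVBP
        else:
            # shrink from the apex downward, partial slice in row-major order
            to_remove = n0 - target
            for sl in stack.slices_with(RVBP)[::-1]:
                if to_remove <= 0:
                    break
                rr, cc = np.nonzero(stack.voxels[sl] == RVBP)
                take = min(to_remove, len(rr))
                stack.voxels[sl, rr[-take:], cc[-take:]] = BG
                to_remove -= take

    elif kind == "duplicate_of":
        if source_study is None:
            raise DefectError("duplicate_of requires source_study")
        phase = p.get("phase", ED)
        if phase not in source_study.stacks:
            raise DefectError(f"duplicate_of: source lacks phase {phase!r}")
        stack_for(phase)
        out.stacks[phase] = source_study.stacks[phase].copy()
        out.stacks[phase].phase_tag = phase
        out.intensities.pop(phase, None)
        out.meta["duplicate_source"] = source_study.study_id

    elif kind == "absent_class":
        stack = stack_for(p.get("phase", ES))
        label = CANONICAL_LABELS[p.get("class_name", "MYO")]
        mask = stack.voxels == label
        if not mask.any():
            raise DefectError(f"absent_class: class already absent at {p.get('phase')}")
        stack.voxels[mask] = BG

    out.meta.setdefault("injected_defects", []).append(
        {"kind": kind, "params": {k: (v if not isinstance(v, (list, tuple)) else list(v)) for k, v in p.items()}}
    )
    return out


# ---------------------------------------------------------------------------
# JSON (de)serialization of specs, for the CLI
# ---------------------------------------------------------------------------


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "study_id": spec.study_id,
        "n_slices": spec.n_slices,
        "grid": list(spec.grid),
        "spacing_mm": list(spec.spacing_mm),
        "lv": {p: [g.base_radius_mm, g.extent_mm] for p, g in spec.lv.items()},
        "wall_thickness_mm": dict(spec.wall_thickness_mm),
        "rv": {
            p: [g.thickness_mm, g.angular_extent_deg, g.extent_mm, g.orientation_deg]
            for p, g in spec.rv.items()
        },
        "papillary": [
            {
                "chamber": i.chamber,
                "z_frac": i.z_frac,
                "r_frac": i.r_frac,
                "angle_deg": i.angle_deg,
                "radius_mm": i.radius_mm,
                "phases": list(i.phases),
            }
            for i in spec.papillary
        ],
        "intensity_levels": {
            "blood_mean": spec.intensity_levels.blood_mean,
            "myo_mean": spec.intensity_levels.myo_mean,
            "background_mean": spec.intensity_levels.background_mean,
            "noise_sd": spec.intensity_levels.noise_sd,
        },
        "seed": spec.seed,
        "meta": dict(spec.meta),
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    base = PhantomSpec()
    spec = PhantomSpec(
        study_id=d.get("study_id", base.study_id),
        n_slices=int(d.get("n_slices", base.n_slices)),
        grid=tuple(d.get("grid", base.grid)),
        spacing_mm=tuple(d.get("spacing_mm", base.spacing_mm)),
        lv={p: LVPhaseGeom(*v) for p, v in d["lv"].items()} if "lv" in d else base.lv,
        wall_thickness_mm=dict(d.get("wall_thickness_mm", base.wall_thickness_mm)),
        rv={p: RVPhaseGeom(*v) for p, v in d["rv"].items()} if "rv" in d else base.rv,
        papillary=[
            PapillaryInclusion(
                chamber=i.get("chamber", "LV"),
                z_frac=i["z_frac"],
                r_frac=i["r_frac"],
                angle_deg=i["angle_deg"],
                radius_mm=i["radius_mm"],
                phases=tuple(i.get("phases", (ED, ES))),
            )
            for i in d["papillary"]
        ]
        if "papillary" in d
        else base.papillary,
        intensity_levels=IntensityLevels(**d["intensity_levels"])
        if "intensity_levels" in d
        else base.intensity_levels,
        seed=int(d.get("seed", 0)),
        meta=dict(d.get("meta", base.meta)),
    )
    spec.validate()
    return spec
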