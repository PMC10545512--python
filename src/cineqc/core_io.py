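"""Canonical data model and file I/O for SAX cine segmentation studies.

The package works on short-axis (SAX) stacks of integer label volumes, one
stack per segmented cardiac phase (typically end-diastole ``ED`` and
end-systole ``ES``).  The canonical label vocabulary is fixed:

=========  ==  =========================================
class      id  meaning
=========  ==  =========================================
BG          0  background
LVBP        1  left-ventricular blood pool
MYO         2  left-ventricular myocardium
RVBP        3  right-ventricular blood pool
PAP         4  papillary muscle (refinement output only)
=========  ==  =========================================

On disk a stack is a NIfTI-1 volume plus a JSON sidecar declaring the label
map, phase tag, voxel spacings and slice direction; a study is a directory
of such pairs tied together by a manifest table.  Sidecars may declare a
permuted label encoding, which is remapped to the canonical one on load;
they may also declare ``slice0: apex``, which triggers a flip so that in
memory slice index 0 is always the most basal slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    GeometryError,
    LabellingError,
    ManifestError,
)

BG, LVBP, MYO, RVBP, PAP = 0, 1, 2, 3, 4

#: canonical label vocabulary (PAP only appears after papillary refinement)
CANONICAL_LABELS: dict[str, int] = {"BG": BG, "LVBP": LVBP, "MYO": MYO, "RVBP": RVBP}
EXTENDED_LABELS: dict[str, int] = {**CANONICAL_LABELS, "PAP": PAP}

ED, ES = "ED", "ES"


@dataclass
class LabelStack:
    """One cardiac phase's 3D integer label volume with voxel geometry.

    Parameters
    ----------
    voxels
        3D integer array indexed ``(slice, row, col)``; slice 0 is the most
        basal slice.
    in_plane_spacing
        (row, col) spacing in mm per voxel edge.
    slice_spacing
        Center-to-center distance between adjacent slices in mm
        (slice thickness + gap); one voxel's volume is
        ``row_spacing * col_spacing * slice_spacing``.
    label_map
        Name-to-id mapping; canonical after loading.
    phase_tag
        ``"ED"``, ``"ES"`` or a frame identifier string.
    """

    voxels: np.ndarray
    in_plane_spacing: tuple[float, float]
    slice_spacing: float
    label_map: dict[str, int] = field(default_factory=lambda: dict(CANONICAL_LABELS))
    phase_tag: str = ED

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise LabellingError(
                f"label voxels must be integer, got dtype {self.voxels.dtype}"
            )
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise GeometryError(
                f"label volume must be 3D (slice,row,col), got shape {self.voxels.shape}"
            )
        rs, cs = (float(s) for s in self.in_plane_spacing)
        if rs <= 0 or cs <= 0 or float(self.slice_spacing) <= 0:
            raise GeometryError(
                f"spacings must be strictly positive, got in-plane {self.in_plane_spacing}, "
                f"slice {self.slice_spacing}"
            )
        self.in_plane_spacing = (rs, cs)
        self.slice_spacing = float(self.slice_spacing)
        allowed = set(self.label_map.values())
        values, counts = np.unique(self.voxels, return_counts=True)
        for value, count in zip(values, counts):
            if int(value) not in allowed:
                raise LabellingError(
                    f"unknown label value {int(value)} on {int(count)} voxel(s); "
                    f"declared vocabulary {sorted(allowed)}"
                )

    # -- geometry helpers -------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        r, c = self.in_plane_spacing
        return r * c * self.slice_spacing

    def copy(self) -> "LabelStack":
        return replace(
            self, voxels=self.voxels.copy(), label_map=dict(self.label_map)
        )

    def slices_with(self, label: int) -> np.ndarray:
        """Sorted indices of slices containing at least one voxel of `label`."""
        return np.flatnonzero((self.voxels == label).any(axis=(1, 2)))


@dataclass
class CineStudy:
    """A subject's segmented SAX phases plus optional intensities and metadata.

    ``meta`` may declare ``lv_phases``/``rv_phases`` as (ED-frame, ES-frame)
    tuples; the ventricles need not be segmented in the same frames.
    """

    study_id: str
    stacks: dict[str, LabelStack]
    intensities: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, vol in self.intensities.items():
            if tag not in self.stacks:
                raise ConsistencyError(
                    f"intensity volume for phase {tag!r} has no matching label stack"
                )
            if np.asarray(vol).shape != self.stacks[tag].voxels.shape:
                raise ConsistencyError(
                    f"intensity/label shape mismatch for phase {tag!r}: "
                    f"{np.asarray(vol).shape} vs {self.stacks[tag].voxels.shape}"
                )

    def copy(self) -> "CineStudy":
        return CineStudy(
            study_id=self.study_id,
            stacks={t: s.copy() for t, s in self.stacks.items()},
            intensities={t: v.copy() for t, v in self.intensities.items()},
            meta=json.loads(json.dumps(self.meta)),
        )


@dataclass(frozen=True)
class FlagEntry:
    """One QA/QC finding."""

    rule_id: str
    severity: str  # exclude | flag | corrected
    phase_tag: str
    location: str
    detail: str

    def sort_key(self) -> tuple:
        return (self.rule_id, self.phase_tag, self.location, self.detail)


@dataclass
class FlagReport:
    """Ordered collection of QA/QC findings for one study (may be empty)."""

    study_id: str
    entries: list[FlagEntry] = field(default_factory=list)

    def add(
        self,
        rule_id: str,
        severity: str,
        phase_tag: str = "",
        location: str = "",
        detail: str = "",
    ) -> None:
        if severity not in ("exclude", "flag", "corrected"):
            raise ValueError(f"unknown severity {severity!r}")
        self.entries.append(FlagEntry(rule_id, severity, phase_tag, location, detail))

    def extend(self, entries: Iterable[FlagEntry]) -> None:
        self.entries.extend(entries)

    def sort(self) -> None:
        self.entries.sort(key=FlagEntry.sort_key)

    def has_severity(self, severity: str) -> bool:
        return any(e.severity == severity for e in self.entries)

    def rule_ids(self) -> set[str]:
        return {e.rule_id for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study_id": self.study_id,
                    "phase": e.phase_tag,
                    "rule_id": e.rule_id,
                    "severity": e.severity,
                    "location": e.location,
                    "detail": e.detail,
                }
                for e in self.entries
            ],
            columns=["study_id", "phase", "rule_id", "severity", "location", "detail"],
        )


def reports_to_csv(reports: Iterable[FlagReport], path: str | Path) -> None:
    """Write a cohort of flag reports as one CSV table."""
    frames = [r.to_dataframe() for r in reports]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["study_id", "phase", "rule_id", "severity", "location", "detail"]
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------


def _canonicalize(voxels: np.ndarray, declared: Mapping[str, int]) -> np.ndarray:
    """Remap a declared (possibly permuted) label encoding to canonical ids."""
    target = EXTENDED_LABELS
    unknown = set(declared) - set(target)
    if unknown:
        raise LabellingError(f"sidecar declares unknown class names {sorted(unknown)}")
    if all(declared[name] == target[name] for name in declared):
        return voxels
    out = np.full_like(voxels, -1)
    for name, src in declared.items():
        out[voxels == src] = target[name]
    stray = np.count_nonzero(out < 0)
    if stray:
        bad = np.unique(voxels[out < 0])
        raise LabellingError(
            f"voxel value(s) {bad.tolist()} not covered by the sidecar label_map "
            f"({stray} voxel(s))"
        )
    return out


def read_label_stack(volume_path: str | Path, sidecar_path: str | Path) -> LabelStack:
    """Read a NIfTI label volume + JSON sidecar into a validated LabelStack.

    Sidecar spacings override NIfTI header zooms when both are present; a
    ``slice0: apex`` sidecar flips the stack so slice 0 is basal in memory.
    """
    volume_path, sidecar_path = Path(volume_path), Path(sidecar_path)
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise LabellingError(
                f"{volume_path.name}: label volume stores non-integer values"
            )
        data = data.astype(np.int16)

    if "spacing_mm" in sidecar:
        row_sp, col_sp, slice_sp = (float(v) for v in sidecar["spacing_mm"])
    else:  # fall back to header zooms, stored as (slice, row, col)
        slice_sp, row_sp, col_sp = (float(z) for z in img.header.get_zooms()[:3])

    if sidecar.get("slice0", "base") == "apex":
        data = data[::-1].copy()

    declared = sidecar.get("label_map", CANONICAL_LABELS)
    declared = {k: int(v) for k, v in declared.items()}
    # validate raw values against the declared map before canonicalizing
    allowed = set(declared.values())
    values, counts = np.unique(data, return_counts=True)
    for value, count in zip(values, counts):
        if int(value) not in allowed:
            raise LabellingError(
                f"{volume_path.name}: unknown label value {int(value)} on "
                f"{int(count)} voxel(s); sidecar declares {sorted(allowed)}"
            )
    data = _canonicalize(data, declared)

    label_map = {name: EXTENDED_LABELS[name] for name in declared}
    stack = LabelStack(
        voxels=data,
        in_plane_spacing=(row_sp, col_sp),
        slice_spacing=slice_sp,
        label_map=label_map,
        phase_tag=str(sidecar.get("phase_tag", ED)),
    )
    return stack


def write_label_stack(
    stack: LabelStack, volume_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write a LabelStack as NIfTI + JSON sidecar; read_label_stack inverts it."""
    volume_path, sidecar_path = Path(volume_path), Path(sidecar_path)
    data = stack.voxels
    if not np.issubdtype(data.dtype, np.integer):
        raise LabellingError("labels are integer-only; refusing float storage")
    affine = np.diag(
        [stack.slice_spacing, stack.in_plane_spacing[0], stack.in_plane_spacing[1], 1.0]
    )
    img = nib.Nifti1Image(data.astype(np.int16), affine)
    img.header.set_zooms(
        (stack.slice_spacing, stack.in_plane_spacing[0], stack.in_plane_spacing[1])
    )
    nib.save(img, str(volume_path))
    sidecar = {
        "label_map": {k: int(v) for k, v in sorted(stack.label_map.items())},
        "phase_tag": stack.phase_tag,
        "spacing_mm": [
            stack.in_plane_spacing[0],
            stack.in_plane_spacing[1],
            stack.slice_spacing,
        ],
        "slice0": "base",
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_intensity_volume(
    volume: np.ndarray, stack: LabelStack, volume_path: str | Path
) -> None:
    """Write an intensity volume congruent with `stack` as float NIfTI."""
    if volume.shape != stack.voxels.shape:
        raise ConsistencyError(
            f"intensity shape {volume.shape} != label shape {stack.voxels.shape}"
        )
    affine = np.diag(
        [stack.slice_spacing, stack.in_plane_spacing[0], stack.in_plane_spacing[1], 1.0]
    )
    nib.save(nib.Nifti1Image(volume.astype(np.float32), affine), str(volume_path))


# ---------------------------------------------------------------------------
# Study-level I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["study_id", "phase_tag", "kind", "path"]


def write_study(study: CineStudy, directory: str | Path) -> Path:
    """Write a study's stacks (and intensities) plus manifest into `directory`.

    Returns the manifest path. Layout: ``<phase>_label.nii.gz`` +
    ``<phase>_label.json`` per phase, ``<phase>_image.nii.gz`` per intensity
    volume, ``manifest.csv``, ``meta.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tag in sorted(study.stacks):
        stack = study.stacks[tag]
        vol = directory / f"{tag}_label.nii.gz"
        write_label_stack(stack, vol, directory / f"{tag}_label.json")
        rows.append([study.study_id, tag, "label", vol.name])
        if tag in study.intensities:
            ivol = directory / f"{tag}_image.nii.gz"
            write_intensity_volume(study.intensities[tag], stack, ivol)
            rows.append([study.study_id, tag, "intensity", ivol.name])
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    with open(directory / "meta.json", "w") as fh:
        json.dump(study.meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_study(directory: str | Path, manifest: str | Path | None = None) -> CineStudy:
    """Load a CineStudy from a directory written by :func:`write_study`.

    `manifest` defaults to ``manifest.csv`` inside the directory; it may be a
    CSV or a JSON list of row objects with the same columns.
    """
    directory = Path(directory)
    manifest = Path(manifest) if manifest is not None else directory / "manifest.csv"
    if not manifest.exists():
        raise ManifestError(f"manifest not found: {manifest}")
    if manifest.suffix == ".json":
        with open(manifest) as fh:
            table = pd.DataFrame(json.load(fh))
    else:
        table = pd.read_csv(manifest)
    missing_cols = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ManifestError(f"manifest lacks columns {sorted(missing_cols)}")
    ids = table["study_id"].unique()
    if len(ids) != 1:
        raise ManifestError(f"manifest must describe one study, found ids {list(ids)}")

    stacks: dict[str, LabelStack] = {}
    intensities: dict[str, np.ndarray] = {}
    for _, row in table[table["kind"] == "label"].iterrows():
        vol = directory / str(row["path"])
        sidecar = vol.with_name(vol.name.replace(".nii.gz", ".json").replace(".nii", ".json"))
        if not vol.exists():
            raise ManifestError(f"declared label volume missing: {vol}")
        stacks[str(row["phase_tag"])] = read_label_stack(vol, sidecar)
    for _, row in table[table["kind"] == "intensity"].iterrows():
        tag = str(row["phase_tag"])
        vol = directory / str(row["path"])
        if not vol.exists():
            raise ManifestError(f"declared intensity volume missing: {vol}")
        if tag not in stacks:
            raise ManifestError(f"intensity for phase {tag!r} has no label stack")
        intensities[tag] = np.asanyarray(nib.load(str(vol)).dataobj).astype(np.float64)

    meta = {}
    meta_path = directory / "meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return CineStudy(
        study_id=str(ids[0]), stacks=stacks, intensities=intensities, meta=meta
    )
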