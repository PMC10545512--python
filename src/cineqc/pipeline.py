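"""Start-to-end cohort processing with a pluggable segmentation backend.

The pipeline mirrors a clinical analysis chain: load the canonical study
(format-normalized input), obtain segmentations from a backend, optionally
exclude papillary muscle, quantify biomarkers, and run post-analysis QC
with automatic correction of simple errors.  Network training/inference is
out of scope; backends satisfy a small contract instead:

* ``passthrough`` — returns the stored label stacks (testing, or re-QC of
  existing segmentations);
* ``command:<exe>`` — invokes ``<exe> <image.nii.gz> <labels.nii.gz>`` per
  phase on the intensity volumes and reads the integer result back in the
  canonical vocabulary.

Each study is isolated: a failure is logged and skipped, never aborting the
cohort.  Identical manifest + config + backend reproduce byte-identical
outputs (the run log carries a config hash but no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import subprocess
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import MYO_DENSITY_G_PER_ML, BiomarkerSet, compute_biomarkers
from .core_io import CineStudy, LabelStack, load_study, write_intensity_volume, write_study
from .errors import CineQCError, ConfigurationError, ManifestError
from .papillary import RefineConfig, refine_study
from .screening import ScreeningConfig, run_qc_post

__all__ = [
    "PassthroughBackend",
    "ExternalCommandBackend",
    "PipelineConfig",
    "PipelineResult",
    "make_backend",
    "run_pipeline",
]


class PassthroughBackend:
    """Returns the study's stored label stacks (ground-truth passthrough)."""

    name = "passthrough"

    def segment(self, study: CineStudy) -> dict[str, LabelStack]:
        return {tag: stack.copy() for tag, stack in study.stacks.items()}


class ExternalCommandBackend:
    """Invokes a user-supplied executable on NIfTI in/out, per phase."""

    def __init__(self, executable: str):
        self.executable = executable
        self.name = f"command:{executable}"

    def segment(self, study: CineStudy) -> dict[str, LabelStack]:
        if not study.intensities:
            raise ConfigurationError(
                f"backend {self.name} needs intensity volumes for {study.study_id}"
            )
        out: dict[str, LabelStack] = {}
        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            for tag in sorted(study.intensities):
                ref = study.stacks[tag]
                img = tmp_path / f"{tag}_image.nii.gz"
                seg = tmp_path / f"{tag}_labels.nii.gz"
                write_intensity_volume(study.intensities[tag], ref, img)
                subprocess.run(
                    [self.executable, str(img), str(seg)], check=True, capture_output=True
                )
                import nibabel as nib

                data = np.asanyarray(nib.load(str(seg)).dataobj)
                out[tag] = LabelStack(
                    voxels=np.rint(data).astype(np.int16),
                    in_plane_spacing=ref.in_plane_spacing,
                    slice_spacing=ref.slice_spacing,
                    label_map=dict(ref.label_map),
                    phase_tag=tag,
                )
        return out


def make_backend(name: str):
    if name == "passthrough":
        return PassthroughBackend()
    if name.startswith("command:"):
        return ExternalCommandBackend(name.split(":", 1)[1])
    raise ConfigurationError(f"unknown backend {name!r}")


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration (JSON-serializable)."""

    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    papillary_mode: str = "include"  # include | exclude
    refine: RefineConfig = field(default_factory=RefineConfig)
    myo_density_g_per_ml: float = MYO_DENSITY_G_PER_ML
    backend: str = "passthrough"
    apply_corrections: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "screening" in d:
            sc = dict(d["screening"])
            if "volume_ranges_ml" in sc:
                sc["volume_ranges_ml"] = {
                    k: tuple(v) for k, v in sc["volume_ranges_ml"].items()
                }
            d["screening"] = ScreeningConfig(**sc)
        if "refine" in d:
            d["refine"] = RefineConfig(**dict(d["refine"]))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Cohort-level outcome: exit code 0 (clean) or 2 (partial failures)."""

    biomarkers: pd.DataFrame
    reports: pd.DataFrame
    errors: list[dict]
    exit_code: int
    log_path: Path


def _study_biomarkers_row(study_id: str, bm: BiomarkerSet) -> dict:
    row = {"study_id": study_id}
    row.update({k: round(v, 6) for k, v in bm.as_dict().items()})
    return row


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Process every study in a cohort manifest; write per-study and cohort outputs.

    The manifest is a CSV with columns ``study_id, directory`` (directories
    resolved relative to the manifest); an optional ``series_type`` column
    filters to ``SAX`` rows, standing in for automatic view identification.
    Outputs under `out_dir`: ``biomarkers.csv``, ``qc_reports.csv``,
    ``run_log.json``, and per-study corrected stacks.
    """
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(manifest_path)
    if not {"study_id", "directory"} <= set(table.columns):
        raise ManifestError("cohort manifest needs columns study_id, directory")
    if "series_type" in table.columns:
        table = table[table["series_type"] == "SAX"]
    backend = make_backend(config.backend)

    bio_rows: list[dict] = []
    report_frames: list[pd.DataFrame] = []
    errors: list[dict] = []
    flag_counts: dict[str, int] = {}
    for _, row in table.iterrows():
        study_id = str(row["study_id"])
        try:
            directory = manifest_path.parent / str(row["directory"])
            study = load_study(directory)
            segmented = study.copy()
            segmented.stacks = backend.segment(study)
            if config.papillary_mode == "exclude":
                segmented, _ = refine_study(segmented, config.refine)
            corrected, report = run_qc_post(
                segmented,
                config.screening,
                apply_corrections=config.apply_corrections,
            )
            bm = compute_biomarkers(
                corrected, myo_density_g_per_ml=config.myo_density_g_per_ml
            )
            bio_rows.append(_study_biomarkers_row(study_id, bm))
            report_frames.append(report.to_dataframe())
            flag_counts[study_id] = len(report)
            write_study(corrected, out_dir / study_id)
            report.to_dataframe().to_csv(out_dir / study_id / "qc_report.csv", index=False)
        except (CineQCError, OSError, subprocess.CalledProcessError) as exc:
            errors.append({"study_id": study_id, "error": f"{type(exc).__name__}: {exc}"})

    biomarkers = pd.DataFrame(
        bio_rows,
        columns=["study_id", *BiomarkerSet.FIELDS],
    )
    reports = (
        pd.concat(report_frames, ignore_index=True)
        if report_frames
        else pd.DataFrame(columns=["study_id", "phase", "rule_id", "severity", "location", "detail"])
    )
    biomarkers.to_csv(out_dir / "biomarkers.csv", index=False)
    reports.to_csv(out_dir / "qc_reports.csv", index=False)
    log = {
        "cineqc_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "backend": backend.name,
        "n_studies": int(len(table)),
        "n_processed": len(bio_rows),
        "per_study_flag_counts": dict(sorted(flag_counts.items())),
        "errors": errors,
    }
    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        biomarkers=biomarkers,
        reports=reports,
        errors=errors,
        exit_code=2 if errors else 0,
        log_path=log_path,
    )
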