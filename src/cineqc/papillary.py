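"""Papillary-muscle exclusion from blood-pool masks via Otsu thresholding.

On bright-blood (bSSFP) cine images the blood pool is bright and muscle is
dark, so papillary muscles included in a blood-pool mask form a dark mode in
the intensity histogram of that mask.  Otsu's method picks the threshold
maximizing the between-class variance; voxels darker than the threshold are
reassigned out of the blood pool (to a dedicated ``PAP`` label by default,
so downstream volumetry can choose whether they count toward mass).

Histograms are built per ventricle and per phase rather than pooled, since
coil shading differs regionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BG, LVBP, MYO, PAP, RVBP, LabelStack
from .errors import ConfigurationError, ConsistencyError, DegenerateHistogramError

__all__ = [
    "IntensityHistogram",
    "RefineConfig",
    "otsu_threshold",
    "refine_blood_pool",
    "refine_study",
]


@dataclass
class IntensityHistogram:
    """Binned intensity histogram: ``len(bin_edges) == len(counts) + 1``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise ValueError("bin_edges and counts must be 1D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_values(cls, values: np.ndarray, bins: int = 256) -> "IntensityHistogram":
        counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
        return cls(bin_edges=edges, counts=counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def otsu_threshold(hist: IntensityHistogram) -> float:
    """Threshold (a bin edge) maximizing between-class variance.

    Candidate thresholds are the interior bin edges; for each split the
    statistic is ``w0 * w1 * (mu0 - mu1)**2`` with class means taken over
    bin centers.  Ties break toward the lowest threshold.  Raises
    :class:`DegenerateHistogramError` when all mass sits in one bin.
    """
    counts = hist.counts.astype(float)
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram has mass in fewer than 2 bins; no threshold separates it"
        )
    centers = hist.centers
    # cumulative class-0 weight/mean for split after bin k (k = 0 .. n-2)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.zeros_like(w0)
    bcv[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    k = int(np.argmax(bcv))  # first max == lowest threshold on ties
    return float(hist.bin_edges[k + 1])


@dataclass
class RefineConfig:
    """Configuration of the blood-pool refinement step.

    ``target`` chooses which ventricle's blood pool is refined;
    ``reassign_to`` is where removed voxels go (``PAP`` keeps them as a
    separate muscle label, ``MYO`` merges into myocardium, ``background``
    discards).  Dark islands of at most ``min_island_voxels`` voxels are
    treated as noise and kept as blood.  ``dark_is_muscle=False`` flips the
    polarity for non-bright-blood sequences.
    """

    bins: int = 256
    min_island_voxels: int = 2
    target: str = "both"  # LV | RV | both
    reassign_to: str = "PAP"  # MYO | background | PAP
    dark_is_muscle: bool = True
    #: minimum relative contrast (mu1 - mu0) / max(mu0, mu1) between the two
    #: Otsu classes for the split to be trusted.  A blood pool without muscle
    #: has a unimodal (noise-only) histogram, which Otsu happily splits down
    #: the middle; requiring real tissue contrast makes that case a no-op.
    min_contrast_fraction: float = 0.2

    def target_labels(self) -> list[int]:
        return {"LV": [LVBP], "RV": [RVBP], "both": [LVBP, RVBP]}[self.target]

    def reassign_label(self) -> int:
        return {"MYO": MYO, "background": BG, "PAP": PAP}[self.reassign_to]


# face adjacency across slices, 8-neighbour in plane (anisotropic stacks)
_ISLAND_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_ISLAND_STRUCTURE[1] = True
_ISLAND_STRUCTURE[0, 1, 1] = _ISLAND_STRUCTURE[2, 1, 1] = True

_VENTRICLE_NAME = {LVBP: "LV", RVBP: "RV"}


def refine_blood_pool(
    stack: LabelStack,
    intensity: np.ndarray,
    config: RefineConfig | None = None,
) -> tuple[LabelStack, dict]:
    """Remove dark (muscle) voxels from the blood pool(s) of one stack.

    Returns a new stack plus a per-ventricle summary
    ``{"LV": {"threshold", "moved_voxels", "warning"}, ...}``.  The output
    blood pool is always a subset of the input's; removed and reassigned
    voxel counts balance exactly.
    """
    config = config or RefineConfig()
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != stack.voxels.shape:
        raise ConsistencyError(
            f"intensity shape {intensity.shape} != label shape {stack.voxels.shape}"
        )
    out = stack.copy()
    dest = config.reassign_label()
    if dest == PAP and "PAP" not in out.label_map:
        out.label_map["PAP"] = PAP
    summary: dict[str, dict] = {}
    for label in config.target_labels():
        name = _VENTRICLE_NAME[label]
        mask = stack.voxels == label
        n_mask = int(mask.sum())
        entry = {"threshold": None, "moved_voxels": 0, "warning": None}
        summary[name] = entry
        if n_mask == 0:
            entry["warning"] = "empty blood pool; skipped"
            continue
        hist = IntensityHistogram.from_values(intensity[mask], bins=config.bins)
        try:
            thr = otsu_threshold(hist)
        except DegenerateHistogramError:
            entry["warning"] = "degenerate histogram; mask unchanged"
            continue
        values = intensity[mask]
        lo, hi = values[values < thr], values[values >= thr]
        if lo.size == 0 or hi.size == 0:
            entry["warning"] = "threshold separates no voxels; mask unchanged"
            continue
        mu0, mu1 = float(lo.mean()), float(hi.mean())
        contrast = abs(mu1 - mu0) / max(abs(mu0), abs(mu1), 1e-12)
        if contrast < config.min_contrast_fraction:
            entry["warning"] = (
                f"class contrast {contrast:.2f} below "
                f"{config.min_contrast_fraction:.2f}; unimodal histogram, "
                "mask unchanged"
            )
            continue
        entry["threshold"] = thr
        dark = mask & (
            (intensity < thr) if config.dark_is_muscle else (intensity >= thr)
        )
        # small dark islands are treated as noise and stay in the blood pool
        comp, n_comp = ndimage.label(dark, structure=_ISLAND_STRUCTURE)
        if n_comp:
            sizes = ndimage.sum_labels(dark, comp, index=np.arange(1, n_comp + 1))
            keep = np.flatnonzero(sizes <= config.min_island_voxels) + 1
            if keep.size:
                dark &= ~np.isin(comp, keep)
        moved = int(dark.sum())
        out.voxels[dark] = dest
        entry["moved_voxels"] = moved
    return out, summary


def refine_study(study, config: RefineConfig | None = None):
    """Apply :func:`refine_blood_pool` to every phase that has intensities.

    Returns ``(refined CineStudy, {phase: summary})``.  Raises
    :class:`ConfigurationError` when no phase carries an intensity volume.
    """
    config = config or RefineConfig()
    if not study.intensities:
        raise ConfigurationError(
            "papillary refinement requires intensity volumes; none present"
        )
    refined = study.copy()
    summaries: dict[str, dict] = {}
    for tag in sorted(study.intensities):
        new_stack, summary = refine_blood_pool(
            study.stacks[tag], study.intensities[tag], config
        )
        refined.stacks[tag] = new_stack
        summaries[tag] = summary
    return refined, summaries
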