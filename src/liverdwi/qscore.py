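"""ROI-based image-quality scoring for multi-repetition liver DWI.

Cardiac pulsation darkens the left liver lobe in a subset of diffusion-weighted
repetitions.  Post-processing that re-brightens those regions risks brightening
vessels (which flicker bright in single repetitions) and distorting regions that
were never corrupted.  This module quantifies that trade-off with four feature
scores computed over manually (or synthetically) segmented ROIs:

``PA``
    pulsation-artifact severity: mean intensity in the left lobe (R1) divided
    by mean intensity in the right lobe (R2).  Signal loss pushes it below 1.
``VD``
    vessel darkness: mean background-parenchyma intensity divided by mean
    vessel intensity.  Darker vessels give larger values.
``CNR``
    lesion contrast-to-noise ratio: (mean lesion - mean background) divided by
    the background standard deviation.
``DC``
    data consistency: 1 minus the relative mean absolute deviation from the
    reference image over the right lobe (a region assumed artifact-free),
    floored at 0.

Each score is designed so that *higher is better*.  Scores of a processed image
are normalized to those of the unprocessed trace-weighted reference image, and
their arithmetic mean is the total quality score ``Qtotal``; values above 1
mean the processing improved the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12

__all__ = [
    "RoiSet",
    "FeatureScores",
    "NormalizedScores",
    "trace_reference",
    "pa_score",
    "vd_score",
    "cnr_score",
    "dc_score",
    "raw_scores",
    "normalized_scores",
    "qtotal",
]


@dataclass
class RoiSet:
    """Named boolean masks on one H x W pixel grid.

    ``background`` is lesion-free, vessel-free parenchyma in the artifact-free
    (right) lobe; it provides the CNR denominator.  ``lesions`` may be absent
    (all-False) on slices without a lesion, in which case CNR is unavailable.
    """

    left_lobe: np.ndarray
    right_lobe: np.ndarray
    vessels: np.ndarray
    lesions: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        masks = {
            "left_lobe": self.left_lobe,
            "right_lobe": self.right_lobe,
            "vessels": self.vessels,
            "lesions": self.lesions,
            "background": self.background,
        }
        shape = None
        for name, m in masks.items():
            arr = np.asarray(m, dtype=bool)
            setattr(self, name, arr)
            if arr.ndim != 2:
                raise ValueError(f"mask {name!r} must be 2-D, got shape {arr.shape}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"mask {name!r} has shape {arr.shape}, expected {shape}"
                )
        if np.any(self.left_lobe & self.right_lobe):
            raise ValueError("left_lobe and right_lobe masks overlap")
        if np.any(self.vessels & self.lesions):
            raise ValueError("vessel and lesion masks overlap")
        if np.any(self.lesions & self.background):
            raise ValueError("lesion and background masks overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.left_lobe.shape

    @property
    def has_lesions(self) -> bool:
        return bool(self.lesions.any())

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "left_lobe": self.left_lobe,
            "right_lobe": self.right_lobe,
            "vessels": self.vessels,
            "lesions": self.lesions,
            "background": self.background,
        }


@dataclass(frozen=True)
class FeatureScores:
    """Raw (unnormalized) feature scores of a single image."""

    pa: float
    vd: float
    cnr: float
    dc: float

    def as_dict(self) -> dict[str, float]:
        return {"pa": self.pa, "vd": self.vd, "cnr": self.cnr, "dc": self.dc}


@dataclass(frozen=True)
class NormalizedScores:
    """Feature scores of a processed image relative to the reference image.

    By construction the reference scores itself (1, 1, 1, 1) and qtotal 1.
    """

    pa_n: float
    vd_n: float
    cnr_n: float
    dc_n: float
    qtotal: float = field(default=float("nan"))

    def as_dict(self) -> dict[str, float]:
        return {
            "pa_n": self.pa_n,
            "vd_n": self.vd_n,
            "cnr_n": self.cnr_n,
            "dc_n": self.dc_n,
            "qtotal": self.qtotal,
        }


def _masked_mean(image: np.ndarray, mask: np.ndarray, name: str) -> float:
    if not mask.any():
        raise ValueError(f"ROI {name!r} is empty")
    return float(np.mean(image[mask]))


def trace_reference(stack: np.ndarray, dirs_per_rep: int = 3) -> np.ndarray:
    """Trace-weighted reference image of a repetition stack.

    Consecutive groups of ``dirs_per_rep`` images (the orthogonal diffusion
    directions of one repetition) are combined voxelwise by their geometric
    mean; the per-repetition trace images are then averaged arithmetically.

    Parameters
    ----------
    stack
        H x W x N nonnegative intensities.
    dirs_per_rep
        Number of diffusion directions per repetition; N must be divisible.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"stack must be H x W x N, got shape {stack.shape}")
    n = stack.shape[2]
    if dirs_per_rep < 1 or n % dirs_per_rep:
        raise ValueError(
            f"stack depth {n} is not divisible by dirs_per_rep={dirs_per_rep}"
        )
    if np.any(stack < 0):
        raise ValueError("stack intensities must be nonnegative")
    groups = stack.reshape(stack.shape[0], stack.shape[1], -1, dirs_per_rep)
    geo = np.prod(groups, axis=3) ** (1.0 / dirs_per_rep)
    return geo.mean(axis=2)


def pa_score(image: np.ndarray, rois: RoiSet) -> float:
    """Pulsation-artifact score: mean(left lobe) / mean(right lobe)."""
    left = _masked_mean(image, rois.left_lobe, "left_lobe")
    right = _masked_mean(image, rois.right_lobe, "right_lobe")
    if right <= EPS:
        warnings.warn("right-lobe mean is ~0; PA denominator guarded", RuntimeWarning)
        right = EPS
    return left / right


def vd_score(image: np.ndarray, rois: RoiSet) -> float:
    """Vessel-darkness score: mean(background parenchyma) / mean(vessels)."""
    bg = _masked_mean(image, rois.background, "background")
    ves = _masked_mean(image, rois.vessels, "vessels")
    if ves <= EPS:
        warnings.warn("vessel mean is ~0; VD denominator guarded", RuntimeWarning)
        ves = EPS
    return bg / ves


def cnr_score(image: np.ndarray, rois: RoiSet) -> float:
    """Lesion contrast-to-noise ratio against background parenchyma.

    The denominator is the background standard deviation; it collapses when an
    image is constant over the liver, in which case the value is guarded and a
    warning emitted (large CNR from a flat image signals degeneracy, not
    quality).
    """
    lesion = _masked_mean(image, rois.lesions, "lesions")
    bg_vals = np.asarray(image)[rois.background]
    if bg_vals.size < 2:
        raise ValueError("background ROI needs at least 2 voxels for CNR")
    bg_mean = float(bg_vals.mean())
    bg_std = float(bg_vals.std())
    if bg_std <= EPS:
        warnings.warn(
            "background std is ~0 (constant liver signal); CNR guarded",
            RuntimeWarning,
        )
        bg_std = EPS
    return (lesion - bg_mean) / bg_std


def dc_score(image: np.ndarray, reference: np.ndarray, rois: RoiSet) -> float:
    """Data consistency over the right lobe (assumed artifact-free).

    1 - mean(|image - reference|) / mean(reference) over R2, floored at 0.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(
            f"image shape {image.shape} != reference shape {reference.shape}"
        )
    mask = rois.right_lobe
    if not mask.any():
        raise ValueError("ROI 'right_lobe' is empty")
    ref_mean = float(reference[mask].mean())
    if ref_mean <= EPS:
        warnings.warn("reference right-lobe mean is ~0; DC guarded", RuntimeWarning)
        ref_mean = EPS
    dev = float(np.abs(image[mask] - reference[mask]).mean())
    return max(0.0, 1.0 - dev / ref_mean)


def raw_scores(image: np.ndarray, reference: np.ndarray, rois: RoiSet) -> FeatureScores:
    """All four raw feature scores of ``image`` (DC needs the reference)."""
    return FeatureScores(
        pa=pa_score(image, rois),
        vd=vd_score(image, rois),
        cnr=cnr_score(image, rois),
        dc=dc_score(image, reference, rois),
    )


def qtotal(pa_n: float, dc_n: float, vd_n: float, cnr_n: float) -> float:
    """Total quality score: arithmetic mean of the four normalized scores."""
    vals = np.array([pa_n, dc_n, vd_n, cnr_n], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite normalized score in {vals}")
    return float(vals.mean())


def normalized_scores(
    processed: np.ndarray, reference: np.ndarray, rois: RoiSet
) -> NormalizedScores:
    """Score ``processed`` against the trace-weighted ``reference``.

    PA, VD and CNR of the processed image are divided by the reference's own
    values; DC is already relative to the reference (the reference's DC is 1
    by construction).  ``qtotal`` is the mean of the four ratios.
    """
    proc = raw_scores(processed, reference, rois)
    ref = FeatureScores(
        pa=pa_score(reference, rois),
        vd=vd_score(reference, rois),
        cnr=cnr_score(reference, rois),
        dc=1.0,
    )
    for name, value in (("pa", ref.pa), ("vd", ref.vd), ("cnr", ref.cnr)):
        if abs(value) <= EPS:
            raise ValueError(
                f"reference {name.upper()} score is degenerate ({value!r}); "
                "cannot normalize"
            )
    pa_n = proc.pa / ref.pa
    vd_n = proc.vd / ref.vd
    cnr_n = proc.cnr / ref.cnr
    dc_n = proc.dc
    return NormalizedScores(
        pa_n=pa_n,
        vd_n=vd_n,
        cnr_n=cnr_n,
        dc_n=dc_n,
        qtotal=qtotal(pa_n, dc_n, vd_n, cnr_n),
    )
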