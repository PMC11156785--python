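"""Feature-guided composite loss for training a correction network.

Instead of regressing onto gold-standard target images (which do not exist for
pulsation-corrupted liver DWI), the network is trained to optimize the four
raw feature scores directly, with three regularizers that keep the
optimization honest:

``L = -l_DC*DC - l_CNR*CNR - l_PA*PA - l_VD*VD + l_DI*DI + l_PA2*PA2 + l_xi*xi``

* the minus signs turn higher-is-better scores into loss reductions;
* ``DI = Var(DC, CNR, PA, VD)`` (population variance) penalizes one score
  diverging at the expense of the others, e.g. CNR blowing up when the
  network flattens the liver;
* ``PA2 = <MIP>_R1 - <I_pred>_R1`` compares the left-lobe mean against the
  per-voxel maximum over repetitions, so brightening the left lobe is favored
  over darkening the right lobe (which would also raise PA);
* ``xi`` is the root-mean-square deviation from the reference image, keeping
  the overall image impression and a dark background.

Default weights: l_DC=0.5, l_CNR=1.5, l_PA=1, l_VD=1, l_DI=0.5, l_PA2=0.05,
l_xi=0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qscore import RoiSet, cnr_score, dc_score, pa_score, vd_score

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "mip",
    "pa2_term",
    "dispersion",
    "xi_term",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """The seven nonnegative coefficients of the composite loss."""

    lam_dc: float = 0.5
    lam_cnr: float = 1.5
    lam_pa: float = 1.0
    lam_vd: float = 1.0
    lam_di: float = 0.5
    lam_pa2: float = 0.05
    lam_xi: float = 0.05

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class LossBreakdown:
    """All seven loss terms of one prediction plus the weighted total."""

    dc: float
    cnr: float
    pa: float
    vd: float
    di: float
    pa2: float
    xi: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def mip(stack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection along the repetition axis."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"stack must be H x W x N, got shape {stack.shape}")
    return stack.max(axis=2)


def pa2_term(mip_image: np.ndarray, predicted: np.ndarray, rois: RoiSet) -> float:
    """Left-lobe MIP deficit: mean(MIP) - mean(predicted) over R1.

    Positive when the prediction is darker than the brightest voxel values
    available across repetitions.
    """
    mask = rois.left_lobe
    if not mask.any():
        raise ValueError("ROI 'left_lobe' is empty")
    mip_image = np.asarray(mip_image, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if mip_image.shape != predicted.shape:
        raise ValueError("MIP and predicted image shapes differ")
    return float(mip_image[mask].mean() - predicted[mask].mean())


def dispersion(dc: float, cnr: float, pa: float, vd: float) -> float:
    """Population variance of the four raw feature scores."""
    vals = np.array([dc, cnr, pa, vd], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite feature score in {vals}")
    return float(vals.var())


def xi_term(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square deviation between prediction and reference image."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {reference.shape}"
        )
    diff = predicted - reference
    return float(np.sqrt(np.mean(diff * diff)))


def total_loss(
    predicted: np.ndarray,
    stack: np.ndarray,
    reference: np.ndarray,
    rois: RoiSet,
    weights: LossWeights | None = None,
) -> LossBreakdown:
    """Composite feature-guided loss of a predicted image.

    The four feature scores enter raw (unnormalized): the published weight
    magnitudes are calibrated on raw ratio scales, and a reference
    normalization constant would simply be absorbed into the weights.
    """
    w = weights if weights is not None else LossWeights()
    dc = dc_score(predicted, reference, rois)
    cnr = cnr_score(predicted, rois)
    pa = pa_score(predicted, rois)
    vd = vd_score(predicted, rois)
    di = dispersion(dc, cnr, pa, vd)
    pa2 = pa2_term(mip(stack), predicted, rois)
    xi = xi_term(predicted, reference)
    total = (
        -w.lam_dc * dc
        - w.lam_cnr * cnr
        - w.lam_pa * pa
        - w.lam_vd * vd
        + w.lam_di * di
        + w.lam_pa2 * pa2
        + w.lam_xi * xi
    )
    return LossBreakdown(dc=dc, cnr=cnr, pa=pa, vd=vd, di=di, pa2=pa2, xi=xi, total=total)
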