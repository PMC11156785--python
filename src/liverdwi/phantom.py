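"""Synthetic multi-repetition liver-DWI phantom.

Real acquisitions collect N co-registered diffusion-weighted images per slice
(several repetitions of several diffusion directions).  Cardiac pulsation
randomly destroys signal in the left liver lobe in a subset of those images,
vessels occasionally flash bright from inflowing blood, and lesions appear as
bright focal discs.  The phantom reproduces exactly this statistical structure
on a cartoon liver — an ellipse split into a small left and a large right lobe,
thin dark vessels, bright lesion discs — together with the ground-truth
artifact-free image and the ROI masks every scoring and training stage needs.

The geometry is deliberately schematic: the point is not anatomical realism but
a generator whose artifact statistics are known exactly, so that every
correction algorithm can be tested against ground truth without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk, line

from .qscore import RoiSet

__all__ = ["PhantomConfig", "PhantomSlice", "generate_slice", "generate_dataset"]


class PhantomConfigError(ValueError):
    """Invalid phantom configuration or degenerate generated geometry."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, artifact and noise parameters of the phantom.

    Intensities are in units of the parenchyma mean (parenchyma == 1).

    Parameters
    ----------
    dropout_prob
        Probability that a given repetition suffers a left-lobe signal
        dropout.
    dropout_factor_range
        Interval of multiplicative signal retention inside a dropout; the
        applied field varies smoothly across the lobe within this range.
    flicker_prob
        Per-vessel, per-repetition probability of a bright-blood flash.
    flicker_gain
        Multiplicative brightening of a flashing vessel.
    lesion_contrast
        Lesion / parenchyma intensity ratio.
    n_lesions
        Lesion count per slice, an inclusive (low, high) range sampled per
        slice; the first lesion is always placed in the left lobe.
    noise_sigma
        Additive Gaussian noise scale relative to the parenchyma mean;
        values are clipped at zero.
    texture_sigma
        Relative amplitude of the static low-frequency parenchyma texture
        (identical in all repetitions); supplies the biological background
        variability against which lesion contrast is measured.
    """

    height: int = 128
    width: int = 128
    n_reps: int = 12
    dropout_prob: float = 0.4
    dropout_factor_range: tuple[float, float] = (0.2, 0.7)
    flicker_prob: float = 0.15
    flicker_gain: float = 3.0
    lesion_contrast: float = 1.8
    n_lesions: tuple[int, int] = (1, 2)
    noise_sigma: float = 0.05
    texture_sigma: float = 0.15
    vessel_intensity: float = 0.3
    outside_intensity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise PhantomConfigError("n_reps must be >= 2")
        for name in ("dropout_prob", "flicker_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise PhantomConfigError(f"{name}={p} not in [0, 1]")
        lo, hi = self.dropout_factor_range
        if not (0.0 < lo <= hi <= 1.0):
            raise PhantomConfigError(
                f"dropout_factor_range {self.dropout_factor_range} not within (0, 1]"
            )
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        if self.texture_sigma < 0:
            raise PhantomConfigError("texture_sigma must be >= 0")
        if isinstance(self.n_lesions, int):
            object.__setattr__(self, "n_lesions", (self.n_lesions, self.n_lesions))
        nlo, nhi = self.n_lesions
        if not (0 <= nlo <= nhi):
            raise PhantomConfigError(f"invalid n_lesions range {self.n_lesions}")
        if min(self.height, self.width) < 32:
            raise PhantomConfigError("phantom grid must be at least 32 x 32")


@dataclass
class PhantomSlice:
    """One generated slice: repetition stack, masks, truth and provenance."""

    stack: np.ndarray  # H x W x N
    rois: RoiSet
    truth: np.ndarray  # H x W artifact-free image
    dropout_log: np.ndarray  # per-repetition mean applied dropout factor
    patient_id: int = 0
    slice_index: int = 0
    config: PhantomConfig = field(default_factory=PhantomConfig)


def _liver_masks(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Liver ellipse and its left/right lobe partition."""
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    liver = ((yy - cy) / (0.38 * h)) ** 2 + ((xx - cx) / (0.42 * w)) ** 2 <= 1.0
    split = cx - 0.14 * w  # left lobe is the smaller, heart-adjacent portion
    left = liver & (xx < split)
    right = liver & (xx >= split)
    return liver, left, right


def _draw_vessels(
    cfg: PhantomConfig,
    liver: np.ndarray,
    left: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """2-4 thin dark vessel segments; at least one crosses the left lobe."""
    h, w = cfg.height, cfg.width
    n_vessels = int(rng.integers(2, 5))
    vessel_masks: list[np.ndarray] = []
    for i in range(n_vessels):
        region = left if i == 0 else liver
        idx = np.flatnonzero(region)
        for _ in range(50):
            a, b = rng.choice(idx, size=2, replace=False)
            r0, c0 = divmod(int(a), w)
            r1, c1 = divmod(int(b), w)
            if abs(r1 - r0) + abs(c1 - c0) < max(6, h // 12):
                continue
            canvas = np.zeros((h, w), dtype=bool)
            rr, cc = line(r0, c0, r1, c1)
            canvas[rr, cc] = True
            canvas = ndimage.binary_dilation(canvas, iterations=1) & liver
            if canvas.any():
                vessel_masks.append(canvas)
                break
    return vessel_masks


def _place_lesions(
    cfg: PhantomConfig,
    liver: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    vessels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bright lesion discs; the first always in the left lobe, the second in
    the right lobe, further ones anywhere in the liver."""
    h, w = cfg.height, cfg.width
    n = int(rng.integers(cfg.n_lesions[0], cfg.n_lesions[1] + 1))
    lesions = np.zeros((h, w), dtype=bool)
    keep_out = ndimage.binary_dilation(vessels, iterations=2)
    interior = ndimage.binary_erosion(liver, iterations=3)
    for i in range(n):
        region = left if i == 0 else (right if i == 1 else liver)
        candidates = np.flatnonzero(region & interior & ~keep_out & ~lesions)
        if candidates.size == 0:
            continue
        radius = float(rng.uniform(0.025, 0.05) * min(h, w))
        center = int(rng.choice(candidates))
        rr, cc = disk(divmod(center, w), radius, shape=(h, w))
        lesions[rr, cc] = True
    lesions &= liver & ~vessels
    return lesions


def _smooth_field(
    shape: tuple[int, int], lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency random field rescaled into [lo, hi]."""
    if hi - lo < 1e-12:
        return np.full(shape, lo)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 8.0)
    rmin, rmax = raw.min(), raw.max()
    if rmax - rmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (raw - rmin) / (rmax - rmin)


def generate_slice(
    config: PhantomConfig | None = None,
    rng: np.random.Generator | int | None = None,
    patient_id: int = 0,
    slice_index: int = 0,
) -> PhantomSlice:
    """Generate one phantom slice.

    The artifact model, applied independently per repetition:

    * with probability ``dropout_prob`` a smooth multiplicative retention
      field in ``dropout_factor_range`` is applied over the left lobe
      (pulsation-induced signal loss);
    * each vessel flashes bright (x ``flicker_gain``) with probability
      ``flicker_prob``;
    * zero-mean Gaussian noise of scale ``noise_sigma`` x parenchyma mean is
      added and intensities clipped at zero.

    ``dropout_log[n]`` is the mean retention factor applied over the left
    lobe in repetition ``n`` (1.0 when no dropout occurred).
    """
    cfg = config if config is not None else PhantomConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    liver, left, right = _liver_masks(cfg)
    vessel_list = _draw_vessels(cfg, liver, left, rng)
    vessels = np.zeros_like(liver)
    for vm in vessel_list:
        vessels |= vm
    lesions = _place_lesions(cfg, liver, left, right, vessels, rng)
    # background parenchyma is drawn well inside the artifact-free lobe, away
    # from the organ boundary and focal structures, as a manual ROI would be
    margin = max(3, round(0.08 * min(cfg.height, cfg.width)))
    background = (
        ndimage.binary_erosion(right, iterations=margin)
        & ~ndimage.binary_dilation(vessels, iterations=2)
        & ~ndimage.binary_dilation(lesions, iterations=2)
    )

    for name, mask in (
        ("left_lobe", left),
        ("right_lobe", right),
        ("vessels", vessels),
        ("background", background),
    ):
        if not mask.any():
            raise PhantomConfigError(f"generated {name} mask is empty")

    truth = np.full((cfg.height, cfg.width), cfg.outside_intensity)
    truth[liver] = 1.0
    truth[vessels] = cfg.vessel_intensity
    truth[lesions] = cfg.lesion_contrast
    if cfg.texture_sigma > 0:
        # static biological texture: identical in every repetition, so it
        # carries the background variability the CNR denominator measures
        # without adding inter-repetition variation
        raw = ndimage.gaussian_filter(
            rng.standard_normal(truth.shape), sigma=min(truth.shape) / 16.0
        )
        sd = raw.std()
        if sd > 1e-12:
            tex = 1.0 + cfg.texture_sigma * raw / sd
            truth[liver] *= np.clip(tex, 0.2, None)[liver]

    stack = np.empty((cfg.height, cfg.width, cfg.n_reps))
    dropout_log = np.ones(cfg.n_reps)
    for n in range(cfg.n_reps):
        img = truth.copy()
        if rng.random() < cfg.dropout_prob:
            field_ = _smooth_field(
                (cfg.height, cfg.width), *cfg.dropout_factor_range, rng
            )
            img[left] *= field_[left]
            dropout_log[n] = float(field_[left].mean())
        for vm in vessel_list:
            if rng.random() < cfg.flicker_prob:
                img[vm] *= cfg.flicker_gain
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
            np.clip(img, 0.0, None, out=img)
        stack[:, :, n] = img

    rois = RoiSet(
        left_lobe=left,
        right_lobe=right,
        vessels=vessels,
        lesions=lesions,
        background=background,
    )
    return PhantomSlice(
        stack=stack,
        rois=rois,
        truth=truth,
        dropout_log=dropout_log,
        patient_id=patient_id,
        slice_index=slice_index,
        config=cfg,
    )


def generate_dataset(
    n_patients: int,
    slices_per_patient: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[PhantomSlice]:
    """Generate a patient-grouped phantom dataset.

    Each patient gets a reproducible sub-stream of the seeded generator, so
    datasets are bit-identical for identical ``(n_patients, slices_per_patient,
    config, seed)`` and slices group by ``patient_id`` for patient-wise
    splitting.
    """
    if n_patients < 2:
        raise PhantomConfigError(
            "n_patients must be >= 2 so a patient-wise split is possible"
        )
    if slices_per_patient < 1:
        raise PhantomConfigError("slices_per_patient must be >= 1")
    cfg = config if config is not None else PhantomConfig()
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    slices: list[PhantomSlice] = []
    for pid, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for s in range(slices_per_patient):
            slices.append(
                generate_slice(cfg, rng=rng, patient_id=pid, slice_index=s)
            )
    return slices


def with_seed(config: PhantomConfig, seed: int) -> PhantomConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
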