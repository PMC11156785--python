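"""Training harness for the feature-guided correction network.

Covers the full recipe around the U-Net: per-slice normalization of the
repetition stack to zero mean / unit standard deviation, random
translation+scaling augmentation applied identically to all repetitions and
masks, a patient-wise 80/20 split, mean-squared-error pretraining on the
trace-weighted reference images, feature-guided training with a moving-window
early-stopping rule, best-weights selection, and inference.

Two sizing profiles exist: ``paper`` (batch 64, 3000 pretraining epochs,
100-epoch stopping windows, learning rate 1e-4) mirrors the published
full-scale run; ``desk`` (batch 8, 50 pretraining epochs, 10-epoch windows,
learning rate 1e-3) is sized for small synthetic phantoms on a single CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._autodiff import Tensor
from .floss import LossWeights
from .phantom import PhantomSlice
from .qscore import RoiSet, trace_reference
from .unet import UNet, UNetSpec

__all__ = [
    "NormRecord",
    "TrainConfig",
    "normalize_stack",
    "denormalize",
    "augment",
    "split_patientwise",
    "should_stop",
    "pretrain",
    "train",
    "predict",
    "FeatureGuidedUNet",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormRecord:
    """Mean/std used to normalize one slice's stack; inverts predictions."""

    mean: float
    std: float


def normalize_stack(stack: np.ndarray) -> tuple[np.ndarray, NormRecord]:
    """Normalize a whole H x W x N stack to zero mean and unit std.

    One mean and one standard deviation are computed jointly over all voxels
    of all N images, so relative brightness between repetitions is preserved.
    """
    stack = np.asarray(stack, dtype=float)
    mean = float(stack.mean())
    std = float(stack.std())
    if std <= _EPS:
        raise ValueError("stack has zero variance; cannot normalize")
    return (stack - mean) / std, NormRecord(mean=mean, std=std)


def denormalize(data: np.ndarray, record: NormRecord) -> np.ndarray:
    return data * record.std + record.mean


# ---------------------------------------------------------------------------
# augmentation


def _affine_params(rng: np.random.Generator, shape: tuple[int, int]):
    h, w = shape
    dy = rng.uniform(-0.1, 0.1) * h
    dx = rng.uniform(-0.1, 0.1) * w
    scale = rng.uniform(0.90, 1.05)
    return dy, dx, scale


def _apply_affine(
    image: np.ndarray, dy: float, dx: float, scale: float, order: int
) -> np.ndarray:
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.eye(2) / scale
    offset = center - (center + np.array([dy, dx])) / scale
    return ndimage.affine_transform(
        image, matrix, offset=offset, order=order, mode="constant", cval=0.0
    )


def augment(
    slice_: PhantomSlice, rng: np.random.Generator | int, max_retries: int = 20
) -> PhantomSlice:
    """Random translation (up to +-10% of each dimension) and scaling
    (factor in [0.90, 1.05]) applied identically to all N repetitions, the
    truth image and every ROI mask.

    Masks are re-binarized (threshold 0.5) after interpolation.  If a
    transform empties a required mask the draw is repeated; after
    ``max_retries`` failures an error is raised.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    shape = slice_.truth.shape
    need_lesions = slice_.rois.has_lesions
    for _ in range(max_retries):
        dy, dx, scale = _affine_params(rng, shape)
        masks = {}
        ok = True
        for name, mask in slice_.rois.as_dict().items():
            warped = _apply_affine(mask.astype(float), dy, dx, scale, order=0) > 0.5
            masks[name] = warped
            required = name != "lesions" or need_lesions
            if required and not warped.any():
                ok = False
                break
        if not ok:
            continue
        # lobe masks can gain overlap only through rounding; they cannot here
        stack = np.stack(
            [
                _apply_affine(slice_.stack[:, :, n], dy, dx, scale, order=1)
                for n in range(slice_.stack.shape[2])
            ],
            axis=2,
        )
        np.clip(stack, 0.0, None, out=stack)
        truth = np.clip(_apply_affine(slice_.truth, dy, dx, scale, order=1), 0, None)
        return PhantomSlice(
            stack=stack,
            rois=RoiSet(**masks),
            truth=truth,
            dropout_log=slice_.dropout_log.copy(),
            patient_id=slice_.patient_id,
            slice_index=slice_.slice_index,
            config=slice_.config,
        )
    raise RuntimeError(
        f"augmentation emptied a required mask in {max_retries} consecutive draws"
    )


# ---------------------------------------------------------------------------
# splitting


def split_patientwise(
    dataset: list[PhantomSlice], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[PhantomSlice], list[PhantomSlice]]:
    """Split slices by patient: ceil(train_frac x n_patients) patients train.

    Patients (never slices) are shuffled by the seed, so all slices of one
    patient land on the same side.  At least one patient is always held out.
    """
    patients = sorted({s.patient_id for s in dataset})
    if len(patients) < 2:
        raise ValueError("patient-wise split needs at least 2 patients")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(patients))
    n_train = min(math.ceil(train_frac * len(patients)), len(patients) - 1)
    train_ids = {patients[i] for i in order[:n_train]}
    train = [s for s in dataset if s.patient_id in train_ids]
    test = [s for s in dataset if s.patient_id not in train_ids]
    return train, test


# ---------------------------------------------------------------------------
# early stopping


def should_stop(losses: list[float] | np.ndarray, window: int) -> bool:
    """Moving-window early-stopping rule.

    Stop once the mean loss over the latest ``window`` epochs is not lower
    than the mean over the ``window`` epochs before that.  Needs at least
    2 x window observed epochs; a pure function of the loss sequence.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    losses = np.asarray(losses, dtype=float)
    if losses.size < 2 * window:
        return False
    recent = losses[-window:].mean()
    previous = losses[-2 * window : -window].mean()
    return bool(recent >= previous)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings.

    Defaults are the desk profile sizes with the published Adam moments; use
    :meth:`desk` / :meth:`paper` for the two named profiles.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    pretrain_epochs: int = 50
    stop_window: int = 10
    max_epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("invalid optimizer settings")
        if self.batch_size < 1 or self.pretrain_epochs < 0 or self.max_epochs < 1:
            raise ValueError("invalid schedule settings")
        if self.stop_window < 1:
            raise ValueError("stop_window must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        return cls(
            learning_rate=1e-3,
            batch_size=8,
            pretrain_epochs=50,
            stop_window=10,
            max_epochs=150,
            seed=seed,
        )

    @classmethod
    def paper(cls, seed: int = 0) -> "TrainConfig":
        return cls(
            learning_rate=1e-4,
            batch_size=64,
            pretrain_epochs=3000,
            stop_window=100,
            max_epochs=100_000,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# differentiable loss


_TERM_NAMES = ("dc", "cnr", "pa", "vd", "di", "pa2", "xi")


def _loss_tensor(
    pred: Tensor,
    reference: np.ndarray,
    mip_mean_r1: float,
    rois: RoiSet,
    weights: LossWeights,
) -> tuple[Tensor, dict[str, float]]:
    """Composite feature-guided loss as an autodiff graph over ``pred``.

    Mirrors :func:`liverdwi.floss.total_loss` term by term (asserted equal in
    the test suite).  On slices without a lesion ROI the CNR term is dropped,
    its weight redistributed equally onto DC, PA and VD, and the dispersion
    taken over the remaining three scores.
    """
    r = rois
    ref_r2_mean = float(reference[r.right_lobe].mean())
    dc = (
        1.0 - (pred - reference).abs().masked_mean(r.right_lobe) / max(ref_r2_mean, _EPS)
    ).relu()
    pa = pred.masked_mean(r.left_lobe) / pred.masked_mean(r.right_lobe)
    bg_mean = pred.masked_mean(r.background)
    vd = bg_mean / pred.masked_mean(r.vessels)
    w = weights
    if r.has_lesions:
        bg_var = ((pred - bg_mean) ** 2).masked_mean(r.background)
        cnr = (pred.masked_mean(r.lesions) - bg_mean) / (bg_var + _EPS**2).sqrt()
        s = (dc + cnr + pa + vd) * 0.25
        di = ((dc - s) ** 2 + (cnr - s) ** 2 + (pa - s) ** 2 + (vd - s) ** 2) * 0.25
    else:
        cnr = Tensor(np.zeros((), dtype=pred.data.dtype))
        extra = w.lam_cnr / 3.0
        w = replace(
            w,
            lam_cnr=0.0,
            lam_dc=w.lam_dc + extra,
            lam_pa=w.lam_pa + extra,
            lam_vd=w.lam_vd + extra,
        )
        s = (dc + pa + vd) * (1.0 / 3.0)
        di = ((dc - s) ** 2 + (pa - s) ** 2 + (vd - s) ** 2) * (1.0 / 3.0)
    pa2 = -(pred.masked_mean(r.left_lobe) - mip_mean_r1)
    diff = pred - reference
    xi = ((diff * diff).mean() + _EPS**2).sqrt()

    total = (
        -w.lam_dc * dc
        - w.lam_cnr * cnr
        - w.lam_pa * pa
        - w.lam_vd * vd
        + w.lam_di * di
        + w.lam_pa2 * pa2
        + w.lam_xi * xi
    )
    terms = {
        name: float(t.data)
        for name, t in zip(_TERM_NAMES, (dc, cnr, pa, vd, di, pa2, xi))
    }
    for name, value in {**terms, "total": float(total.data)}.items():
        if not np.isfinite(value):
            raise FloatingPointError(
                f"loss term {name!r} became non-finite during training"
            )
    return total, terms


# ---------------------------------------------------------------------------
# slice preparation


@dataclass
class _Prepped:
    x: np.ndarray  # (C, H, W) normalized float32 network input
    record: NormRecord
    reference: np.ndarray  # H x W intensity-space trace reference
    rois: RoiSet
    mip_mean_r1: float


def _as_slice(item) -> PhantomSlice:
    if isinstance(item, PhantomSlice):
        return item
    stack, rois = item
    return PhantomSlice(
        stack=np.asarray(stack, dtype=float),
        rois=rois,
        truth=np.zeros(np.asarray(stack).shape[:2]),
        dropout_log=np.ones(np.asarray(stack).shape[2]),
    )


def _prep(slice_: PhantomSlice, dirs_per_rep: int) -> _Prepped:
    norm, record = normalize_stack(slice_.stack)
    reference = trace_reference(slice_.stack, dirs_per_rep)
    return _Prepped(
        x=np.ascontiguousarray(norm.transpose(2, 0, 1), dtype=np.float32),
        record=record,
        # float32 keeps the whole training tape single-precision
        reference=np.asarray(reference, dtype=np.float32),
        rois=slice_.rois,
        mip_mean_r1=float(
            slice_.stack.max(axis=2)[slice_.rois.left_lobe].mean()
        ),
    )


def _forward_intensity(model: UNet, prep: _Prepped) -> Tensor:
    """Network output mapped back to nonnegative intensity units.

    The linear network output (normalized units) is de-normalized and passed
    through a softplus whose sharpness scales with the slice std, so it is
    near-identity over the tissue intensity range while smoothly clamping the
    background at zero.
    """
    y = model.forward(prep.x[None])  # (1, 1, H, W)
    z = y * prep.record.std + prep.record.mean
    return z.softplus(beta=10.0 / prep.record.std)


# ---------------------------------------------------------------------------
# training loops


def pretrain(
    model: UNet,
    train_set: list,
    config: TrainConfig,
    dirs_per_rep: int = 3,
) -> list[float]:
    """Pretrain the network to reproduce the trace-weighted reference images
    from the N-image input, under mean-squared error.  Returns per-epoch
    losses."""
    preps = [_prep(_as_slice(s), dirs_per_rep) for s in train_set]
    if not preps:
        raise ValueError("training set is empty")
    opt = model.make_optimizer(config.learning_rate, config.beta1, config.beta2)
    rng = np.random.default_rng(config.seed)
    losses: list[float] = []
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(len(preps))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [preps[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            total = None
            for prep in batch:
                pred = _forward_intensity(model, prep)
                diff = pred - prep.reference
                mse = (diff * diff).mean()
                total = mse if total is None else total + mse
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
        losses.append(float(np.mean(epoch_losses)))
    return losses


def _eval_loss(
    model: UNet, preps: list[_Prepped], weights: LossWeights
) -> tuple[float, dict[str, float]]:
    totals, terms_acc = [], {name: 0.0 for name in _TERM_NAMES}
    for prep in preps:
        pred = _forward_intensity(model, prep)
        total, terms = _loss_tensor(
            pred, prep.reference, prep.mip_mean_r1, prep.rois, weights
        )
        totals.append(float(total.data))
        for name in _TERM_NAMES:
            terms_acc[name] += terms[name] / len(preps)
    return float(np.mean(totals)), terms_acc


def train(
    model: UNet,
    train_set: list,
    test_set: list | None,
    weights: LossWeights | None = None,
    config: TrainConfig | None = None,
    dirs_per_rep: int = 3,
) -> tuple[UNet, pd.DataFrame]:
    """Feature-guided training with moving-window early stopping.

    Per epoch, the mean composite loss over training batches is minimized
    with Adam.  The monitored loss (test-set loss when a test set is given,
    else the training loss) drives the stopping rule of :func:`should_stop`;
    the weights with the lowest monitored loss are restored at the end.
    Returns the model and a per-epoch history with all term breakdowns.
    """
    weights = weights if weights is not None else LossWeights()
    config = config if config is not None else TrainConfig()
    preps = [_prep(_as_slice(s), dirs_per_rep) for s in train_set]
    if not preps:
        raise ValueError("training set is empty")
    test_preps = [_prep(_as_slice(s), dirs_per_rep) for s in (test_set or [])]
    opt = model.make_optimizer(config.learning_rate, config.beta1, config.beta2)
    rng = np.random.default_rng(config.seed + 1)

    history: list[dict] = []
    monitored: list[float] = []
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(preps))
        batch_losses = []
        terms_acc = {name: 0.0 for name in _TERM_NAMES}
        for start in range(0, len(order), config.batch_size):
            batch = [preps[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            total = None
            for prep in batch:
                pred = _forward_intensity(model, prep)
                loss, terms = _loss_tensor(
                    pred, prep.reference, prep.mip_mean_r1, prep.rois, weights
                )
                total = loss if total is None else total + loss
                for name in _TERM_NAMES:
                    terms_acc[name] += terms[name] / len(preps)
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            batch_losses.append(float(total.data) * len(batch))
        train_loss = float(np.sum(batch_losses) / len(preps))
        if test_preps:
            test_loss, _ = _eval_loss(model, test_preps, weights)
            monitor = test_loss
        else:
            test_loss = np.nan
            monitor = train_loss
        monitored.append(monitor)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "test_loss": test_loss,
                **{f"term_{k}": v for k, v in terms_acc.items()},
            }
        )
        if monitor < best_loss:
            best_loss = monitor
            best_weights = model.get_weights()
            best_epoch = epoch
        if should_stop(monitored, config.stop_window):
            break
    model.set_weights(best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def predict(
    model: UNet, stack: np.ndarray, record: NormRecord | None = None
) -> np.ndarray:
    """De-normalized, nonnegative prediction for one repetition stack.

    When ``record`` is omitted the stack is normalized with its own per-slice
    statistics (the same convention used at training time).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"stack must be H x W x N, got shape {stack.shape}")
    if stack.shape[2] != model.spec.in_channels:
        raise ValueError(
            f"stack has {stack.shape[2]} repetitions, "
            f"model expects {model.spec.in_channels}"
        )
    if record is None:
        norm, record = normalize_stack(stack)
    else:
        norm = (stack - record.mean) / record.std
    x = np.ascontiguousarray(norm.transpose(2, 0, 1), dtype=np.float32)
    prep = _Prepped(
        x=x,
        record=record,
        reference=np.zeros(stack.shape[:2]),
        rois=None,  # type: ignore[arg-type]
        mip_mean_r1=0.0,
    )
    out = _forward_intensity(model, prep)
    return np.asarray(out.data[0, 0], dtype=float)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: UNet, outdir) -> None:
    """Store weights (npz) and architecture (yaml) in a directory."""
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "weights.npz", *[p.data for p in model.params])
    with open(outdir / "unet_spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "in_channels": model.spec.in_channels,
                "out_channels": model.spec.out_channels,
                "depth": model.spec.depth,
                "base_channels": model.spec.base_channels,
            },
            fh,
        )


def load_model(indir) -> UNet:
    import yaml
    from pathlib import Path

    indir = Path(indir)
    with open(indir / "unet_spec.yaml") as fh:
        spec = UNetSpec(**yaml.safe_load(fh))
    model = UNet(spec, rng=0)
    with np.load(indir / "weights.npz") as data:
        model.set_weights([data[k] for k in data.files])
    return model


# ---------------------------------------------------------------------------
# estimator facade


class FeatureGuidedUNet(BaseEstimator):
    """Scikit-learn style estimator around the feature-guided U-Net.

    ``fit`` runs MSE pretraining on the trace references followed by
    feature-guided training with early stopping; ``predict`` maps an
    H x W x N stack to the corrected H x W image.

    Parameters mirror :class:`UNetSpec`, :class:`TrainConfig` and
    :class:`~liverdwi.floss.LossWeights`; ``profile`` selects the desk or
    paper schedule for any setting left at None.
    """

    def __init__(
        self,
        in_channels: int = 12,
        depth: int = 4,
        base_channels: int = 32,
        profile: str = "desk",
        learning_rate: float | None = None,
        batch_size: int | None = None,
        pretrain_epochs: int | None = None,
        stop_window: int | None = None,
        max_epochs: int | None = None,
        loss_weights: LossWeights | None = None,
        dirs_per_rep: int = 3,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.depth = depth
        self.base_channels = base_channels
        self.profile = profile
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.pretrain_epochs = pretrain_epochs
        self.stop_window = stop_window
        self.max_epochs = max_epochs
        self.loss_weights = loss_weights
        self.dirs_per_rep = dirs_per_rep
        self.seed = seed

    def _config(self) -> TrainConfig:
        if self.profile == "desk":
            base = TrainConfig.desk(seed=self.seed)
        elif self.profile == "paper":
            base = TrainConfig.paper(seed=self.seed)
        else:
            raise ValueError(f"unknown profile {self.profile!r}")
        overrides = {
            name: getattr(self, name)
            for name in (
                "learning_rate",
                "batch_size",
                "pretrain_epochs",
                "stop_window",
                "max_epochs",
            )
            if getattr(self, name) is not None
        }
        return replace(base, **overrides)

    def fit(self, X: list, y=None, test_set: list | None = None) -> "FeatureGuidedUNet":
        """Train on a list of slices (``PhantomSlice`` or (stack, RoiSet))."""
        config = self._config()
        spec = UNetSpec(
            in_channels=self.in_channels,
            depth=self.depth,
            base_channels=self.base_channels,
        )
        model = UNet(spec, rng=np.random.default_rng(self.seed))
        self.n_parameters_ = model.n_parameters
        self.pretrain_losses_ = pretrain(model, X, config, self.dirs_per_rep)
        model, self.history_ = train(
            model,
            X,
            test_set,
            weights=self.loss_weights,
            config=config,
            dirs_per_rep=self.dirs_per_rep,
        )
        self.model_ = model
        self.best_epoch_ = int(self.history_.attrs["best_epoch"])
        self.n_epochs_ = int(len(self.history_))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("FeatureGuidedUNet must be fit before predict")
        return predict(self.model_, X)
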