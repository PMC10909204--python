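"""Training loops: self-supervised projection-domain loss, supervised baseline,
and the inference path.

The self-supervised loop consumes *only* low-dose sinograms.  Per iteration:

1. perturb the sinogram's cycling blind-spot subset (4-neighbour means),
2. FBP the perturbed sinogram into image space,
3. denoise with f_theta,
4. re-project with the same discrete forward operator,
5. penalise the squared residual against the *unperturbed* sinogram on the
   perturbed subset only.

Because the forward operator is linear, the loss gradient with respect to the
denoised image is the operator's transpose applied to the masked residual;
from there the network's hand-written backward pass takes over.  The FBP
input branch carries no parameters, so no gradient flows through it.
Ground-truth images never enter this loop — the function signature cannot
even receive them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .denoiser import Denoiser
from .exceptions import InvalidInputError
from .geometry import ProjectionGeometry, RadonTransform, fbp_reconstruct
from .masking import PerturbationGrid, perturb_sinogram, select_pixel_index
from .noise import NoiseModel

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "train_proj2proj",
    "train_supervised",
    "reconstruct",
]


@dataclass
class TrainConfig:
    """Optimisation settings shared by both training modes.

    ``learning_rate`` defaults to 1e-4 (the value used at full scale; desk
    runs usually raise it — see the presets in :mod:`proj2proj.cli`).
    ``val_offset`` fixes the perturbation phase used for validation so the
    validation loss is comparable across evaluations.  ``perturb=False`` is
    the identity-collapse ablation: the network sees the raw FBP input and
    the loss covers every sinogram pixel, which lets f_theta satisfy the
    objective by reproducing its input.
    """

    geometry: ProjectionGeometry
    learning_rate: float = 1e-4
    n_iterations: int = 2000
    batch_size: int = 2
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    seed: int = 0
    grid: PerturbationGrid = field(default_factory=PerturbationGrid)
    noise: NoiseModel | None = None
    val_interval: int = 200
    val_offset: int = 7
    perturb: bool = True

    def __post_init__(self) -> None:
        if not (self.learning_rate > 0):
            raise InvalidInputError("learning_rate must be > 0")
        if self.n_iterations < 1 or self.batch_size < 1:
            raise InvalidInputError("n_iterations and batch_size must be >= 1")


@dataclass
class TrainingLog:
    """Per-iteration training losses plus periodic validation losses."""

    iterations: np.ndarray
    train_loss: np.ndarray
    val_iterations: np.ndarray
    val_loss: np.ndarray
    best_iteration: int


class _Adam:
    """Adaptive-moment optimiser with standard defaults."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, betas, eps):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_stack(sinos, geom: ProjectionGeometry) -> np.ndarray:
    arr = np.asarray(sinos, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != geom.sinogram_shape:
        raise InvalidInputError(
            f"sinogram stack shape {arr.shape} does not match geometry "
            f"{geom.sinogram_shape}"
        )
    return arr


def _check_loss(loss: float, iteration: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"training diverged: non-finite loss {loss} at iteration {iteration}; "
            "reduce the learning rate or check the input scaling"
        )


def train_proj2proj(
    train_sinos,
    val_sinos,
    denoiser: Denoiser,
    cfg: TrainConfig,
) -> tuple[Denoiser, TrainingLog]:
    """Self-supervised training on low-dose sinograms alone.

    Returns the parameters with the best validation self-supervised loss
    (clean references do not exist by construction, so validation uses the
    same masked projection loss at a fixed perturbation phase).
    """
    geom = cfg.geometry
    y_train = _as_stack(train_sinos, geom)
    y_val = _as_stack(val_sinos, geom)
    proj = RadonTransform(geom)
    rng = np.random.default_rng(cfg.seed)
    d = denoiser.copy()
    opt = _Adam(d.params, cfg.learning_rate, cfg.betas, cfg.eps)
    n_phases = cfg.grid.n_pixels

    # The perturbed sinogram (hence its FBP) depends on the iteration only
    # through t mod n_phases, so FBP inputs are computed once per phase.
    fbp_cache: dict[tuple[str, int, int], np.ndarray] = {}
    mask_cache: dict[int, np.ndarray] = {}

    def fbp_input(split: str, stack: np.ndarray, idx: int, phase: int) -> np.ndarray:
        key = (split, idx, phase)
        if key not in fbp_cache:
            if cfg.perturb:
                pert, mask = perturb_sinogram(stack[idx], phase, cfg.grid)
            else:
                pert, mask = stack[idx], np.ones(geom.sinogram_shape, dtype=bool)
            mask_cache[phase] = mask
            fbp_cache[key] = fbp_reconstruct(pert, geom).astype(np.float32)
        return fbp_cache[key]

    def masked_step(stack: np.ndarray, idxs, phase: int, split: str, update: bool) -> float:
        x_in = np.stack([fbp_input(split, stack, i, phase) for i in idxs])
        mask = mask_cache[phase]
        x_hat, cache = d.forward_batch(x_in[..., None], train=update)
        resid = np.zeros((len(idxs),) + geom.sinogram_shape)
        for k, i in enumerate(idxs):
            resid[k] = proj.forward(x_hat[k, :, :, 0].astype(np.float64)) - stack[i]
        resid *= mask
        n_masked = int(mask.sum())
        loss = float(np.sum(resid**2) / (len(idxs) * n_masked))
        if update:
            dresid = 2.0 * resid / (len(idxs) * n_masked)
            dx_hat = np.stack(
                [proj.adjoint(dresid[k]) for k in range(len(idxs))]
            ).astype(np.float32)
            grads = d.backward_batch(cache, dx_hat[..., None])
            opt.step(d.params, grads)
        return loss

    losses = np.empty(cfg.n_iterations)
    val_iters: list[int] = []
    val_losses: list[float] = []
    best = (np.inf, -1, None)
    for t in range(cfg.n_iterations):
        phase = select_pixel_index(t, cfg.grid)
        idxs = rng.integers(0, len(y_train), size=cfg.batch_size)
        losses[t] = masked_step(y_train, idxs, phase, "train", update=True)
        _check_loss(losses[t], t)
        if (t + 1) % cfg.val_interval == 0 or t == cfg.n_iterations - 1:
            vphase = select_pixel_index(cfg.val_offset, cfg.grid)
            vloss = float(
                np.mean(
                    [
                        masked_step(y_val, [i], vphase, "val", update=False)
                        for i in range(len(y_val))
                    ]
                )
            )
            val_iters.append(t + 1)
            val_losses.append(vloss)
            if vloss < best[0]:
                best = (vloss, t + 1, {k: v.copy() for k, v in d.params.items()})
    best_params = best[2] if best[2] is not None else d.params
    log = TrainingLog(
        iterations=np.arange(1, cfg.n_iterations + 1),
        train_loss=losses,
        val_iterations=np.asarray(val_iters),
        val_loss=np.asarray(val_losses),
        best_iteration=best[1],
    )
    return Denoiser(d.config, best_params), log


def train_supervised(
    pairs,
    denoiser: Denoiser,
    cfg: TrainConfig,
    val_pairs=None,
) -> tuple[Denoiser, TrainingLog]:
    """Supervised baseline: match denoise(FBP(y)) to a reference image.

    ``pairs`` is a sequence of (sinogram, reference image).  Uses the same
    network, optimiser and FBP front end as the self-supervised loop; only
    the loss differs (plain MSE in image space).
    """
    geom = cfg.geometry
    sinos = _as_stack([p[0] for p in pairs], geom)
    targets = np.asarray([geom.check_image(p[1]) for p in pairs], dtype=np.float32)
    x_in = np.asarray(
        [fbp_reconstruct(s, geom) for s in sinos], dtype=np.float32
    )
    if val_pairs is not None:
        v_in = np.asarray(
            [fbp_reconstruct(np.asarray(p[0]), geom) for p in val_pairs],
            dtype=np.float32,
        )
        v_t = np.asarray([p[1] for p in val_pairs], dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    d = denoiser.copy()
    opt = _Adam(d.params, cfg.learning_rate, cfg.betas, cfg.eps)

    losses = np.empty(cfg.n_iterations)
    val_iters: list[int] = []
    val_losses: list[float] = []
    best = (np.inf, -1, None)
    for t in range(cfg.n_iterations):
        idxs = rng.integers(0, len(sinos), size=cfg.batch_size)
        xb = x_in[idxs][..., None]
        tb = targets[idxs][..., None]
        y, cache = d.forward_batch(xb, train=True)
        diff = y - tb
        losses[t] = float(np.mean(diff**2))
        _check_loss(losses[t], t)
        grads = d.backward_batch(cache, 2.0 * diff / diff.size)
        opt.step(d.params, grads)
        if val_pairs is not None and ((t + 1) % cfg.val_interval == 0 or t == cfg.n_iterations - 1):
            yv, _ = d.forward_batch(v_in[..., None])
            vloss = float(np.mean((yv[..., 0] - v_t) ** 2))
            val_iters.append(t + 1)
            val_losses.append(vloss)
            if vloss < best[0]:
                best = (vloss, t + 1, {k: v.copy() for k, v in d.params.items()})
    best_params = best[2] if best[2] is not None else d.params
    log = TrainingLog(
        iterations=np.arange(1, cfg.n_iterations + 1),
        train_loss=losses,
        val_iterations=np.asarray(val_iters),
        val_loss=np.asarray(val_losses),
        best_iteration=best[1],
    )
    return Denoiser(d.config, best_params), log


def reconstruct(sino: np.ndarray, denoiser: Denoiser, geom: ProjectionGeometry) -> np.ndarray:
    """Inference: denoise(FBP(sinogram)).  No perturbation is applied."""
    from .denoiser import denoise

    sino = geom.check_sinogram(sino)
    return denoise(denoiser, fbp_reconstruct(sino, geom))
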