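"""Semi-supervised training with cross pseudo supervision and FA-map updates.

Two identically shaped, differently initialized networks are trained jointly.
On labeled images both take the Dice loss against the ground truth; on
unlabeled images each is supervised by the *other* branch's hard (argmax,
detached) pseudo-label.  The total objective at epoch r is

    L_total = L_sup + lambda(r) * L_unsup,   lambda(r) = lambda_max * r / R,

with the unsupervised weight ramping linearly over the R training epochs.
After every epoch the fracture-attention map of each training image is
rebuilt from the two binarized predictions and blended with its initial map
(see :mod:`ssfa.famap`).  Inference is two-stage: predict with an initial FA
map from the supervised init network, rebuild the map from the dual
predictions, then re-run the branch that scored the better validation Dice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import famap, nn
from .famap import BINARIZE_THRESHOLD
from .network import NetworkSpec, Predictor, build_network

DICE_EPS = 1e-5

AUGMENTATIONS = ("flip", "rotation", "transposition")


@dataclass
class TrainConfig:
    """Hyperparameters for supervised pretraining and the semi-supervised loop.

    Optimizer defaults are the reference settings (SGD momentum 0.9, weight
    decay 5e-5, batch 16, 100 epochs, lr 0.1 halved every 25 epochs);
    ``desk_profile`` scales the run down to a single CPU.
    """

    lambda_max: float = 3.0
    k: float = 0.6
    levels: int = famap.DEFAULT_LEVELS
    delta: int = 5
    max_epoch: int = 100
    batch: int = 16
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-5
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 25
    augmentations: tuple[str, ...] = AUGMENTATIONS
    seed_net1: int = 1
    seed_net2: int = 2
    seed_data: int = 3
    image_size: int = 256
    depth: int = 5
    base_channels: int = 64
    fusion: str = "multiple"
    norm_groups: int = 8
    val_fraction: float = 0.2
    init_epochs: int | None = None  # supervised pretraining budget; None => max_epoch

    def __post_init__(self):
        if not (0.0 <= self.k <= 1.0):
            raise ValueError(f"update weight k={self.k} outside [0, 1]")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")

    @classmethod
    def desk_profile(cls, **overrides) -> "TrainConfig":
        """CPU-scale profile: 64x64 images, 8 base channels, depth 3, batch 4,
        20 epochs."""
        defaults = dict(image_size=64, base_channels=8, depth=3, batch=4,
                        max_epoch=20, norm_groups=4)
        defaults.update(overrides)
        return cls(**defaults)

    def network_spec(self, fusion: str | None = None) -> NetworkSpec:
        return NetworkSpec(depth=self.depth, base_channels=self.base_channels,
                           fusion=self.fusion if fusion is None else fusion,
                           norm_groups=self.norm_groups)

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_decay_factor ** ((epoch - 1) // self.lr_decay_every)


@dataclass(frozen=True)
class LossReport:
    total: float
    sup: float
    unsup: float
    lam: float


@dataclass
class DualState:
    predictor1: Predictor
    predictor2: Predictor
    fa_states: dict[int, famap.FAState]
    epoch: int
    best_branch: int
    best_val_dice: float
    config: TrainConfig


def lambda_schedule(epoch: int, max_epoch: int, lambda_max: float) -> float:
    """Linear ramp: lambda_max * epoch / max_epoch."""
    if max_epoch <= 0:
        raise ValueError("max_epoch must be positive")
    if not 0 <= epoch <= max_epoch:
        raise ValueError(f"epoch {epoch} outside [0, {max_epoch}]")
    return lambda_max * epoch / max_epoch


def dice_loss(prob: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss 1 - (2*sum(p*y)+eps)/(sum(p)+sum(y)+eps) on foreground."""
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    inter = float((prob * target).sum())
    denom = float(prob.sum() + target.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def _dice_loss_t(prob_fg: "nn.Tensor", target: np.ndarray) -> "nn.Tensor":
    """Batch-mean soft Dice loss as a graph tensor. prob_fg, target: (N,H,W,1)."""
    n = prob_fg.data.shape[0]
    y = nn.Tensor(target.astype(prob_fg.data.dtype))
    inter = nn.sum_axes(nn.mul(prob_fg, y), (1, 2, 3))
    denom = nn.sum_axes(prob_fg, (1, 2, 3)) + nn.Tensor(
        target.sum(axis=(1, 2, 3), keepdims=True))
    dice = (nn.scale(inter, 2.0) + DICE_EPS) / (denom + DICE_EPS)
    return nn.scale(nn.sum_all(1.0 - dice), 1.0 / n)


# ---------------------------------------------------------------- transforms

def _dihedral(rng, augmentations) -> tuple[bool, bool, int, bool]:
    flip_lr = flip_ud = False
    rot = 0
    transp = False
    if "flip" in augmentations:
        flip_lr = bool(rng.integers(2))
        flip_ud = bool(rng.integers(2))
    if "rotation" in augmentations:
        rot = int(rng.integers(4))
    if "transposition" in augmentations:
        transp = bool(rng.integers(2))
    return flip_lr, flip_ud, rot, transp


def _apply_dihedral(arr: np.ndarray, tf) -> np.ndarray:
    """Apply one dihedral transform to the trailing two (spatial) axes."""
    flip_lr, flip_ud, rot, transp = tf
    if flip_lr:
        arr = arr[..., :, ::-1]
    if flip_ud:
        arr = arr[..., ::-1, :]
    if rot:
        arr = np.rot90(arr, rot, axes=(-2, -1))
    if transp:
        arr = np.swapaxes(arr, -2, -1)
    return np.ascontiguousarray(arr)


# ------------------------------------------------------------- pretraining

def pretrain_supervised(labeled, config: TrainConfig,
                        seed: int | None = None) -> tuple[Predictor, list[float]]:
    """Train a plain single-encoder UNet on the labeled images with Dice loss.

    Returns the trained predictor (used to initialize FA maps and as the
    supervised baseline) and the per-epoch mean training loss.
    """
    if not labeled:
        raise ValueError("pretrain_supervised needs at least one labeled image")
    epochs = config.init_epochs or config.max_epoch
    net = build_network(config.network_spec(fusion="none"),
                        config.seed_net1 if seed is None else seed)
    opt = nn.SGD(net.params, config.lr, config.momentum, config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed_data, 0x5E9]))
    imgs = np.stack([np.asarray(i, dtype=np.float32) for i, _ in labeled])
    masks = np.stack([np.asarray(m, dtype=bool) for _, m in labeled])
    history = []
    for epoch in range(1, epochs + 1):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(len(labeled))
        losses = []
        for start in range(0, len(order), config.batch):
            idx = order[start:start + config.batch]
            xb, yb = [], []
            for i in idx:
                tf = _dihedral(rng, config.augmentations)
                xb.append(_apply_dihedral(imgs[i], tf))
                yb.append(_apply_dihedral(masks[i], tf))
            x = nn.Tensor(np.stack(xb)[..., None])
            y = np.stack(yb)[..., None]
            prob = net.forward_t(x, None)
            loss = _dice_loss_t(nn.channel(prob, 1), y)
            if not math.isfinite(loss.item()):
                raise RuntimeError(f"NaN loss in supervised pretraining, epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    net.trained = True
    return net, history


# ----------------------------------------------------------------- training

def _predict_batched(net: Predictor, images, fas, batch: int) -> list[np.ndarray]:
    """Foreground-probability maps for a list of images, batched, no grad."""
    out = []
    frozen = {k: nn.Tensor(p.data) for k, p in net.params.items()}
    shadow = Predictor.__new__(Predictor)
    shadow.spec = net.spec
    shadow.params = frozen
    for start in range(0, len(images), batch):
        x = nn.Tensor(np.stack(images[start:start + batch])[..., None])
        fa_t = None
        if net.spec.fusion != "none":
            fa_t = nn.Tensor(np.moveaxis(
                np.stack(fas[start:start + batch]), 1, -1))
        prob = shadow.forward_t(x, fa_t)
        out.extend(prob.data[..., 1].astype(np.float32))
    return out


def ssfa_train(labeled, unlabeled, config: TrainConfig,
               init_predictor: Predictor | None = None
               ) -> tuple[DualState, dict]:
    """Run the full semi-supervised loop.

    ``labeled`` is a list of (image, mask) pairs; ``unlabeled`` a list of
    images (may be empty, degrading to dual supervised training).  A held-out
    fraction of the labeled images (fixed by the data seed) is used only to
    select the better branch.  Returns the final state and a history dict
    with per-step loss reports and per-epoch validation Dice.
    """
    if not labeled:
        raise ValueError("ssfa_train needs at least one labeled image")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed_data, 0xD0]))

    # validation split for branch selection, fixed by the data seed
    n_val = min(max(1, round(config.val_fraction * len(labeled))), len(labeled) - 1) \
        if len(labeled) > 1 else 0
    perm = rng.permutation(len(labeled))
    val_idx = sorted(perm[:n_val].tolist())
    tr_idx = sorted(perm[n_val:].tolist())
    train_lab = [labeled[i] for i in tr_idx]
    val_lab = [labeled[i] for i in val_idx]

    if init_predictor is None:
        init_predictor, _ = pretrain_supervised(train_lab, config)
    if not init_predictor.trained:
        raise ValueError("init predictor must be trained before FA initialization")

    # image inventory: labeled-train, unlabeled, then validation images
    images = ([np.asarray(i, dtype=np.float32) for i, _ in train_lab]
              + [np.asarray(i, dtype=np.float32) for i in unlabeled]
              + [np.asarray(i, dtype=np.float32) for i, _ in val_lab])
    lab_ids = list(range(len(train_lab)))
    unl_ids = list(range(len(train_lab), len(train_lab) + len(unlabeled)))
    val_ids = list(range(len(train_lab) + len(unlabeled), len(images)))
    masks = {i: np.asarray(m, dtype=bool) for i, (_, m) in
             zip(lab_ids, train_lab)}
    val_masks = {i: np.asarray(m, dtype=bool) for i, (_, m) in
                 zip(val_ids, val_lab)}

    a0 = famap.init_fa_maps(init_predictor, images, config.levels)
    fa_states = {i: famap.FAState(a0[i], config.k) for i in range(len(images))}

    net1 = build_network(config.network_spec(), config.seed_net1)
    net2 = build_network(config.network_spec(), config.seed_net2)
    opt1 = nn.SGD(net1.params, config.lr, config.momentum, config.weight_decay)
    opt2 = nn.SGD(net2.params, config.lr, config.momentum, config.weight_decay)

    history: dict = {"loss": [], "val_dice": [], "lambda": []}
    best = {1: (-1.0, None), 2: (-1.0, None)}  # branch -> (val dice, weights)

    for epoch in range(1, config.max_epoch + 1):
        lam = lambda_schedule(epoch, config.max_epoch, config.lambda_max)
        opt1.lr = opt2.lr = config.lr_at(epoch)
        lab_order = [lab_ids[i] for i in rng.permutation(len(lab_ids))]
        unl_order = [unl_ids[i] for i in rng.permutation(len(unl_ids))]
        b = config.batch
        n_steps = max(math.ceil(len(lab_order) / b),
                      math.ceil(len(unl_order) / b) if unl_order else 0)
        for step in range(n_steps):
            lab_batch = [lab_order[(step * b + j) % len(lab_order)]
                         for j in range(min(b, len(lab_order)))]
            unl_batch = [unl_order[(step * b + j) % len(unl_order)]
                         for j in range(min(b, len(unl_order)))] if unl_order else []
            ids = lab_batch + unl_batch
            tfs = [_dihedral(rng, config.augmentations) for _ in ids]
            x = np.stack([_apply_dihedral(images[i], tf)
                          for i, tf in zip(ids, tfs)])[..., None]
            fa = np.moveaxis(np.stack([_apply_dihedral(fa_states[i].current, tf)
                                       for i, tf in zip(ids, tfs)]), 1, -1)
            y = np.stack([_apply_dihedral(masks[i], tf)
                          for i, tf in zip(ids, tfs[:len(lab_batch)])])[..., None]
            x_t, fa_t = nn.Tensor(x), nn.Tensor(fa)
            p1 = net1.forward_t(x_t, fa_t)
            p2 = net2.forward_t(x_t, fa_t)
            p1f, p2f = nn.channel(p1, 1), nn.channel(p2, 1)
            nl = len(lab_batch)

            def fg_slice(pf, lo, hi):
                t = nn.Tensor(pf.data[lo:hi], (pf,))

                def bw(g, pf=pf, lo=lo, hi=hi):
                    full = np.zeros_like(pf.data)
                    full[lo:hi] = g
                    nn._accum(pf, full)

                t._backward = bw
                return t

            l_sup = nn.add(_dice_loss_t(fg_slice(p1f, 0, nl), y),
                           _dice_loss_t(fg_slice(p2f, 0, nl), y))
            if unl_batch:
                # hard pseudo-labels from the other branch, detached
                y1_hat = (p1f.data[nl:] > BINARIZE_THRESHOLD)
                y2_hat = (p2f.data[nl:] > BINARIZE_THRESHOLD)
                l_unsup = nn.add(
                    _dice_loss_t(fg_slice(p1f, nl, nl + len(unl_batch)), y2_hat),
                    _dice_loss_t(fg_slice(p2f, nl, nl + len(unl_batch)), y1_hat))
            else:
                l_unsup = nn.Tensor(np.asarray(0.0))
            l_total = nn.add(l_sup, nn.scale(l_unsup, lam))
            if not math.isfinite(l_total.item()):
                raise RuntimeError(
                    f"NaN loss at epoch {epoch} step {step}: "
                    f"sup={l_sup.item()} unsup={l_unsup.item()} lambda={lam}")
            opt1.zero_grad()
            opt2.zero_grad()
            l_total.backward()
            opt1.step()
            opt2.step()
            history["loss"].append(LossReport(l_total.item(), l_sup.item(),
                                              l_unsup.item(), lam))
        history["lambda"].append(lam)

        # rebuild FA maps from this epoch's (clean, un-augmented) predictions
        if config.k > 0.0:
            fas = [fa_states[i].current for i in range(len(images))]
            prob1 = _predict_batched(net1, images, fas, config.batch)
            prob2 = _predict_batched(net2, images, fas, config.batch)
            for i in range(len(images)):
                a_hat = famap.fa_map_from_predictions(
                    prob1[i] > BINARIZE_THRESHOLD, prob2[i] > BINARIZE_THRESHOLD,
                    config.levels)
                famap.update_fa_map(fa_states[i], a_hat)

        # branch selection on the held-out labeled split
        if val_ids:
            val_imgs = [images[i] for i in val_ids]
            val_fas = [fa_states[i].current for i in val_ids]
            for branch, net in ((1, net1), (2, net2)):
                probs = _predict_batched(net, val_imgs, val_fas, config.batch)
                dices = [1.0 - dice_loss(p > BINARIZE_THRESHOLD, val_masks[i])
                         for p, i in zip(probs, val_ids)]
                d = float(np.mean(dices))
                if d > best[branch][0]:
                    best[branch] = (d, net.state_dict())
            history["val_dice"].append((best[1][0], best[2][0]))

    for branch, net in ((1, net1), (2, net2)):
        if best[branch][1] is not None:
            net.load_state_dict(best[branch][1])
        net.trained = True
    best_branch = 1 if best[1][0] >= best[2][0] else 2
    state = DualState(net1, net2, fa_states, config.max_epoch, best_branch,
                      max(best[1][0], best[2][0]), config)
    return state, history


# ---------------------------------------------------------------- inference

def two_stage_inference(state: DualState, init_predictor: Predictor | None,
                        image: np.ndarray) -> np.ndarray:
    """Predict a binary mask with FA-map refinement.

    Stage 0 builds the initial FA map from the supervised init network
    (TS1 = TS2, DS = 0; a zero map is used with a warning if no init predictor
    is available).  Stage 1 runs both branches and rebuilds the map from
    their predictions via the configured update weight.  Stage 2 re-runs the
    better branch on the refined map and binarizes at 0.5.
    """
    import warnings

    cfg = state.config
    image = np.asarray(image, dtype=np.float32)
    if init_predictor is not None and init_predictor.trained:
        p0 = init_predictor.predict_mask(image, threshold=BINARIZE_THRESHOLD)
        ts0 = famap.ts_map(p0, cfg.levels)
        a_init = famap.compose_fa_map(ts0, ts0, np.zeros_like(ts0))
    else:
        warnings.warn("no init predictor available; starting from a zero FA map")
        a_init = np.zeros((3,) + image.shape, dtype=np.float32)
    prob1 = state.predictor1.predict_proba(image, a_init)
    prob2 = state.predictor2.predict_proba(image, a_init)
    a_hat = famap.fa_map_from_predictions(prob1 > BINARIZE_THRESHOLD,
                                          prob2 > BINARIZE_THRESHOLD, cfg.levels)
    a_upd = (1.0 - cfg.k) * a_init + cfg.k * a_hat
    net = state.predictor1 if state.best_branch == 1 else state.predictor2
    return net.predict_proba(image, a_upd) > BINARIZE_THRESHOLD
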