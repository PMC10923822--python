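"""Batch planning, validation splitting, and the optimisation loops.

Semi-supervised steps mix labeled and unlabeled samples inside one batch
of total size ``bs`` (16 by default).  The split is proportional to the
pool sizes: with n labeled and m unlabeled training samples,

    δ = (n + m) / bs,   bs_l = ⌊n/δ⌋,   bs_u = ⌈m/δ⌉,

which always satisfies bs_l + bs_u = bs.  For very scarce labels the
floor can yield bs_l = 0 (e.g. n=247, m=9763, bs=16); bs_l is then
clamped to 1 with bs_u reduced accordingly, since a semi-supervised step
needs at least one labeled sample.

Each semi-supervised step encodes the combined batch once, runs the main
decoder on everything, applies the k latent perturbations to the
unlabeled representations, and runs the auxiliary decoder on those.
Gradient routing follows the cross-consistency scheme: the supervised
loss updates the main decoder and the encoder; the ramp-up-weighted
consistency loss updates the auxiliary decoder and the encoder; the main
decoder's unlabeled outputs serve as fixed targets (no gradient flows
back through them).  An epoch is one pass over the unlabeled training
pool; the labeled pool is cycled with reshuffling.  Model selection
keeps the epoch with the best mean validation Jaccard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import losses, perturb
from .evalmetrics import jaccard
from .nets import ModelBundle
from .nn import Adam
from .preprocess import augment


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class BatchPlan:
    bs: int
    bs_l: int
    bs_u: int
    delta: float
    n: int
    m: int
    clamped: bool = False


def plan_batches(n: int, m: int, bs: int = 16) -> BatchPlan:
    """Labeled/unlabeled per-step batch sizes from the pool sizes."""
    if n < 1 or m < 0 or bs < 2:
        raise ValueError("require n >= 1, m >= 0, bs >= 2")
    if bs > n + m:
        raise ValueError(f"batch size {bs} exceeds pool size {n + m}")
    delta = (n + m) / bs
    # floor(n/delta) and ceil(m/delta) in exact integer arithmetic
    bs_l = (n * bs) // (n + m)
    bs_u = -((-m * bs) // (n + m))
    assert bs_l + bs_u == bs
    clamped = False
    if bs_l == 0:
        bs_l, bs_u, clamped = 1, bs - 1, True
    return BatchPlan(bs=bs, bs_l=bs_l, bs_u=bs_u, delta=delta, n=n, m=m,
                     clamped=clamped)


def _val_count(n: int, frac: float) -> int:
    v = math.floor(frac * n + 0.5)  # round half away from zero
    return min(max(v, 1), n - 1)


def _stratified_val(labels, n_val: int, rng) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    per_class = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        per_class[c] = (idx, _val_count(len(idx), n_val / len(labels))
                        if len(idx) > 1 else 0)
    counts = {c: v for c, (idx, v) in per_class.items()}
    # adjust rounding drift so the overall count is honoured
    while sum(counts.values()) > n_val:
        c = max(counts, key=lambda c: counts[c])
        counts[c] -= 1
    while sum(counts.values()) < n_val:
        c = max(counts, key=lambda c: len(per_class[c][0]) - counts[c])
        counts[c] += 1
    chosen = []
    for c, (idx, _) in per_class.items():
        perm = rng.permutation(idx)
        chosen.append(perm[:counts[c]])
    return np.sort(np.concatenate(chosen))


def split_validation(n_labeled: int, n_unlabeled: int = 0, labels=None,
                     labeled_val_fraction: float = 0.2,
                     unlabeled_val_fraction: float = 0.1,
                     rng: np.random.Generator | None = None):
    """Disjoint, exhaustive train/validation index sets for both pools.

    Returns ``(lab_train, lab_val, unl_train, unl_val)``.  The labeled
    split is stratified by image-level label when labels are provided.
    Reproducible for a fixed generator state.
    """
    rng = rng or np.random.default_rng(0)
    if n_labeled < 2:
        raise ValueError("need at least 2 labeled samples to split")
    n_val = _val_count(n_labeled, labeled_val_fraction)
    if labels is not None:
        if len(labels) != n_labeled:
            raise ValueError("labels length mismatch")
        lab_val = _stratified_val(labels, n_val, rng)
    else:
        lab_val = np.sort(rng.permutation(n_labeled)[:n_val])
    lab_train = np.setdiff1d(np.arange(n_labeled), lab_val)

    if n_unlabeled == 0:
        unl_train = unl_val = np.array([], dtype=int)
    else:
        if n_unlabeled < 2:
            raise ValueError("need at least 2 unlabeled samples to split")
        u_val = _val_count(n_unlabeled, unlabeled_val_fraction)
        unl_val = np.sort(rng.permutation(n_unlabeled)[:u_val])
        unl_train = np.setdiff1d(np.arange(n_unlabeled), unl_val)
    return lab_train, lab_val, unl_train, unl_val


@dataclass
class TrainingConfig:
    organ: str = "heart"
    mode: str = "semi_supervised"  # or "supervised"
    input_size: int = 299
    bs: int = 16
    learning_rate: float = 1e-3
    epochs: int = 100
    ramp_length: int = 50
    labeled_val_fraction: float = 0.2
    unlabeled_val_fraction: float = 0.1
    seed: int = 0
    # architecture
    base_filters: int = 16
    depth: int = 5
    blocks_per_stage: int = 3
    cbam: bool = True
    reduction: int = 16
    spatial_k: int = 7
    # consistency training
    k: int = 3
    perturbation: perturb.PerturbationParams = field(
        default_factory=perturb.PerturbationParams)
    unsup_pixel_mean: bool = True
    aux_decoders: int = 1
    # data handling
    augment: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    # batch-norm running-stat momentum; lower it for short desk-scale runs
    # so eval-mode statistics can catch up within few optimisation steps
    bn_momentum: float = 0.99

    def __post_init__(self):
        if self.mode not in ("supervised", "semi_supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.labeled_val_fraction < 1
                and 0 < self.unlabeled_val_fraction < 1):
            raise ValueError("validation fractions must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.aux_decoders != 1:
            raise ValueError(
                "a single auxiliary decoder serves all k perturbations; "
                "aux_decoders != 1 is not supported"
            )


# ---------------------------------------------------------------------------
# loss gradients (probability-map space)

def _supervised_grad(p: np.ndarray, y: np.ndarray, eps: float = 1e-6):
    """Batch BCE+Dice loss value and gradient d(loss)/d(p).

    ``p``/``y`` are (B, H, W); the loss is the batch mean of per-image
    bce + dice, matching the supervised-loss definition.
    """
    b = p.shape[0]
    npix = p.shape[1] * p.shape[2]
    pc = np.clip(p, eps, 1.0 - eps)
    bce_terms = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc),
                         axis=(1, 2))
    grad = (pc - y) / (pc * (1 - pc)) / npix
    ssum = y.sum(axis=(1, 2)) + p.sum(axis=(1, 2)) + losses.DICE_EPS
    inum = 2.0 * (y * p).sum(axis=(1, 2)) + losses.DICE_EPS
    dice_terms = 1.0 - inum / ssum
    grad += -(2.0 * y * ssum[:, None, None] - inum[:, None, None]) \
        / (ssum[:, None, None] ** 2)
    loss = float(np.mean(bce_terms + dice_terms))
    return loss, grad / b


def _consistency_grad(aux_out: np.ndarray, targets: np.ndarray,
                      k: int, bs_u: int, pixel_mean: bool):
    """Loss value and gradient wrt the auxiliary outputs (k*bs_u, H, W)."""
    diff = aux_out - targets
    scale = 1.0 / (k * bs_u)
    if pixel_mean:
        scale /= aux_out.shape[1] * aux_out.shape[2]
    loss = float(np.sum(diff ** 2) * scale)
    return loss, 2.0 * scale * diff


# ---------------------------------------------------------------------------
# training loops

def _snapshot(bundle: ModelBundle):
    params = [p.value.copy() for p in bundle.all_params()]
    bufs = []
    for _, net in bundle._nets():
        for mod in net.iter_modules():
            bufs.append({k: v.copy() for k, v in mod.buffers().items()})
    return params, bufs


def _restore(bundle: ModelBundle, snap):
    params, bufs = snap
    for p, v in zip(bundle.all_params(), params):
        p.value = v.copy()
    i = 0
    for _, net in bundle._nets():
        for mod in net.iter_modules():
            if bufs[i]:
                mod.load_buffers({k: v.copy() for k, v in bufs[i].items()})
            i += 1


def _validate(bundle: ModelBundle, images: np.ndarray, masks: np.ndarray
              ) -> float:
    probs = bundle.predict(images.transpose(0, 3, 1, 2))
    return float(np.mean([
        jaccard(m, p > 0.5) for m, p in zip(masks, probs)
    ]))


def _augment_batch(images, masks, rng, enabled: bool):
    if not enabled:
        return images, masks
    out_i, out_m = [], []
    for im, mk in zip(images, masks):
        ai, am = augment(im, mk, rng)
        out_i.append(ai)
        out_m.append(am)
    return np.stack(out_i), np.stack(out_m)


def _check_finite(*vals):
    for v in vals:
        if not np.isfinite(v):
            raise TrainingDivergedError(f"non-finite loss encountered: {v}")


def _set_bn_momentum(bundle: ModelBundle, momentum: float) -> None:
    for _, net in bundle._nets():
        for mod in net.iter_modules():
            if hasattr(mod, "momentum"):
                mod.momentum = momentum


def _cycler(n_items: int, rng):
    """Endless stream of indices, reshuffled after each full pass."""
    while True:
        for i in rng.permutation(n_items):
            yield int(i)


def train_supervised(config: TrainingConfig, images: np.ndarray,
                     masks: np.ndarray, labels=None):
    """Supervised training: encoder + main decoder, BCE+Dice loss only.

    ``images`` are standardized (N, H, W, 3) arrays in [0, 1]; ``masks``
    are binary (N, H, W).  Returns ``(ModelBundle, history)`` where
    history rows are dicts with epoch, loss_s, loss_u (None), omega
    (None), and val_jaccard; the bundle carries the best-validation
    parameters.
    """
    rng = np.random.default_rng(config.seed)
    lab_train, lab_val, _, _ = split_validation(
        len(images), labels=labels,
        labeled_val_fraction=config.labeled_val_fraction, rng=rng)
    bundle = ModelBundle.build(
        input_size=config.input_size, base_filters=config.base_filters,
        depth=config.depth, blocks_per_stage=config.blocks_per_stage,
        cbam=config.cbam, reduction=config.reduction,
        spatial_k=config.spatial_k, with_aux=False,
        seed=int(rng.integers(2**31 - 1)),
        organ=config.organ, mode="supervised")
    _set_bn_momentum(bundle, config.bn_momentum)
    opt = Adam(bundle.all_params(), lr=config.learning_rate,
               beta1=config.adam_beta1, beta2=config.adam_beta2)

    tr_img, tr_msk = images[lab_train], masks[lab_train]
    va_img, va_msk = images[lab_val], masks[lab_val]
    bs = min(config.bs, len(tr_img))
    history, best = [], (-1.0, None, -1)
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_img))
        losses_s = []
        for s in range(math.ceil(len(tr_img) / bs)):
            idx = order[s * bs:(s + 1) * bs]
            bi, bm = _augment_batch(tr_img[idx], tr_msk[idx], rng,
                                    config.augment)
            x = np.ascontiguousarray(
                bi.transpose(0, 3, 1, 2).astype(np.float32))
            opt.zero_grad()
            p = bundle.main_decoder.forward(
                bundle.encoder.forward(x, train=True), train=True)
            loss_s, dp = _supervised_grad(p[:, 0], bm.astype(np.float32))
            _check_finite(loss_s)
            dz = bundle.main_decoder.backward(
                dp[:, None].astype(np.float32))
            bundle.encoder.backward(dz)
            opt.step()
            losses_s.append(loss_s)
        vj = _validate(bundle, va_img, va_msk)
        history.append({"epoch": epoch, "loss_s": float(np.mean(losses_s)),
                        "loss_u": None, "omega": None, "val_jaccard": vj})
        if vj > best[0]:
            best = (vj, _snapshot(bundle), epoch)
    if best[1] is not None:
        _restore(bundle, best[1])
        bundle.meta.update(best_val_jaccard=best[0], best_epoch=best[2],
                           epochs_run=config.epochs)
    return bundle, history


def train_semi_supervised(config: TrainingConfig, labeled_images: np.ndarray,
                          labeled_masks: np.ndarray,
                          unlabeled_images: np.ndarray, labels=None):
    """Cross-consistency training with a shared encoder and two decoders.

    Returns ``(ModelBundle, history)``; history rows carry the mean
    supervised and consistency losses, the ramp-up weight, and the
    validation Jaccard per epoch.
    """
    rng = np.random.default_rng(config.seed)
    lab_train, lab_val, unl_train, _ = split_validation(
        len(labeled_images), len(unlabeled_images), labels=labels,
        labeled_val_fraction=config.labeled_val_fraction,
        unlabeled_val_fraction=config.unlabeled_val_fraction, rng=rng)
    plan = plan_batches(len(lab_train), len(unl_train), config.bs)
    bundle = ModelBundle.build(
        input_size=config.input_size, base_filters=config.base_filters,
        depth=config.depth, blocks_per_stage=config.blocks_per_stage,
        cbam=config.cbam, reduction=config.reduction,
        spatial_k=config.spatial_k, with_aux=True,
        seed=int(rng.integers(2**31 - 1)),
        organ=config.organ, mode="semi_supervised")
    _set_bn_momentum(bundle, config.bn_momentum)
    opt = Adam(bundle.all_params(), lr=config.learning_rate,
               beta1=config.adam_beta1, beta2=config.adam_beta2)

    tr_img, tr_msk = labeled_images[lab_train], labeled_masks[lab_train]
    va_img, va_msk = labeled_images[lab_val], labeled_masks[lab_val]
    unl = unlabeled_images[unl_train]
    names = perturb.perturbation_names(config.k)

    history, best = [], (-1.0, None, -1)
    lab_stream = _cycler(len(tr_img), rng)
    steps = math.ceil(len(unl) / plan.bs_u)
    for epoch in range(config.epochs):
        omega = losses.rampup_weight(epoch, config.ramp_length)
        u_order = rng.permutation(len(unl))
        ep_s, ep_u = [], []
        for s in range(steps):
            u_idx = u_order[s * plan.bs_u:(s + 1) * plan.bs_u]
            l_idx = [next(lab_stream) for _ in range(plan.bs_l)]
            bi, bm = _augment_batch(tr_img[l_idx], tr_msk[l_idx], rng,
                                    config.augment)
            xl = bi.transpose(0, 3, 1, 2).astype(np.float32)
            xu = unl[u_idx].transpose(0, 3, 1, 2).astype(np.float32)
            x = np.ascontiguousarray(np.concatenate([xl, xu], axis=0))
            nl, nu = len(xl), len(xu)

            opt.zero_grad()
            z = bundle.encoder.forward(x, train=True)
            p = bundle.main_decoder.forward(z, train=True)

            # supervised path: labeled rows only
            loss_s, dp_l = _supervised_grad(p[:nl, 0],
                                            bm.astype(np.float32))
            dp = np.zeros_like(p)
            dp[:nl, 0] = dp_l
            dz = bundle.main_decoder.backward(dp.astype(np.float32))

            # consistency path: perturb unlabeled latents, auxiliary decoder
            z_u = z[nl:]
            outs, vjps = [], []
            for name in names:
                o, v = perturb.apply_perturbation_vjp(
                    name, z_u, rng, config.perturbation,
                    channel_axis=1, batch_axis=0)
                outs.append(o)
                vjps.append(v)
            z_aux = np.ascontiguousarray(
                np.concatenate(outs, axis=0).astype(np.float32))
            a = bundle.aux_decoder.forward(z_aux, train=True)
            targets = np.tile(p[nl:, 0], (config.k, 1, 1))  # detached
            loss_u, da = _consistency_grad(a[:, 0], targets, config.k, nu,
                                           config.unsup_pixel_mean)
            _check_finite(loss_s, loss_u)
            dz_aux = bundle.aux_decoder.backward(
                (omega * da)[:, None].astype(np.float32))
            for d, vjp in enumerate(vjps):
                dz[nl:] += vjp(dz_aux[d * nu:(d + 1) * nu])

            bundle.encoder.backward(dz)
            opt.step()
            ep_s.append(loss_s)
            ep_u.append(loss_u)
        vj = _validate(bundle, va_img, va_msk)
        history.append({"epoch": epoch, "loss_s": float(np.mean(ep_s)),
                        "loss_u": float(np.mean(ep_u)), "omega": omega,
                        "val_jaccard": vj})
        if vj > best[0]:
            best = (vj, _snapshot(bundle), epoch)
    if best[1] is not None:
        _restore(bundle, best[1])
        bundle.meta.update(best_val_jaccard=best[0], best_epoch=best[2],
                           epochs_run=config.epochs)
    return bundle, history
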