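"""U-Net T2 estimator: architecture, cross-validation splits, training, inference.

The network maps a 2-channel slice (normalized T1-weighted and
T2-weighted images) to a 1-channel scaled T2 map.  It is the classic
2D U-Net shape: a four-stage encoder (each stage two 3x3 convolutions
with batch normalization and ReLU, followed by 2x2 max pooling), a
bottleneck, and a four-stage decoder (2x2 upsampling, skip
concatenation, two 3x3 convolutions), closing with a 1-channel
projection.  Channel width doubles at every encoder stage from
``base_width``.  Spatial dimensions must be divisible by 16 (= 2^4
poolings).

Training minimizes a masked L1 loss with Adam; pixels under the
extreme-value mask (reference T2 above the scaling threshold) are
excluded from both loss and gradient.  The network operates on
dimensionless inputs/outputs; conversion to ms happens at the
:func:`predict` boundary via the 400 ms scaling constant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import TrainingConfig
from .io_core import ImageVolume

__all__ = ["NetworkSpec", "SplitPlan", "UNet", "make_splits", "build_network",
           "train", "predict", "TrainHistory"]


@dataclass
class NetworkSpec:
    in_channels: int = 2
    out_channels: int = 1
    depth: int = 4
    base_width: int = 32
    upsample: str = "transposed"   # transposed | nearest


@dataclass
class SplitPlan:
    """Subject-level fold assignments for cross-validation."""

    folds: list[dict[str, list[str]]]
    k: int

    def role_of(self, subject_id: str, fold: int) -> str | None:
        for role in ("train", "val", "test"):
            if subject_id in self.folds[fold][role]:
                return role
        return None


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


class _NearestUp:
    """2x nearest-neighbour upsampling (parameter-free)."""

    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(nn.F32)


class UNet:
    """The 2-channel -> 1-channel slice-wise estimator."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.base_width
        widths = [w * 2 ** i for i in range(spec.depth)]          # encoder widths
        bott = w * 2 ** spec.depth

        def block(c_in, c_out):
            return [nn.Conv3x3(c_in, c_out, rng), nn.BatchNorm(c_out), nn.ReLU(),
                    nn.Conv3x3(c_out, c_out, rng), nn.BatchNorm(c_out), nn.ReLU()]

        self.enc = []
        c = spec.in_channels
        for cw in widths:
            self.enc.append(block(c, cw))
            c = cw
        self.pools = [nn.MaxPool2() for _ in widths]
        self.bottleneck = block(widths[-1], bott)
        self.ups, self.dec = [], []
        c = bott
        for cw in reversed(widths):
            if spec.upsample == "transposed":
                self.ups.append(nn.UpConv2(c, cw, rng))
                up_out = cw
            else:
                self.ups.append(_NearestUp())
                up_out = c
            self.dec.append(block(up_out + cw, cw))
            c = cw
        self.head = nn.Conv3x3(widths[0], spec.out_channels, rng)
        self.layers = ([l for b in self.enc for l in b] + self.pools
                       + self.bottleneck
                       + [u for u in self.ups if u.params]
                       + [l for b in self.dec for l in b] + [self.head])

    # -- plumbing ----------------------------------------------------------
    def _run_block(self, block, x, train):
        for layer in block:
            x = layer.forward(x, train=train)
        return x

    def _back_block(self, block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, H, W, 2) float32 with H, W divisible by 16."""
        _, h, w, c = x.shape
        if h % 16 or w % 16:
            raise ValueError(
                f"input {h}x{w} not divisible by 16; pad or crop the field of view")
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = self._run_block(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self._run_block(self.bottleneck, x, train)
        self._skip_widths = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_widths.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = self._run_block(blk, x, train)
        return self.head.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        dskips = []
        for up, blk, cw in zip(reversed(self.ups), reversed(self.dec),
                               reversed(self._skip_widths)):
            dy = self._back_block(blk, dy)
            dskips.append(dy[..., :cw])
            dy = up.backward(np.ascontiguousarray(dy[..., cw:]))
        dy = self._back_block(self.bottleneck, dy)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = self._back_block(blk, dy)

    # -- state -------------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for layer in self.layers for p in layer.params]
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                state += [layer.run_mean.copy(), layer.run_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = state[i]
                i += 1
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                layer.run_mean[...] = state[i]
                layer.run_var[...] = state[i + 1]
                i += 2


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> UNet:
    """Construct the U-Net; identical seeds give identical initial weights."""
    return UNet(spec or NetworkSpec(), seed=seed)


# ---------------------------------------------------------------------------
# cross-validation splits
# ---------------------------------------------------------------------------

def make_splits(
    subject_ids: list[str],
    k: int = 4,
    sizes: tuple[int, int, int] = (19, 2, 4),
    seed: int = 0,
    must_test_ids: list[str] | None = None,
) -> SplitPlan:
    """Subject-level k-fold plan with fixed train:val:test sizes.

    Test sets are pairwise disjoint across folds.  Ids in
    ``must_test_ids`` (e.g. all cancer patients, so every one of them is
    evaluated exactly once) are placed into test sets first, greedily;
    if fold capacity cannot cover them all an error lists the uncovered
    ids.
    """
    n_train, n_val, n_test = sizes
    ids = list(subject_ids)
    if n_train + n_val + n_test != len(ids):
        raise ValueError(
            f"sizes {sizes} must sum to the number of subjects ({len(ids)})")
    must = list(must_test_ids or [])
    unknown = set(must) - set(ids)
    if unknown:
        raise ValueError(f"must_test_ids not among subjects: {sorted(unknown)}")
    if len(must) > k * n_test:
        raise ValueError(
            "cannot cover all required test subjects: capacity "
            f"{k * n_test} < {len(must)}; uncovered: "
            f"{sorted(must)[k * n_test:]}")

    rng = np.random.default_rng(seed)
    rest = [i for i in ids if i not in must]
    order = [must[i] for i in rng.permutation(len(must))] + \
            [rest[i] for i in rng.permutation(len(rest))]
    folds = []
    for f in range(k):
        test = order[f * n_test:(f + 1) * n_test]
        if len(test) < n_test:  # wrap around for k*n_test > n
            pool = [i for i in ids if i not in test]
            extra = [pool[j] for j in rng.permutation(len(pool))]
            test = test + extra[: n_test - len(test)]
        others = [i for i in ids if i not in test]
        perm = rng.permutation(len(others))
        others = [others[j] for j in perm]
        folds.append({"train": sorted(others[:n_train]),
                      "val": sorted(others[n_train:n_train + n_val]),
                      "test": sorted(test)})
    return SplitPlan(folds=folds, k=k)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train(
    model: UNet,
    train_samples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    val_samples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
    seed: int = 0,
) -> tuple[UNet, TrainHistory]:
    """Minimize masked L1 between network output and reference slices.

    Each sample is ``(input (H,W,2), target (H,W,1), mask (H,W,1))``; the
    mask selects pixels that contribute to loss and gradient (the
    extreme-value exclusion).  Returns the model restored to its
    best-validation-loss state and the loss history.
    """
    if not train_samples:
        raise ValueError("empty training set")
    opt = nn.Adam(model.layers, lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)
    hist = TrainHistory()
    best_val = np.inf
    best_state = model.get_state()
    patience = cfg.early_stop_patience
    bad = 0

    def batches(samples, shuffle):
        idx = np.arange(len(samples))
        if shuffle:
            rng.shuffle(idx)
        for s in range(0, len(idx), cfg.batch_size):
            sel = idx[s:s + cfg.batch_size]
            x = np.stack([samples[i][0] for i in sel]).astype(nn.F32)
            t = np.stack([samples[i][1] for i in sel]).astype(nn.F32)
            m = np.stack([samples[i][2] for i in sel]).astype(nn.F32)
            yield x, t, m

    for epoch in range(cfg.epochs):
        ep_loss, nb = 0.0, 0
        for x, t, m in batches(train_samples, shuffle=True):
            pred = model.forward(x, train=True)
            loss, dpred = nn.masked_l1_loss(pred, t, m)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check input scaling")
            model.backward(dpred)
            opt.step()
            ep_loss += loss
            nb += 1
        hist.train_loss.append(ep_loss / max(nb, 1))

        if val_samples:
            vl, nv = 0.0, 0
            for x, t, m in batches(val_samples, shuffle=False):
                pred = model.forward(x, train=False)
                loss, _ = nn.masked_l1_loss(pred, t, m)
                vl += loss
                nv += 1
            vloss = vl / max(nv, 1)
        else:
            vloss = hist.train_loss[-1]
        hist.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = model.get_state()
            hist.best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if patience and bad >= patience:
                break

    model.set_state(best_state)
    return model, hist


def predict(
    model: UNet,
    t1w_norm: ImageVolume,
    t2w_norm: ImageVolume,
    scale_t2_ms: float = 400.0,
) -> ImageVolume:
    """Slice-wise inference; output in ms, clamped at 0.

    Inputs must be normalized, co-registered, with in-plane dimensions
    divisible by 16.  Slices are independent (2D network), so the output
    slice order follows the input order exactly.
    """
    if t1w_norm.shape != t2w_norm.shape:
        raise ValueError(
            f"channel shape mismatch: {t1w_norm.shape} vs {t2w_norm.shape}")
    out = np.empty(t1w_norm.shape, dtype=float)
    for k in range(t1w_norm.n_slices):
        x = np.stack([t1w_norm.data[:, :, k], t2w_norm.data[:, :, k]],
                     axis=-1)[None].astype(nn.F32)
        pred = model.forward(x, train=False)[0, :, :, 0]
        out[:, :, k] = pred
    out = np.clip(out * scale_t2_ms, 0.0, None)
    return t1w_norm.with_data(out, units="ms")
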