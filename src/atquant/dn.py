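"""Densely connected convolutional network (DN) for air-trapping segmentation.

The architecture is a dense encoder–decoder: an initial 3x3 convolution, then
``n_down`` stages of [dense block -> transition down], a bottleneck dense
block, and ``n_up`` stages of [transition up -> skip concatenation -> dense
block], closed by a 1x1 convolution and a per-pixel two-class softmax.

* A dense-block layer is BN -> ReLU -> 3x3 convolution producing
  ``growth_rate`` new channels, concatenated onto the running feature stack.
* A transition down is BN -> ReLU -> 1x1 convolution -> 2x2 max pooling.
* A transition up is a stride-2 3x3 transposed convolution applied to the new
  feature maps produced by the preceding dense block (the FC-DenseNet
  convention, which keeps decoder cost bounded); its output is concatenated
  with the matching-resolution encoder stack.

Training minimizes the soft Dice loss with SGD-momentum on 2D slices whose
labels are air-trapping maps produced by the personalized threshold method
(weak labels): the network distils an automatic intensity rule into a
contextual classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import DivergenceError, EmptyMaskError
from .qat import QATResult, qat_from_map
from .volume import BinaryMask, CTVolume, ProbabilityMap


@dataclass
class DNConfig:
    """Hyperparameters of the dense network and its training loop.

    Defaults follow the reference training regime (growth rate 8, mini-batches
    of 16, SGD momentum 0.9, learning rate 0.001); ``desk()`` returns a
    lighter preset suited to CPU-scale experiments on the synthetic phantom.
    """

    growth_rate: int = 8
    dense_layers_per_block: int = 4
    n_down: int = 2
    n_up: int = 2
    initial_channels: int = 16
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0
    prob_threshold: float = 0.5
    normalization_window: tuple[float, float] = (-1000.0, 200.0)
    dtype: str = "float32"

    def __post_init__(self):
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.n_down != self.n_up:
            raise ValueError("n_down must equal n_up (shape symmetry)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        lo, hi = self.normalization_window
        if hi <= lo:
            raise ValueError("normalization window must be increasing")
        self.normalization_window = (float(lo), float(hi))

    @classmethod
    def desk(cls, **overrides) -> "DNConfig":
        """CPU-scale preset: half-width network, same depth and training recipe."""
        base = dict(growth_rate=4, initial_channels=8, epochs=32, learning_rate=0.03)
        base.update(overrides)
        return cls(**base)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def normalize(self, hu: np.ndarray) -> np.ndarray:
        """Map HU through the window to [0, 1] (clipped)."""
        lo, hi = self.normalization_window
        return np.clip((np.asarray(hu, dtype=self.np_dtype) - lo) / (hi - lo), 0.0, 1.0)


@dataclass(frozen=True)
class SliceSample:
    """One 2D training sample: normalized image, weak AT label, lung mask."""

    image: np.ndarray  # float in [0, 1]
    label: np.ndarray  # {0,1}
    lung: np.ndarray  # {0,1}
    provenance: tuple = ("", 0, 0)  # (subject, timepoint, z-index)

    def __post_init__(self):
        if self.image.ndim != 2:
            raise ValueError("slice samples are 2D")
        if not (self.image.shape == self.label.shape == self.lung.shape):
            raise ValueError("image/label/lung must share one 2D shape")
        if np.any((self.label == 1) & (self.lung == 0)):
            raise ValueError("label must be a subset of the lung mask")


@dataclass
class TrainingRecord:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    fold_id: int = 0
    seed: int = 0
    best_epoch: int | None = None
    rollbacks: list[int] = field(default_factory=list)  # epochs where lr was halved


class _DenseLayer:
    def __init__(self, cin, growth, rng, dtype):
        self.bn = nn.BatchNorm2d(cin, dtype=dtype)
        self.relu = nn.ReLU()
        self.conv = nn.Conv3x3(cin, growth, rng, dtype)

    def params(self):
        return self.bn.params() + self.conv.params()

    def forward(self, x, train):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(dy)))


class _DenseBlock:
    """Concatenative dense block tracking the full stack and the new features."""

    def __init__(self, cin, n_layers, growth, rng, dtype):
        self.cin = cin
        self.growth = growth
        self.layers = []
        c = cin
        for _ in range(n_layers):
            self.layers.append(_DenseLayer(c, growth, rng, dtype))
            c += growth
        self.cout = c
        self.c_new = c - cin

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        cur = x
        for layer in self.layers:
            new = layer.forward(cur, train)
            cur = np.concatenate([cur, new], axis=1)
        if train:
            self._out_shape = cur.shape
        return cur, cur[:, self.cin :]

    def backward(self, dfull=None, dnew=None):
        """Gradient w.r.t. the block input given gradients on its outputs.

        ``dfull`` is the gradient on the full concatenated stack (may be None),
        ``dnew`` the gradient on the new-features view (may be None)."""
        if dfull is None:
            dfull = np.zeros(self._out_shape, dtype=dnew.dtype)
        else:
            dfull = dfull.copy()
        if dnew is not None:
            dfull[:, self.cin :] += dnew
        for layer in reversed(self.layers):
            c_prev = dfull.shape[1] - self.growth
            dfull = dfull[:, :c_prev] + layer.backward(dfull[:, c_prev:])
        return dfull


class _TransitionDown:
    def __init__(self, c, rng, dtype):
        self.bn = nn.BatchNorm2d(c, dtype=dtype)
        self.relu = nn.ReLU()
        self.conv = nn.Conv1x1(c, c, rng, dtype)
        self.pool = nn.MaxPool2x2()

    def params(self):
        return self.bn.params() + self.conv.params()

    def forward(self, x, train):
        h = self.relu.forward(self.bn.forward(x, train), train)
        return self.pool.forward(self.conv.forward(h, train), train)

    def backward(self, dy):
        dh = self.conv.backward(self.pool.backward(dy))
        return self.bn.backward(self.relu.backward(dh))


class DNNet:
    """The assembled encoder–decoder; construct via :func:`build_dn`."""

    def __init__(self, cfg: DNConfig, rng: np.random.Generator):
        self.cfg = cfg
        dtype = cfg.np_dtype
        g, L = cfg.growth_rate, cfg.dense_layers_per_block
        self.init_conv = nn.Conv3x3(1, cfg.initial_channels, rng, dtype)
        c = cfg.initial_channels
        self.down_blocks, self.transitions_down, self.skip_channels = [], [], []
        for _ in range(cfg.n_down):
            db = _DenseBlock(c, L, g, rng, dtype)
            self.down_blocks.append(db)
            self.skip_channels.append(db.cout)
            self.transitions_down.append(_TransitionDown(db.cout, rng, dtype))
            c = db.cout
        self.bottleneck = _DenseBlock(c, L, g, rng, dtype)
        self.transitions_up, self.up_blocks = [], []
        c_new = self.bottleneck.c_new
        for skip_c in reversed(self.skip_channels):
            self.transitions_up.append(
                nn.TransposedConv3x3Stride2(c_new, c_new, rng, dtype)
            )
            db = _DenseBlock(skip_c + c_new, L, g, rng, dtype)
            self.up_blocks.append(db)
            c_new = db.c_new
        self.head = nn.Conv1x1(self.up_blocks[-1].cout, 2, rng, dtype)

    # -- parameter access ---------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.init_conv.params()
        for db, td in zip(self.down_blocks, self.transitions_down):
            ps += db.params() + td.params()
        ps += self.bottleneck.params()
        for tu, db in zip(self.transitions_up, self.up_blocks):
            ps += tu.params() + db.params()
        return ps + self.head.params()

    def batch_norms(self) -> list[nn.BatchNorm2d]:
        bns = []
        for db in self.down_blocks + [self.bottleneck] + self.up_blocks:
            bns += [l.bn for l in db.layers]
        bns += [td.bn for td in self.transitions_down]
        return bns

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, x):
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.cfg.n_down
        if h % div or w % div:
            raise ValueError(f"input spatial dims must be divisible by {div}, got {h}x{w}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Images (N, 1, H, W) -> per-pixel class probabilities (N, 2, H, W)."""
        self._check_shape(x)
        cur = self.init_conv.forward(x, train)
        skips = []
        for db, td in zip(self.down_blocks, self.transitions_down):
            full, _ = db.forward(cur, train)
            skips.append(full)
            cur = td.forward(full, train)
        _, new = self.bottleneck.forward(cur, train)
        full = None
        for tu, db, skip in zip(self.transitions_up, self.up_blocks, reversed(skips)):
            up = tu.forward(new, train)
            full, new = db.forward(np.concatenate([skip, up], axis=1), train)
        scores = self.head.forward(full, train)
        return nn.softmax2(scores)

    def backward(self, dscores: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-softmax scores into Param.grad."""
        dfull = self.head.backward(dscores)
        dskips = []
        dnew = None
        for tu, db, skip_c in zip(
            reversed(self.transitions_up),
            reversed(self.up_blocks),
            self.skip_channels,
        ):
            dcat = db.backward(dfull=dfull, dnew=dnew)
            dskips.append(dcat[:, :skip_c])
            dnew = tu.backward(dcat[:, skip_c:])
            dfull = None
        dcur = self.bottleneck.backward(dnew=dnew)
        for db, td, dskip in zip(
            reversed(self.down_blocks), reversed(self.transitions_down), reversed(dskips)
        ):
            dfull_enc = td.backward(dcur) + dskip
            dcur = db.backward(dfull=dfull_enc)
        self.init_conv.backward(dcur)

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.params()]
        for bn in self.batch_norms():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def set_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value = a.copy()
            p.grad = np.zeros_like(p.value)
        rest = arrays[len(ps) :]
        for bn, (m, v) in zip(self.batch_norms(), zip(rest[::2], rest[1::2])):
            bn.running_mean = m.copy()
            bn.running_var = v.copy()


def build_dn(cfg: DNConfig, rng: np.random.Generator | None = None) -> DNNet:
    """Construct the dense network with seeded normal weight initialization."""
    rng = rng or np.random.default_rng(cfg.seed)
    return DNNet(cfg, rng)


# ---------------------------------------------------------------------------
# loss re-exported at module level for discoverability
soft_dice_loss = nn.soft_dice_loss


def _batch_arrays(samples: list[SliceSample], idx, dtype):
    x = np.stack([samples[i].image for i in idx]).astype(dtype)[:, None]
    y = np.stack([samples[i].label for i in idx]).astype(dtype)
    return x, y


def train_dn(
    samples: list[SliceSample],
    cfg: DNConfig,
    val_samples: list[SliceSample] | None = None,
    fold_id: int = 0,
) -> tuple[DNNet, TrainingRecord]:
    """Train the DN on weak-label slices with seeded SGD-momentum.

    Deterministic given ``cfg.seed`` (single-threaded).  When ``val_samples``
    is given, the epoch with the best validation soft Dice is kept.

    Dice-loss training with plain momentum occasionally collapses into a
    degenerate all-foreground/all-background state from which gradients cannot
    recover.  A collapse guard watches the epoch loss: on a catastrophic jump
    it restores the best weights seen so far, halves the learning rate, and
    resets the momentum buffer, then continues.
    """
    if not samples:
        raise ValueError("no training samples")
    if cfg.batch_size > len(samples):
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds number of samples {len(samples)}"
        )
    rng = np.random.default_rng(cfg.seed)
    model = build_dn(cfg, rng)
    opt = nn.SGDMomentum(model.params(), cfg.learning_rate, cfg.momentum)
    record = TrainingRecord(fold_id=fold_id, seed=cfg.seed)
    dtype = cfg.np_dtype
    n_batches = len(samples) // cfg.batch_size
    # snapshots are judged on the *post-epoch* weights (validation slices, or
    # a fixed probe of training slices when no validation set is given); the
    # mean loss of an epoch says nothing about the state its last step left
    probe = val_samples if val_samples else samples[: cfg.batch_size]
    best = (-np.inf, None)
    min_loss = np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        losses = []
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            x, y = _batch_arrays(samples, idx, dtype)
            prob = model.forward(x, train=True)
            loss, dp = nn.soft_dice_loss(prob[:, 1], y, with_grad=True)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.backward(nn.dice_grad_to_scores(prob, dp))
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        record.train_loss.append(epoch_loss)
        vd = validation_soft_dice(model, probe, cfg)
        if val_samples:
            record.val_dice.append(vd)
        if epoch_loss > min_loss + 0.2 and best[1] is not None:
            # degenerate collapse: restore the best verified state and take
            # smaller steps with cleared momentum
            model.set_state(best[1])
            opt.params = model.params()
            opt.lr *= 0.5
            opt.reset()
            record.rollbacks.append(epoch)
            continue
        min_loss = min(min_loss, epoch_loss)
        if vd > best[0]:
            best = (vd, [a.copy() for a in model.state_arrays()])
            record.best_epoch = epoch
    if best[1] is not None:
        model.set_state(best[1])
    return model, record


def validation_soft_dice(model: DNNet, samples: list[SliceSample], cfg: DNConfig) -> float:
    """Batch-aggregated soft Dice of predictions against labels (eval mode)."""
    dtype = cfg.np_dtype
    inter = psum = ysum = 0.0
    for start in range(0, len(samples), cfg.batch_size):
        idx = range(start, min(start + cfg.batch_size, len(samples)))
        x, y = _batch_arrays(samples, list(idx), dtype)
        p = model.forward(x, train=False)[:, 1]
        inter += float((p * y).sum())
        psum += float(p.sum())
        ysum += float(y.sum())
    return (2.0 * inter + 1.0) / (psum + ysum + 1.0)


def nested_cv(
    subject_ids: list, k_outer: int = 8, inner_split: int = 2, seed: int = 0
) -> list[tuple[list, list]]:
    """Subject-grouped repeated bipartitions for nested 2-fold cross-validation.

    Each of the ``k_outer`` repetitions shuffles the subjects and splits them
    into two equal (+-1) random pools; all timepoints of a subject stay on one
    side because the split is by subject identifier.
    """
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValueError("nested CV needs at least 2 subjects")
    if inner_split != 2:
        raise ValueError("only 2-fold inner splits are supported")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(k_outer):
        perm = list(rng.permutation(len(ids)))
        half = len(ids) // 2
        train = sorted(ids[i] for i in perm[:half])
        test = sorted(ids[i] for i in perm[half:])
        splits.append((train, test))
    return splits


def predict(
    model: DNNet, exp: CTVolume, lung: BinaryMask, cfg: DNConfig | None = None
) -> tuple[ProbabilityMap, BinaryMask, QATResult]:
    """Slice-wise inference reassembled to 3D.

    Returns the probability map, the binary AT map (probability >= threshold,
    restricted to the lung mask) and the corresponding QAT result.
    """
    cfg = cfg or model.cfg
    exp.require_same_geometry(lung, "expiratory volume and lung mask")
    if lung.count == 0:
        raise EmptyMaskError("lung mask is empty")
    nz = exp.shape[0]
    prob = np.zeros(exp.shape, dtype=np.float32)
    norm = cfg.normalize(exp.voxels)
    step = max(1, cfg.batch_size)
    for start in range(0, nz, step):
        x = norm[start : start + step][:, None]
        prob[start : start + step] = model.forward(x, train=False)[:, 1]
    pmap = ProbabilityMap(prob, exp.spacing, exp.origin)
    at = BinaryMask(
        (prob >= cfg.prob_threshold) & lung.as_bool(), exp.spacing, exp.origin
    )
    base = qat_from_map(at, lung)
    qat = QATResult(
        method="dn",
        threshold_used=None,
        at_voxels=base.at_voxels,
        lung_voxels=base.lung_voxels,
    )
    return pmap, at, qat


def make_slice_samples(
    exp: CTVolume,
    lung: BinaryMask,
    label: BinaryMask,
    cfg: DNConfig,
    subject: str = "",
    timepoint: int = 0,
    lung_only: bool = True,
) -> list[SliceSample]:
    """Cut a labelled volume into per-slice training samples.

    ``exp`` should be the median-filtered expiratory scan, ``label`` the weak
    AT map.  Slices without any lung voxel are skipped when ``lung_only``.
    """
    exp.require_same_geometry(lung, "volume and lung mask")
    exp.require_same_geometry(label, "volume and label")
    norm = cfg.normalize(exp.voxels)
    out = []
    for z in range(exp.shape[0]):
        if lung_only and not lung.voxels[z].any():
            continue
        out.append(
            SliceSample(
                image=norm[z],
                label=label.voxels[z].copy(),
                lung=lung.voxels[z].copy(),
                provenance=(subject, timepoint, z),
            )
        )
    return out


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: DNNet, path) -> None:
    """Single-file model state: parameters, BN running stats, config, seed."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    cfg = asdict(model.cfg)
    cfg["normalization_window"] = list(cfg["normalization_window"])
    np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> DNNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config"]).decode())
        cfg_dict["normalization_window"] = tuple(cfg_dict["normalization_window"])
        cfg = DNConfig(**cfg_dict)
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model = build_dn(cfg)
    model.set_state(arrays)
    return model
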