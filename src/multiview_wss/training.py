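"""Dataset splitting, view pairing, the masked loss, and the training loop.

Splitting happens at the geometry level *before* any images exist, and whole
families (a base geometry plus its variants) move together, so no rendered
view of a test geometry — nor of a near-duplicate variant of one — can leak
into training. Training pairs join an input render (curvature colormap or
shaded geometry) with the stress-map render of the same camera; the loss and
all optimization run only over foreground pixels.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor, masked_mse
from .render import ViewImage, random_zoom

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitManifest",
    "ViewPair",
    "split_dataset",
    "make_pairs",
    "emse_loss",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam on the effective MSE)."""

    learning_rate: float = 1e-4
    max_epochs: int = 300
    early_stop_patience: int = 30
    batch_size: int = 8
    seed: int = 0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")


@dataclass
class SplitManifest:
    """Disjoint, exhaustive train/test partition of geometry ids."""

    train_ids: list[str]
    test_ids: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        fams_train = {self.provenance[g]["family"] for g in self.train_ids
                      if g in self.provenance}
        fams_test = {self.provenance[g]["family"] for g in self.test_ids
                     if g in self.provenance}
        spanning = fams_train & fams_test
        if spanning:
            raise ValueError(f"families span both partitions: {sorted(spanning)[:5]}")


def split_dataset(manifest: list[dict], n_synthetic_test: int,
                  seed: int = 0) -> SplitManifest:
    """Family-respecting split: all real geometries plus ``n_synthetic_test``
    randomly drawn synthetic geometries (whole families) go to test.

    Families are shuffled with ``seed`` and added to the test set until it
    holds exactly ``n_synthetic_test`` synthetic geometries; a count not
    reachable by whole families is an error rather than a silent leak.
    """
    by_family: dict[str, list[dict]] = {}
    for rec in manifest:
        by_family.setdefault(rec["family"], []).append(rec)
    for fam, recs in by_family.items():
        flags = {bool(r.get("real", False)) for r in recs}
        if len(flags) > 1:
            raise ValueError(f"family {fam!r} mixes real and synthetic records")

    real_ids = [r["id"] for r in manifest if r.get("real", False)]
    synth_fams = sorted(f for f, recs in by_family.items()
                        if not recs[0].get("real", False))
    n_synth = sum(len(by_family[f]) for f in synth_fams)
    if n_synthetic_test > n_synth:
        raise ValueError("n_synthetic_test exceeds the synthetic geometry count")

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(synth_fams))
    test_synth: list[str] = []
    remaining = n_synthetic_test
    for fam in list(order):
        size = len(by_family[fam])
        if size <= remaining:
            test_synth.extend(r["id"] for r in by_family[fam])
            remaining -= size
            order.remove(fam)
        if remaining == 0:
            break
    if remaining:
        raise ValueError(
            f"cannot reach exactly {n_synthetic_test} synthetic test "
            "geometries with whole families")

    test_ids = sorted(real_ids + test_synth)
    train_ids = sorted(r["id"] for r in manifest if r["id"] not in set(test_ids))
    if not test_ids:
        logger.warning("empty test partition")
    provenance = {r["id"]: {"real": bool(r.get("real", False)),
                            "family": r["family"]} for r in manifest}
    return SplitManifest(train_ids, test_ids, provenance)


@dataclass
class ViewPair:
    """One training/evaluation example: input and target render of one camera."""

    input: ViewImage
    target: ViewImage
    geometry_id: str
    family: str
    axis: str
    step: int
    augmentation: bool


def make_pairs(
    split: SplitManifest,
    rendered: dict[str, dict[str, list[ViewImage]]],
) -> tuple[list[ViewPair], list[ViewPair]]:
    """Pair input/target views per geometry; returns (train, test) pair lists.

    ``rendered[gid]`` maps roles ``"input"``/``"target"`` to view lists.
    Views are matched on (axis, step index); input and target of a pair must
    share the exact silhouette mask (same camera, same geometry). Test pairs
    keep only non-augmentation (z-axis) views.
    """
    train_pairs: list[ViewPair] = []
    test_pairs: list[ViewPair] = []
    for gid in split.train_ids + split.test_ids:
        is_test = gid in set(split.test_ids)
        if gid not in rendered:
            raise KeyError(f"no rendered views for geometry {gid!r}")
        views = rendered[gid]
        targets = {(v.meta["axis"], v.meta["step_index"]): v for v in views["target"]}
        for inp in views["input"]:
            key = (inp.meta["axis"], inp.meta["step_index"])
            aug = bool(inp.meta.get("augmentation", False))
            if is_test and aug:
                continue
            if key not in targets:
                raise ValueError(f"missing target view {key} for {gid!r}")
            tgt = targets[key]
            if not np.array_equal(inp.mask, tgt.mask):
                raise ValueError(f"input/target masks differ for {gid!r} view {key}")
            pair = ViewPair(inp, tgt, gid,
                            split.provenance.get(gid, {}).get("family", gid),
                            key[0], key[1], aug)
            (test_pairs if is_test else train_pairs).append(pair)
    return train_pairs, test_pairs


def emse_loss(predicted: np.ndarray, target: np.ndarray,
              mask: np.ndarray) -> float:
    """Effective MSE: mean squared intensity difference over masked pixels.

    Background pixels contribute nothing; channels enter through each
    pixel's channel mean, so an all-true mask recovers the plain MSE.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_e = int(mask.sum())
    if n_e == 0:
        raise ValueError("empty mask: effective MSE undefined (N_e = 0)")
    if predicted.shape != target.shape:
        raise ValueError("shape mismatch between predicted and target")
    diff2 = (predicted - target) ** 2
    if predicted.ndim == mask.ndim + 1:
        diff2 = diff2.mean(axis=-1)
    return float((diff2 * mask).sum() / n_e)


def _stack(pairs: list[ViewPair]):
    x = np.stack([p.input.pixels for p in pairs]).astype(np.float32)
    y = np.stack([p.target.pixels for p in pairs]).astype(np.float32)
    m = np.stack([p.input.mask for p in pairs])
    return x, y, m


def _eval_loss(model, pairs: list[ViewPair], batch_size: int) -> float:
    model.eval()
    total, n = 0.0, 0
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        x, y, m = _stack(chunk)
        out = model(Tensor(x))
        total += float(masked_mse(out, y, m).data) * len(chunk)
        n += len(chunk)
    model.train()
    return total / n


def train(model, train_pairs: list[ViewPair], config: TrainConfig,
          val_pairs: list[ViewPair] | None = None) -> dict:
    """Minimize the effective MSE with Adam; early-stop on validation loss.

    If no validation pairs are given, a family-stratified fraction of the
    training families is held out (families never straddle the boundary).
    Random zoom is applied at runtime to training pairs only, with one
    factor per pair shared by input and target. Stops when the validation
    loss has not improved for ``early_stop_patience`` epochs, restoring the
    best-validation weights. Fully deterministic given the config seed and
    the model's initial state.
    """
    if not train_pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(config.seed)
    if val_pairs is None:
        families = sorted({p.family for p in train_pairs})
        n_val = max(1, int(round(config.validation_fraction * len(families))))
        if n_val >= len(families):
            raise ValueError("not enough families for a validation split")
        val_fams = set(rng.permutation(families)[:n_val].tolist())
        val_pairs = [p for p in train_pairs if p.family in val_fams]
        train_pairs = [p for p in train_pairs if p.family not in val_fams]
        logger.info("validation families: %s (%d pairs)", sorted(val_fams),
                    len(val_pairs))

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None,
                     "stopped_epoch": None}
    best_val = np.inf
    best_state = None
    patience_left = config.early_stop_patience
    model.train()

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_pairs))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_pairs[j] for j in order[i:i + config.batch_size]]
            if config.zoom_range != (1.0, 1.0):
                batch_imgs = [random_zoom([p.input, p.target], config.zoom_range, rng)
                              for p in batch]
                x = np.stack([a.pixels for a, _ in batch_imgs]).astype(np.float32)
                y = np.stack([b.pixels for _, b in batch_imgs]).astype(np.float32)
                m = np.stack([a.mask for a, _ in batch_imgs])
            else:
                x, y, m = _stack(batch)
            out = model(Tensor(x))
            loss = masked_mse(out, y, m)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(batch)
            seen += len(batch)
        train_loss = epoch_loss / seen
        val_loss = _eval_loss(model, val_pairs, config.batch_size) if val_pairs \
            else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        logger.info("epoch %d: train %.3e val %.3e", epoch, train_loss, val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_arrays())
            history["best_epoch"] = epoch
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history["stopped_epoch"] = epoch
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return history
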