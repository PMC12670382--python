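"""Layer-wise metabolic-cost proxies of feedforward vision networks.

A network is partitioned into *blocks*, one per parameterized (conv or fc)
layer, each block spanning that weight layer and every parameter-free
function applied to its output before the next weight layer (ReLU, pooling).
The tensor captured for a block is the last one before the next weight layer.

Two cost metrics are defined on a captured tensor:

``active_count``
    number of strictly positive elements — each active unit standing in for
    a spiking neuron, spikes being far more energy-expensive than rest.
``activation_sum``
    sum of the positive parts of the elements, weighting active units by
    their activation intensity.

Post-ReLU tensors are non-negative, so on them "nonzero" and "> 0" coincide;
on the final (ReLU-free) classifier logits the same positive-part rule is
applied for a uniform metric across blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .nn import Network, Residual

#: channel statistics of the ImageNet pretraining distribution, applied only
#: when trained weights expecting them are in use.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

DEFAULT_SIDE = 375  # stimulus resolution used for rating collection

METRICS = ("active_count", "activation_sum")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_image(image, side: int = DEFAULT_SIDE,
                     normalize: tuple[Sequence[float], Sequence[float]] | None = None,
                     ) -> np.ndarray:
    """Decode and rescale an image to the network input tensor.

    Parameters
    ----------
    image : PIL.Image.Image or ndarray
        RGB, RGBA, or single-channel raster. Single-channel inputs are
        replicated to 3 channels.
    side : int
        Output spatial size; bilinear interpolation, matching the stimulus
        resolution the ratings were collected at (375 x 375 by default).
    normalize : (mean, std) per channel, optional
        Identity by default (untrained networks); pass ``(IMAGENET_MEAN,
        IMAGENET_STD)`` when loading weights trained under that convention.

    Returns
    -------
    ndarray of shape (3, side, side), float32 in [0, 1] before normalization.
    """
    if isinstance(image, np.ndarray):
        if image.size == 0:
            raise ValueError("zero-sized image")
        arr = image
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0.0, 1.0)
            arr = (arr * 255).round().astype(np.uint8)
        image = Image.fromarray(arr)
    if image.width == 0 or image.height == 0:
        raise ValueError("zero-sized image")
    image = image.convert("RGB")  # replicates single-channel inputs
    if (image.width, image.height) != (side, side):
        image = image.resize((side, side), Image.BILINEAR)
    x = np.asarray(image, dtype=np.float32) / 255.0
    x = x.transpose(2, 0, 1)
    if normalize is not None:
        mean, std = normalize
        x = (x - np.asarray(mean, np.float32)[:, None, None]) \
            / np.asarray(std, np.float32)[:, None, None]
    return x


# ---------------------------------------------------------------------------
# block partition


@dataclass(frozen=True)
class BlockSpec:
    """One parameterized layer plus its trailing parameter-free functions."""

    index: int            # 1-based depth order
    kind: str             # "conv" | "fc"
    name: str             # name of the weight layer opening the block
    capture_event: int    # position in the execution-event sequence to record

    def __str__(self) -> str:
        return f"block{self.index}:{self.kind}:{self.name}"


def _execution_sequence(network: Network) -> list:
    """Atomic layers in execution order, with a marker for residual adds."""
    seq: list = []
    for layer in network.layers:
        if isinstance(layer, Residual):
            seq.extend(layer.inner)
            seq.append("residual_add")
        else:
            seq.append(layer)
    return seq


def partition_blocks(network: Network) -> list[BlockSpec]:
    """Partition a feedforward network into blocks, one per weight layer.

    Each block's capture point is the last tensor produced before the next
    weight layer runs (for the deepest block: the network output).  For a
    VGG-19 this yields 19 blocks — 16 convolutional and 3 fully connected.
    """
    seq = _execution_sequence(network)
    param_pos = [i for i, item in enumerate(seq)
                 if item != "residual_add" and item.has_params]
    if not param_pos:
        raise ValueError("network has no parameterized layers to partition")
    blocks = []
    for b, pos in enumerate(param_pos):
        nxt = param_pos[b + 1] if b + 1 < len(param_pos) else len(seq)
        layer = seq[pos]
        blocks.append(BlockSpec(index=b + 1, kind=layer.kind,
                                name=layer.name, capture_event=nxt - 1))
    return blocks


# ---------------------------------------------------------------------------
# cost metrics


def _metric_value(tensor: np.ndarray, metric: str) -> float:
    if metric == "active_count":
        return float(np.count_nonzero(tensor > 0))
    if metric == "activation_sum":
        return float(np.maximum(tensor, 0).sum(dtype=np.float64))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass
class LayerCostMatrix:
    """images x blocks matrix of per-layer cost-proxy values."""

    image_ids: list
    blocks: list[BlockSpec]
    values: np.ndarray            # shape (n_images, n_blocks)
    metric: str
    meta: dict = field(default_factory=dict)

    @property
    def totals(self) -> np.ndarray:
        """Whole-network cost per image (row sums over blocks)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(b) for b in self.blocks])
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            side = {
                "metric": self.metric,
                "blocks": [{"index": b.index, "kind": b.kind, "name": b.name}
                           for b in self.blocks],
                **self.meta,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=1)


def compute_layer_costs(network: Network, images: Iterable[np.ndarray],
                        metric: str = "active_count",
                        image_ids: Sequence | None = None) -> LayerCostMatrix:
    """Run each image through the network and record per-block costs.

    ``images`` is an iterable of preprocessed (C, H, W) tensors; images are
    processed one at a time (no cross-image state), so permuting the input
    order permutes the rows identically.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    blocks = partition_blocks(network)
    rows, ids = [], []
    for i, img in enumerate(images):
        x = np.asarray(img, dtype=np.float32)[None]
        _, events = network.forward(x, record=True)
        row = np.empty(len(blocks))
        for b, spec in enumerate(blocks):
            tensor = events[spec.capture_event][1]
            if not np.all(np.isfinite(tensor)):
                raise FloatingPointError(
                    f"non-finite activations at {spec} (image index {i})")
            row[b] = _metric_value(tensor, metric)
        rows.append(row)
        ids.append(image_ids[i] if image_ids is not None else i)
    if not rows:
        raise ValueError("no images supplied")
    return LayerCostMatrix(image_ids=ids, blocks=blocks,
                           values=np.vstack(rows), metric=metric,
                           meta={"network": network.name})


# ---------------------------------------------------------------------------
# null ensembles


@dataclass(frozen=True)
class EnsembleSpec:
    """A family of freshly initialized networks indexed by seed.

    ``seeds`` defaults to 0..999, the convention for a 1,000-member null
    ensemble of untrained models.
    """

    arch_factory: Callable[[], Network]
    seeds: tuple = tuple(range(1000))
    metric: str = "active_count"

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("ensemble seeds must be unique")
        if len(self.seeds) == 0:
            raise ValueError("ensemble needs at least one seed")


def make_null_ensemble(spec: EnsembleSpec) -> Iterator[tuple[int, Network]]:
    """Lazily yield (seed, network) with framework-default random init.

    One model is materialized at a time; the same seed always reproduces the
    same weights.
    """
    for seed in spec.seeds:
        net = spec.arch_factory()
        net.initialize(int(seed))
        yield int(seed), net


def ensemble_statistics(spec: EnsembleSpec, images: Sequence[np.ndarray],
                        stat: Callable[[LayerCostMatrix], float],
                        progress: Callable[[int, float], None] | None = None,
                        ) -> np.ndarray:
    """Stream the ensemble, computing ``stat`` of each member's cost matrix.

    Returns the per-seed statistic vector (the null distribution).
    """
    out = np.empty(len(spec.seeds))
    for i, (seed, net) in enumerate(make_null_ensemble(spec)):
        costs = compute_layer_costs(net, images, metric=spec.metric)
        out[i] = stat(costs)
        if progress is not None:
            progress(seed, out[i])
    return out
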