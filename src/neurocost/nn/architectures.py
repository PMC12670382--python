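"""Stock architectures: VGG-19, a desk-scale toy CNN, and a small residual net.

Networks are built uninitialized (shape metadata only); call
``net.initialize(seed)`` to draw weights.
"""

from __future__ import annotations

from .layers import AdaptiveAvgPool2d, Conv2d, Flatten, Linear, MaxPool2d, ReLU
from .network import Network, Residual

# Channel plan of the 16 convolutional stages; "M" marks 2x2 max pooling.
_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


def vgg19(n_classes: int = 1000, pool_grid: int = 7) -> Network:
    """VGG-19: 16 conv + 3 fully connected weight layers, each followed by a
    ReLU except the final FC; 5 max-pooling steps and one adaptive average
    pooling step ahead of the classifier.

    The adaptive pooling stage maps any input resolution onto the
    ``pool_grid`` x ``pool_grid`` grid the first FC layer expects, so
    non-square-224 inputs (e.g. 375 x 375) are handled without touching the
    FC dimensions.
    """
    layers = []
    in_ch = 3
    for item in _VGG19_CFG:
        if item == "M":
            layers.append(MaxPool2d(2))
        else:
            layers.append(Conv2d(in_ch, item, 3, padding=1))
            layers.append(ReLU())
            in_ch = item
    layers.append(AdaptiveAvgPool2d(pool_grid))
    layers.append(Flatten())
    layers.append(Linear(512 * pool_grid * pool_grid, 4096))
    layers.append(ReLU())
    layers.append(Linear(4096, 4096))
    layers.append(ReLU())
    layers.append(Linear(4096, n_classes))  # no ReLU on the classifier logits
    return Network(layers, name="vgg19")


def toy_cnn(n_classes: int = 4, in_channels: int = 3,
            channels: tuple[int, int, int] = (8, 16, 16)) -> Network:
    """Three conv stages plus one FC head — small enough to train on a CPU in
    seconds while exercising the identical capture/cost pipeline as VGG-19."""
    c1, c2, c3 = channels
    return Network([
        Conv2d(in_channels, c1, 3, padding=1), ReLU(), MaxPool2d(2),
        Conv2d(c1, c2, 3, padding=1), ReLU(), MaxPool2d(2),
        Conv2d(c2, c3, 3, padding=1), ReLU(),
        AdaptiveAvgPool2d(1), Flatten(),
        Linear(c3, n_classes),
    ], name="toy_cnn")


def toy_resnet(n_classes: int = 4, in_channels: int = 3, width: int = 8) -> Network:
    """A small residual network used to check that block partitioning
    enumerates parameterized layers correctly through skip connections."""
    return Network([
        Conv2d(in_channels, width, 3, padding=1), ReLU(),
        Residual([Conv2d(width, width, 3, padding=1), ReLU(),
                  Conv2d(width, width, 3, padding=1), ReLU()]),
        MaxPool2d(2),
        Residual([Conv2d(width, width, 3, padding=1), ReLU(),
                  Conv2d(width, width, 3, padding=1), ReLU()]),
        AdaptiveAvgPool2d(1), Flatten(),
        Linear(width, n_classes),
    ], name="toy_resnet")
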