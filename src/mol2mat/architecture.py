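"""Layer-by-layer specification of the single- and multi-branch fused CNN.

Each fingerprint matrix feeds one branch: two 3x3 unpadded convolutions
(stride 1), one 2x2 max-pool (stride 2), then a flatten.  Branch features are
concatenated and passed through two ReLU dense layers and a softmax output.
Both convolutions use 16 channels by default — the unique channel plan under
which a 32x32 branch flattens to 3136 features, making the concatenation
widths for k = 2..5 branches 6272, 9408, 12544 and 15680.

The dense head widens with the number of fused branches:
k=2 -> (128, 64), k=3 -> (256, 128), k=4 -> (512, 256), k=5 -> (1024, 512);
a single branch uses (256, 128).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .encoding import matrix_size
from .fingerprints import get_spec

__all__ = [
    "BranchSpec",
    "FusedArchitectureSpec",
    "branch_flatten_width",
    "make_fused_spec",
    "DENSE_PLANS",
]

KERNEL = 3  # convolution kernel side
POOL = 2  # max-pool side and stride
DEFAULT_CHANNELS = (16, 16)

#: Dense-head node counts per number of fused branches.
DENSE_PLANS: dict[int, tuple[int, int]] = {
    1: (256, 128),
    2: (128, 64),
    3: (256, 128),
    4: (512, 256),
    5: (1024, 512),
}


def branch_flatten_width(input_side: int, final_channels: int) -> int:
    """Flattened feature count of one branch.

    Two valid 3x3 convolutions shrink the side by 4; the 2x2 pool halves it
    (floor); the result is squared and multiplied by the channel count:
    ``floor((input_side - 4) / 2)**2 * final_channels``.
    """
    side = (input_side - 2 * (KERNEL - 1)) // POOL
    if side < 1:
        raise ValueError(
            f"input side {input_side} too small: two 3x3 convolutions and a "
            f"2x2 pool need at least side 6"
        )
    return side * side * final_channels


@dataclass(frozen=True)
class BranchSpec:
    """One convolutional branch: its input side, channel plan and flatten width."""

    input_side: int
    channels: tuple[int, int] = DEFAULT_CHANNELS
    spec_name: str = ""

    def __post_init__(self):
        if len(self.channels) != 2:
            raise ValueError("each branch has exactly two convolution layers")

    @property
    def flatten_width(self) -> int:
        return branch_flatten_width(self.input_side, self.channels[-1])


@dataclass(frozen=True)
class FusedArchitectureSpec:
    """Complete description of a fused (or single-branch) CNN classifier."""

    branches: tuple[BranchSpec, ...]
    dense_1: int
    dense_2: int
    n_classes: int
    hidden_activation: str = "relu"
    output_activation: str = "softmax"

    def __post_init__(self):
        if not self.branches:
            raise ValueError("at least one branch is required")
        if self.n_classes < 2:
            raise ValueError(f"need >= 2 output classes, got {self.n_classes}")

    @property
    def concat_width(self) -> int:
        return sum(b.flatten_width for b in self.branches)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["concat_width"] = self.concat_width
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FusedArchitectureSpec":
        payload = json.loads(text)
        payload.pop("concat_width", None)
        branches = tuple(
            BranchSpec(b["input_side"], tuple(b["channels"]), b.get("spec_name", ""))
            for b in payload.pop("branches")
        )
        return cls(branches=branches, **payload)


def make_fused_spec(
    specs,
    n_classes: int,
    channels: tuple[int, int] = DEFAULT_CHANNELS,
    dense: tuple[int, int] | None = None,
) -> FusedArchitectureSpec:
    """Build the fused architecture for a list of fingerprint specs.

    One branch per fingerprint, sized by the fingerprint's matrix side.
    Branches of different sides (e.g. MACCS 13x13 fused with ECFP4 32x32) are
    allowed; the concatenation width is the sum of branch flatten widths.
    ``dense`` overrides the per-k default head plan.
    """
    if not specs:
        raise ValueError("spec list must be non-empty")
    if len(specs) > 8:
        raise ValueError(f"at most 8 branches supported, got {len(specs)}")
    branches = []
    for s in specs:
        if isinstance(s, int):
            side, name = matrix_size(s), str(s)
        else:
            fp = get_spec(s)
            side, name = matrix_size(fp.length), fp.name
        branches.append(BranchSpec(input_side=side, channels=channels, spec_name=name))
    if dense is None:
        dense = DENSE_PLANS.get(len(branches), DENSE_PLANS[5])
    return FusedArchitectureSpec(
        branches=tuple(branches), dense_1=dense[0], dense_2=dense[1], n_classes=n_classes
    )
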