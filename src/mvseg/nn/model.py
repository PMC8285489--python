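"""The multi-view, multi-scale voxel-classification network.

One branch per (scale, view): two 3x3 convolutions (each batch-normalized
before its ReLU), a 2x2 max-pool, dropout (p = 0.25), then a dense layer
with 32 output neurons (again BN before ReLU). Branch outputs are
concatenated per scale and across scales, passed through another dense(32)
with BN + ReLU, dropout, and a final dense softmax over the 6 classes.
Batch normalization always precedes the activation; it is not applied
before the final softmax. The single-view (axial) and 3D-view ablations
keep every non-structural hyperparameter and change only the input branches.

Convolution filter counts default to (32, 64) — a conventional doubling —
and are configurable, since only the relative block sizes are fixed by the
topology. Dropout is not repeated after the per-branch dense layer; the
listed layer sequence is followed literally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

from ..core import VIEWS_2D
from .branch import Branch2D
from .layers import (
    F32,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    Sequential,
    softmax,
)

PATCH = 32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``views`` is either a subset of the three anatomical planes or the
    single ``"3d"`` view; ``scales`` are pyramid levels (0 = unaltered
    patch). ``dense_units`` (32) and ``dropout_p`` (0.25) are fixed by the
    architecture and should normally be left at their defaults.
    """

    views: tuple[str, ...] = VIEWS_2D
    scales: tuple[int, ...] = (0, 1, 2)
    ch: int = 3
    n_classes: int = 6
    conv_filters: tuple[int, int] = (32, 64)
    dense_units: int = 32
    dropout_p: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        views = tuple(self.views)
        if views == ("3d",):
            pass
        elif set(views) <= set(VIEWS_2D) and views:
            # canonical order
            object.__setattr__(
                self, "views", tuple(v for v in VIEWS_2D if v in views)
            )
        else:
            raise ValueError(
                f"views must be planar views or ('3d',), got {views}"
            )
        scales = tuple(int(s) for s in self.scales)
        if not scales or list(scales) != sorted(set(scales)) or min(scales) < 0:
            raise ValueError("scales must be distinct, sorted, non-negative")
        object.__setattr__(self, "scales", scales)
        if len(self.conv_filters) != 2 or min(self.conv_filters) < 1:
            raise ValueError("conv_filters must be two positive ints")

    @property
    def is_3d(self) -> bool:
        return self.views == ("3d",)

    @property
    def branch_keys(self) -> tuple[tuple[str, int], ...]:
        """(view, scale) branches in fixed order: scales outer, views inner."""
        return tuple((v, s) for s in self.scales for v in self.views)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("views", "scales", "conv_filters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))

    def architecture_hash(self) -> str:
        d = self.to_dict()
        d.pop("seed")  # weights-compatibility is seed-independent
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def ablation_config(kind: str, seed: int = 0) -> NetworkConfig:
    """Best-model settings with only the input branch structure changed.

    ``axial_view``: one axial 32x32 branch per pyramid scale (3 branches);
    ``3d_view``: one 32^3 branch per pyramid scale. All other
    hyperparameters (3 channels, scales 0-2, filter counts, dense width,
    dropout) match the best multi-view configuration.
    """
    if kind == "axial_view":
        return NetworkConfig(views=("axial",), scales=(0, 1, 2), ch=3, seed=seed)
    if kind == "3d_view":
        return NetworkConfig(views=("3d",), scales=(0, 1, 2), ch=3, seed=seed)
    raise ValueError(f"unknown ablation kind {kind!r}")


class MVCNN:
    """The built network graph; see module docstring for the topology."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_rng, self.dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        f1, f2 = config.conv_filters
        du, p = config.dense_units, config.dropout_p
        self.branches: dict[tuple[str, int], Sequential | Branch2D] = {}
        for key in config.branch_keys:
            view, _ = key
            if view == "3d":
                stem = [
                    Conv3D(config.ch, f1, init_rng, first=True), BatchNorm(f1), _relu(),
                    Conv3D(f1, f2, init_rng), BatchNorm(f2), _relu(),
                    MaxPool3D(), Dropout(p, self.dropout_rng), Flatten(),
                    Dense((PATCH // 2) ** 3 * f2, du, init_rng),
                    BatchNorm(du), _relu(),
                ]
                self.branches[key] = Sequential(stem)
            else:
                # kernel-backed stem; identical architecture, faster path
                self.branches[key] = Branch2D(
                    config.ch, f1, f2, du, p, init_rng, self.dropout_rng
                )
        n_branches = len(self.branches)
        self.head = Sequential(
            [
                Dense(n_branches * du, du, init_rng), BatchNorm(du), _relu(),
                Dropout(p, self.dropout_rng),
                Dense(du, config.n_classes, init_rng),
            ]
        )

    # -- forward / backward -------------------------------------------------

    def forward_logits(
        self, batch: dict[tuple[str, int], np.ndarray], training: bool = False
    ) -> np.ndarray:
        outs = [
            self.branches[key].forward(
                np.asarray(batch[key], dtype=F32), training
            )
            for key in self.config.branch_keys
        ]
        self._widths = [o.shape[1] for o in outs]
        return self.head.forward(np.concatenate(outs, axis=1), training)

    def forward(
        self, batch: dict[tuple[str, int], np.ndarray], training: bool = False
    ) -> np.ndarray:
        """Class probabilities (softmax output), rows summing to 1."""
        return softmax(self.forward_logits(batch, training))

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        offsets = np.cumsum([0] + self._widths)
        for key, lo, hi in zip(self.config.branch_keys, offsets[:-1], offsets[1:]):
            self.branches[key].backward(g[:, lo:hi])

    # -- parameters ---------------------------------------------------------

    def parameters(self):
        ps = []
        for key in self.config.branch_keys:
            ps.extend(self.branches[key].params())
        ps.extend(self.head.params())
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- introspection / persistence ----------------------------------------

    def architecture(self) -> list[dict]:
        """Flat, serializable description of the graph (echo contract)."""
        desc = []
        for key in self.config.branch_keys:
            desc.append(
                {
                    "branch": list(key),
                    **self.branches[key].describe(),
                }
            )
        desc.append({"branch": ["head", -1], **self.head.describe()})
        return desc

    def architecture_yaml(self) -> str:
        return yaml.safe_dump(self.architecture(), sort_keys=True)

    def save_weights(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        stats = {}
        for j, bn in enumerate(self._batchnorms()):
            stats[f"rm{j}"] = bn.running_mean
            stats[f"rv{j}"] = bn.running_var
        np.savez(
            path,
            __hash__=np.frombuffer(
                self.config.architecture_hash().encode(), dtype=np.uint8
            ),
            **arrays,
            **stats,
        )

    def load_weights(self, path) -> None:
        data = np.load(path)
        stored = bytes(data["__hash__"]).decode()
        if stored != self.config.architecture_hash():
            raise ValueError(
                "checkpoint architecture hash mismatch: "
                f"{stored} != {self.config.architecture_hash()}"
            )
        for i, p in enumerate(self.parameters()):
            p.value[...] = data[f"p{i}"]
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = data[f"rm{j}"]
            bn.running_var[...] = data[f"rv{j}"]

    def _batchnorms(self):
        for key in self.config.branch_keys:
            branch = self.branches[key]
            if isinstance(branch, Branch2D):
                yield from branch.batchnorms()
            else:
                for layer in branch.layers:
                    if isinstance(layer, BatchNorm):
                        yield layer
        for layer in self.head.layers:
            if isinstance(layer, BatchNorm):
                yield layer


def _relu():
    from .layers import ReLU

    return ReLU()


def build_network(config: NetworkConfig) -> MVCNN:
    """Build the configured graph with seeded, reproducible initialization."""
    return MVCNN(config)


def count_parameters(config_or_model: NetworkConfig | MVCNN) -> int:
    """Exact trainable parameter count of the (built) graph."""
    model = (
        config_or_model
        if isinstance(config_or_model, MVCNN)
        else MVCNN(config_or_model)
    )
    return model.count_parameters()
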