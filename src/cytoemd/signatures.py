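"""Probability-binning signatures.

A sample is summarized by a *signature*: a set of variable-size
hyper-rectangular bins, each represented by the mean of its member events
(the centroid m_j) and the fraction of events it holds (the weight w_j).
Bins come from recursive median splits: at each node the events are split in
half at the median of the maximum-variance dimension, recursing while both
children would still hold at least ``stop_threshold`` events (default
2 ln N).  High-density regions therefore get many small bins and sparse
regions few large ones, unlike a fixed-grid histogram.

Routing convention for new samples: the stored split value is the lower
median of the builder sample, and ``value <= split`` goes to the left child.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DegenerateInputError, NormalizationError, SchemaError
from .flow_io import EventMatrix

__all__ = [
    "SchemaNode",
    "BinningSchema",
    "Signature",
    "build_schema",
    "apply_schema",
    "assign_bins",
    "compute_signature",
]


@dataclass(frozen=True)
class SchemaNode:
    """One node of the split tree.

    Internal nodes carry (split_dim, split_value, left, right); leaves carry
    only their ``leaf_id`` (assigned depth-first, left before right).
    """

    leaf_id: int | None = None
    split_dim: int | None = None
    split_value: float | None = None
    left: "SchemaNode | None" = None
    right: "SchemaNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None


@dataclass(frozen=True)
class BinningSchema:
    """Recursive median-split tree defining hyper-rectangular bins."""

    root: SchemaNode
    n_channels: int
    n_leaves: int
    stop_threshold: float
    degenerate: bool = False  # root had zero variance everywhere

    def leaf_depths(self) -> np.ndarray:
        depths = np.zeros(self.n_leaves, dtype=int)

        def walk(node: SchemaNode, depth: int) -> None:
            if node.is_leaf:
                depths[node.leaf_id] = depth
            else:
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return depths

    def to_json(self) -> str:
        def encode(node: SchemaNode) -> dict:
            if node.is_leaf:
                return {"leaf": node.leaf_id}
            return {
                "dim": node.split_dim,
                "value": node.split_value,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return json.dumps(
            {
                "n_channels": self.n_channels,
                "n_leaves": self.n_leaves,
                "stop_threshold": self.stop_threshold,
                "degenerate": self.degenerate,
                "tree": encode(self.root),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BinningSchema":
        data = json.loads(text)

        def decode(obj: dict) -> SchemaNode:
            if "leaf" in obj:
                return SchemaNode(leaf_id=obj["leaf"])
            return SchemaNode(
                split_dim=obj["dim"],
                split_value=obj["value"],
                left=decode(obj["left"]),
                right=decode(obj["right"]),
            )

        return cls(
            root=decode(data["tree"]),
            n_channels=data["n_channels"],
            n_leaves=data["n_leaves"],
            stop_threshold=data["stop_threshold"],
            degenerate=data.get("degenerate", False),
        )


@dataclass(frozen=True)
class Signature:
    """Centroid/weight summary of a sample: {(m_j, w_j)}, weights sum to 1."""

    centroids: np.ndarray  # (m, d)
    weights: np.ndarray  # (m,)
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        weights = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "weights", weights)
        if centroids.shape[0] != weights.shape[0]:
            raise NormalizationError(
                f"{centroids.shape[0]} centroids but {weights.shape[0]} weights"
            )
        if weights.shape[0] < 1:
            raise DegenerateInputError("signature must have at least one bin")
        if np.any(weights < 0):
            raise NormalizationError("signature weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise NormalizationError(
                f"signature weights sum to {weights.sum():.12f}, expected 1"
            )

    @property
    def n_bins(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.centroids.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "centroids": self.centroids.tolist(),
                "weights": self.weights.tolist(),
                "channels": list(self.channels) if self.channels else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Signature":
        data = json.loads(text)
        channels = tuple(data["channels"]) if data.get("channels") else None
        return cls(np.array(data["centroids"]), np.array(data["weights"]), channels)


def _resolve_threshold(stop_threshold: Union[float, str], n: int) -> float:
    if stop_threshold == "auto":
        return 2.0 * math.log(n)
    value = float(stop_threshold)
    if value <= 0:
        raise DegenerateInputError(f"stop_threshold must be positive, got {value}")
    return value


def build_schema(
    events: EventMatrix, stop_threshold: Union[float, str] = "auto"
) -> BinningSchema:
    """Build the recursive median-split tree for a sample.

    At each node the dimension with the largest sample variance (n-1
    denominator; lowest index on ties) is split at its lower median, the
    first ceil(n/2) sorted events going left.  Recursion stops when either
    child would fall below ``stop_threshold`` events, or when every dimension
    has zero variance.  ``"auto"`` sets the threshold to 2 ln N with N the
    root event count.
    """
    values = events.values
    n = values.shape[0]
    if n < 2:
        raise DegenerateInputError(f"need at least 2 events to build a schema, got {n}")
    threshold = _resolve_threshold(stop_threshold, n)

    counter = {"next": 0}

    def split(index: np.ndarray) -> SchemaNode:
        sub = values[index]
        m = index.shape[0]
        if m >= 2:
            variances = sub.var(axis=0, ddof=1)
        else:
            variances = np.zeros(values.shape[1])
        n_left = (m + 1) // 2
        n_right = m - n_left
        can_split = (
            m >= 2
            and variances.max() > 0.0
            and n_left >= threshold
            and n_right >= threshold
        )
        if not can_split:
            leaf = SchemaNode(leaf_id=counter["next"])
            counter["next"] += 1
            return leaf
        dim = int(np.argmax(variances))  # argmax takes the lowest index on ties
        order = np.argsort(sub[:, dim], kind="stable")
        split_value = float(sub[order[n_left - 1], dim])  # lower median
        left = split(index[order[:n_left]])
        right = split(index[order[n_left:]])
        return SchemaNode(split_dim=dim, split_value=split_value, left=left, right=right)

    root = split(np.arange(n))
    degenerate = root.is_leaf
    return BinningSchema(
        root=root,
        n_channels=values.shape[1],
        n_leaves=counter["next"],
        stop_threshold=threshold,
        degenerate=degenerate,
    )


def assign_bins(events: EventMatrix, schema: BinningSchema) -> np.ndarray:
    """Leaf id for each event, routing ``value <= split_value`` left."""
    if events.n_channels < schema.n_channels:
        raise SchemaError(
            f"schema needs {schema.n_channels} channels, events have {events.n_channels}"
        )
    values = events.values
    out = np.empty(events.n_events, dtype=int)

    def route(node: SchemaNode, index: np.ndarray) -> None:
        if node.is_leaf:
            out[index] = node.leaf_id
            return
        go_left = values[index, node.split_dim] <= node.split_value
        route(node.left, index[go_left])
        route(node.right, index[~go_left])

    route(schema.root, np.arange(events.n_events))
    return out


def apply_schema(events: EventMatrix, schema: BinningSchema) -> np.ndarray:
    """Per-leaf event counts for a (possibly different) sample; sums to N."""
    labels = assign_bins(events, schema)
    return np.bincount(labels, minlength=schema.n_leaves)


def compute_signature(
    events: EventMatrix,
    schema: Union[BinningSchema, str] = "auto",
    stop_threshold: Union[float, str] = "auto",
) -> Signature:
    """Summarize a sample as a signature.

    With ``schema="auto"`` the split tree is built from these events (each
    sample gets its own bins, the default for EMD); passing an existing
    schema bins the sample with foreign bins (the control-derived binning
    used by the PB and chi-square statistics).  Centroids are the means of
    the member events of each non-empty leaf; weights are occupancy
    fractions.  Empty leaves are dropped.
    """
    if isinstance(schema, str):
        if schema != "auto":
            raise SchemaError(f"schema must be a BinningSchema or 'auto', got {schema!r}")
        if events.n_events == 1:
            return Signature(events.values.mean(axis=0, keepdims=True), np.ones(1), events.channels)
        schema = build_schema(events, stop_threshold)
    labels = assign_bins(events, schema)
    counts = np.bincount(labels, minlength=schema.n_leaves)
    occupied = np.flatnonzero(counts)
    centroids = np.empty((occupied.size, events.n_channels))
    for row, leaf in enumerate(occupied):
        centroids[row] = events.values[labels == leaf].mean(axis=0)
    weights = counts[occupied] / events.n_events
    return Signature(centroids, weights, events.channels)
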