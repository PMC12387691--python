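"""Operation-count accounting for the attention-fusion network.

Cost model (multiply–accumulates, MACs) for a convolution producing a
``D_f × D_f`` map with kernel ``D_k``, ``M`` input and ``N`` output
channels::

    standard conv : D_k · D_k · M · N · D_f · D_f
    DSC           : D_k · D_k · M · D_f · D_f  +  M · N · D_f · D_f
                    (depthwise)                   (pointwise)

so the DSC/standard MAC ratio is exactly ``1/N + 1/D_k²`` per layer.

MACs expand to FLOPs under one pinned convention, stated here once:

* 2 FLOPs per MAC for every convolution and dense layer;
* +1 FLOP per bias addition — one bias per depthwise-separable pair
  (carried by the pointwise stage, as in fused separable-conv layers)
  and one per dense output;
* max-pooling costs one comparison per kernel cell per output element
  (4 for a 2×2 pool);
* elementwise activations (ReLU, softmax, sigmoid) and the per-vector
  standardization are not counted.

Under this convention the reference configuration totals 78,108,028
FLOPs. The MAC-level per-layer breakdown is the binding contract; the
op-level total depends only on the convention above.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import ModelConfig

__all__ = [
    "LayerSpec",
    "LayerCount",
    "DscComparison",
    "FlopsBreakdown",
    "standard_conv_macs",
    "dsc_macs",
    "count_flops",
]

FLOPS_PER_MAC = 2
POOL_OPS_PER_OUTPUT_CELL = 1  # per kernel cell, i.e. 4 per 2×2 pool output


@dataclass(frozen=True)
class LayerSpec:
    """Symbolic description of one counted layer."""

    kind: str            # depthwise | pointwise | dense | pool
    name: str
    d_k: int             # kernel size (1 for dense)
    m: int               # input channels / fan-in
    n: int               # output channels / fan-out
    d_f: int             # output spatial side (1 for dense)


@dataclass(frozen=True)
class LayerCount:
    spec: LayerSpec
    macs: int
    flops: int


@dataclass(frozen=True)
class DscComparison:
    """Standard-vs-separable MAC cost for one conv layer."""

    name: str
    standard_macs: int
    dsc_macs: int

    @property
    def ratio(self) -> float:
        return self.dsc_macs / self.standard_macs


@dataclass
class FlopsBreakdown:
    per_layer: list[LayerCount]
    dsc_comparisons: list[DscComparison]

    @property
    def total(self) -> int:
        return sum(lc.flops for lc in self.per_layer)

    @property
    def total_macs(self) -> int:
        return sum(lc.macs for lc in self.per_layer)

    def table(self) -> pd.DataFrame:
        rows = [{"layer": lc.spec.name, "kind": lc.spec.kind,
                 "D_k": lc.spec.d_k, "M": lc.spec.m, "N": lc.spec.n,
                 "D_f": lc.spec.d_f, "MACs": lc.macs, "FLOPs": lc.flops}
                for lc in self.per_layer]
        return pd.DataFrame(rows)


def standard_conv_macs(d_k: int, m: int, n: int, d_f: int) -> int:
    """MACs of a standard convolution."""
    return d_k * d_k * m * n * d_f * d_f


def dsc_macs(d_k: int, m: int, n: int, d_f: int) -> int:
    """MACs of the equivalent depthwise-separable convolution."""
    return d_k * d_k * m * d_f * d_f + m * n * d_f * d_f


def count_flops(cfg: ModelConfig = ModelConfig()) -> FlopsBreakdown:
    """Per-layer MAC and FLOP counts for one forward pass."""
    layers: list[LayerCount] = []
    comparisons: list[DscComparison] = []
    h, w, m = cfg.input_size
    if h != w:
        raise ValueError("the cost model assumes square inputs")
    side = h
    k = cfg.kernel
    flat_dims: list[int] = []
    for i, n in enumerate(cfg.block_filters, start=1):
        dw = LayerSpec("depthwise", f"block{i}/depthwise", k, m, m, side)
        dw_macs = k * k * m * side * side
        layers.append(LayerCount(dw, dw_macs, FLOPS_PER_MAC * dw_macs))
        pw = LayerSpec("pointwise", f"block{i}/pointwise", 1, m, n, side)
        pw_macs = m * n * side * side
        # the separable pair carries a single bias, added here
        layers.append(LayerCount(pw, pw_macs,
                                 FLOPS_PER_MAC * pw_macs + n * side * side))
        comparisons.append(DscComparison(
            f"block{i}", standard_conv_macs(k, m, n, side),
            dsc_macs(k, m, n, side)))
        pooled = side // cfg.pool
        pool = LayerSpec("pool", f"block{i}/maxpool", cfg.pool, n, n, pooled)
        pool_ops = (POOL_OPS_PER_OUTPUT_CELL * cfg.pool * cfg.pool
                    * n * pooled * pooled)
        layers.append(LayerCount(pool, 0, pool_ops))
        flat_dims.append(pooled * pooled * n)
        side, m = pooled, n
    d = cfg.projection_dim
    for i, flat in enumerate(flat_dims, start=1):
        spec = LayerSpec("dense", f"proj{i}", 1, flat, d, 1)
        layers.append(LayerCount(spec, flat * d, FLOPS_PER_MAC * flat * d + d))
    hid = cfg.attention_hidden
    # shared scorer applied to each of the three feature vectors
    a1 = LayerSpec("dense", "attention/hidden(x3)", 1, d, hid, 1)
    a1_macs = 3 * d * hid
    layers.append(LayerCount(a1, a1_macs, FLOPS_PER_MAC * a1_macs + 3 * hid))
    a2 = LayerSpec("dense", "attention/logit(x3)", 1, hid, 1, 1)
    a2_macs = 3 * hid
    layers.append(LayerCount(a2, a2_macs, FLOPS_PER_MAC * a2_macs + 3))
    head = LayerSpec("dense", "head", 1, d, 1, 1)
    layers.append(LayerCount(head, d, FLOPS_PER_MAC * d + 1))
    return FlopsBreakdown(per_layer=layers, dsc_comparisons=comparisons)
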