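"""Layer graphs for the three lesion-segmentation architectures.

Three encoder-decoder networks over the two-class label set
{background, lesion}:

* **CNN1** — a series (single-path) network: three sub-sampling modules
  (Conv-BN-ReLU x2 then 2x2/stride-2 MaxPool), a two-conv bottleneck,
  three up-sampling modules (4x4 Deconv-BN-ReLU then Conv-BN-ReLU, with
  one Dropout after the first), a size-preserving MaxPool, a 1x1
  two-channel conv head, Softmax and a pixel-classification sink.
  A 160x160 input is sub-sampled to 20x20 at the bottleneck and
  up-sampled back to 160x160.
* **CNN2** — CNN1 plus one skip path: the full-resolution features after
  the first module's second ReLU are reduced by two MaxPool-Conv-BN-ReLU
  stages to the first deconv's resolution and depth-concatenated there,
  re-injecting pixel-localization detail into the decoder.
* **CNN3** — CNN2 plus three further skip paths tapping each
  sub-sampling module after its second ReLU, brought to full resolution
  (identity / one stride-2 deconv / one stride-4 deconv) and
  depth-concatenated just before the 1x1 conv head, so the classifier
  sees detail from every encoder scale.

Processing-layer totals (input layer excluded) are 52, 61 and 68.
Graphs are plain data (layers + edges) validated and topologically
ordered with networkx; the numerical engine interprets them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "LayerSpec",
    "LayerGraph",
    "build_network",
    "count_layers",
    "infer_shapes",
    "VARIANTS",
]

VARIANTS = ("CNN1", "CNN2", "CNN3")

#: layer kinds that count as processing layers (everything but input)
PROCESSING_KINDS = frozenset(
    {"conv", "batchnorm", "relu", "maxpool", "deconv", "dropout", "concat",
     "softmax", "pixelclass"}
)
KINDS = PROCESSING_KINDS | {"input"}


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass
class LayerGraph:
    """A directed acyclic graph of typed layers.

    ``edges`` are (src_name, dst_name); for concat layers the incoming
    edge order defines the channel order of the concatenation.
    """

    layers: list[LayerSpec]
    edges: list[tuple[str, str]]
    variant: str

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self._by_name = {l.name: l for l in self.layers}
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("layer graph has a cycle")
        self._nx = g

    def layer(self, name: str) -> LayerSpec:
        return self._by_name[name]

    def predecessors(self, name: str) -> list[str]:
        """Incoming layers in edge-declaration order (matters for concat)."""
        return [s for s, d in self.edges if d == name]

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._nx))

    @property
    def input_name(self) -> str:
        (name,) = [l.name for l in self.layers if l.kind == "input"]
        return name

    @property
    def output_name(self) -> str:
        (name,) = [l.name for l in self.layers if l.kind == "pixelclass"]
        return name

    def n_paths(self) -> int:
        """Number of distinct input-to-sink paths (1 for a series net)."""
        return len(
            list(nx.all_simple_paths(self._nx, self.input_name, self.output_name))
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "variant": self.variant,
                "layers": [
                    {"name": l.name, "kind": l.kind, "hyperparams": l.hyperparams}
                    for l in self.layers
                ],
                "edges": self.edges,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LayerGraph":
        d = json.loads(text)
        return cls(
            layers=[LayerSpec(x["name"], x["kind"], x["hyperparams"]) for x in d["layers"]],
            edges=[tuple(e) for e in d["edges"]],
            variant=d["variant"],
        )


def count_layers(g: LayerGraph) -> int:
    """Number of processing layers, excluding the data input layer."""
    return sum(1 for l in g.layers if l.kind in PROCESSING_KINDS)


class _Builder:
    def __init__(self):
        self.layers: list[LayerSpec] = []
        self.edges: list[tuple[str, str]] = []
        self._counts: dict[str, int] = {}

    def add(self, kind: str, prev: str | list[str] | None, name: str | None = None,
            **hp) -> str:
        if name is None:
            i = self._counts.get(kind, 0) + 1
            self._counts[kind] = i
            name = f"{kind}{i}"
        self.layers.append(LayerSpec(name, kind, hp))
        if prev is not None:
            for p in ([prev] if isinstance(prev, str) else prev):
                self.edges.append((p, name))
        return name

    def conv_bn_relu(self, prev: str, filters: int, kernel: int = 3) -> str:
        c = self.add("conv", prev, filters=filters, kernel=kernel, stride=1,
                     padding=(kernel - 1) // 2)
        b = self.add("batchnorm", c)
        return self.add("relu", b)

    def deconv_bn_relu(self, prev: str, filters: int, stride: int = 2) -> str:
        # 4x4 kernels; padding chosen so spatial size is multiplied exactly
        # by the stride: out = (H-1)*s + 4 - 2p  ->  p = (4-s)/2
        pad = (4 - stride) // 2
        d = self.add("deconv", prev, filters=filters, kernel=4, stride=stride,
                     padding=pad)
        b = self.add("batchnorm", d)
        return self.add("relu", b)


def build_network(variant: str, input_side: int, width: int = 64) -> LayerGraph:
    """Construct one of the three architectures as a LayerGraph.

    ``width`` is the feature-map count of every conv/deconv layer except
    the two-channel classification head; the layer structure (and hence
    the layer count) does not depend on it.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if input_side <= 0 or input_side % 8 != 0:
        raise ValueError(f"input_side must be a positive multiple of 8, got {input_side}")
    if width < 2:
        raise ValueError(f"width must be >= 2, got {width}")

    b = _Builder()
    x = b.add("input", None, name="input", side=input_side, channels=1)

    # --- encoder: three sub-sampling modules ------------------------------
    taps = []  # output of each module's second ReLU, before its pool
    for _ in range(3):
        x = b.conv_bn_relu(x, width)
        x = b.conv_bn_relu(x, width)
        taps.append(x)
        x = b.add("maxpool", x, kernel=2, stride=2, padding=0)

    # --- bottleneck -------------------------------------------------------
    x = b.conv_bn_relu(x, width)
    x = b.conv_bn_relu(x, width)

    # --- skip branch of CNN2/CNN3: full-res tap reduced to the first
    # deconv's resolution by two pool-conv stages --------------------------
    skip2 = None
    if variant in ("CNN2", "CNN3"):
        s = b.add("maxpool", taps[0], kernel=2, stride=2, padding=0)
        s = b.conv_bn_relu(s, width)
        s = b.add("maxpool", s, kernel=2, stride=2, padding=0)
        skip2 = b.conv_bn_relu(s, width)

    # --- decoder: three up-sampling modules -------------------------------
    x = b.deconv_bn_relu(x, width)
    if skip2 is not None:
        x = b.add("concat", [x, skip2])
    x = b.conv_bn_relu(x, width)
    x = b.add("dropout", x, ratio=0.5)
    for _ in range(2):
        x = b.deconv_bn_relu(x, width)
        x = b.conv_bn_relu(x, width)

    # size-preserving pool: 2x2 window, stride 1, same padding — a stride-2
    # pool here would halve the output and break same-size pixel labeling
    x = b.add("maxpool", x, kernel=2, stride=1, padding="same")

    # --- CNN3: every encoder tap re-aggregated at full resolution ---------
    if variant == "CNN3":
        up_half = b.deconv_bn_relu(taps[1], width, stride=2)
        up_quarter = b.deconv_bn_relu(taps[2], width, stride=4)
        x = b.add("concat", [x, taps[0], up_half, up_quarter])

    # --- two-channel classification head ----------------------------------
    x = b.conv_bn_relu(x, filters=2, kernel=1)
    x = b.add("softmax", x)
    b.add("pixelclass", x)

    return LayerGraph(layers=b.layers, edges=b.edges, variant=variant)


# ---------------------------------------------------------------------------
# symbolic shape propagation

def infer_shapes(g: LayerGraph, input_side: int | None = None) -> dict[str, tuple[int, int, int]]:
    """Propagate (channels, height, width) through the graph.

    Raises if concat inputs disagree spatially or a pool hits an odd
    size; used by tests to verify scale bookkeeping and by the engine to
    size parameters.
    """
    shapes: dict[str, tuple[int, int, int]] = {}
    for name in g.topological_order():
        layer = g.layer(name)
        hp = layer.hyperparams
        preds = g.predecessors(name)
        if layer.kind == "input":
            side = input_side if input_side is not None else hp["side"]
            shapes[name] = (hp.get("channels", 1), side, side)
            continue
        ins = [shapes[p] for p in preds]
        c, h, w = ins[0]
        if layer.kind == "conv":
            k, s, p = hp["kernel"], hp["stride"], hp["padding"]
            shapes[name] = (hp["filters"], (h + 2 * p - k) // s + 1,
                            (w + 2 * p - k) // s + 1)
        elif layer.kind == "deconv":
            k, s, p = hp["kernel"], hp["stride"], hp["padding"]
            shapes[name] = (hp["filters"], (h - 1) * s + k - 2 * p,
                            (w - 1) * s + k - 2 * p)
        elif layer.kind == "maxpool":
            if hp["padding"] == "same":
                shapes[name] = (c, h, w)
            else:
                k, s = hp["kernel"], hp["stride"]
                if h % s or w % s:
                    raise ValueError(f"maxpool {name}: odd input size {h}x{w}")
                shapes[name] = (c, h // s, w // s)
        elif layer.kind == "concat":
            hs = {sh[1:] for sh in ins}
            if len(hs) != 1:
                raise ValueError(
                    f"concat {name}: spatial shapes differ: {[sh[1:] for sh in ins]}"
                )
            shapes[name] = (sum(sh[0] for sh in ins), h, w)
        else:  # batchnorm, relu, dropout, softmax, pixelclass
            shapes[name] = (c, h, w)
    return shapes
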