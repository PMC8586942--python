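"""Parameter, FLOP and receptive-field accounting for layer graphs.

Conventions (deliberately simple and auditable):

* Parameters: each convolution contributes ``k^2 * c_in * c_out + c_out``
  (weights plus biases).  Pooling, upsampling, concatenation, addition
  and activations contribute nothing.
* FLOPs (floating additions + multiplications for one forward pass):
  a convolution producing an ``h x w x c_out`` tensor costs
  ``h * w * c_out * 2 * k^2 * c_in`` — per output element, ``k^2 c_in``
  multiplications and ``k^2 c_in - 1`` additions plus one bias addition.
  An element-wise ``add`` node costs one addition per element.  Pooling,
  upsampling, concatenation and activations count zero floating ops.
* Receptive field: the standard recursion ``r <- r + (k - 1) * j`` with
  jump updates ``j <- j * s`` through convolutions and poolings, taking
  the maximum over merging branches; upsampling halves the jump.

The per-node breakdown makes any alternative convention easy to audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .graph import ModelSpec


@dataclass
class ComplexityReport:
    parameter_count: int
    flops: int
    receptive_field: float
    per_node: pd.DataFrame  # columns: node, op, stage, params, flops

    def to_csv(self, path) -> None:
        self.per_node.to_csv(path, index=False)


def count_parameters(model: ModelSpec) -> int:
    """Total trainable scalars (conv weights and biases)."""
    return sum(n.conv.n_parameters for n in model.conv_nodes())


def count_flops(model: ModelSpec,
                input_shape: tuple[int, int, int] | None = None) -> int:
    """Floating additions + multiplications for one forward prediction."""
    model = _reshaped(model, input_shape)
    shapes = model.infer_shapes()
    total = 0
    for node in model.nodes:
        total += _node_flops(node, shapes)
    return total


def _node_flops(node, shapes) -> int:
    if node.op == "conv":
        h, w, cout = shapes[node.id]
        k = node.conv.kernel_size
        return h * w * cout * 2 * k * k * node.conv.in_channels
    if node.op == "add":
        h, w, c = shapes[node.id]
        return h * w * c
    return 0


def receptive_field(model: ModelSpec) -> float:
    """Receptive field (px) of the output node by the standard recursion."""
    rf: dict[str, tuple[float, float]] = {}  # id -> (r, jump)
    for node in model.nodes:
        ins = [rf[i] for i in node.inputs]
        if node.op == "input":
            rf[node.id] = (1.0, 1.0)
        elif node.op == "conv":
            r, j = ins[0]
            k, s = node.conv.kernel_size, node.conv.stride
            rf[node.id] = (r + (k - 1) * j, j * s)
        elif node.op == "maxpool2":
            r, j = ins[0]
            rf[node.id] = (r + j, j * 2)
        elif node.op == "upsample2":
            r, j = ins[0]
            rf[node.id] = (r, j / 2)
        else:  # concat / add / relu: field of the widest operand
            rf[node.id] = (max(r for r, _ in ins), max(j for _, j in ins))
    return rf[model.output_id][0]


def complexity_report(model: ModelSpec,
                      input_shape: tuple[int, int, int] | None = None
                      ) -> ComplexityReport:
    model = _reshaped(model, input_shape)
    shapes = model.infer_shapes()
    rows = []
    for node in model.nodes:
        params = node.conv.n_parameters if node.op == "conv" else 0
        rows.append({"node": node.id, "op": node.op, "stage": node.stage,
                     "params": params, "flops": _node_flops(node, shapes)})
    table = pd.DataFrame(rows)
    return ComplexityReport(
        parameter_count=int(table["params"].sum()),
        flops=int(table["flops"].sum()),
        receptive_field=receptive_field(model),
        per_node=table,
    )


def _reshaped(model: ModelSpec, input_shape) -> ModelSpec:
    if input_shape is None or tuple(input_shape) == model.input_shape:
        return model
    return ModelSpec(model.name, model.nodes, tuple(input_shape))
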