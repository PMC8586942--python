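"""HDF5 weight archives: one group per conv node (kernel + bias)."""

from __future__ import annotations

import h5py
import numpy as np

from .graph import ModelSpec


def save_weights(model: ModelSpec, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = model.name
        f.attrs["input_shape"] = model.input_shape
        for nid, (kernel, bias) in model.parameters().items():
            g = f.create_group(nid)
            g.create_dataset("kernel", data=kernel)
            g.create_dataset("bias", data=bias)


def load_weights(model: ModelSpec, path) -> ModelSpec:
    """Load an archive into *model* (in place); shapes are checked."""
    with h5py.File(path, "r") as f:
        for node in model.conv_nodes():
            if node.id not in f:
                raise KeyError(f"archive lacks weights for node {node.id!r}")
            kernel = np.asarray(f[node.id]["kernel"], dtype=np.float32)
            bias = np.asarray(f[node.id]["bias"], dtype=np.float32)
            spec = node.conv
            expect = (spec.kernel_size, spec.kernel_size,
                      spec.in_channels, spec.out_channels)
            if kernel.shape != expect:
                raise ValueError(
                    f"{node.id}: kernel shape {kernel.shape} != {expect}")
            spec.kernel, spec.bias = kernel, bias
    return model


def count_scalars(path) -> int:
    """Total number of stored weight/bias scalars in an archive."""
    total = 0

    def visit(_, obj):
        nonlocal total
        if isinstance(obj, h5py.Dataset):
            total += obj.size

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    return total
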