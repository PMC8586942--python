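"""Shared fixtures: deterministic RNG and small toy models."""

import numpy as np
import pytest

import tinyseg as ts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_unet():
    """Half U-net shaped graph with tiny widths on a 32x32 grayscale input."""
    return ts.build_model(
        "half_unet", config={"encoder": [4, 8, 12], "decoder": [8, 4]},
        input_shape=(32, 32, 1))


@pytest.fixture
def toy_quarter():
    """Quarter MultiResUNet with tiny widths on a 16x16 grayscale input."""
    return ts.build_model(
        "quarter_multiresunet",
        config={"stem": 5, "blocks": [6, 6], "respath": [4], "decoder": [6]},
        input_shape=(16, 16, 1))


def brute_force_conv(x, kernel, bias):
    """Scalar-loop same-padded convolution: the independent oracle."""
    k = kernel.shape[0]
    pad = (k - 1) // 2
    n, h, w, cin = x.shape
    cout = kernel.shape[3]
    out = np.zeros((n, h, w, cout))
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                for u in range(k):
                    for v in range(k):
                        ii, jj = i + u - pad, j + v - pad
                        if 0 <= ii < h and 0 <= jj < w:
                            for ci in range(cin):
                                out[ni, i, j] += (x[ni, ii, jj, ci]
                                                  * kernel[u, v, ci])
    return out + bias


def brute_force_forward(model, image):
    """Evaluate a whole graph with scalar-loop primitives (oracle)."""
    x = np.asarray(image, dtype=np.float64)[None]
    acts = {}
    for node in model.nodes:
        ins = [acts[s] for s in node.inputs]
        if node.op == "input":
            val = x
        elif node.op == "conv":
            spec = node.conv
            val = brute_force_conv(ins[0], spec.kernel.astype(np.float64),
                                   spec.bias.astype(np.float64))
            if spec.activation == "relu":
                val = np.maximum(val, 0.0)
            elif spec.activation == "sigmoid":
                val = 1.0 / (1.0 + np.exp(-val))
        elif node.op == "maxpool2":
            a = ins[0]
            n, h, w, c = a.shape
            val = np.zeros((n, h // 2, w // 2, c))
            for i in range(h // 2):
                for j in range(w // 2):
                    val[:, i, j] = a[:, 2*i:2*i+2, 2*j:2*j+2].max(axis=(1, 2))
        elif node.op == "upsample2":
            a = ins[0]
            n, h, w, c = a.shape
            val = np.zeros((n, 2 * h, 2 * w, c))
            for i in range(2 * h):
                for j in range(2 * w):
                    val[:, i, j] = a[:, i // 2, j // 2]
        elif node.op == "concat":
            val = np.concatenate(ins, axis=-1)
        elif node.op == "add":
            val = ins[0] + ins[1]
        elif node.op == "relu":
            val = np.maximum(ins[0], 0.0)
        acts[node.id] = val
    return acts[model.output_id][0, ..., 0]
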