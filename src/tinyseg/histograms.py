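"""Kernel-weight histograms and stage-utilization analysis.

After training, the distribution of each convolution's kernel weights
indicates how much that layer participates in feature learning: layers
whose weights collapse into a narrow band around zero effectively pass
nothing, while utilized layers keep a wide spread.  Summarizing this
per encoder stage motivates architecture reduction — if the deep stages
of an encoder are inert, the same task can be served by the half (or
quarter) variant that simply omits them.

"Close to zero" is operationalized as the *zero-concentration*: the
fraction of a layer's kernel scalars with ``|w| <= epsilon``.  A stage
is called underutilized when the mean zero-concentration of its
feature-extraction convolutions exceeds a threshold.  Both knobs are
explicit (defaults ``epsilon=0.01``, ``threshold=0.9``) and reported
alongside the verdicts, turning a visual judgment into a reproducible
computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import ModelSpec

__all__ = ["WeightHistogram", "UtilizationReport", "layer_histograms",
           "zero_concentration", "utilization_report"]


@dataclass
class WeightHistogram:
    layer_id: str
    stage: int | None
    kind: str  # feature | skip | output
    edges: np.ndarray  # ascending bin edges
    counts: np.ndarray  # one entry per bin
    values: np.ndarray  # flattened kernel scalars (bias excluded)


@dataclass
class UtilizationReport:
    epsilon: float
    threshold: float
    stages: pd.DataFrame  # stage, zero_concentration, iqr, verdict
    suggestion: str  # architecture that keeps exactly the utilized stages


def layer_histograms(model: ModelSpec, bins: int = 101
                     ) -> list[WeightHistogram]:
    """One histogram per conv node over its kernel scalars (bias excluded).

    Bins are uniform over ``[-max|w|, +max|w|]`` per layer, so a
    symmetric layer histogram is centered on zero as in the stacked
    TensorBoard-style views.
    """
    out = []
    for node in model.conv_nodes():
        if node.conv.kernel is None:
            raise ValueError(f"{node.id}: weights missing")
        values = np.asarray(node.conv.kernel, dtype=np.float64).ravel()
        lim = float(np.abs(values).max())
        if lim == 0.0:
            lim = 1e-12
        edges = np.linspace(-lim, lim, bins + 1)
        counts, _ = np.histogram(values, bins=edges)
        out.append(WeightHistogram(
            layer_id=node.id, stage=node.stage, kind=node.kind or "feature",
            edges=edges, counts=counts, values=values))
    return out


def zero_concentration(h: WeightHistogram | np.ndarray,
                       epsilon: float) -> float:
    """Fraction of kernel scalars with ``|w| <= epsilon`` (exact weights)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = h.values if isinstance(h, WeightHistogram) else np.ravel(h)
    return float(np.count_nonzero(np.abs(values) <= epsilon) / values.size)


_REDUCTIONS: dict[str, list[tuple[str, int]]] = {
    # candidate (architecture, retained encoder stages 0..s-1), deepest first
    "unet": [("unet", 5), ("half_unet", 2)],
    "multires": [("multiresunet", 5), ("half_multiresunet", 2),
                 ("quarter_multiresunet", 1)],
}


def utilization_report(model: ModelSpec, epsilon: float = 0.01,
                       threshold: float = 0.9) -> UtilizationReport:
    """Per-encoder-stage utilization verdicts and a reduction suggestion.

    A stage is *underutilized* when the mean zero-concentration of its
    feature-extraction convolutions exceeds *threshold*.  The suggestion
    is the deepest architecture in the model's family whose retained
    encoder stages are all utilized (falling back to the smallest
    variant when even the first stages are inert).
    """
    hists = layer_histograms(model)
    depth = max((h.stage for h in hists if h.stage is not None), default=0) // 2
    rows = []
    for stage in range(depth + 1):  # encoder stages incl. bottleneck
        feats = [h for h in hists
                 if h.stage == stage and h.kind == "feature"]
        if not feats:
            continue
        zc = float(np.mean([zero_concentration(h, epsilon) for h in feats]))
        pooled = np.concatenate([h.values for h in feats])
        q75, q25 = np.percentile(pooled, [75, 25])
        rows.append({"stage": stage, "zero_concentration": zc,
                     "iqr": float(q75 - q25),
                     "verdict": "underutilized" if zc > threshold
                     else "utilized"})
    table = pd.DataFrame(rows)
    utilized = {int(r["stage"]) for _, r in table.iterrows()
                if r["verdict"] == "utilized"}
    family = "multires" if "multires" in model.name else "unet"
    candidates = [(arch, keep) for arch, keep in _REDUCTIONS[family]
                  if keep <= depth + 1]  # no deeper than the model itself
    suggestion = candidates[-1][0]
    for arch, keep in candidates:
        if all(s in utilized for s in range(keep)):
            suggestion = arch
            break
    return UtilizationReport(epsilon=epsilon, threshold=threshold,
                             stages=table, suggestion=suggestion)
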