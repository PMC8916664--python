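"""Attribution maps for the gait encoder and their perturbation analysis.

Two explanation methods are implemented against the trained encoder f:

* **Sensitivity analysis (SA)** — the element-wise absolute gradient
  |d f(s)_c / d s_ij| of one embedding component c, computed by
  back-propagation (through the final L2 normalization, whose gradient is
  well defined).
* **LRP-epsilon** — layer-wise relevance propagation: the component's
  pre-normalization output value is redistributed backwards through the
  weighted connections with the epsilon-stabilized rule
  R_i = sum_j x_i w_ij / (sum_i x_i w_ij + eps sign(.)) R_j.
  The L2 normalization stage carries no weights, so relevance starts at
  the dense-128 layer.

Because embedding components have no individual meaning, the per-component
maps A_c are averaged over all 128 components into A(s), and A(s) is
averaged over training steps into the *common attribution map*.  The
common map is evaluated by region perturbation: positions are ranked by
relevance magnitude, split into quintiles O1..O5, occluded (set to exactly
zero, distinguishable from live pressure >= delta) and the recognition
metrics re-measured against a random-occlusion baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import Encoder
from .gait_signal import UnitStep
from .layout import CHANNELS, N_CHANNELS


@dataclass
class LRPConfig:
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class AttributionMap:
    data: np.ndarray          # (T, 28)
    method: str               # "sa" | "lrp"
    component: int | None = None   # None for component-averaged maps


@dataclass
class CommonAttributionMap:
    data: np.ndarray          # (T, 28)
    method: str
    n_subjects: int
    n_steps: int


def _as_array(step) -> np.ndarray:
    return step.data if isinstance(step, UnitStep) else np.asarray(step, dtype=float)


def _check_component(c: int, dim: int) -> None:
    if not 0 <= c < dim:
        raise IndexError(f"component {c} outside [0, {dim})")


def sensitivity_map(encoder: Encoder, step, c: int) -> AttributionMap:
    """|gradient| of embedding component c w.r.t. every input entry."""
    data = _as_array(step)
    _check_component(c, encoder.config.embedding_dim)
    encoder.forward(data[None])
    seed = np.zeros((1, encoder.config.embedding_dim))
    seed[0, c] = 1.0
    grad = encoder.backward(seed)[0]
    return AttributionMap(np.abs(grad), "sa", c)


def lrp_map(encoder: Encoder, step, c: int,
            config: LRPConfig | None = None) -> AttributionMap:
    """LRP-epsilon relevance of embedding component c at the input layer.

    Relevance is initialized one-hot at component c with the component's
    output value, then redistributed with the epsilon rule; bias relevance
    is absorbed.
    """
    config = config or LRPConfig()
    data = _as_array(step)
    _check_component(c, encoder.config.embedding_dim)
    v = encoder.forward(data[None])
    R = np.zeros((1, encoder.config.embedding_dim))
    R[0, c] = v[0, c]
    return AttributionMap(encoder.lrp(R, config.epsilon)[0], "lrp", c)


def _all_component_maps(encoder: Encoder, data: np.ndarray, method: str,
                        config: LRPConfig) -> np.ndarray:
    """(128, T, 28) stack of per-component maps, one replicated batch pass."""
    dim = encoder.config.embedding_dim
    batch = np.repeat(data[None], dim, axis=0)
    v = encoder.forward(batch)
    if method == "sa":
        return np.abs(encoder.backward(np.eye(dim)))
    if method == "lrp":
        # row r of the replicated batch explains component r: one-hot init
        # carrying that component's output value
        return encoder.lrp(np.eye(dim) * v[0], config.epsilon)
    raise ValueError(f"unknown attribution method: {method!r}")


def average_components(maps: list[AttributionMap] | np.ndarray) -> AttributionMap:
    """A(s): element-wise mean of the 128 per-component maps."""
    if isinstance(maps, np.ndarray):
        stack = maps
        method = "sa"
    else:
        stack = np.stack([m.data for m in maps])
        method = maps[0].method
    if stack.shape[0] != 128:
        raise ValueError(f"expected 128 component maps, got {stack.shape[0]}")
    return AttributionMap(stack.mean(axis=0), method, None)


def attribution_map(encoder: Encoder, step, method: str = "lrp",
                    config: LRPConfig | None = None) -> AttributionMap:
    """Component-averaged map A(s) for one unit step."""
    config = config or LRPConfig()
    data = _as_array(step)
    stack = _all_component_maps(encoder, data, method, config)
    return AttributionMap(stack.mean(axis=0), method, None)


def common_map(encoder: Encoder, steps, method: str = "lrp",
               config: LRPConfig | None = None) -> CommonAttributionMap:
    """Grand mean of A(s) over training steps, each step weighted equally.

    ``steps`` is either a {subject: (n, T, 28)} mapping or an (N, T, 28)
    array (treated as one subject's steps).
    """
    config = config or LRPConfig()
    if isinstance(steps, dict):
        groups = {a: np.asarray(v, dtype=float) for a, v in steps.items()}
    else:
        arr = np.asarray(steps, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        groups = {0: arr}
    n_total = sum(g.shape[0] for g in groups.values())
    if n_total == 0:
        raise ValueError("cannot average attributions over an empty training set")
    acc = None
    for g in groups.values():
        for row in g:
            m = attribution_map(encoder, row, method, config).data
            acc = m if acc is None else acc + m
    return CommonAttributionMap(acc / n_total, method, len(groups), n_total)


# ---------------------------------------------------------------------------
# Region perturbation
# ---------------------------------------------------------------------------

@dataclass
class OcclusionPlan:
    """All T*28 positions ordered by relevance magnitude, split in quintiles."""

    order: np.ndarray              # (L,) flat indices, most relevant first
    shape: tuple[int, int]

    @property
    def L(self) -> int:
        return len(self.order)

    def quintile(self, k: int) -> np.ndarray:
        """Flat indices of sub-sequence O_k, k = 1..5 (O5 takes any remainder)."""
        if not 1 <= k <= 5:
            raise IndexError("quintile index must be in 1..5")
        base = self.L // 5
        start = (k - 1) * base
        stop = k * base if k < 5 else self.L
        return self.order[start:stop]

    def positions(self, k: int) -> np.ndarray:
        """(m, 2) row/column pairs of O_k."""
        return np.stack(np.unravel_index(self.quintile(k), self.shape), axis=1)


def make_occlusion_plan(cmap: CommonAttributionMap | np.ndarray) -> OcclusionPlan:
    """Rank positions by |relevance| descending; ties break row-major."""
    data = cmap.data if isinstance(cmap, CommonAttributionMap) else np.asarray(cmap)
    flat = np.abs(data).ravel()
    order = np.argsort(-flat, kind="stable")
    return OcclusionPlan(order, data.shape)


def occlude(step, positions) -> np.ndarray:
    """Copy of the step with the listed (row, col) entries set to exactly 0."""
    data = _as_array(step).copy()
    positions = np.asarray(positions)
    if positions.size == 0:
        return data
    if positions.ndim == 1:   # flat indices
        rows, cols = np.unravel_index(positions, data.shape)
    else:
        rows, cols = positions[:, 0], positions[:, 1]
    if rows.max() >= data.shape[0] or cols.max() >= data.shape[1] or \
       rows.min() < 0 or cols.min() < 0:
        raise IndexError("occlusion position out of bounds")
    data[rows, cols] = 0.0
    return data


def occlude_batch(steps: np.ndarray, flat_positions: np.ndarray) -> np.ndarray:
    """Occlude the same flat positions in every step of an (N, T, 28) stack."""
    out = steps.copy()
    flat = out.reshape(out.shape[0], -1)
    flat[:, flat_positions] = 0.0
    return out


def random_occlusion_batch(steps: np.ndarray, m: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Occlude m uniformly random positions, drawn fresh for every step."""
    out = steps.copy()
    flat = out.reshape(out.shape[0], -1)
    L = flat.shape[1]
    for i in range(flat.shape[0]):
        flat[i, rng.choice(L, size=m, replace=False)] = 0.0
    return out


def perturbation_curve(plan: OcclusionPlan, known_test: dict[int, np.ndarray],
                       unknown_test: dict[int, np.ndarray], pipeline,
                       rng: np.random.Generator) -> dict[str, "object"]:
    """Re-evaluate the fixed pipeline under occlusion of O1..O5 + random.

    ``pipeline`` must expose ``embed(steps) -> (N, d)`` and
    ``evaluate(known_emb, unknown_emb) -> MetricsReport`` with its encoder,
    centroids and one-class models held fixed; only test steps are
    occluded.  The random baseline occludes |O1| positions per step, drawn
    fresh per step from ``rng``.
    """
    results = {}
    unknown = np.concatenate([v for v in unknown_test.values()], axis=0) \
        if unknown_test else np.empty((0,) + plan.shape)

    def run(occl):
        known_emb = {a: pipeline.embed(occl(v)) for a, v in known_test.items()}
        unknown_emb = pipeline.embed(occl(unknown)) if len(unknown) else unknown
        return pipeline.evaluate(known_emb, unknown_emb)

    for k in range(1, 6):
        idx = plan.quintile(k)
        results[f"O{k}"] = run(lambda v, idx=idx: occlude_batch(v, idx))
    m = len(plan.quintile(1))
    results["random"] = run(lambda v: random_occlusion_batch(v, m, rng))
    return results


# ---------------------------------------------------------------------------
# Serialization / rendering
# ---------------------------------------------------------------------------

def save_map_csv(amap, path: str | Path) -> None:
    import pandas as pd

    data = amap.data if hasattr(amap, "data") else np.asarray(amap)
    pd.DataFrame(data, columns=list(CHANNELS)).to_csv(path, index=False)


def save_heatmap(amap, path: str | Path, title: str = "") -> None:
    """Render a T x 28 map as a heat map (x = channels, y = time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = amap.data if hasattr(amap, "data") else np.asarray(amap)
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(N_CHANNELS))
    ax.set_xticklabels(CHANNELS, rotation=90, fontsize=6)
    ax.set_xlabel("sensor channel")
    ax.set_ylabel("time stamp")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
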