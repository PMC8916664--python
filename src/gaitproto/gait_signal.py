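"""Unit-step extraction and prototypes for multimodal insole recordings.

A *unit step* is one full walking cycle (stance phase followed by swing
phase) of all 28 sensor channels, linearly resampled to a fixed number of
rows T.  Segmentation exploits the fact that plantar pressure is zero while
the foot is in the air: the summed (Gaussian-smoothed) pressure crossing a
small threshold marks stance onsets, and each cycle runs from one onset to
the next.

A subject's *prototype* is the element-wise mean of their unit steps,
channel by channel — the canonical gait shape the reconstruction loss of
the encoder-decoder pulls towards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .layout import CHANNELS, N_CHANNELS, PRE


@dataclass
class RawRecording:
    """Continuous multichannel recording for a single subject.

    ``data`` has shape (n_samples, 28); one row per 0.01 s sample.
    """

    data: np.ndarray
    subject: int = 0
    sample_period: float = 0.01

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"recording must have shape (n_samples, {N_CHANNELS}), "
                f"got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")


@dataclass
class UnitStep:
    """One walking cycle: a T x 28 matrix (rows = time, columns = channels)."""

    data: np.ndarray
    subject: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"unit step must have shape (T, {N_CHANNELS}), got {self.data.shape}"
            )

    @property
    def T(self) -> int:
        return self.data.shape[0]


@dataclass
class Prototype:
    """Per-subject mean unit step; ``q`` is the number of steps averaged."""

    data: np.ndarray
    subject: int
    q: int


def smooth_pressure(recording: RawRecording, sigma: float) -> RawRecording:
    """Gaussian-smooth the pressure channels along time.

    Removes sporadic non-zero pressure readings during the swing phase that
    would otherwise split one cycle in two.  Acceleration and rotation
    channels pass through unchanged.

    Parameters
    ----------
    sigma
        Kernel standard deviation in samples; the kernel is truncated at
        +/- 4 sigma and the signal reflected at the boundaries.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    out = recording.data.copy()
    out[:, PRE] = gaussian_filter1d(
        recording.data[:, PRE], sigma=sigma, axis=0, mode="reflect", truncate=4.0
    )
    return RawRecording(out, recording.subject, recording.sample_period)


def _resample_rows(segment: np.ndarray, T: int) -> np.ndarray:
    """Linearly resample a (L, C) segment to exactly T rows."""
    L = segment.shape[0]
    if L == T:
        return segment.copy()
    pos = np.linspace(0.0, L - 1.0, T)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, L - 1)
    frac = (pos - i0)[:, None]
    return segment[i0] * (1.0 - frac) + segment[i1] * frac


def segment_unit_steps(
    recording: RawRecording, T: int, swing_threshold: float = 0.5
) -> list[UnitStep]:
    """Split a (smoothed) recording into unit steps of fixed length T.

    Stance onsets are rising edges of ``sum(pressure) > swing_threshold``;
    each unit step spans one onset to the next (stance + following swing)
    and is linearly resampled to T rows.  Incomplete leading and trailing
    cycles are discarded; a recording with no complete cycle yields an
    empty list.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if swing_threshold < 0:
        raise ValueError("swing_threshold must be non-negative")
    total = recording.data[:, PRE].sum(axis=1)
    stance = total > swing_threshold
    # Rising edges only; stance already in progress at sample 0 has an
    # unknown onset, so it does not start a cycle.
    rising = np.flatnonzero(stance[1:] & ~stance[:-1]) + 1
    if stance.size and stance[0]:
        pass  # leading partial cycle implicitly discarded
    steps: list[UnitStep] = []
    for i in range(len(rising) - 1):
        seg = recording.data[rising[i] : rising[i + 1]]
        if seg.shape[0] < 2:
            continue
        steps.append(UnitStep(_resample_rows(seg, T), recording.subject, i))
    return steps


def apply_pressure_floor(step: UnitStep, delta: float) -> UnitStep:
    """Replace exactly-zero pressure entries by ``delta``.

    Keeps live pressure distinguishable from occluded (zeroed) entries in
    the perturbation analysis.  Non-pressure channels are untouched.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    data = step.data.copy()
    pre = data[:, PRE]
    pre[pre == 0.0] = delta
    return UnitStep(data, step.subject, step.index)


def compute_prototype(steps: list[UnitStep]) -> Prototype:
    """Element-wise mean of a subject's unit steps (channel by channel)."""
    if not steps:
        raise ValueError("cannot compute a prototype from an empty step list")
    subject = steps[0].subject
    shape = steps[0].data.shape
    for s in steps:
        if s.subject != subject:
            raise ValueError("all steps must belong to the same subject")
        if s.data.shape != shape:
            raise ValueError("all steps must share the same T x 28 shape")
    stack = np.stack([s.data for s in steps])
    return Prototype(stack.mean(axis=0), subject, len(steps))


def l2_normalize_modality(x: np.ndarray) -> np.ndarray:
    """Scale a matrix (or vector) to unit L2 norm of its flattened entries."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0.0:
        raise ZeroDivisionError(
            "cannot L2-normalize an all-zero signal (norm is zero)"
        )
    return x / norm


# ---------------------------------------------------------------------------
# Dataset container and on-disk bundle format
# ---------------------------------------------------------------------------

@dataclass
class StepDataset:
    """Unit steps grouped by subject: ``steps[a]`` is an (n_a, T, 28) array."""

    steps: dict[int, np.ndarray] = field(default_factory=dict)
    delta: float = 0.01
    sigma: float | None = None

    @property
    def subjects(self) -> list[int]:
        return sorted(self.steps)

    @property
    def T(self) -> int:
        first = next(iter(self.steps.values()))
        return first.shape[1]

    @property
    def n_steps(self) -> int:
        return sum(arr.shape[0] for arr in self.steps.values())

    def unit_steps(self, subject: int) -> list[UnitStep]:
        return [
            UnitStep(row, subject, i)
            for i, row in enumerate(self.steps[subject])
        ]

    def save(self, path: str | Path) -> None:
        """Write one directory per subject with ``step_<i>.csv`` files."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for a in self.subjects:
            sub = path / f"subject_{a}"
            sub.mkdir(exist_ok=True)
            for i, step in enumerate(self.steps[a]):
                write_step_csv(sub / f"step_{i}.csv", step)
        manifest = {
            "subjects": self.subjects,
            "T": int(self.T),
            "delta": self.delta,
            "sigma": self.sigma,
            "n_steps": {str(a): int(self.steps[a].shape[0]) for a in self.subjects},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StepDataset":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        steps: dict[int, np.ndarray] = {}
        for a in manifest["subjects"]:
            n = manifest["n_steps"][str(a)]
            arrs = [
                read_step_csv(path / f"subject_{a}" / f"step_{i}.csv")
                for i in range(n)
            ]
            steps[int(a)] = np.stack(arrs)
        return cls(steps, delta=manifest["delta"], sigma=manifest["sigma"])


def write_step_csv(path: str | Path, data: np.ndarray) -> None:
    pd.DataFrame(np.asarray(data), columns=list(CHANNELS)).to_csv(path, index=False)


def read_step_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != list(CHANNELS):
        raise ValueError(f"{path}: unexpected channel header")
    return df.to_numpy(dtype=float)
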