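"""Synthetic multimodal gait data with per-subject signatures.

Each synthetic subject owns a smooth template of all 28 channels over one
walking cycle: pressure channels are non-negative, exactly zero during the
swing window (foot in the air), and built from clipped sums of 2-4
random-phase sinusoids; acceleration and rotation channels are random
low-order harmonic series scaled to unit amplitude.  Individual unit steps
are noisy, time-warped draws around the template, which gives the dataset
the two properties the recognition pipeline relies on: within-subject
steps cluster around their prototype, and templates differ across
subjects.

The generator matches the statistical structure the method consumes; it
does not model ground-reaction-force biomechanics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gait_signal import RawRecording, StepDataset, UnitStep
from .layout import ACC, N_CHANNELS, PRE, ROT


@dataclass
class SubjectTemplate:
    """Per-subject canonical cycle: (T, 28) template plus its swing window."""

    subject: int
    data: np.ndarray          # (T, 28); pressure zero on the swing window
    swing_fraction: float

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def swing_slice(self) -> slice:
        T = self.T
        swing_len = int(round(self.swing_fraction * T))
        return slice(T - swing_len, T)


@dataclass
class GenerationConfig:
    """Study-scale defaults: 40 subjects x 158 steps of length T=100."""

    n_subjects: int = 40
    steps_per_subject: int = 158
    T: int = 100
    noise_sd: float = 0.1
    jitter: float = 0.05
    seed: int = 0
    delta: float = 0.01
    swing_fraction: float = 0.35
    quantize_pressure: bool = False

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.steps_per_subject, self.T) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.jitter <= 0.2:
            raise ValueError("jitter fraction must be in [0, 0.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.swing_fraction < 1.0:
            raise ValueError("swing_fraction must be in (0, 1)")


def _harmonic_series(rng: np.random.Generator, t: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Sum of random-amplitude, random-phase sinusoids over phase t in [0, 1)."""
    out = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        amp = rng.uniform(0.3, 1.0) / k
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += amp * np.sin(2.0 * np.pi * k * t + phase)
    return out


def make_subject_template(
    seed: int, T: int = 100, swing_fraction: float = 0.35, subject: int = 0
) -> SubjectTemplate:
    """Draw a deterministic subject template from ``seed``.

    Pressure: clipped sums of 2-4 random-phase sinusoids over the stance
    window, scaled to unit peak, exactly zero during swing.  Acceleration
    and rotation: 4-harmonic series scaled to unit amplitude.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    rng = np.random.default_rng(seed)
    data = np.zeros((T, N_CHANNELS))
    swing_len = int(round(swing_fraction * T))
    stance_len = T - swing_len
    u = np.arange(stance_len) / max(stance_len - 1, 1)   # stance phase in [0, 1]
    for c in range(PRE.start, PRE.stop):
        while True:
            n_h = int(rng.integers(2, 5))
            curve = np.clip(_harmonic_series(rng, u, n_h), 0.0, None)
            if curve.max() > 1e-3:
                break
        data[:stance_len, c] = curve / curve.max()
    t = np.arange(T) / T
    for c in range(ACC.start, ROT.stop):
        curve = _harmonic_series(rng, t, 4)
        data[:, c] = curve / np.abs(curve).max()
    return SubjectTemplate(subject, data, swing_fraction)


def _warp_positions(T: int, amount: float) -> np.ndarray:
    """Smooth monotone warp of row positions, fixed at both ends.

    ``amount`` is the peak displacement in rows; monotonicity holds for
    |amount| < T/pi, satisfied for all jitter fractions <= 0.2.
    """
    t = np.arange(T, dtype=float)
    return t + amount * np.sin(np.pi * t / (T - 1))


def _sample_at(template: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of all channels at fractional row positions."""
    pos = np.clip(pos, 0.0, template.shape[0] - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, template.shape[0] - 1)
    frac = (pos - i0)[:, None]
    return template[i0] * (1.0 - frac) + template[i1] * frac


def generate_unit_step(
    template: SubjectTemplate,
    noise_sd: float,
    jitter: float,
    rng: np.random.Generator,
    delta: float | None = 0.01,
    index: int = 0,
    quantize_pressure: bool = False,
) -> UnitStep:
    """One noisy, time-warped draw around a subject template.

    The template is warped by up to +/- jitter*T rows, Gaussian noise of
    sd ``noise_sd`` is added to every channel, pressure is clipped to >= 0
    and re-zeroed on the swing window, and the pressure floor ``delta`` is
    applied (so swing pressure entries are exactly ``delta``).  Pass
    ``delta=None`` to keep raw zeros (pre-preprocessing data).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    T = template.T
    amount = rng.uniform(-jitter, jitter) * T if jitter > 0 else 0.0
    data = _sample_at(template.data, _warp_positions(T, amount))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    pre = data[:, PRE]
    np.clip(pre, 0.0, None, out=pre)
    if quantize_pressure:
        pre[:] = np.round(np.clip(pre, 0.0, 2.0))
    pre[template.swing_slice, :] = 0.0
    if delta is not None:
        pre[pre == 0.0] = delta
    return UnitStep(data, template.subject, index)


def generate_dataset(config: GenerationConfig) -> StepDataset:
    """Full synthetic study: one template per subject, i.i.d. unit steps."""
    root = np.random.SeedSequence(config.seed)
    template_seeds, step_seeds = root.spawn(2)
    t_children = template_seeds.spawn(config.n_subjects)
    s_children = step_seeds.spawn(config.n_subjects)
    steps: dict[int, np.ndarray] = {}
    for a in range(config.n_subjects):
        template = make_subject_template(
            t_children[a], config.T, config.swing_fraction, subject=a
        )
        rng = np.random.default_rng(s_children[a])
        arr = np.empty((config.steps_per_subject, config.T, N_CHANNELS))
        for i in range(config.steps_per_subject):
            arr[i] = generate_unit_step(
                template,
                config.noise_sd,
                config.jitter,
                rng,
                delta=config.delta,
                index=i,
                quantize_pressure=config.quantize_pressure,
            ).data
        steps[a] = arr
    return StepDataset(steps, delta=config.delta)


def subject_templates(config: GenerationConfig) -> list[SubjectTemplate]:
    """The templates ``generate_dataset`` draws steps from, in subject order."""
    root = np.random.SeedSequence(config.seed)
    template_seeds, _ = root.spawn(2)
    return [
        make_subject_template(child, config.T, config.swing_fraction, subject=a)
        for a, child in enumerate(template_seeds.spawn(config.n_subjects))
    ]


def generate_recording(
    template: SubjectTemplate,
    n_cycles: int,
    noise_sd: float = 0.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    lead_swing: int = 20,
) -> RawRecording:
    """Concatenate noisy cycles into a continuous recording.

    Useful for exercising segmentation end-to-end: the recording starts
    with ``lead_swing`` zero-pressure samples so the first stance onset is
    a clean rising edge.  Pressure is left un-floored (raw zeros), as a
    real recording would be before preprocessing.
    """
    rng = rng or np.random.default_rng(0)
    chunks = [np.zeros((lead_swing, N_CHANNELS))]
    for i in range(n_cycles):
        step = generate_unit_step(template, noise_sd, jitter, rng, delta=None, index=i)
        chunks.append(step.data)
    return RawRecording(np.vstack(chunks), template.subject)


def save_dataset(config: GenerationConfig, path: str | Path) -> StepDataset:
    ds = generate_dataset(config)
    ds.save(path)
    return ds
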