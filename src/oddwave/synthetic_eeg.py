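"""Synthetic epoched EEG with hierarchical MMN signal structure.

The generative model mirrors the variance structure assumed by the
simulation-based power analysis for this kind of nested design:

* each simulated participant draws one deviant-minus-standard effect per
  contrast, ``c ~ Normal(mu_subj, sigma_subj)`` (defaults -0.84 and 2.28 uV,
  the reference MMN at Cz over 200-400 ms);
* every epoch is white Gaussian single-trial noise with SD ``sigma_trial``
  at each channel and sample (no printed reference value exists for this
  component, so it must be supplied explicitly);
* deviant epochs additionally receive ``c`` times a spatiotemporal effect
  kernel (unit peak at Cz, raised-cosine time course over 200-400 ms by
  default);
* with probability ``artifact_rate`` an epoch gains a +-``artifact_amplitude``
  square pulse on one random scalp channel inside the -150..600 ms artifact
  screening window.

Epochs span the half-open window [-150, 750) ms at 1000 Hz (900 samples;
stimulus onset at sample 150).  Ground truth (drawn effect, artifact flag)
is carried in the per-trial metadata so downstream stages can be validated
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import ChannelLayout
from .sequence_design import SessionPlan, CONDITION_CONTRAST

__all__ = [
    "EffectKernel",
    "SimulationParams",
    "EpochArray",
    "simulate_participant_epochs",
    "draw_participant_effects",
]

SFREQ_HZ = 1000.0
EPOCH_WINDOW_MS = (-150, 750)          # half-open: samples at -150 .. 749 ms
N_SAMPLES = int(EPOCH_WINDOW_MS[1] - EPOCH_WINDOW_MS[0])


def default_times() -> np.ndarray:
    """Sample grid in ms: sample s lies at (-150 + s) ms."""
    return np.arange(EPOCH_WINDOW_MS[0], EPOCH_WINDOW_MS[1], dtype=float)


# ---------------------------------------------------------------------------
# Effect kernel
# ---------------------------------------------------------------------------


@dataclass
class EffectKernel:
    """Separable spatiotemporal effect pattern: topography x time course.

    ``topography`` has one weight per layout channel in [0, 1] with weight 1
    at exactly one (peak) channel; ``time_course`` is a unit-peak window
    function over the epoch grid.  The induced single-trial deflection is
    ``amplitude_scale * effect_uv * outer(topography, time_course)``.
    """

    peak_channel: str
    topography: np.ndarray           # (n_channels,)
    time_course: np.ndarray          # (n_samples,)
    window_ms: tuple[float, float]
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        self.time_course = np.asarray(self.time_course, dtype=float)
        if not np.isclose(self.time_course.max(), 1.0):
            raise ValueError("time_course must have unit peak")
        if (self.topography < 0).any() or (self.topography > 1).any():
            raise ValueError("topography weights must lie in [0, 1]")
        if np.sum(np.isclose(self.topography, 1.0)) != 1:
            raise ValueError("topography must peak (=1) at exactly one channel")

    @classmethod
    def default(
        cls,
        layout: ChannelLayout,
        peak_channel: str | None = None,
        window_ms: tuple[float, float] = (200.0, 400.0),
        spatial_fwhm: float | None = None,
        times: np.ndarray | None = None,
        amplitude_scale: float = 1.0,
    ) -> "EffectKernel":
        """Raised-cosine time course over ``window_ms``; Gaussian spatial
        falloff from the peak channel (mastoids weighted 0)."""
        times = default_times() if times is None else np.asarray(times, dtype=float)
        if peak_channel is None:
            peak_channel = "Cz" if "Cz" in layout.channel_names else layout.scalp_channels[0]
        lo, hi = window_ms
        tc = np.zeros_like(times)
        inside = (times >= lo) & (times <= hi)
        tc[inside] = 0.5 * (1 - np.cos(2 * np.pi * (times[inside] - lo) / (hi - lo)))
        tc /= tc.max()

        pk = layout.positions[layout.index(peak_channel)]
        d = np.linalg.norm(layout.positions - pk, axis=1)
        scalp = set(layout.scalp_channels)
        if spatial_fwhm is None:
            nz = d[[i for i, c in enumerate(layout.channel_names) if c in scalp]]
            spread = np.median(nz[nz > 0]) if (nz > 0).any() else 1.0
            spatial_fwhm = float(spread)
        sigma = spatial_fwhm / 2.3548
        topo = np.exp(-0.5 * (d / sigma) ** 2)
        for i, c in enumerate(layout.channel_names):
            if c not in scalp:
                topo[i] = 0.0
        topo[layout.index(peak_channel)] = 1.0
        return cls(peak_channel, topo, tc, (float(lo), float(hi)), amplitude_scale)

    def pattern(self) -> np.ndarray:
        """(n_channels, n_samples) unit-effect deflection."""
        return self.amplitude_scale * np.outer(self.topography, self.time_course)

    def window_mask(self, times: np.ndarray) -> np.ndarray:
        lo, hi = self.window_ms
        return (times >= lo) & (times <= hi)


# ---------------------------------------------------------------------------
# Simulation parameters
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Variance components and epoch geometry of the generative model.

    ``sigma_trial`` (uV, single-trial white-noise SD per channel/sample) has
    no published reference value and therefore no default -- it must be set
    explicitly (10 uV is a workable magnitude for pipeline studies that pass
    through the 75 uV amplitude screen; see docs/methods.md).
    """

    sigma_trial: float
    mu_subj: float = -0.84
    sigma_subj: float = 2.28
    artifact_rate: float = 0.0
    artifact_amplitude: float = 120.0
    sampling_rate: float = SFREQ_HZ
    epoch_window_ms: tuple[int, int] = EPOCH_WINDOW_MS

    def __post_init__(self) -> None:
        if self.sigma_trial < 0 or self.sigma_subj < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Epoch container
# ---------------------------------------------------------------------------


@dataclass
class EpochArray:
    """Epoched multichannel trials: (n_trials, n_channels, n_samples) uV."""

    data: np.ndarray
    times: np.ndarray                 # ms, one per sample
    metadata: pd.DataFrame            # one row per trial
    layout: ChannelLayout
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n, ch, s = self.data.shape
        if ch != self.layout.n_channels:
            raise ValueError("channel dimension does not match layout")
        if s != len(self.times):
            raise ValueError("sample dimension does not match time grid")
        if len(self.metadata) != n:
            raise ValueError("metadata rows must equal trial count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data=None, metadata=None, step: dict | None = None) -> "EpochArray":
        """Functional update: never mutates the source object."""
        return EpochArray(
            data=self.data.copy() if data is None else data,
            times=self.times,
            metadata=(self.metadata if metadata is None else metadata).copy(),
            layout=self.layout,
            history=self.history + ([step] if step else []),
        )

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.times >= lo_ms) & (self.times <= hi_ms)

    def select(self, mask) -> "EpochArray":
        mask = np.asarray(mask)
        return EpochArray(
            data=self.data[mask],
            times=self.times,
            metadata=self.metadata.iloc[mask].reset_index(drop=True),
            layout=self.layout,
            history=list(self.history),
        )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def draw_participant_effects(
    contrasts: list[str], params: SimulationParams, rng: np.random.Generator
) -> dict[str, float]:
    """One Normal(mu_subj, sigma_subj) effect per contrast (drawn in sorted
    contrast order so the draw is independent of block ordering)."""
    return {
        c: float(rng.normal(params.mu_subj, params.sigma_subj))
        for c in sorted(contrasts)
    }


def simulate_participant_epochs(
    plan: SessionPlan,
    params: SimulationParams,
    kernel: EffectKernel,
    layout: ChannelLayout,
    rng: np.random.Generator,
) -> EpochArray:
    """Simulate one epoch per planned trial.

    Deviant epochs receive the participant's per-contrast drawn effect times
    the kernel pattern on top of the trial noise; artifact pulses are
    injected at ``artifact_rate``.  Metadata carries the ground truth.
    """
    if not plan.blocks:
        raise ValueError("plan contains no blocks")
    times = default_times()
    n_samples = len(times)
    n_ch = layout.n_channels
    contrasts = sorted({CONDITION_CONTRAST[b.block_type] for b in plan.blocks})
    effects = draw_participant_effects(contrasts, params, rng)
    pattern = kernel.pattern()
    if pattern.shape != (n_ch, n_samples):
        raise ValueError("kernel pattern does not match layout/time grid")

    n_trials = plan.n_trials
    data = np.empty((n_trials, n_ch, n_samples))
    rows = []
    scalp_idx = layout.scalp_indices()
    art_lo, art_hi = -150.0, 600.0
    art_len_ms = 100.0
    art_mask_start = times.searchsorted(art_lo)
    i = 0
    for bi, block in enumerate(plan.blocks):
        contrast = CONDITION_CONTRAST[block.block_type]
        c_eff = effects[contrast]
        for t in block.trials:
            epoch = rng.normal(0.0, params.sigma_trial, size=(n_ch, n_samples)) \
                if params.sigma_trial > 0 else np.zeros((n_ch, n_samples))
            true_eff = 0.0
            if t.role == "deviant":
                true_eff = c_eff
                epoch += c_eff * pattern
            artifact = bool(params.artifact_rate > 0 and rng.random() < params.artifact_rate)
            if artifact:
                ch = int(scalp_idx[rng.integers(len(scalp_idx))])
                start_ms = float(rng.uniform(art_lo, art_hi - art_len_ms))
                s0 = int(times.searchsorted(start_ms))
                s1 = int(times.searchsorted(start_ms + art_len_ms))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                epoch[ch, max(s0, art_mask_start):s1] += sign * params.artifact_amplitude
            data[i] = epoch
            rows.append(
                (plan.participant_id, bi, block.block_type, contrast, t.index_in_block,
                 t.role, t.segment, t.token, t.analyzable, true_eff, artifact)
            )
            i += 1

    metadata = pd.DataFrame(
        rows,
        columns=["participant", "block", "block_type", "contrast", "trial",
                 "role", "segment", "token", "analyzable", "true_effect", "artifact"],
    )
    return EpochArray(
        data=data,
        times=times,
        metadata=metadata,
        layout=layout,
        history=[{
            "step": "simulate",
            "mu_subj": params.mu_subj, "sigma_subj": params.sigma_subj,
            "sigma_trial": params.sigma_trial, "artifact_rate": params.artifact_rate,
            "effects": effects,
        }],
    )
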