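"""Identity-MMN construction: trial exclusions, condition ERPs, difference waves.

The identity MMN (iMMN) contrasts the ERP of the *same physical tokens*
presented as deviants in one block type versus as standards in the sibling
block type of the same contrast, which removes acoustic confounds from the
difference wave.  Before averaging, the pre-registered exclusions are
applied: the opening habituation standards of each block, the first deviant
of each block, and the standard immediately following every deviant are not
analyzable; artifact trials are dropped by preprocessing.  With 40 deviants
per block and 3 blocks per condition this leaves (40 - 1) * 3 = 117
analyzable deviants per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_design import SessionPlan, SIBLING_CONDITION, CONDITION_CONTRAST, INVENTORIES
from .synthetic_eeg import EpochArray, EffectKernel

__all__ = [
    "ERPWaveform",
    "DifferenceWave",
    "mark_analyzable",
    "compute_condition_erps",
    "compute_immn",
    "participant_immn",
    "filter_participants",
    "kernel_aligned_amplitude",
]

MIN_TRIALS_PER_CONDITION = 30


@dataclass
class ERPWaveform:
    participant: str
    condition: str            # deviant condition labelling the block type
    role: str                 # "standard" | "deviant"
    tokens: tuple[str, ...]
    n_trials: int
    data: np.ndarray          # (n_channels, n_samples) uV
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an ERP must average at least one trial")


@dataclass
class DifferenceWave:
    participant: str
    contrast: str
    deviant_condition: str
    data: np.ndarray          # deviant ERP minus standard ERP, (ch, samples)
    times: np.ndarray
    n_deviant_trials: int
    n_standard_trials: int


def mark_analyzable(plan: SessionPlan) -> SessionPlan:
    """Set per-trial ``analyzable`` flags in place (and return the plan).

    Excluded: every habituation-segment trial, the first deviant of each
    block, and the standard immediately following every deviant.
    """
    for block in plan.blocks:
        first_deviant_seen = False
        prev_was_deviant = False
        for t in block.trials:
            ok = True
            if t.segment == "habituation":
                ok = False
            if t.role == "deviant" and not first_deviant_seen:
                first_deviant_seen = True
                ok = False
            if t.role == "standard" and prev_was_deviant:
                ok = False
            t.analyzable = ok
            prev_was_deviant = t.role == "deviant"
    return plan


def _qualifying(md: pd.DataFrame) -> pd.Series:
    mask = md["analyzable"].astype(bool)
    if "artifact" in md.columns:
        mask &= ~md["artifact"].astype(bool)
    return mask


def compute_condition_erps(
    epochs: EpochArray,
    condition: str,
    role: str,
    token_filter: tuple[str, ...] | list[str] | set[str],
) -> ERPWaveform:
    """Average analyzable, artifact-free epochs of one (block type, role)
    cell, restricted to ``token_filter``."""
    token_filter = tuple(sorted(set(token_filter)))
    if not token_filter:
        raise ValueError("token_filter must be nonempty")
    md = epochs.metadata
    mask = (
        _qualifying(md)
        & (md["block_type"] == condition)
        & (md["role"] == role)
        & md["token"].isin(token_filter)
    )
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no qualifying trials for condition={condition!r} role={role!r} "
            f"tokens={token_filter}"
        )
    return ERPWaveform(
        participant=str(md["participant"].iloc[0]),
        condition=condition,
        role=role,
        tokens=token_filter,
        n_trials=n,
        data=epochs.data[np.asarray(mask)].mean(axis=0),
        times=epochs.times,
    )


def compute_immn(dev: ERPWaveform, std: ERPWaveform) -> DifferenceWave:
    """Elementwise deviant-minus-standard difference of same-token ERPs."""
    if dev.participant != std.participant:
        raise ValueError("ERPs come from different participants")
    if dev.tokens != std.tokens:
        raise ValueError(f"token sets differ: {dev.tokens} vs {std.tokens}")
    if dev.data.shape != std.data.shape or not np.array_equal(dev.times, std.times):
        raise ValueError("ERP grids do not match")
    condition = dev.condition if dev.role == "deviant" else std.condition
    return DifferenceWave(
        participant=dev.participant,
        contrast=CONDITION_CONTRAST.get(condition, "unknown"),
        deviant_condition=condition,
        data=dev.data - std.data,
        times=dev.times,
        n_deviant_trials=dev.n_trials,
        n_standard_trials=std.n_trials,
    )


def participant_immn(epochs: EpochArray, deviant_condition: str) -> DifferenceWave:
    """iMMN for one deviant condition.

    The deviant ERP averages that condition's deviant tokens in its own
    blocks; the standard ERP averages the *same tokens* where they serve as
    standards, i.e. in the sibling block type of the same contrast.
    """
    tokens = INVENTORIES[deviant_condition].deviant_tokens
    sibling = SIBLING_CONDITION[deviant_condition]
    dev = compute_condition_erps(epochs, deviant_condition, "deviant", tokens)
    std = compute_condition_erps(epochs, sibling, "standard", tokens)
    return compute_immn(dev, std)


def filter_participants(
    trial_counts: pd.DataFrame, min_trials: int = MIN_TRIALS_PER_CONDITION
) -> list[str]:
    """Participants with at least ``min_trials`` in *every* condition.

    ``trial_counts`` has columns (participant, condition, n); a participant
    missing any condition present in the table is an error.
    """
    required = {"participant", "condition", "n"}
    if not required.issubset(trial_counts.columns):
        raise ValueError(f"trial_counts needs columns {sorted(required)}")
    conditions = set(trial_counts["condition"])
    included = []
    for p, grp in trial_counts.groupby("participant", sort=True):
        missing = conditions - set(grp["condition"])
        if missing:
            raise ValueError(f"participant {p!r} missing conditions {sorted(missing)}")
        if int(grp["n"].min()) >= min_trials:
            included.append(p)
    return included


def kernel_aligned_amplitude(wave: DifferenceWave, kernel: EffectKernel) -> float:
    """Effect amplitude implied by a difference wave, in uV.

    Mean of the wave at the kernel's peak channel over the kernel's support,
    normalized by the kernel's own mean over that support -- so that on
    noiseless data the estimate equals the generating effect exactly, for
    any unit-peak time-course shape.
    """
    # the wave carries no layout; the kernel's topography indexes the same grid
    layout_idx = int(np.argmax(kernel.topography))
    support = kernel.time_course > 0
    if not support.any():
        raise ValueError("kernel has empty support")
    gain = float(kernel.amplitude_scale * kernel.time_course[support].mean())
    return float(wave.data[layout_idx, support].mean() / gain)
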