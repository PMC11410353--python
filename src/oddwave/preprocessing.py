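"""Epoch-level preprocessing: re-referencing, demeaning, baseline correction,
amplitude-based artifact rejection, zero-phase low-pass filtering, and bad
channel interpolation.

All operations are pure -- the input :class:`~oddwave.synthetic_eeg.EpochArray`
is never modified; each stage returns a new array with a provenance record
appended to ``history``.  The canonical stage order for the pipeline driver is

    rereference -> demean -> (ICA placeholder: skipped) -> baseline ->
    reject -> lowpass filter

and :func:`run_preproc` enforces it unless explicitly overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import convolve1d

from .layout import ChannelLayout
from .synthetic_eeg import EpochArray

__all__ = [
    "RejectionLog",
    "rereference",
    "demean_epochs",
    "baseline_correct",
    "reject_artifacts",
    "lowpass_filter",
    "interpolate_bad_channels",
    "design_lowpass",
    "run_preproc",
]

REJECT_THRESHOLD_UV = 75.0
REJECT_WINDOW_MS = (-150.0, 600.0)
BASELINE_WINDOW_MS = (-100.0, 0.0)
LOWPASS_CUTOFF_HZ = 30.0


@dataclass
class RejectionLog:
    """Per-trial artifact screening decisions."""

    table: pd.DataFrame  # columns: trial, kept, channel, time_ms, peak_uv
    threshold_uv: float
    window_ms: tuple[float, float]

    @property
    def n_removed(self) -> int:
        return int((~self.table["kept"]).sum())

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rereference(epochs: EpochArray, ref_channels: list[str] | None = None) -> EpochArray:
    """Subtract the samplewise mean of ``ref_channels`` (default: the layout's
    reference channels, i.e. linked mastoids) from every channel.

    Reference channels are retained in the array; applying the operation a
    second time is the identity, because the first pass zeroes their mean.
    """
    if ref_channels is None:
        ref_channels = epochs.layout.reference_channels
    missing = [c for c in ref_channels if c not in epochs.layout.channel_names]
    if missing:
        raise KeyError(f"reference channels not in layout: {missing}")
    if not ref_channels:
        raise ValueError("no reference channels given")
    idx = [epochs.layout.index(c) for c in ref_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(
        data=epochs.data - ref,
        step={"step": "rereference", "ref_channels": list(ref_channels)},
    )


def demean_epochs(epochs: EpochArray) -> EpochArray:
    """Subtract each channel's whole-epoch mean, per epoch."""
    return epochs.copy_with(
        data=epochs.data - epochs.data.mean(axis=2, keepdims=True),
        step={"step": "demean"},
    )


def baseline_correct(
    epochs: EpochArray, window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> EpochArray:
    """Subtract the mean over the pre-stimulus ``window_ms`` per channel/epoch."""
    lo, hi = window_ms
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(
        data=epochs.data - base,
        step={"step": "baseline", "window_ms": [lo, hi]},
    )


def reject_artifacts(
    epochs: EpochArray,
    threshold_uv: float = REJECT_THRESHOLD_UV,
    window_ms: tuple[float, float] = REJECT_WINDOW_MS,
) -> tuple[EpochArray, RejectionLog]:
    """Remove trials whose absolute amplitude exceeds ``threshold_uv`` on any
    scalp channel at any sample inside ``window_ms``.

    Reference (mastoid) channels are not screened.  Returns the kept epochs
    and a log with one row per input trial.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    lo, hi = window_ms
    tmask = (epochs.times >= lo) & (epochs.times <= hi)
    if not tmask.any() or lo < epochs.times[0] or hi > epochs.times[-1] + 1:
        raise ValueError(f"rejection window {window_ms} outside epoch")
    scalp = epochs.layout.scalp_indices()
    seg = np.abs(epochs.data[:, scalp[:, None], np.flatnonzero(tmask)[None, :]])
    peak_flat = seg.reshape(epochs.n_trials, -1).argmax(axis=1)
    peaks = seg.reshape(epochs.n_trials, -1)[np.arange(epochs.n_trials), peak_flat]
    ch_i, s_i = np.unravel_index(peak_flat, seg.shape[1:])
    removed = peaks > threshold_uv
    names = np.array(epochs.layout.channel_names)
    times_in = epochs.times[tmask]
    log = RejectionLog(
        table=pd.DataFrame({
            "trial": np.arange(epochs.n_trials),
            "kept": ~removed,
            "channel": names[scalp[ch_i]],
            "time_ms": times_in[s_i],
            "peak_uv": peaks,
        }),
        threshold_uv=threshold_uv,
        window_ms=(lo, hi),
    )
    kept = epochs.select(~removed)
    kept.history = epochs.history + [{
        "step": "reject",
        "threshold_uv": threshold_uv,
        "window_ms": [lo, hi],
        "n_removed": int(removed.sum()),
    }]
    return kept, log


def design_lowpass(cutoff_hz: float, sfreq: float) -> tuple[np.ndarray, dict]:
    """Hamming-windowed sinc FIR low-pass.

    Transition bandwidth is 25% of the cutoff; the -6 dB point sits at
    cutoff + half the transition band; filter order 3.3 / normalized
    transition width, rounded up to even (odd tap count => exactly
    symmetric, hence zero-phase when applied by centered convolution).
    """
    nyq = sfreq / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    trans = cutoff_hz * 0.25
    order = int(np.ceil(3.3 / (trans / sfreq)))
    order += order % 2
    taps = signal.firwin(order + 1, cutoff_hz + trans / 2.0, window="hamming", fs=sfreq)
    w, h = signal.freqz(taps, worN=4096, fs=sfreq)
    mag = np.abs(h)
    passband = mag[w <= cutoff_hz]
    stopband = mag[w >= cutoff_hz + trans]
    report = {
        "n_taps": len(taps),
        "transition_bw_hz": trans,
        "passband_ripple_db": float(20 * np.log10(passband.max() / max(passband.min(), 1e-12))),
        "stopband_attenuation_db": float(-20 * np.log10(max(stopband.max(), 1e-12))),
    }
    return taps, report


def lowpass_filter(epochs: EpochArray, cutoff_hz: float = LOWPASS_CUTOFF_HZ) -> EpochArray:
    """Zero-phase FIR low-pass per channel per epoch.

    The symmetric kernel is applied by centered convolution with reflect
    padding at the epoch edges, so the output has exactly zero phase delay.
    """
    sfreq = 1000.0 * 1.0 / float(np.median(np.diff(epochs.times)))
    taps, report = design_lowpass(cutoff_hz, sfreq)
    out = convolve1d(epochs.data, taps, axis=2, mode="reflect")
    return epochs.copy_with(
        data=out,
        step={"step": "lowpass", "cutoff_hz": cutoff_hz, **report},
    )


def interpolate_bad_channels(
    epochs: EpochArray, bad: list[str], layout: ChannelLayout | None = None
) -> EpochArray:
    """Replace up to three bad channels by the inverse-distance-weighted mean
    of their good neighbors, samplewise."""
    layout = epochs.layout if layout is None else layout
    if len(bad) > 3:
        raise ValueError(f"at most 3 channels may be interpolated, got {len(bad)}")
    if not bad:
        return epochs.copy_with(step={"step": "interpolate", "bad": []})
    data = epochs.data.copy()
    bad_set = set(bad)
    for ch in bad:
        nbrs = [n for n in layout.neighbors.get(ch, []) if n not in bad_set]
        if not nbrs:
            raise ValueError(f"bad channel {ch!r} has no good neighbors")
        pi = layout.index(ch)
        d = np.array([np.linalg.norm(layout.positions[layout.index(n)] - layout.positions[pi])
                      for n in nbrs])
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum()
        idx = [layout.index(n) for n in nbrs]
        data[:, pi, :] = np.einsum("k,nks->ns", w, epochs.data[:, idx, :])
    return epochs.copy_with(data=data, step={"step": "interpolate", "bad": list(bad)})


def run_preproc(
    epochs: EpochArray,
    *,
    ref_channels: list[str] | None = None,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    reject_uv: float = REJECT_THRESHOLD_UV,
    reject_window_ms: tuple[float, float] = REJECT_WINDOW_MS,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    bad_channels: list[str] | None = None,
    order_override: list[str] | None = None,
) -> tuple[EpochArray, RejectionLog]:
    """Run the canonical preprocessing chain in its fixed order.

    ``order_override`` reorders the stages explicitly; the override is
    recorded in the provenance history, with a warning, so a non-standard
    order is never silent.
    """
    def _reref(e: EpochArray) -> EpochArray:
        refs = ref_channels if ref_channels is not None else e.layout.reference_channels
        if not refs:  # reference-free micro-layouts
            return e.copy_with(step={"step": "rereference", "status": "skipped (no refs)"})
        return rereference(e, refs)

    stages = {
        "interpolate": lambda e: interpolate_bad_channels(e, bad_channels or []),
        "rereference": _reref,
        "demean": demean_epochs,
        "ica": lambda e: e.copy_with(step={"step": "ica", "status": "skipped"}),
        "baseline": lambda e: baseline_correct(e, baseline_ms),
        "reject": None,  # handled below (returns a log)
        "lowpass": lambda e: lowpass_filter(e, cutoff_hz),
    }
    order = ["interpolate", "rereference", "demean", "ica", "baseline", "reject", "lowpass"]
    if order_override is not None:
        unknown = set(order_override) - set(stages)
        if unknown:
            raise ValueError(f"unknown stages in override: {sorted(unknown)}")
        warnings.warn(f"non-standard preprocessing order: {order_override}")
        order = list(order_override)
        epochs = epochs.copy_with(step={"step": "order_override", "order": order})

    log = RejectionLog(
        table=pd.DataFrame(columns=["trial", "kept", "channel", "time_ms", "peak_uv"]),
        threshold_uv=reject_uv,
        window_ms=reject_window_ms,
    )
    for name in order:
        if name == "reject":
            epochs, log = reject_artifacts(epochs, reject_uv, reject_window_ms)
        else:
            epochs = stages[name](epochs)
    return epochs, log
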