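"""Detectors and derived quantities on simulation (or experimental-like)
voltage and [K+]out traces.

Depolarization block — sustained depolarization with firing failure — is
the model's operational marker of CSD initiation.  The default plateau
criterion is V above -35 mV for at least 2 s with no spikes; both the
threshold and the window are arguments, and block detection is robust to
a few mV either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import SCENARIOS, Scenario, SimulationTrace, simulate

__all__ = [
    "BlockEvent",
    "SweepResult",
    "detect_spikes",
    "firing_frequency",
    "detect_depolarization_block",
    "cascade_onset",
    "kout_phase_maxima",
    "minimal_blocking_drive",
    "block_latency",
    "interneuron_fI",
    "analyze_trace",
]

#: defaults for spike and block detection
SPIKE_THRESHOLD = 0.0        # mV
SPIKE_REFRACTORY = 2.0       # ms
PLATEAU_THRESHOLD = -35.0    # mV
MIN_PLATEAU = 2.0            # s


@dataclass(frozen=True)
class BlockEvent:
    """A depolarization-block episode of one neuron."""

    onset: float                  # s
    offset: float | None          # s, None if open-ended
    neuron: str
    latency_from_drive: float     # s, relative to drive onset

    def __post_init__(self) -> None:
        if self.offset is not None and self.offset <= self.onset:
            raise ValueError("block offset must follow onset")


@dataclass(frozen=True)
class SweepResult:
    persistent_fraction: float
    minimal_blocking_drive: float | None    # mS/cm^2
    block_latency: float | None             # s
    fi_samples: tuple[tuple[float, float], ...]  # (drive, Hz)


def detect_spikes(time, v, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Upward threshold crossings separated by at least ``refractory`` ms.

    ``time`` in seconds, monotone; returns spike times in seconds.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if time.size == 0:
        raise ValueError("empty trace")
    idx = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    if idx.size == 0:
        return np.empty(0)
    times = time[idx + 1]
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory * 1e-3:
            keep.append(t)
    return np.asarray(keep)


def firing_frequency(spike_times, window: tuple[float, float]) -> float:
    """Spike count in [t0, t1) divided by the window length (Hz)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must be non-degenerate")
    spike_times = np.asarray(spike_times, dtype=float)
    n = int(np.sum((spike_times >= t0) & (spike_times < t1)))
    return n / (t1 - t0)


def detect_depolarization_block(time, v, spike_times=None,
                                plateau_threshold: float = PLATEAU_THRESHOLD,
                                min_plateau: float = MIN_PLATEAU,
                                neuron: str = "",
                                drive_onset: float = 0.0) -> BlockEvent | None:
    """First interval where V stays above ``plateau_threshold`` for at
    least ``min_plateau`` seconds with no spikes; None if absent."""
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if spike_times is None:
        spike_times = detect_spikes(time, v)
    above = v > plateau_threshold
    if not above.any():
        return None
    # runs of consecutive "above" samples
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        t0, t1 = time[start], time[min(stop, time.size) - 1]
        if t1 - t0 < min_plateau:
            continue
        if np.any((spike_times >= t0) & (spike_times <= t1)):
            # a plateau-with-spikes run may still end in spike-free block:
            last_spike = spike_times[(spike_times >= t0) & (spike_times <= t1)].max()
            if t1 - last_spike < min_plateau:
                continue
            t0 = last_spike
        offset = None if stop >= time.size else float(t1)
        return BlockEvent(onset=float(t0), offset=offset, neuron=neuron,
                          latency_from_drive=float(t0 - drive_onset))
    return None


def _trace_blocks(trace: SimulationTrace,
                  plateau_threshold: float = PLATEAU_THRESHOLD,
                  min_plateau: float = MIN_PLATEAU):
    onset = trace.scenario.drive_onset
    out = {}
    for label, v in (("interneuron", trace.v_interneuron),
                     ("pyramidal", trace.v_pyramidal)):
        spikes = detect_spikes(trace.time, v)
        out[label] = detect_depolarization_block(
            trace.time, v, spikes, plateau_threshold, min_plateau,
            neuron=label, drive_onset=onset)
    return out


def cascade_onset(trace: SimulationTrace, **kw) -> BlockEvent | None:
    """Earliest depolarization-block onset of either neuron: the start
    of the regenerative [K+]out surge (the ignition point)."""
    blocks = [b for b in _trace_blocks(trace, **kw).values() if b is not None]
    if not blocks:
        return None
    return min(blocks, key=lambda b: b.onset)


def kout_phase_maxima(trace: SimulationTrace,
                      block: BlockEvent | None) -> tuple[float, float | None]:
    """Maximum [K+]out before and after a block onset.

    With no block the pre-phase spans the whole trace and the post-phase
    is None.
    """
    k_out = trace.k_out
    if block is None:
        return float(k_out.max()), None
    pre_mask = trace.time < block.onset
    pre = float(k_out[pre_mask].max()) if pre_mask.any() else float(k_out[0])
    post = float(k_out[~pre_mask].max())
    return pre, post


class BracketError(ValueError):
    """The bisection bracket does not straddle the block threshold."""


def _blocks_at(fraction: float, drive: float, window: float, circuit) -> bool:
    sc = Scenario(name=f"bisect_{fraction:g}_{drive:g}",
                  persistent_fraction=fraction, gD_i=drive, gD_e=0.0,
                  duration=window)
    trace = simulate(sc, circuit=circuit)
    blocks = _trace_blocks(trace)
    return blocks["pyramidal"] is not None


def bisect_threshold(predicate, lo: float, hi: float, tol: float) -> float:
    """Bisect the boundary of a monotone boolean ``predicate`` (False at
    ``lo``, True at ``hi``) to within ``tol``."""
    if predicate(lo):
        raise BracketError(f"predicate already true at the low bracket {lo}")
    if not predicate(hi):
        raise BracketError(f"predicate false at the high bracket {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def minimal_blocking_drive(fraction: float,
                           bracket: tuple[float, float] = (0.05, 0.6),
                           tol: float = 0.001,
                           window: float = 30.0,
                           circuit=None) -> float:
    """Bisect the lowest interneuron drive gD_i inducing depolarization
    block of the pyramidal neuron within ``window`` seconds."""
    return bisect_threshold(
        lambda d: _blocks_at(fraction, d, window, circuit),
        bracket[0], bracket[1], tol)


def block_latency(fraction: float, drive: float,
                  window: float = 30.0, circuit=None) -> float | None:
    """Latency (s) from drive onset to pyramidal depolarization block at
    a fixed drive; None if no block occurs within the window."""
    sc = Scenario(name=f"latency_{fraction:g}", persistent_fraction=fraction,
                  gD_i=drive, gD_e=0.0, duration=window)
    trace = simulate(sc, circuit=circuit)
    block = _trace_blocks(trace)["pyramidal"]
    return None if block is None else block.latency_from_drive


def interneuron_fI(fraction: float, drives, duration: float = 3.0,
                   circuit=None) -> list[tuple[float, float]]:
    """Steady-state firing frequency of the interneuron with the
    pyramidal neuron removed and ion concentrations clamped at rest,
    per drive value.

    Clamping (zero flux-to-concentration conversion) isolates the direct
    effect of the persistent Na+ conductance on repetitive firing from
    the slower [K+]out-mediated loop; without it the high-fraction cell
    enters depolarization block within seconds and the curve measures
    block latency rather than excitability.
    """
    out = []
    for drive in drives:
        if drive < 0:
            raise ValueError("drives must be non-negative")
        sc = Scenario(
            name=f"fI_{fraction:g}_{drive:g}", persistent_fraction=fraction,
            gD_i=drive, gD_e=0.0, duration=duration,
            overrides={"synapse.g_max": 0.0, "homeostasis.gamma_i": 0.0,
                       "homeostasis.gamma_p": 0.0},
        )
        trace = simulate(sc, circuit=circuit)
        spikes = detect_spikes(trace.time, trace.v_interneuron)
        out.append((drive, firing_frequency(spikes, (duration - 1.0, duration))))
    return out


def analyze_trace(trace: SimulationTrace) -> dict:
    """Standard report: spikes, rates, block events, [K+]out maxima."""
    blocks = _trace_blocks(trace)
    onset = cascade_onset(trace)
    pre, post = kout_phase_maxima(trace, onset)
    sp_i = detect_spikes(trace.time, trace.v_interneuron)
    sp_p = detect_spikes(trace.time, trace.v_pyramidal)
    t1 = trace.time[-1]
    _, post_pyr = kout_phase_maxima(trace, blocks["pyramidal"])
    return {
        "scenario": trace.scenario.name,
        "n_spikes_interneuron": int(sp_i.size),
        "n_spikes_pyramidal": int(sp_p.size),
        "rate_interneuron_first2s": firing_frequency(sp_i, (0.0, min(2.0, t1))),
        "block_interneuron": blocks["interneuron"],
        "block_pyramidal": blocks["pyramidal"],
        "cascade_onset": onset,
        "k_out_max_pre_ignition": pre,
        "k_out_max_post_ignition": post,
        "k_out_max_post_pyramidal_block": post_pyr,
        "k_out_max": float(trace.k_out.max()),
    }
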