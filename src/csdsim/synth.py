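"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators: Bernoulli slice-outcome tables (emulating the
success/failure CSD-induction experiments), stereotyped spike/plateau
voltage traces with known ground truth (for validating the detectors),
and a Monte-Carlo calibration harness for the exact tests.  All
randomness flows through an explicit integer seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import ContingencyTable, fisher_exact_2x2, fisher_exact_rx2

__all__ = [
    "OutcomeSpec",
    "TraceSpec",
    "generate_outcome_table",
    "generate_trace",
    "type_I_error_suite",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """Per-group success probabilities and sizes for a slice experiment."""

    probabilities: tuple[float, ...]
    sizes: tuple[int, ...]
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.sizes):
            raise ValueError("probabilities and sizes must align")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.sizes):
            raise ValueError("group sizes must be >= 1")


def generate_outcome_table(spec: OutcomeSpec) -> ContingencyTable:
    """Binomial(n_g, p_g) successes per group, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    successes = tuple(int(rng.binomial(n, p))
                      for p, n in zip(spec.probabilities, spec.sizes))
    labels = spec.labels or tuple(f"group{i}" for i in range(len(spec.sizes)))
    return ContingencyTable(labels=tuple(labels), successes=successes,
                            totals=tuple(spec.sizes))


@dataclass(frozen=True)
class TraceSpec:
    """A synthetic membrane-potential trace.

    Spikes are placed by an inhomogeneous renewal process following
    ``rate_schedule`` (a sequence of ``(t_start_s, rate_hz)`` steps) with
    a refractory floor; an optional depolarized plateau replaces firing
    after ``block_onset``.  The spike waveform is a fixed 2 ms triangular
    template — detectors must not depend on waveform details.
    """

    duration: float = 10.0              # s
    sample_dt: float = 0.5              # ms
    rate_schedule: tuple[tuple[float, float], ...] = ((0.0, 20.0),)
    block_onset: float | None = None    # s
    plateau_level: float = -20.0        # mV
    baseline: float = -70.0             # mV
    spike_peak: float = 30.0            # mV
    noise_amplitude: float = 0.0        # mV
    refractory: float = 3.0             # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(r < 0 for _, r in self.rate_schedule):
            raise ValueError("rates must be non-negative")
        max_rate = max((r for _, r in self.rate_schedule), default=0.0)
        if max_rate > 0 and 1.0 / max_rate < self.refractory * 1e-3:
            raise ValueError("rate schedule incompatible with the refractory floor")


def _rate_at(spec: TraceSpec, t: float) -> float:
    rate = 0.0
    for t0, r in spec.rate_schedule:
        if t >= t0:
            rate = r
    return rate


def generate_trace(spec: TraceSpec):
    """Return ``(time_s, v_mv, spike_times_s, block_onset_s)``.

    Ground truth (spike times, block onset) is returned alongside the
    trace so detector tests need no re-derivation.
    """
    rng = np.random.default_rng(spec.seed)
    time = np.arange(0.0, spec.duration, spec.sample_dt * 1e-3)
    v = np.full(time.size, spec.baseline)

    spike_end = spec.block_onset if spec.block_onset is not None else spec.duration
    spikes = []
    t = 0.0
    while t < spike_end:
        rate = _rate_at(spec, t)
        if rate <= 0:
            # jump to the next schedule step, if any
            nxt = [t0 for t0, _ in spec.rate_schedule if t0 > t]
            if not nxt:
                break
            t = min(nxt)
            continue
        # renewal: refractory floor plus exponential tail keeps the mean 1/rate
        mean_isi = 1.0 / rate
        floor = spec.refractory * 1e-3
        t = t + floor + rng.exponential(max(mean_isi - floor, 1e-9))
        if t < spike_end:
            spikes.append(t)
    spikes = np.asarray(spikes)

    # triangular 2 ms template
    half = 1.0e-3
    for ts in spikes:
        lo = np.searchsorted(time, ts - half)
        hi = np.searchsorted(time, ts + half)
        seg = time[lo:hi]
        if seg.size:
            shape = 1.0 - np.abs(seg - ts) / half
            v[lo:hi] = np.maximum(v[lo:hi], spec.baseline
                                  + (spec.spike_peak - spec.baseline) * shape)

    if spec.block_onset is not None:
        v[time >= spec.block_onset] = spec.plateau_level

    if spec.noise_amplitude > 0:
        v = v + rng.normal(0.0, spec.noise_amplitude, size=v.size)
    return time, v, spikes, spec.block_onset


def type_I_error_suite(null_spec: OutcomeSpec, n_reps: int = 1000,
                       alpha: float = 0.05) -> float:
    """Empirical rejection rate of the exact test at level ``alpha`` when
    every group shares one success probability (the null).  Exact tests
    are conservative, so the rate should not exceed alpha beyond
    binomial noise."""
    if len(set(null_spec.probabilities)) != 1:
        raise ValueError("null requires a single shared success probability")
    rng = np.random.default_rng(null_spec.seed)
    test = fisher_exact_2x2 if len(null_spec.sizes) == 2 else fisher_exact_rx2
    rejections = 0
    for _ in range(n_reps):
        sub = OutcomeSpec(null_spec.probabilities, null_spec.sizes,
                          seed=int(rng.integers(0, 2**31 - 1)))
        table = generate_outcome_table(sub)
        if test(table) <= alpha:
            rejections += 1
    return rejections / n_reps
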