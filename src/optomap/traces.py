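"""Trace containers for voltage- and current-clamp recordings.

Time is always milliseconds on a uniform grid, currents in pA, voltages in
mV, sampling rates in kHz. Simulated traces carry their ground truth in
``metadata`` so that feature extractors can be checked against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["VoltageClampTrace", "CurrentClampTrace"]

_GRID_RTOL = 1e-6


def _check_uniform_grid(time: np.ndarray, sampling_rate: float) -> None:
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid must be a 1-D array with >=2 samples")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=_GRID_RTOL, atol=1e-9):
        raise ValueError("time grid must be uniform")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive (kHz)")
    expected_dt = 1.0 / sampling_rate
    if not np.isclose(dt[0], expected_dt, rtol=1e-4):
        raise ValueError(
            f"grid spacing {dt[0]:.6g} ms does not match sampling rate "
            f"{sampling_rate} kHz (expected {expected_dt:.6g} ms)"
        )


@dataclass
class VoltageClampTrace:
    """A voltage-clamp sweep: clamped membrane potential, recorded current.

    ``step_onset`` / ``step_duration`` locate the command-voltage step
    (``step_delta_v`` relative to ``holding_potential``) inside the sweep.
    """

    time: np.ndarray                # ms
    current: np.ndarray             # pA
    step_onset: float               # ms
    step_delta_v: float             # mV
    step_duration: float | None = None   # ms; None for non-step protocols
    holding_potential: float = -70.0     # mV
    sampling_rate: float = 10.0          # kHz
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.current.shape != self.time.shape:
            raise ValueError("current and time must have the same shape")
        _check_uniform_grid(self.time, self.sampling_rate)
        if not (self.time[0] <= self.step_onset <= self.time[-1]):
            raise ValueError("step_onset must lie within the trace")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the grid sample nearest to time ``t`` (ms)."""
        return int(round((t - self.time[0]) * self.sampling_rate))


@dataclass
class CurrentClampTrace:
    """A current-clamp sweep: injected current command, recorded voltage."""

    time: np.ndarray                # ms
    voltage: np.ndarray             # mV
    injected_current: np.ndarray    # pA, per sample
    sampling_rate: float = 10.0     # kHz
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.injected_current = np.asarray(self.injected_current, dtype=float)
        if self.voltage.shape != self.time.shape:
            raise ValueError("voltage and time must have the same shape")
        if self.injected_current.shape != self.time.shape:
            raise ValueError("injected_current and time must have the same shape")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage must be finite")
        _check_uniform_grid(self.time, self.sampling_rate)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def index_at(self, t: float) -> int:
        return int(round((t - self.time[0]) * self.sampling_rate))
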