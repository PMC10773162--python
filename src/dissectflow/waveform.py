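"""Periodic flow-rate waveforms.

A :class:`FlowWaveform` is one cardiac cycle of a scalar flow rate,
sampled at strictly increasing times on ``[0, T)`` with the periodic
end point excluded (sample 0 is reused at ``t = T`` when integrating).
Flow is signed: positive means forward along the owning plane's normal
or the owning tear's positive direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FlowWaveform"]


@dataclass(frozen=True)
class FlowWaveform:
    """One periodic cycle of a signed scalar flow rate.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds, strictly increasing, covering ``[0, T)``.
    flow_L_min : np.ndarray
        Signed flow rate in L/min at each sample.
    period_s : float
        Cycle period ``T``; must exceed the last sample time.
    """

    time_s: np.ndarray
    flow_L_min: np.ndarray
    period_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        q = np.asarray(self.flow_L_min, dtype=float)
        if t.ndim != 1 or q.shape != t.shape:
            raise ValueError("time and flow must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if not (self.period_s > t[-1]):
            raise ValueError("period must exceed the last sample time "
                             "(periodic end point is excluded)")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "flow_L_min", q)

    def __len__(self) -> int:
        return self.time_s.size

    def _closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples with the periodic end point appended (t[0]+T, q[0])."""
        t = np.append(self.time_s, self.time_s[0] + self.period_s)
        q = np.append(self.flow_L_min, self.flow_L_min[0])
        return t, q

    def cycle_integral(self) -> float:
        """Trapezoid integral of Q over one period, in L/min · s."""
        t, q = self._closed_cycle()
        return float(np.trapezoid(q, t))

    def cycle_mean(self) -> float:
        """Cycle-mean flow rate in L/min (trapezoid, periodic closure)."""
        return self.cycle_integral() / self.period_s

    def scaled(self, factor: float) -> "FlowWaveform":
        return FlowWaveform(self.time_s, self.flow_L_min * factor, self.period_s)

    def negated(self) -> "FlowWaveform":
        return self.scaled(-1.0)

    def same_time_base(self, other: "FlowWaveform", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.time_s, other.time_s, rtol=rtol, atol=1e-12)
            and np.isclose(self.period_s, other.period_s, rtol=rtol)
        )

    # ---- CSV round trip (columns: time_s, flow_L_per_min) ----

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.time_s, "flow_L_per_min": self.flow_L_min})
        with open(path, "w") as fh:
            fh.write(f"# period_s={self.period_s!r}\n")
            df.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowWaveform":
        path = Path(path)
        period = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "period_s=" in first:
            period = float(first.split("period_s=")[1])
        df = pd.read_csv(path, comment="#")
        t = df["time_s"].to_numpy(float)
        q = df["flow_L_per_min"].to_numpy(float)
        if period is None:
            # assume uniform sampling; period extends one step past the end
            period = t[-1] + (t[1] - t[0])
        return cls(t, q, period)
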