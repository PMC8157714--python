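"""Shared trajectory container for tracer position time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A 3-D position time series of a single tracer in a periodic box.

    Parameters
    ----------
    times : (n,) array, ps
        Uniformly spaced sample times.
    positions : (n, 3) array, nm
        Positions wrapped into the box (each coordinate in [0, box_i)).
    unwrapped : (n, 3) array, nm or None
        Continuous (image-consistent) positions; ``unwrapped - positions``
        is an integer multiple of the box in every coordinate.
    box : (3,) array, nm
        Box edge lengths; origin at the corner.
    periodic : bool
        Whether the box is periodic.
    """

    times: np.ndarray
    positions: np.ndarray
    unwrapped: np.ndarray | None = None
    box: np.ndarray | None = None
    periodic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if dts.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                bad = int(np.argmax(np.abs(dts - dts[0]) > 1e-6 * dts[0]))
                raise ValueError(f"non-uniform time step at frame {bad + 1}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Frame interval in ps."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration_ns(self) -> float:
        return float(self.times[-1] - self.times[0]) / 1e3

    def wrap(self) -> np.ndarray:
        """Positions wrapped into [0, box) (identity if already wrapped)."""
        if self.box is None or not self.periodic:
            return self.positions
        return np.mod(self.positions, self.box)

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            times=self.times[start:stop],
            positions=self.positions[start:stop],
            unwrapped=None if self.unwrapped is None else self.unwrapped[start:stop],
            box=self.box,
            periodic=self.periodic,
            meta=dict(self.meta),
        )
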