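"""Eye-position trace container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class EyeTrace:
    """One trial's uniformly sampled 2-D gaze series.

    ``t_ms`` is trial-relative time in milliseconds with a constant step of
    ``1000 / sample_rate``; ``x_deg`` / ``y_deg`` are gaze position in visual
    degrees (NaN marks missing samples, e.g. blinks or track loss).
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sample_rate: float
    trial_id: int | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if not (self.t_ms.shape == self.x_deg.shape == self.y_deg.shape):
            raise InvalidArgumentError("t, x and y must have identical shapes")
        if self.t_ms.ndim != 1:
            raise InvalidArgumentError("trace arrays must be one-dimensional")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if self.t_ms.size >= 2:
            steps = np.diff(self.t_ms)
            expected = 1000.0 / self.sample_rate
            if not np.allclose(steps, expected, rtol=0, atol=1e-6):
                raise InvalidArgumentError(
                    "t must be strictly increasing with constant step "
                    f"{expected:g} ms"
                )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.t_ms.size

    def index_of(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(round((t_ms - self.t_ms[0]) / self.dt_ms))
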