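"""Simulation configuration for the synthetic center-out saccade task.

The simulated experiment mirrors a standard primate oculomotor protocol: the
animal fixates a central point for 800 ms, the point then jumps 7 degrees
left or right along the horizontal meridian, and the animal saccades to it.
On half of the trials a single electrode of a 96-channel prefrontal array is
stimulated concurrently with the jump.  The configuration gathers every
constant of that protocol plus the injected behavioral effects (latency
shifts, evoked saccades) that the analysis stages are meant to recover.

Direction convention: 0 degrees = rightward.  The array sits in the *left*
hemisphere, so rightward target jumps and saccades are *contraversive* and
leftward ones *ipsiversive*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Tuple

import yaml

from .errors import ConfigurationError

#: The two task directions, named relative to the stimulated hemisphere.
DIRECTIONS = ("contra", "ipsi")

#: Electrode-grid halves along the rostro-caudal axis.
GROUPS = ("rostral", "caudal")


@dataclass(frozen=True)
class EvokingElectrode:
    """An electrode whose stimulation can directly evoke a saccade.

    The evoked movement is drawn around a fixed preferred vector: direction
    from a von Mises distribution centered on ``preferred_direction_deg``
    and amplitude from a Gaussian whose mean grows with current.
    """

    electrode_id: int
    preferred_direction_deg: float
    #: evocation probability per stimulation current (uA)
    prob_by_current: Mapping[int, float]
    #: mean evoked amplitude (deg) per stimulation current (uA)
    amplitude_mean_by_current: Mapping[int, float]
    amplitude_sd_deg: float = 0.8
    direction_kappa: float = 20.0

    def validate(self, currents: Sequence[int]) -> None:
        for c in currents:
            if c not in self.prob_by_current:
                raise ConfigurationError(
                    f"evoking electrode {self.electrode_id}: no evocation "
                    f"probability for current {c} uA"
                )
            p = self.prob_by_current[c]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"evoking electrode {self.electrode_id}: probability {p} "
                    f"outside [0, 1]"
                )
            if c not in self.amplitude_mean_by_current:
                raise ConfigurationError(
                    f"evoking electrode {self.electrode_id}: no amplitude for "
                    f"current {c} uA"
                )


def default_effect_map() -> dict:
    """Latency shifts (ms, stim minus control) per (group, current, direction).

    Contraversive saccades are delayed only from the caudal half of the grid
    (strongly at the high current); ipsiversive saccades are speeded from
    both halves.  Positive = delayed by stimulation.
    """
    return {
        ("caudal", 250, "contra"): 25.0,
        ("rostral", 250, "contra"): 0.0,
        ("caudal", 100, "contra"): 4.0,
        ("rostral", 100, "contra"): 0.0,
        ("caudal", 250, "ipsi"): -22.0,
        ("rostral", 250, "ipsi"): -22.0,
        ("caudal", 100, "ipsi"): -9.0,
        ("rostral", 100, "ipsi"): -9.0,
    }


def default_evoking_electrodes(grid_shape: Tuple[int, int] = (8, 12)) -> tuple:
    """Cluster of saccade-evoking electrodes on the caudal border of the grid.

    Four "strong" sites evoke robustly at both currents; three neighbours
    evoke reliably only at the high current, so the evoking patch appears to
    grow with current, and all evoked vectors point into the contralateral
    (rightward) hemifield.
    """
    n_rows, n_cols = grid_shape
    last_row_start = (n_rows - 1) * n_cols  # electrode ids are row-major
    strong_cols = (4, 5, 6, 7)
    weak_cols = (3, 8, 9)
    strong_dirs = (-40.0, -15.0, 10.0, 35.0)
    weak_dirs = (-55.0, 45.0, 60.0)
    out = []
    for col, d in zip(strong_cols, strong_dirs):
        out.append(
            EvokingElectrode(
                electrode_id=last_row_start + col,
                preferred_direction_deg=d,
                prob_by_current={100: 0.6, 250: 0.9},
                amplitude_mean_by_current={100: 4.0, 250: 5.5},
            )
        )
    for col, d in zip(weak_cols, weak_dirs):
        out.append(
            EvokingElectrode(
                electrode_id=last_row_start + col,
                preferred_direction_deg=d,
                prob_by_current={100: 0.05, 250: 0.55},
                amplitude_mean_by_current={100: 4.0, 250: 5.5},
            )
        )
    return tuple(out)


@dataclass
class SimConfig:
    """Parameters of one synthetic stimulation session.

    Latency model: saccadic reaction time is ex-Gaussian,
    ``mu_dir + sigma * N(0,1) + Exp(tau)``, with the contraversive mean
    lower than the ipsiversive one by ``baseline_contra_advantage_ms``.
    Stimulated trials additionally receive the shift configured in
    ``effect_map`` for their (electrode group, current, direction) cell.
    """

    sample_rate: float = 500.0          # Hz
    fixation_ms: float = 800.0          # fixation epoch before the jump
    post_jump_ms: float = 700.0         # recorded window after the jump
    jump_amplitude_deg: float = 7.0     # horizontal target eccentricity
    fixation_radius_deg: float = 2.0    # fixation tolerance (metadata only)
    n_electrodes: int = 96
    grid_shape: Tuple[int, int] = (8, 12)   # (rostro-caudal rows, cols)
    trials_per_block: int = 20
    stim_fraction: float = 0.5
    currents_uA: Tuple[int, ...] = (100, 250)
    latency_mu_ipsi_ms: float = 170.0
    baseline_contra_advantage_ms: float = 26.0
    latency_sigma_ms: float = 20.0
    latency_tau_ms: float = 40.0
    effect_map: Mapping[tuple, float] = field(default_factory=default_effect_map)
    evoking_electrodes: Tuple[EvokingElectrode, ...] = field(
        default_factory=default_evoking_electrodes
    )
    evoked_onset_window_ms: Tuple[float, float] = (20.0, 60.0)
    noise_sd_deg: float = 0.05
    broken_electrodes: Tuple[int, ...] = ()
    seed: int = 0

    # main-sequence coefficients: duration = d0 + d1 * amplitude
    saccade_d0_ms: float = 21.0
    saccade_d1_ms_per_deg: float = 2.2

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def latency_mu_contra_ms(self) -> float:
        return self.latency_mu_ipsi_ms - self.baseline_contra_advantage_ms

    def latency_mu_ms(self, direction: str) -> float:
        return (
            self.latency_mu_contra_ms
            if direction == "contra"
            else self.latency_mu_ipsi_ms
        )

    @property
    def n_trials(self) -> int:
        return self.n_electrodes * len(self.currents_uA) * self.trials_per_block

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        if not 0.0 <= self.stim_fraction <= 1.0:
            raise ConfigurationError("stim_fraction must be in [0, 1]")
        if self.latency_sigma_ms <= 0:
            raise ConfigurationError("latency_sigma_ms must be > 0")
        if self.latency_tau_ms < 0:
            raise ConfigurationError("latency_tau_ms must be >= 0")
        if self.noise_sd_deg < 0:
            raise ConfigurationError("noise_sd_deg must be >= 0")
        n_rows, n_cols = self.grid_shape
        if n_rows * n_cols != self.n_electrodes:
            raise ConfigurationError(
                f"grid_shape {self.grid_shape} does not tile "
                f"{self.n_electrodes} electrodes"
            )
        if n_rows % 2 != 0:
            raise ConfigurationError(
                "grid_shape needs an even number of rows for an equal "
                "rostral/caudal split"
            )
        n_stim = self.trials_per_block * self.stim_fraction
        if abs(n_stim - round(n_stim)) > 1e-9:
            raise ConfigurationError(
                f"trials_per_block={self.trials_per_block} with "
                f"stim_fraction={self.stim_fraction} does not give a whole "
                f"number of stimulation trials per block"
            )
        for el in self.evoking_electrodes:
            el.validate(self.currents_uA)
            if not 0 <= el.electrode_id < self.n_electrodes:
                raise ConfigurationError(
                    f"evoking electrode id {el.electrode_id} outside the grid"
                )
        lo, hi = self.evoked_onset_window_ms
        if not 0 <= lo < hi:
            raise ConfigurationError("evoked_onset_window_ms must satisfy 0 <= lo < hi")

    def require_effect(self, group: str, current: int, direction: str) -> float:
        key = (group, current, direction)
        try:
            return float(self.effect_map[key])
        except KeyError:
            raise ConfigurationError(
                f"effect_map has no entry for (group={group!r}, "
                f"current={current}, direction={direction!r})"
            ) from None

    # -- convenience constructors -------------------------------------------

    @classmethod
    def no_effect(cls, **overrides) -> "SimConfig":
        """A null session: no latency shifts, no baseline asymmetry, no
        saccade-evoking electrodes.  Stim and control trials are exchangeable,
        so every downstream test should reject at its nominal rate only."""
        base = dict(
            baseline_contra_advantage_ms=0.0,
            effect_map={
                (g, c, d): 0.0
                for g in GROUPS
                for c in (100, 250)
                for d in DIRECTIONS
            },
            evoking_electrodes=(),
        )
        if "currents_uA" in overrides:
            base["effect_map"] = {
                (g, c, d): 0.0
                for g in GROUPS
                for c in overrides["currents_uA"]
                for d in DIRECTIONS
            }
        base.update(overrides)
        return cls(**base)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_map"] = {
            f"{g}:{c}:{dr}": v for (g, c, dr), v in self.effect_map.items()
        }
        d["evoking_electrodes"] = [
            {
                **asdict(el),
                "prob_by_current": {int(k): float(v) for k, v in el.prob_by_current.items()},
                "amplitude_mean_by_current": {
                    int(k): float(v) for k, v in el.amplitude_mean_by_current.items()
                },
            }
            for el in self.evoking_electrodes
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "effect_map" in d:
            em = {}
            for key, v in d["effect_map"].items():
                if isinstance(key, str):
                    g, c, dr = key.split(":")
                    em[(g, int(c), dr)] = float(v)
                else:
                    em[tuple(key)] = float(v)
            d["effect_map"] = em
        if "evoking_electrodes" in d:
            d["evoking_electrodes"] = tuple(
                el if isinstance(el, EvokingElectrode) else EvokingElectrode(**el)
                for el in d["evoking_electrodes"]
            )
        for key in ("grid_shape", "currents_uA", "broken_electrodes",
                    "evoked_onset_window_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
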