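"""Acquisition and pipeline configuration.

The :class:`AcquisitionConfig` collects everything the synthetic generators and
the fitting models need to agree on: the DCE time grid, the diffusion b-value
scheme, the multi-echo train, scanner timing (TR/TE, flip angle), voxel
geometry, the contrast-agent injection schedule and the noise model.  All
randomness is routed through the explicit ``seed`` field; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

#: Diffusion weightings of the fat-suppressed EPI protocol, s mm^-2.
DEFAULT_B_VALUES = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 50.0,
                    100.0, 200.0, 400.0, 600.0, 800.0)

#: Multi-echo T2 train: 8-400 ms in steps of 8 ms (50 echoes).
DEFAULT_ECHO_TIMES = tuple(float(te) for te in range(8, 401, 8))

#: Literature values for blood relaxation at 7 T, ms.
BLOOD_T1_MS = 2200.0
BLOOD_T2_MS = 50.0


@dataclass
class AcquisitionConfig:
    """Acquisition metadata shared by the phantom generators and the fitters.

    Parameters
    ----------
    time_grid : array-like of float
        Uniform DCE sampling times in seconds, strictly increasing.
    b_values : sequence of float
        Diffusion weightings in s mm^-2; first entry must be 0.
    echo_times : sequence of float
        Echo times of the multi-echo T2 train in ms, strictly increasing.
    tr_ms, te_ms : float
        Repetition and echo time of the diffusion sequence, ms.
    flip_angle_deg : float
        Excitation flip angle in degrees (spoiled gradient echo for DCE).
    voxel_size_um : tuple of float
        Voxel edge lengths in micrometres, (x, y, z).
    injection_times_s : sequence of float
        One injection time per contrast agent, seconds, strictly increasing.
    agents : sequence of str
        Contrast agent names, same order as the injections.
    molecular_weights_da : sequence of float
        Agent molecular weights in Dalton (metadata only).
    relaxivities : sequence of float
        Longitudinal relaxivity r1 per agent, s^-1 mM^-1.
    noise_sd : float
        Noise standard deviation as a fraction of the baseline signal.
    seed : int
        Seed for every stochastic generator consuming this config.
    """

    time_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 1700.0, 2.0))
    b_values: tuple = DEFAULT_B_VALUES
    echo_times: tuple = DEFAULT_ECHO_TIMES
    tr_ms: float = 4000.0
    te_ms: float = 18.5
    flip_angle_deg: float = 20.0
    voxel_size_um: tuple = (28.0, 28.0, 28.0)
    injection_times_s: tuple = (60.0, 600.0, 1140.0)
    agents: tuple = ("G5", "G2", "Gd-DOTA")
    molecular_weights_da: tuple = (59517.0, 7317.0, 754.0)
    relaxivities: tuple = (5.0, 4.5, 3.5)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        t = self.time_grid
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time_grid must be a 1-D array of >=2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-10):
            raise ValueError("time_grid must be uniformly sampled")
        b = np.asarray(self.b_values, dtype=float)
        if b.size and (b[0] != 0.0 or np.any(b < 0)):
            raise ValueError("b_values must be non-negative with b[0] == 0")
        te = np.asarray(self.echo_times, dtype=float)
        if te.size and (np.any(te <= 0) or np.any(np.diff(te) <= 0)):
            raise ValueError("echo_times must be positive, strictly increasing")
        inj = np.asarray(self.injection_times_s, dtype=float)
        if np.any(np.diff(inj) <= 0):
            raise ValueError("injection_times_s must be strictly increasing")
        if inj.size and (inj[0] < t[0] or inj[-1] > t[-1]):
            raise ValueError("injection_times_s must lie inside time_grid")
        if len(self.agents) != inj.size:
            raise ValueError("one injection time per agent is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- convenience ------------------------------------------------------
    @property
    def dt(self) -> float:
        """Time-grid spacing in seconds."""
        return float(self.time_grid[1] - self.time_grid[0])

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["time_grid"] = self.time_grid.tolist()
        for k in ("b_values", "echo_times", "voxel_size_um",
                  "injection_times_s", "agents", "molecular_weights_da",
                  "relaxivities"):
            d[k] = list(d[k])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        for k in ("b_values", "echo_times", "voxel_size_um",
                  "injection_times_s", "agents", "molecular_weights_da",
                  "relaxivities"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
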