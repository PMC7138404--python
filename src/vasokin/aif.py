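"""Arterial input functions for the three-agent bolus protocol.

The animal protocol injects three contrast agents of very different size
(a G5 dendrimer, a G2 dendrimer and Gd-DOTA) through one infusion line in a
single acquisition, so the plasma concentration seen by the tissue is the sum
of three temporally separated boluses.  Each bolus is modelled as a
gamma-variate

    C_a(t) = A * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)

for t > t0, which peaks at value ``A`` a time ``alpha * beta`` after arrival.
Setting ``normalize=True`` instead scales the bolus to unit time-integral
(i.e. the gamma probability density with shape ``alpha + 1`` and scale
``beta``), which is convenient when a nominal dose is prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .config import AcquisitionConfig


@dataclass
class BolusShape:
    """Gamma-variate bolus shape for one agent.

    ``amplitude`` is the peak plasma concentration in mM (or the total dose
    when ``normalize`` is true), ``alpha`` the dimensionless sharpness and
    ``beta`` the decay time constant in seconds.
    """

    amplitude: float = 0.5
    alpha: float = 2.5
    beta: float = 3.0
    normalize: bool = False


def gamma_variate(t: np.ndarray, t0: float, shape: BolusShape) -> np.ndarray:
    """Evaluate one gamma-variate bolus on ``t`` (seconds); zero for t <= t0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    s = t - t0
    m = s > 0
    a, b = shape.alpha, shape.beta
    if shape.normalize:
        # gamma(a+1, b) pdf: integral exactly 1
        out[m] = (s[m] ** a * np.exp(-s[m] / b)
                  / (special.gamma(a + 1.0) * b ** (a + 1.0)))
        out[m] *= shape.amplitude
    else:
        out[m] = shape.amplitude * (s[m] / (a * b)) ** a * np.exp(a - s[m] / b)
    return out


def generate_aif(config: AcquisitionConfig,
                 bolus_shapes: Sequence[BolusShape] | None = None
                 ) -> np.ndarray:
    """Per-agent plasma concentration curves on the shared time grid.

    Returns an array of shape ``(n_agents, n_time)``; the composite arterial
    input is the sum over the first axis.  Each agent's curve is exactly zero
    before its injection time.
    """
    if bolus_shapes is None:
        bolus_shapes = [BolusShape() for _ in config.agents]
    if len(bolus_shapes) != config.n_agents:
        raise ValueError("need one BolusShape per agent")
    inj = np.asarray(config.injection_times_s, dtype=float)
    if np.any(np.diff(inj) <= 0):
        raise ValueError("bolus injection times must be strictly increasing")
    curves = np.stack([gamma_variate(config.time_grid, t0, sh)
                       for t0, sh in zip(inj, bolus_shapes)])
    return curves
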