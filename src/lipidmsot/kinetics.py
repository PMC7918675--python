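"""Parametric postprandial lipid kinetics.

After a high-fat meal the lipid signal in blood and soft tissue rises from
its fasting baseline to a single peak a few hours later and then decays. A
gamma-variate multiplier captures this shape with exactly the two numbers
the downstream analysis reports — the fractional peak increase A and the
peak time tp:

    m(t) = 1 + A * (t/tp)**alpha * exp(alpha * (1 - t/tp))

so that m(0) = 1 (fasting) and max m = 1 + A, attained at t = tp. The shape
parameter alpha controls how sharp the bolus is (default 3, a smooth
rise over ~2-4 h as seen in postprandial lipemia).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticParams", "lipid_timecourse"]


@dataclass(frozen=True)
class KineticParams:
    """Gamma-variate lipid kinetics for one tissue compartment.

    baseline : relative lipid concentration at fasting, > 0
    amplitude : peak fractional increase A, >= 0 (0.839 means +83.9%)
    peak_time : minutes to peak, > 0
    shape : dimensionless gamma-variate exponent, > 0
    """

    baseline: float = 1.0
    amplitude: float = 0.0
    peak_time: float = 180.0
    shape: float = 3.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.peak_time <= 0:
            raise ValueError(f"peak_time must be > 0, got {self.peak_time}")
        if self.shape <= 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")


def lipid_timecourse(params: KineticParams, t: float | np.ndarray) -> float | np.ndarray:
    """Concentration multiplier m(t) at time ``t`` (minutes, >= 0).

    The compartment lipid concentration at time t is ``baseline * m(t)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0 minutes")
    tau = t_arr / params.peak_time
    m = 1.0 + params.amplitude * tau**params.shape * np.exp(params.shape * (1.0 - tau))
    return float(m) if np.isscalar(t) or t_arr.ndim == 0 else m
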