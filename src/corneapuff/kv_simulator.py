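"""Kelvin-Voigt viscoelastic response simulator.

The cornea (together with the pressurised globe behind it) is modelled
as the simplest linear viscoelastic element: a spring of stiffness k
(N/m) in parallel with a dashpot of damping c (N*s/m), driven by the
air-puff force F(t):

    c * x'(t) + k * x(t) = F(t),      x(0) = 0.

The element is massless; an inertial extension (m * x'' term) is out of
scope.  The spring constant is the effective apex stiffness, which grows
with intraocular pressure, and the dashpot captures viscous dissipation
— the quantity the hysteresis-loop area measures.

Integration uses an exact per-step exponential update assuming F is
piecewise linear between samples, which is unconditionally stable and
requires no tolerance tuning: over a step of length h with force going
linearly from F0 to F1, the particular solution is affine in time and
the homogeneous part decays as exp(-k h / c).  For c = 0 the equation is
algebraic and x = F / k exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, InvalidSpecError, InvalidTraceError
from .force_calibration import ForceTrace
from .mscan_segmentation import DisplacementTrace

__all__ = ["KVParams", "kv_response", "sweep_parameter", "SweepResult"]


@dataclass(frozen=True)
class KVParams:
    """Kelvin-Voigt parameters.

    Attributes
    ----------
    k : float
        Coefficient of elasticity, N/m; must be positive.
    c : float
        Damping coefficient, N*s/m; non-negative (0 = purely elastic).
    """

    k: float
    c: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.k) or self.k <= 0:
            raise InvalidParameterError(f"elasticity k must be positive, got {self.k}")
        if not np.isfinite(self.c) or self.c < 0:
            raise InvalidParameterError(f"damping c must be >= 0, got {self.c}")

    @property
    def tau(self) -> float:
        """Relaxation time constant c/k in seconds."""
        return self.c / self.k


def kv_response(f: ForceTrace, p: KVParams) -> DisplacementTrace:
    """Displacement response of a Kelvin-Voigt element to a force trace.

    Solves ``c x' + k x = F`` with ``x(0) = 0`` by the exact exponential
    integrator for piecewise-linear F.  The input force is in newtons;
    the returned displacement is in microns, inward-positive, on the
    same time base.

    Parameters
    ----------
    f : ForceTrace
        Finite force samples on a strictly increasing (not necessarily
        uniform) time grid.
    p : KVParams

    Returns
    -------
    DisplacementTrace
    """
    t, F = f.time, f.force
    n = len(t)
    if n < 2:
        raise InvalidTraceError("force trace needs at least 2 samples")

    if p.c == 0.0:
        x = F / p.k
    else:
        lam = p.k / p.c
        dt = np.diff(t)
        decay = np.exp(-lam * dt)
        slope = np.diff(F) / dt  # N/s within each interval
        # Particular solution on [t_i, t_i + h]:  x_p(s) = (F_i + slope*s)/k - slope*c/k^2
        xp0 = F[:-1] / p.k - slope * p.c / p.k**2
        xp1 = F[1:] / p.k - slope * p.c / p.k**2
        x = np.empty(n)
        x[0] = 0.0
        for i in range(n - 1):
            x[i + 1] = xp1[i] + (x[i] - xp0[i]) * decay[i]

    return DisplacementTrace(time=t.copy(), x=x * 1e6)


@dataclass(frozen=True)
class SweepResult:
    """Family of responses from a one-parameter Kelvin-Voigt sweep."""

    which: str
    values: tuple
    traces: tuple  # of DisplacementTrace
    metrics: object  # pandas DataFrame, one row per parameter value


def sweep_parameter(f: ForceTrace, base: KVParams, which: str, values) -> SweepResult:
    """Simulate the same force pulse across a sweep of k or c values.

    One Kelvin-Voigt simulation is run per value of the swept parameter
    (the other held at its ``base`` value) and the full hysteresis
    descriptor set is computed for each response, tabulating how the
    loop metrics move with stiffness or damping.

    Parameters
    ----------
    which : {"k", "c"}
        Which parameter to sweep.
    values : sequence of float
        Non-empty; positive for k, non-negative for c.

    Returns
    -------
    SweepResult
        ``metrics`` is a DataFrame indexed by the swept value with the
        hysteresis descriptors as columns.
    """
    import pandas as pd

    from .hysteresis_metrics import compute_all_metrics

    if which not in ("k", "c"):
        raise InvalidSpecError(f"which must be 'k' or 'c', got {which!r}")
    values = tuple(float(v) for v in values)
    if len(values) == 0:
        raise InvalidSpecError("sweep requires at least one parameter value")

    traces, rows = [], []
    for v in values:
        params = KVParams(k=v, c=base.c) if which == "k" else KVParams(k=base.k, c=v)
        x = kv_response(f, params)
        traces.append(x)
        metrics = compute_all_metrics(x, f, cct=None)
        row = metrics.to_dict()
        row[which] = v
        rows.append(row)

    table = pd.DataFrame(rows).set_index(which)
    return SweepResult(which=which, values=values, traces=tuple(traces), metrics=table)
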