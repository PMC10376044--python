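"""Isothermal titration calorimetry: injection bookkeeping and isotherm fit.

The titrant (guest) is injected stepwise into a fixed-volume cell holding
the macromolecule (host).  Each injection of volume dv overflows an equal
volume of well-mixed cell content, so both totals dilute by (1 - dv/V0)
while the syringe adds titrant.  Per-injection heats are differences of
the cumulative single-class-of-sites heat Q, plus a small correction for
the heat carried out by the displaced volume.  The fit recovers the site
count n, association constant K and molar enthalpy dH; dG and TdS follow
from the thermodynamic identities in :mod:`cdbind.binding_core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .binding_core import ThermoResult, itc_cumulative_heat, thermo_result
from .errors import IdentifiabilityError, ValidationError

#: Bounds for the fit: log10 K (M^-1) and stoichiometry n.
LOG10K_BOUNDS = (0.0, 9.0)
N_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class ITCProtocol:
    """Injection protocol: cell volume (L), cell macromolecule and syringe
    titrant concentrations (M), per-injection volumes (L), temperature (K)."""

    cell_volume: float
    cell_concentration: float
    syringe_concentration: float
    injection_volumes: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes", tuple(self.injection_volumes))
        if self.cell_volume <= 0:
            raise ValidationError("cell_volume must be positive")
        if self.cell_concentration < 0 or self.syringe_concentration < 0:
            raise ValidationError("concentrations must be non-negative")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValidationError("injection volumes must be positive")
        if sum(self.injection_volumes) >= self.cell_volume:
            raise ValidationError("total injected volume must stay below the cell volume")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class ITCData:
    """Integrated heats per injection (J, exothermic negative) with an
    optional control (blank titration) series of the same length."""

    heats: tuple[float, ...]
    control_heats: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", tuple(float(q) for q in self.heats))
        if self.control_heats is not None:
            object.__setattr__(
                self, "control_heats", tuple(float(q) for q in self.control_heats)
            )
        for q in self.heats:
            if not math.isfinite(q):
                raise ValidationError("non-finite heat value")
        if self.control_heats is not None:
            if len(self.control_heats) != len(self.heats):
                raise ValidationError(
                    f"control series length {len(self.control_heats)} does not match "
                    f"{len(self.heats)} injections"
                )
            for q in self.control_heats:
                if not math.isfinite(q):
                    raise ValidationError("non-finite control heat value")


@dataclass(frozen=True)
class ITCFitResult:
    """Fitted stoichiometry n, association constant K (M^-1) and molar
    enthalpy dH (kJ/mol), with the derived thermodynamic decomposition and
    the residual sum of squares (J^2)."""

    n: float
    K: float
    dH: float
    thermo: ThermoResult
    rss: float
    converged: bool


def concentration_series(protocol: ITCProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Total titrant and macromolecule concentrations (M) after each injection.

    Sequential well-mixed overflow model: per injection of volume dv,
    M_t <- M_t (1 - dv/V0) and X_t <- X_t (1 - dv/V0) + X_syr dv/V0.
    Returns arrays (X_t, M_t) of length n_injections.
    """
    v0 = protocol.cell_volume
    m_t = protocol.cell_concentration
    x_t = 0.0
    xs, ms = [], []
    for dv in protocol.injection_volumes:
        f = dv / v0
        m_t *= 1.0 - f
        x_t = x_t * (1.0 - f) + protocol.syringe_concentration * f
        xs.append(x_t)
        ms.append(m_t)
    return np.asarray(xs), np.asarray(ms)


def concentrations_after_injections(protocol: ITCProtocol, upto: int) -> tuple[float, float]:
    """(titrant_total, macromolecule_total) in M after injection ``upto`` (1-based)."""
    if not 1 <= upto <= protocol.n_injections:
        raise ValidationError(
            f"injection index {upto} out of range 1..{protocol.n_injections}"
        )
    xs, ms = concentration_series(protocol)
    return float(xs[upto - 1]), float(ms[upto - 1])


def subtract_control(data: ITCData) -> ITCData:
    """Subtract the blank-titration heats elementwise; clears the control."""
    if data.control_heats is None:
        raise ValidationError("no control series to subtract")
    corrected = tuple(q - c for q, c in zip(data.heats, data.control_heats))
    return replace(data, heats=corrected, control_heats=None)


def predicted_injection_heats(
    protocol: ITCProtocol,
    n: float,
    K: float,
    dH: float,
    include_displacement: bool = True,
) -> np.ndarray:
    """Model heats per injection (J) for site count n, K (M^-1), dH (J/mol).

    dq_i = Q(i) - Q(i-1) + (dv_i/V0) * (Q(i) + Q(i-1))/2, where Q is the
    cumulative isotherm heat evaluated at post-injection concentrations and
    the last term accounts for bound complex expelled with the overflow
    (switchable via ``include_displacement``).
    """
    xs, ms = concentration_series(protocol)
    v0 = protocol.cell_volume
    q_prev = 0.0
    heats = []
    for dv, x_t, m_t in zip(protocol.injection_volumes, xs, ms):
        q = itc_cumulative_heat(n, K, dH, m_t, x_t, v0)
        dq = q - q_prev
        if include_displacement:
            dq += (dv / v0) * (q + q_prev) / 2.0
        heats.append(dq)
        q_prev = q
    return np.asarray(heats)


def _profiled_dh(model_unit: np.ndarray, y: np.ndarray) -> float:
    """Closed-form molar enthalpy: the model is linear in dH."""
    denom = float(model_unit @ model_unit)
    return float(model_unit @ y) / denom if denom > 0 else 0.0


def fit_itc(
    protocol: ITCProtocol,
    data: ITCData,
    start: tuple[float, float] | None = None,
    include_displacement: bool = True,
) -> ITCFitResult:
    """Least-squares fit of the single-class-of-sites model to injection heats.

    Searches (log10 K, n) with dH profiled out in closed form at each
    iterate; the control series, when present, is subtracted first.
    ``start`` optionally overrides the default initial guesses (K, n) =
    (1e3 M^-1, 1).  ``converged`` is False when the optimiser fails or a
    parameter pins to its bound.
    """
    if data.control_heats is not None:
        data = subtract_control(data)
    y = np.asarray(data.heats)
    if y.size < 5:
        raise ValidationError(f"need >= 5 injections, got {y.size}")
    if np.allclose(y, 0.0):
        raise IdentifiabilityError("all heats are zero; no binding signal to fit")

    k0, n0 = start if start is not None else (1e3, 1.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        logk, n = theta
        unit = predicted_injection_heats(
            protocol, n, 10.0**logk, 1.0, include_displacement=include_displacement
        )
        return y - _profiled_dh(unit, y) * unit

    res = least_squares(
        residuals,
        x0=np.array([math.log10(k0), n0]),
        bounds=(np.array([LOG10K_BOUNDS[0], N_BOUNDS[0]]),
                np.array([LOG10K_BOUNDS[1], N_BOUNDS[1]])),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    logk_hat, n_hat = res.x
    unit = predicted_injection_heats(
        protocol, n_hat, 10.0**logk_hat, 1.0, include_displacement=include_displacement
    )
    dh_hat = _profiled_dh(unit, y)  # J/mol
    rss = float(np.sum((y - dh_hat * unit) ** 2))

    margin = 1e-6
    pinned = (
        logk_hat <= LOG10K_BOUNDS[0] + margin
        or logk_hat >= LOG10K_BOUNDS[1] - margin
        or n_hat <= N_BOUNDS[0] + margin
        or n_hat >= N_BOUNDS[1] - margin
    )
    K_hat = 10.0**logk_hat
    dh_kJ = dh_hat / 1000.0
    return ITCFitResult(
        n=float(n_hat),
        K=float(K_hat),
        dH=dh_kJ,
        thermo=thermo_result(K_hat, dh_kJ, protocol.temperature),
        rss=rss,
        converged=bool(res.success) and not pinned,
    )
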