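"""Continuous-variation (Job plot) NMR analysis of a 1:1 host-guest complex.

A continuous-variation series holds the total concentration [H]t + [G]t
fixed while the host mole fraction sweeps the open interval (0, 1).  Under
fast exchange each proton j of sample i shows a shift change

    ddelta(i,j) = delta_free(j) - delta_obs(i,j) = ddelta_c(j) * c_i / [X]_i

where c_i is the equilibrium complex concentration and [X]_i the total of
the species bearing proton j.  Two inferences follow:

* stoichiometry — the Job curve |ddelta| * [X] versus r = [X]/([H]+[G])
  peaks at r = 0.5 for a 1:1 complex;
* affinity — for a trial K the per-proton amplitudes ddelta_c(j) enter the
  model linearly, so the global least-squares fit reduces to a 1-D search
  over K with closed-form amplitudes (conditional linearity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .binding_core import EquilibriumSpec, complex_concentration
from .errors import (
    DegenerateCurveError,
    IdentifiabilityError,
    MissingObservationError,
    ValidationError,
)

HOST = "host"
GUEST = "guest"

#: Default search bounds for the association constant, M^-1.
DEFAULT_K_BOUNDS = (1.0, 1e7)

#: Mole-fraction bands mapping the Job-curve maximum to a stoichiometry label.
STOICHIOMETRY_BANDS = (
    ((0.45, 0.55), "1:1"),
    ((0.30, 0.37), "1:2"),
    ((0.63, 0.70), "2:1"),
)


@dataclass(frozen=True)
class ProtonAssignment:
    """One observed proton: its label, which species bears it, and its
    free-state chemical shift (ppm)."""

    label: str
    species: str
    delta_free: float

    def __post_init__(self) -> None:
        if self.species not in (HOST, GUEST):
            raise ValidationError(f"species must be 'host' or 'guest', got {self.species!r}")
        if not math.isfinite(self.delta_free):
            raise ValidationError(f"delta_free must be finite for proton {self.label!r}")


@dataclass(frozen=True)
class CVSample:
    """One continuous-variation sample: totals (M) and observed shifts (ppm).

    ``observed_shifts`` maps proton label -> delta_obs; a missing key means
    the proton was not observed in this sample (e.g. the species is absent).
    """

    sample_id: int
    host_total: float
    guest_total: float
    observed_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.host_total < 0 or self.guest_total < 0:
            raise ValidationError(f"sample {self.sample_id}: negative total concentration")
        if self.host_total + self.guest_total <= 0:
            raise ValidationError(f"sample {self.sample_id}: empty sample")
        for label, value in self.observed_shifts.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"sample {self.sample_id}: non-finite shift for proton {label!r}"
                )

    def species_total(self, species: str) -> float:
        return self.host_total if species == HOST else self.guest_total


@dataclass(frozen=True)
class CVDataset:
    """A continuous-variation series at constant total concentration (M)."""

    samples: tuple[CVSample, ...]
    assignments: tuple[ProtonAssignment, ...]
    total_concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "assignments", tuple(self.assignments))
        labels = [a.label for a in self.assignments]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate proton labels in assignments")
        for s in self.samples:
            if abs(s.host_total + s.guest_total - self.total_concentration) > 1e-9:
                raise ValidationError(
                    f"sample {s.sample_id}: host+guest total "
                    f"{s.host_total + s.guest_total:g} M deviates from the series "
                    f"total {self.total_concentration:g} M"
                )

    def assignment(self, label: str) -> ProtonAssignment:
        for a in self.assignments:
            if a.label == label:
                return a
        raise KeyError(f"no assignment for proton {label!r}")

    @property
    def proton_labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.assignments)


@dataclass(frozen=True)
class JobPlotCurve:
    """Job curve of one proton: r_i, y_i = |ddelta_i| * [X]_i, and the
    parabola-estimated peak location."""

    label: str
    r: np.ndarray
    y: np.ndarray
    r_max: float


@dataclass(frozen=True)
class JobPlotResult:
    curves: tuple[JobPlotCurve, ...]
    r_max: float
    inferred_ratio: str


@dataclass(frozen=True)
class NMRFitResult:
    """Global continuous-variation fit: K (M^-1), per-proton amplitudes
    ddelta_c (ppm), residual sum of squares E (ppm^2), pooled Pearson
    correlation between observed and calculated shift changes."""

    K: float
    delta_c: dict[str, float]
    E: float
    correlation_r: float
    n_points: int
    converged: bool


def observed_delta(sample: CVSample, assignment: ProtonAssignment) -> float:
    """Shift change ddelta = delta_free - delta_obs (ppm), sign preserved."""
    try:
        obs = sample.observed_shifts[assignment.label]
    except KeyError:
        raise MissingObservationError(
            f"proton {assignment.label!r} not observed in sample {sample.sample_id}"
        ) from None
    return assignment.delta_free - obs


def _proton_table(
    dataset: CVDataset, assignment: ProtonAssignment
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrays (host_total, guest_total/X, ddelta) over samples where the
    proton is observed and its species present.  Returns (H, G, X, dd)."""
    H, G, X, dd = [], [], [], []
    for s in dataset.samples:
        x = s.species_total(assignment.species)
        if x <= 0 or assignment.label not in s.observed_shifts:
            continue
        H.append(s.host_total)
        G.append(s.guest_total)
        X.append(x)
        dd.append(observed_delta(s, assignment))
    return np.asarray(H), np.asarray(G), np.asarray(X), np.asarray(dd)


def estimate_shift_noise(dataset: CVDataset) -> float:
    """Pooled estimate of the per-observation shift noise sd (ppm).

    Uses second differences of each proton's shift-change curve ordered by
    mole fraction: second-differencing annihilates the locally linear part
    of the smooth binding curve, and var(d2) = 6 sigma^2 for iid noise.
    Returns 0 for noiseless data.
    """
    estimates = []
    for a in dataset.assignments:
        H, G, X, dd = _proton_table(dataset, a)
        if dd.size < 4:
            continue
        r = X / (H + G)
        dd_sorted = dd[np.argsort(r)]
        d2 = np.diff(dd_sorted, n=2)
        if d2.size:
            estimates.append(float(np.std(d2) / math.sqrt(6.0)))
    return float(np.median(estimates)) if estimates else 0.0


def _parabola_peak(r: np.ndarray, y: np.ndarray) -> float:
    """Abscissa of the parabola vertex through the points near the maximum
    (all points with y >= 0.8 * max y, at least three)."""
    keep = y >= 0.8 * y.max()
    if keep.sum() < 3:
        keep = np.argsort(y)[-3:]
    r_sel, y_sel = r[keep], y[keep]
    a, b, _ = np.polyfit(r_sel, y_sel, 2)
    if a >= 0:  # degenerate: no downward curvature near the peak
        return float(r[np.argmax(y)])
    return float(-b / (2.0 * a))


def build_job_plot(dataset: CVDataset, protons: list[str] | None = None) -> JobPlotResult:
    """Continuous-variation (Job) analysis of complex stoichiometry.

    For each selected proton j the curve y_i = |ddelta(i,j)| * [X]_i is
    built against r_i = [X]_i / ([H]_i + [G]_i), where [X] is the total of
    the species bearing j.  The peak location of each curve is estimated by
    a parabola fit through the points within 80% of the maximum; the
    reported ``r_max`` is the median across protons, mapped to a
    stoichiometry label through fixed mole-fraction bands (0.5 <-> 1:1).
    """
    labels = list(protons) if protons is not None else list(dataset.proton_labels)
    curves = []
    for label in labels:
        a = dataset.assignment(label)
        H, G, X, dd = _proton_table(dataset, a)
        if X.size < 5:
            raise ValidationError(
                f"proton {label!r}: need >= 5 samples with the species present, got {X.size}"
            )
        y = np.abs(dd) * X
        r = X / (H + G)
        if np.allclose(y, 0.0):
            raise DegenerateCurveError(f"proton {label!r}: all shift changes are zero")
        order = np.argsort(r)
        r, y = r[order], y[order]
        curves.append(JobPlotCurve(label=label, r=r, y=y, r_max=_parabola_peak(r, y)))
    r_max = float(np.median([c.r_max for c in curves]))
    if not 0.0 < r_max < 1.0:
        raise DegenerateCurveError(f"estimated r_max={r_max:g} outside (0, 1)")
    ratio = "indeterminate"
    for (lo, hi), label in STOICHIOMETRY_BANDS:
        if lo <= r_max <= hi:
            ratio = label
            break
    return JobPlotResult(curves=tuple(curves), r_max=r_max, inferred_ratio=ratio)


def select_protons(dataset: CVDataset, noise_factor: float = 3.0) -> list[str]:
    """Default proton subset: those whose largest |ddelta| clears
    ``noise_factor`` times the pooled shift-noise estimate."""
    noise = estimate_shift_noise(dataset)
    selected = []
    for a in dataset.assignments:
        _, _, _, dd = _proton_table(dataset, a)
        if dd.size and np.max(np.abs(dd)) >= noise_factor * noise and np.any(dd != 0):
            selected.append(a.label)
    return selected


def _fit_at_k(
    K: float,
    tables: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[float, dict[str, float]]:
    """Residual sum of squares E(K) with closed-form amplitudes.

    For fixed K the model is linear in each ddelta_c(j):
    ddelta_c(j) = sum_i x_ij dd_ij / sum_i x_ij^2 with x_ij = c_i / [X]_i.
    """
    E = 0.0
    amps: dict[str, float] = {}
    for label, (H, G, X, dd) in tables.items():
        c = np.array(
            [complex_concentration(EquilibriumSpec(h, g, K)) for h, g in zip(H, G)]
        )
        x = c / X
        sxx = float(x @ x)
        amp = float(x @ dd) / sxx if sxx > 0 else 0.0
        amps[label] = amp
        resid = dd - amp * x
        E += float(resid @ resid)
    return E, amps


def fit_association_constant(
    dataset: CVDataset,
    protons: list[str] | None = None,
    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    n_grid: int = 200,
) -> NMRFitResult:
    """Global least-squares fit of the association constant to a
    continuous-variation series.

    Minimises E = sum_{i,j} (ddelta(i,j) - ddelta_calc(i,j))^2 over K and
    the per-proton amplitudes.  The amplitudes are profiled out in closed
    form at each trial K, leaving a 1-D problem in log10 K solved by a
    deterministic log-spaced grid scan followed by golden-section
    refinement.  ``converged`` is False when the optimum pins to a search
    bound.
    """
    labels = list(protons) if protons is not None else select_protons(dataset)
    if not labels:
        raise IdentifiabilityError("no proton shows shift changes above the noise level")
    tables = {}
    for label in labels:
        a = dataset.assignment(label)
        H, G, X, dd = _proton_table(dataset, a)
        if dd.size < 3:
            raise ValidationError(f"proton {label!r}: need >= 3 observations, got {dd.size}")
        tables[label] = (H, G, X, dd)

    all_dd = np.concatenate([t[3] for t in tables.values()])
    if np.allclose(all_dd, 0.0):
        raise IdentifiabilityError("all observed shift changes are zero")
    fractions = np.concatenate(
        [t[2] / (t[0] + t[1]) for t in tables.values()]  # r of each (i, j) point
    )
    if np.ptp(fractions) == 0.0:
        raise IdentifiabilityError("all samples share one composition; K is not identifiable")

    lo, hi = math.log10(k_bounds[0]), math.log10(k_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    energies = np.array([_fit_at_k(10.0**g, tables)[0] for g in grid])
    i_best = int(np.argmin(energies))

    def objective(logk: float) -> float:
        return _fit_at_k(10.0**logk, tables)[0]

    converged = 0 < i_best < n_grid - 1
    if converged:
        bracket = (grid[i_best - 1], grid[i_best], grid[i_best + 1])
        try:
            res = minimize_scalar(objective, bracket=bracket, method="golden",
                                  options={"xtol": 1e-12})
            logk_hat = float(res.x)
        except (ValueError, RuntimeError):
            res = minimize_scalar(objective, bounds=(bracket[0], bracket[2]),
                                  method="bounded", options={"xatol": 1e-12})
            logk_hat = float(res.x)
        logk_hat = min(max(logk_hat, lo), hi)
    else:
        logk_hat = grid[i_best]

    K_hat = 10.0**logk_hat
    E, amps = _fit_at_k(K_hat, tables)

    observed, calculated = [], []
    for label, (H, G, X, dd) in tables.items():
        c = np.array([complex_concentration(EquilibriumSpec(h, g, K_hat)) for h, g in zip(H, G)])
        observed.append(dd)
        calculated.append(amps[label] * c / X)
    obs = np.concatenate(observed)
    calc = np.concatenate(calculated)
    denom = float(np.std(obs) * np.std(calc))
    corr = float(np.corrcoef(obs, calc)[0, 1]) if denom > 0 else 0.0

    return NMRFitResult(
        K=K_hat,
        delta_c=amps,
        E=E,
        correlation_r=corr,
        n_points=int(obs.size),
        converged=converged,
    )
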