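"""Core 1:1 binding models shared by every pipeline stage.

The host H (here a cyclodextrin) and guest G associate with equilibrium
constant K (M^-1):

    H + G <-> HG,   K = [HG] / ([H][G])

Everything else in the package — the fast-exchange NMR shift model, the
single-class-of-sites ITC isotherm, and the thermodynamic decomposition
dG = -RT ln K = dH - T dS — is built on the closed-form solution of this
mass-action equilibrium at known totals.

All quantities are SI internally: concentrations in M, volumes in L,
molar energies in J/mol.  Reporting layers convert to the conventional
mM / uJ / kJ-per-mol units at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

#: CODATA molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Default experiment temperature (25 degC), K.
T_STANDARD = 298.15


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class EquilibriumSpec:
    """Total concentrations and association constant of one 1:1 equilibrium.

    Parameters
    ----------
    host_total, guest_total
        Analytical (total) concentrations of host and guest, M.
    K
        Association constant, M^-1.
    """

    host_total: float
    guest_total: float
    K: float

    def __post_init__(self) -> None:
        for name in ("host_total", "guest_total", "K"):
            _require_finite(name, getattr(self, name))
        if self.host_total < 0 or self.guest_total < 0:
            raise ValidationError(
                "total concentrations must be non-negative: "
                f"host_total={self.host_total}, guest_total={self.guest_total}"
            )
        if self.K <= 0:
            raise ValidationError(f"association constant K must be positive, got {self.K}")


def complex_concentration(spec: EquilibriumSpec) -> float:
    """Equilibrium complex concentration [HG] (M) for a 1:1 association.

    Solves K (H - c)(G - c) = c for the root c in [0, min(H, G)].  The
    quadratic is evaluated in the product form

        c = 2 H G / (b + sqrt(b^2 - 4 H G)),   b = H + G + 1/K

    which is algebraically identical to the textbook (b - sqrt(...))/2 root
    but immune to catastrophic cancellation when 4HG << b^2 (weak binding
    or strongly unequal totals).
    """
    H, G, K = spec.host_total, spec.guest_total, spec.K
    if H == 0.0 or G == 0.0:
        return 0.0
    b = H + G + 1.0 / K
    disc = b * b - 4.0 * H * G
    # disc >= (H - G)^2 + 2(H + G)/K + 1/K^2 > 0; clip only guards rounding.
    root = math.sqrt(max(disc, 0.0))
    c = 2.0 * H * G / (b + root)
    return min(c, H, G)


def fast_exchange_shift(
    spec: EquilibriumSpec, delta_c: float, observed_species_total: float
) -> float:
    """Population-weighted chemical-shift change ddelta (ppm) under fast exchange.

    A proton on a species with total concentration [X] (either the host or
    the guest total of ``spec``) shows a single resonance displaced from its
    free-state position by

        ddelta = ddelta_c * [HG] / [X]

    where ``delta_c`` is the complexation-induced shift amplitude (ppm), the
    limiting change at full complexation.  Signed: ``delta_c`` may be
    negative for protons that move downfield on binding.
    """
    _require_finite("delta_c", delta_c)
    x = _require_finite("observed_species_total", observed_species_total)
    if x <= 0:
        raise ValidationError(
            "observed_species_total must be positive; samples where the observed "
            "species is absent carry no resonance and must be excluded"
        )
    return delta_c * complex_concentration(spec) / x


def itc_cumulative_heat(
    n: float,
    K: float,
    dH: float,
    macromolecule_total: float,
    titrant_total: float,
    cell_volume: float,
) -> float:
    """Cumulative heat Q (J) of the single-class-of-sites ITC isotherm.

    For a macromolecule at total concentration M_t carrying ``n`` identical,
    independent sites, titrated to total ligand concentration X_t in a cell
    of volume V0, the bound-ligand concentration equals the 1:1 equilibrium
    complex with site total n*M_t, and

        Q = dH * V0 * [bound ligand]

    ``dH`` is the molar binding enthalpy in J/mol (exothermic negative), so
    Q carries the sign of dH.
    """
    for name, value in (("n", n), ("K", K)):
        _require_finite(name, value)
        if value <= 0:
            raise ValidationError(f"{name} must be positive, got {value}")
    _require_finite("dH", dH)
    if cell_volume <= 0:
        raise ValidationError(f"cell_volume must be positive, got {cell_volume}")
    if macromolecule_total < 0 or titrant_total < 0:
        raise ValidationError("concentrations must be non-negative")
    if macromolecule_total == 0.0:
        return 0.0
    bound = complex_concentration(
        EquilibriumSpec(host_total=n * macromolecule_total, guest_total=titrant_total, K=K)
    )
    return dH * cell_volume * bound


def delta_g_from_k(K: float, T: float = T_STANDARD) -> float:
    """Standard Gibbs free energy of association, kJ/mol: dG = -RT ln K."""
    _require_finite("K", K)
    _require_finite("T", T)
    if K <= 0:
        raise ValidationError(f"K must be positive, got {K}")
    if T <= 0:
        raise ValidationError(f"T must be positive, got {T}")
    return -R_GAS * T * math.log(K) / 1000.0


def entropic_term(dH: float, dG: float) -> tuple[float, str]:
    """Entropic contribution T dS (kJ/mol) and the driving-force class.

    T dS = dH - dG.  Classification by sign of the two favorable terms:

    - ``enthalpy-and-entropy-driven`` : dH < 0 and TdS > 0
    - ``enthalpy-driven``             : dH < 0, TdS <= 0
    - ``entropy-driven``              : dH >= 0, TdS > 0
    - ``unfavorable``                 : neither term favorable (dG >= 0)
    """
    _require_finite("dH", dH)
    _require_finite("dG", dG)
    tds = dH - dG
    if dH < 0 and tds > 0:
        label = "enthalpy-and-entropy-driven"
    elif dH < 0:
        label = "enthalpy-driven"
    elif tds > 0:
        label = "entropy-driven"
    else:
        label = "unfavorable"
    return tds, label


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic decomposition of a binding constant at temperature T.

    Energies in kJ/mol.  ``entropy_dominated`` flags |dH| < |TdS|, the
    signature of a hydrophobically driven association.
    """

    K: float
    T: float
    dG: float
    dH: float
    TdS: float
    driving_class: str
    entropy_dominated: bool


def thermo_result(K: float, dH_kJ: float, T: float = T_STANDARD) -> ThermoResult:
    """Build the full ΔG / TΔS decomposition from fitted K and ΔH (kJ/mol)."""
    dG = delta_g_from_k(K, T)
    tds, label = entropic_term(dH_kJ, dG)
    return ThermoResult(
        K=K,
        T=T,
        dG=dG,
        dH=dH_kJ,
        TdS=tds,
        driving_class=label,
        entropy_dominated=abs(dH_kJ) < abs(tds),
    )
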