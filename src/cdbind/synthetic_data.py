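"""Seed-controlled generators emulating the three experiments.

Each generator reproduces one experimental design — the 11-sample
continuous-variation NMR series at 10 mM total, the 25 x 10 uL calorimetric
titration of 4 mM guest into 1 mM host, and the 15 x 30 s DPPH absorbance
reads — from known ground-truth parameters, so every fitting stage can be
exercised and validated without instrument data.

The DPPH kinetic forms are synthetic scaffolding: the free compound
scavenges as a single exponential approach to its plateau, the complex as a
release-then-scavenge two-step (consecutive first-order) process.  They
encode the qualitative fast-plateau vs sustained-release contrast, not a
fitted mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_core import EquilibriumSpec, complex_concentration
from .dpph_assay import DPPHTrace
from .errors import ValidationError
from .itc_analysis import ITCData, ITCProtocol, predicted_injection_heats
from .nmr_titration import GUEST, HOST, CVDataset, CVSample, ProtonAssignment

#: Free-state chemical shifts (ppm) of the guest protons, with conventional
#: placeholder values for the host cavity protons H3/H5 (configurable).
DEFAULT_DELTA_FREE: dict[str, tuple[str, float]] = {
    "Ha": (GUEST, 7.029),
    "Hb": (GUEST, 6.801),
    "Hc": (GUEST, 7.137),
    "Hd": (GUEST, 7.843),
    "He": (GUEST, 6.387),
    "Hf": (GUEST, 2.145),
    "H3": (HOST, 3.830),
    "H5": (HOST, 3.520),
}

#: Default complexation-shift amplitudes (ppm); Hd, on the hydrazone bridge,
#: moves the most.  One negative amplitude exercises the sign convention.
DEFAULT_DELTA_C: dict[str, float] = {
    "Ha": 0.05,
    "Hb": 0.08,
    "Hc": 0.12,
    "Hd": 0.30,
    "He": -0.06,
    "Hf": 0.05,
    "H3": 0.10,
    "H5": 0.15,
}


@dataclass(frozen=True)
class NMRGenConfig:
    """Continuous-variation series design: 11 samples at 10 mM total."""

    K: float = 6.181e3  # M^-1
    delta_c: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTA_C))
    delta_free: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_FREE)
    )
    total_concentration: float = 0.010  # M
    n_samples: int = 11
    shift_noise_sd: float = 0.001  # ppm

    def __post_init__(self) -> None:
        if self.K <= 0 or self.total_concentration <= 0:
            raise ValidationError("K and total_concentration must be positive")
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")
        if self.shift_noise_sd < 0:
            raise ValidationError("shift_noise_sd must be >= 0")


@dataclass(frozen=True)
class ITCGenConfig:
    """Titration of 4 mM guest into a 1 mL cell of 1 mM host, 25 x 10 uL."""

    n: float = 1.098
    K: float = 3.92e3  # M^-1
    dH: float = -2.36  # kJ/mol
    cell_volume: float = 1.0e-3  # L
    cell_concentration: float = 1.0e-3  # M
    syringe_concentration: float = 4.0e-3  # M
    injection_volume: float = 10.0e-6  # L
    n_injections: int = 25
    temperature: float = 298.15  # K
    heat_noise_sd: float = 0.02  # fraction of max |heat|
    control_heat: float | None = None  # constant blank heat (J), optional

    def protocol(self) -> ITCProtocol:
        return ITCProtocol(
            cell_volume=self.cell_volume,
            cell_concentration=self.cell_concentration,
            syringe_concentration=self.syringe_concentration,
            injection_volumes=(self.injection_volume,) * self.n_injections,
            temperature=self.temperature,
        )


@dataclass(frozen=True)
class DPPHGenConfig:
    """Absorbance at 517 nm read every 30 s, 15 times, at three sample
    concentrations; plateau levels rise with concentration."""

    s_max: dict[float, float] = field(
        default_factory=lambda: {62.5: 25.0, 125.0: 45.0, 250.0: 80.0}  # uM -> %
    )
    k_fast: float = 0.02  # s^-1, direct scavenging rate
    k_release: float = 0.002  # s^-1, release from the cavity
    read_interval: float = 30.0  # s
    n_reads: int = 15
    control_absorbance: float = 1.0  # AU
    absorbance_noise_sd: float = 0.002  # AU

    def __post_init__(self) -> None:
        if not self.k_fast > self.k_release > 0:
            raise ValidationError("rates must satisfy k_fast > k_release > 0")
        if self.read_interval <= 0 or self.n_reads < 2:
            raise ValidationError("invalid read schedule")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    nmr: NMRGenConfig = field(default_factory=NMRGenConfig)
    itc: ITCGenConfig = field(default_factory=ITCGenConfig)
    dpph: DPPHGenConfig = field(default_factory=DPPHGenConfig)


def gen_cv_dataset(config: NMRGenConfig, seed: int = 0) -> CVDataset:
    """Simulate a continuous-variation series from known K and amplitudes.

    Guest mole fractions are equally spaced over the open interval (0, 1):
    r_i = i / (n_samples + 1).  Observed shifts follow the fast-exchange
    model with iid Gaussian noise of sd ``shift_noise_sd``.
    """
    rng = np.random.default_rng(seed)
    assignments = tuple(
        ProtonAssignment(label=lab, species=sp, delta_free=df)
        for lab, (sp, df) in config.delta_free.items()
        if lab in config.delta_c
    )
    total = config.total_concentration
    samples = []
    for i in range(1, config.n_samples + 1):
        r = i / (config.n_samples + 1)
        guest = r * total
        host = total - guest
        spec = EquilibriumSpec(host_total=host, guest_total=guest, K=config.K)
        c = complex_concentration(spec)
        shifts = {}
        for a in assignments:
            x = host if a.species == HOST else guest
            if x <= 0:
                continue
            dd = config.delta_c[a.label] * c / x
            noise = rng.normal(0.0, config.shift_noise_sd) if config.shift_noise_sd else 0.0
            shifts[a.label] = a.delta_free - dd + noise
        samples.append(
            CVSample(sample_id=i, host_total=host, guest_total=guest, observed_shifts=shifts)
        )
    return CVDataset(samples=tuple(samples), assignments=assignments, total_concentration=total)


def gen_itc_heats(config: ITCGenConfig, seed: int = 0) -> tuple[ITCProtocol, ITCData]:
    """Simulate integrated injection heats from known (n, K, dH).

    Noise is Gaussian with sd ``heat_noise_sd`` x max |heat|.  When
    ``control_heat`` is set, that constant is added to every injection and
    also reported as the control series, so control subtraction recovers
    the clean signal.
    """
    rng = np.random.default_rng(seed)
    protocol = config.protocol()
    heats = predicted_injection_heats(protocol, config.n, config.K, config.dH * 1000.0)
    if config.heat_noise_sd:
        scale = config.heat_noise_sd * float(np.max(np.abs(heats)))
        heats = heats + rng.normal(0.0, scale, size=heats.size)
    control = None
    if config.control_heat is not None:
        heats = heats + config.control_heat
        control = (config.control_heat,) * protocol.n_injections
    return protocol, ITCData(heats=tuple(heats), control_heats=control)


def _free_curve(t: np.ndarray, s_max: float, k_fast: float) -> np.ndarray:
    return s_max * (1.0 - np.exp(-k_fast * t))


def _complex_curve(t: np.ndarray, s_max: float, k_fast: float, k_release: float) -> np.ndarray:
    # consecutive first-order release-then-scavenge; requires k_fast != k_release
    num = k_fast * np.exp(-k_release * t) - k_release * np.exp(-k_fast * t)
    return s_max * (1.0 - num / (k_fast - k_release))


def gen_dpph_traces(config: DPPHGenConfig, seed: int = 0) -> list[DPPHTrace]:
    """Simulate free-compound and complex traces at each concentration.

    Returns traces labelled ``free_<c>uM`` and ``complex_<c>uM``.  Both
    saturate at the same plateau; the complex lags because release from the
    cavity (rate ``k_release``) precedes scavenging (rate ``k_fast``).
    """
    if config.k_fast == config.k_release:
        raise ValidationError("degenerate rates: k_fast must differ from k_release")
    rng = np.random.default_rng(seed)
    t = config.read_interval * np.arange(1, config.n_reads + 1)
    traces = []
    for conc, s_max in sorted(config.s_max.items()):
        for kind, s in (
            ("free", _free_curve(t, s_max, config.k_fast)),
            ("complex", _complex_curve(t, s_max, config.k_fast, config.k_release)),
        ):
            absorbance = config.control_absorbance * (1.0 - s / 100.0)
            if config.absorbance_noise_sd:
                absorbance = absorbance + rng.normal(
                    0.0, config.absorbance_noise_sd, size=t.size
                )
            absorbance = np.clip(absorbance, 0.0, None)
            traces.append(
                DPPHTrace(
                    label=f"{kind}_{conc:g}uM",
                    concentration=conc,
                    times=tuple(t),
                    absorbances=tuple(absorbance),
                    control_absorbance=config.control_absorbance,
                )
            )
    return traces
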