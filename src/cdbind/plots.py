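"""Optional diagnostic figures: Job curves, ITC isotherm, kinetics overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dpph_assay import DPPHTrace, scavenging_series
from .itc_analysis import ITCData, ITCFitResult, ITCProtocol, concentration_series, predicted_injection_heats
from .nmr_titration import JobPlotResult


def plot_job_curves(result: JobPlotResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in result.curves:
        ax.plot(curve.r, curve.y * 1e3, "o-", label=curve.label, ms=4)
    ax.axvline(result.r_max, color="k", ls="--", lw=0.8)
    ax.set_xlabel("r = [X] / ([H] + [G])")
    ax.set_ylabel(r"|$\Delta\delta$| $\cdot$ [X]  (mM$\cdot$ppm)")
    ax.set_title(f"Continuous variation: r_max = {result.r_max:.3f} ({result.inferred_ratio})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_itc_isotherm(
    protocol: ITCProtocol, data: ITCData, fit: ITCFitResult | None, path: str | Path
) -> None:
    xs, ms = concentration_series(protocol)
    ratio = xs / ms
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ratio, np.asarray(data.heats) * 1e6, "ks", ms=4, label="measured")
    if fit is not None:
        model = predicted_injection_heats(protocol, fit.n, fit.K, fit.dH * 1000.0)
        ax.plot(ratio, model * 1e6, "r-", lw=1, label="fit")
    ax.set_xlabel("molar ratio (titrant / macromolecule)")
    ax.set_ylabel("heat per injection (uJ)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kinetics(traces: list[DPPHTrace], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for trace in traces:
        ax.plot(trace.times, scavenging_series(trace), "o-", ms=3, label=trace.label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("DPPH scavenging (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
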