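"""Simple plots for coverage maps, binding curves and RMSF profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .binding import BindingResult, DisplacementSeries, TitrationSeries, hyperbola, logistic4
from .mapping import CoverageMap
from .structure import RmsfProfile


def plot_coverage(cov: CoverageMap, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(8, 2.5))
    residues = np.arange(1, len(cov.per_residue_intensity) + 1)
    ax.bar(residues, cov.per_residue_intensity, width=1.0, color="#3465a4")
    ax.set_xlabel("residue")
    ax.set_ylabel("summed intensity")
    ax.set_title(title or cov.protein_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_titration(series: TitrationSeries, result: BindingResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    c = np.asarray(series.ligand_conc)
    ax.plot(c, series.signal, "o", color="k", label="data")
    grid = np.linspace(c.min(), c.max(), 200)
    p = result.params
    if {"f0", "fmax", "kd"} <= p.keys():
        ax.plot(grid, hyperbola(grid, p["f0"], p["fmax"], p["kd"]), "-", color="#cc0000",
                label=f"fit (Kd = {result.kd:.2g} uM)")
    ax.set_xlabel("ligand (uM)")
    ax.set_ylabel("fluorescence (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmsf(profiles: Sequence[tuple[str, RmsfProfile]], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    for label, prof in profiles:
        ax.plot(prof.residue_numbers, prof.rmsf, label=label)
    ax.set_xlabel("residue")
    ax.set_ylabel("RMSF (Å)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
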