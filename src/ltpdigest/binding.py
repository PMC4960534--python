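"""Fluorescence binding analysis: saturation and competitive displacement.

The experimental design is a classic tracer assay: a fluorescent fatty
acid (cis-parinaric acid, CPA) gains quantum yield when sequestered inside
the LTP cavity.  Direct titration of CPA into protein gives a saturation
curve whose half-saturation point is the tracer dissociation constant Kd;
titrating a non-fluorescent competitor into a pre-formed LTP:CPA complex
gives a displacement curve whose midpoint is the IC50.  The competitor's
inhibition constant follows from the Cheng-Prusoff relation

    Ki = IC50 / (1 + [tracer] / Kd_tracer)

and the binding free energy from dG = -R T ln(Ki[molar]), reported as a
positive magnitude in kcal/mol.

The fitting API follows the Model -> fit() -> Results idiom:
``SaturationModel(series).fit()`` and ``DisplacementModel(series).fit()``
return a :class:`BindingResult` with estimates, standard errors,
diagnostics and a ``summary()`` table.  By default the free ligand
concentration is approximated by the total added concentration (no
depletion correction), which matches the standard analysis of this assay;
a depletion-corrected quadratic model is available for saturation fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE_K = 298.15


# ---------------------------------------------------------------------------
# data containers

@dataclass(frozen=True)
class TitrationSeries:
    """Direct-titration data: ligand concentration (uM) vs fluorescence."""

    ligand_conc: tuple[float, ...]
    signal: tuple[float, ...]
    protein_conc: float = 0.0
    buffer: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_conc, float)
        if len(c) != len(self.signal):
            raise ValueError("concentration and signal vectors differ in length")
        if len(c) < 4:
            raise ValueError("at least 4 titration points are required")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class DisplacementSeries:
    """Competitive-displacement data with tracer context."""

    competitor_conc: tuple[float, ...]
    signal: tuple[float, ...]
    tracer_conc: float
    tracer_kd: float
    buffer: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.competitor_conc, float)
        if len(c) != len(self.signal):
            raise ValueError("concentration and signal vectors differ in length")
        if len(c) < 5:
            raise ValueError("at least 5 displacement points are required")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.tracer_conc <= 0 or self.tracer_kd <= 0:
            raise ValueError("tracer_conc and tracer_kd must be positive")


# ---------------------------------------------------------------------------
# results

@dataclass
class BindingResult:
    """Estimates and diagnostics from a binding fit.

    Concentration constants are in uM, ``delta_g`` in kcal/mol (positive
    magnitude).  ``stderr`` maps parameter names to standard errors where
    the fit could estimate them.
    """

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    converged: bool
    residual_ss: float
    n_points: int
    kd: float | None = None
    ic50: float | None = None
    ki: float | None = None
    delta_g: float | None = None
    hill_n: float | None = None
    series_label: str = ""

    def summary(self) -> str:
        lines = [
            f"Binding fit: {self.model}" + (f" [{self.series_label}]" if self.series_label else ""),
            f"  converged: {self.converged}   n = {self.n_points}   residual SS = {self.residual_ss:.4g}",
        ]
        for name, value in self.params.items():
            se = self.stderr.get(name)
            se_txt = f" +/- {se:.3g}" if se is not None else ""
            lines.append(f"  {name:>12s} = {value:.4g}{se_txt}")
        derived = []
        if self.kd is not None:
            derived.append(f"Kd = {self.kd:.3g} uM")
        if self.ic50 is not None:
            derived.append(f"IC50 = {self.ic50:.3g} uM")
        if self.ki is not None:
            derived.append(f"Ki = {self.ki:.3g} uM")
        if self.delta_g is not None:
            derived.append(f"dG = {self.delta_g:.3g} kcal/mol")
        if derived:
            lines.append("  " + "   ".join(derived))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# conversions

def cheng_prusoff(ic50: float, tracer_kd: float, tracer_conc: float) -> float:
    """Convert a competitive IC50 into Ki (same concentration units).

    Ki = IC50 / (1 + [tracer]/Kd_tracer); with no tracer present the IC50
    is the Ki itself.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if tracer_kd <= 0:
        raise ValueError("tracer_kd must be positive")
    if tracer_conc < 0:
        raise ValueError("tracer_conc must be non-negative")
    return ic50 / (1.0 + tracer_conc / tracer_kd)


def binding_free_energy(
    ki_uM: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Binding free-energy magnitude -RT ln(Ki) in kcal/mol, Ki in uM."""
    if ki_uM <= 0:
        raise ValueError("ki must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -GAS_CONSTANT_KCAL * temperature * math.log(ki_uM * 1e-6)


# ---------------------------------------------------------------------------
# forward curves (shared with the synthetic-data generators)

def hyperbola(conc: np.ndarray, f0: float, fmax: float, kd: float) -> np.ndarray:
    conc = np.asarray(conc, float)
    return f0 + fmax * conc / (kd + conc)


def hill_curve(conc: np.ndarray, f0: float, fmax: float, kd: float, n: float) -> np.ndarray:
    conc = np.asarray(conc, float)
    cn = np.power(conc, n, where=conc > 0, out=np.zeros_like(conc, dtype=float))
    return f0 + fmax * cn / (kd**n + cn)


def quadratic_binding(
    conc: np.ndarray, f0: float, fmax: float, kd: float, protein_conc: float
) -> np.ndarray:
    """Depletion-corrected (quadratic) bound fraction for total ligand."""
    L = np.asarray(conc, float)
    P = protein_conc
    s = P + L + kd
    bound = (s - np.sqrt(s**2 - 4.0 * P * L)) / (2.0 * P)
    return f0 + fmax * bound


def logistic4(conc: np.ndarray, top: float, bottom: float, ic50: float, slope: float) -> np.ndarray:
    """Four-parameter logistic in concentration (descending for slope > 0)."""
    conc = np.asarray(conc, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, conc / ic50, 0.0)
        val = bottom + (top - bottom) / (1.0 + np.power(ratio, slope))
    return val


def bell_curve(
    conc: np.ndarray,
    base: float,
    peak: float,
    plateau: float,
    ec_rise: float,
    ic50: float,
    h_rise: float,
    h_fall: float,
) -> np.ndarray:
    """Rise-then-fall two-phase displacement curve.

    A rising phase (midpoint ``ec_rise``) models transient co-occupancy of
    the cavity by tracer plus competitor, which boosts tracer fluorescence
    before displacement wins; the falling phase (midpoint ``ic50``) is the
    displacement proper, whose midpoint is the reported IC50.
    """
    conc = np.asarray(conc, float)
    rise = np.where(conc > 0, 1.0 / (1.0 + np.power(ec_rise / np.maximum(conc, 1e-300), h_rise)), 0.0)
    fall = np.where(conc > 0, 1.0 / (1.0 + np.power(np.maximum(conc, 1e-300) / ic50, h_fall)), 1.0)
    return base + (peak - base) * rise + (plateau - peak) * (1.0 - fall)


# ---------------------------------------------------------------------------
# models

class SaturationModel:
    """Saturation-binding model for a direct tracer titration."""

    def __init__(self, series: TitrationSeries):
        self.series = series

    @classmethod
    def from_file(cls, path: str | Path) -> "SaturationModel":
        series, _ = read_titration(path)
        return cls(series)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc_col: str = "concentration_uM", signal_col: str = "signal", **meta
    ) -> "SaturationModel":
        return cls(
            TitrationSeries(
                ligand_conc=tuple(df[conc_col].astype(float)),
                signal=tuple(df[signal_col].astype(float)),
                **meta,
            )
        )

    def fit(
        self,
        model: str = "hyperbola",
        depletion_correction: bool = False,
        weights: Sequence[float] | None = None,
    ) -> BindingResult:
        c = np.asarray(self.series.ligand_conc, float)
        y = np.asarray(self.series.signal, float)
        span = y.max() - y.min()
        if span == 0:
            raise ValueError("degenerate (flat) signal cannot be fitted")
        if model not in ("hyperbola", "hill"):
            raise ValueError("model must be 'hyperbola' or 'hill'")
        if depletion_correction and self.series.protein_conc <= 0:
            raise ValueError("depletion correction requires protein_conc > 0")

        half = y.min() + span / 2.0
        kd0 = float(np.interp(half, y, c)) or float(np.median(c[c > 0]))
        params = Parameters()
        params.add("f0", value=float(y[0]))
        params.add("fmax", value=float(span), min=1e-12)
        params.add("kd", value=max(kd0, 1e-9), min=1e-12)
        if model == "hill":
            params.add("n", value=1.0, min=0.05, max=10.0)

        w = np.asarray(weights, float) if weights is not None else np.ones_like(y)

        def residual(p):
            if depletion_correction:
                pred = quadratic_binding(
                    c, p["f0"], p["fmax"], p["kd"], self.series.protein_conc
                )
            elif model == "hill":
                pred = hill_curve(c, p["f0"], p["fmax"], p["kd"], p["n"])
            else:
                pred = hyperbola(c, p["f0"], p["fmax"], p["kd"])
            return (pred - y) * w

        out = minimize(residual, params)
        if not out.success:
            raise RuntimeError(f"saturation fit did not converge: {out.message}")
        est = {k: float(v.value) for k, v in out.params.items()}
        err = {k: (float(v.stderr) if v.stderr is not None else None) for k, v in out.params.items()}
        return BindingResult(
            model=("quadratic" if depletion_correction else model),
            params=est,
            stderr=err,
            converged=bool(out.success),
            residual_ss=float(np.sum(out.residual**2)),
            n_points=len(y),
            kd=est["kd"],
            hill_n=est.get("n", 1.0),
            series_label=self.series.label or self.series.buffer,
        )


class DisplacementModel:
    """Competitive-displacement model; fit() reports IC50, Ki and dG."""

    def __init__(self, series: DisplacementSeries):
        self.series = series

    @classmethod
    def from_file(cls, path: str | Path) -> "DisplacementModel":
        series, _ = read_displacement(path)
        return cls(series)

    def fit(self, model: str = "logistic4", temperature: float = DEFAULT_TEMPERATURE_K) -> BindingResult:
        c = np.asarray(self.series.competitor_conc, float)
        y = np.asarray(self.series.signal, float)
        span = y.max() - y.min()
        if span == 0:
            raise ValueError("degenerate (flat) signal cannot be fitted")
        if model == "logistic4":
            result = self._fit_logistic4(c, y)
        elif model == "bell":
            result = self._fit_bell(c, y)
        else:
            raise ValueError("model must be 'logistic4' or 'bell'")
        result.ki = cheng_prusoff(result.ic50, self.series.tracer_kd, self.series.tracer_conc)
        result.delta_g = binding_free_energy(result.ki, temperature)
        result.series_label = self.series.label or self.series.buffer
        return result

    def _fit_logistic4(self, c: np.ndarray, y: np.ndarray) -> BindingResult:
        # displacement must reduce signal overall; monotone-rising data
        # indicate co-occupancy and need the bell model
        if y[-1] >= y[0]:
            raise ValueError(
                "signal does not decrease with competitor; use model='bell'"
            )
        half = (y[0] + y[-1]) / 2.0
        pos = c[c > 0]
        # first crossing of the half-signal, scanning in concentration order
        below = np.nonzero(y <= half)[0]
        ic50_0 = float(c[below[0]]) if len(below) else float(np.median(pos))
        params = Parameters()
        params.add("top", value=float(y.max()))
        params.add("bottom", value=float(y.min()))
        params.add("ic50", value=max(ic50_0, float(pos.min()) / 10), min=1e-12)
        params.add("slope", value=1.0, min=0.05, max=10.0)

        def residual(p):
            return logistic4(c, p["top"], p["bottom"], p["ic50"], p["slope"]) - y

        out = minimize(residual, params)
        if not out.success:
            raise RuntimeError(f"displacement fit did not converge: {out.message}")
        est = {k: float(v.value) for k, v in out.params.items()}
        err = {k: (float(v.stderr) if v.stderr is not None else None) for k, v in out.params.items()}
        return BindingResult(
            model="logistic4",
            params=est,
            stderr=err,
            converged=bool(out.success),
            residual_ss=float(np.sum(out.residual**2)),
            n_points=len(y),
            ic50=est["ic50"],
            hill_n=est["slope"],
        )

    def _fit_bell(self, c: np.ndarray, y: np.ndarray) -> BindingResult:
        ipeak = int(np.argmax(y))
        if ipeak == 0 or ipeak == len(y) - 1:
            raise ValueError("no interior maximum; data are not bell-shaped")
        cpos = c[c > 0]
        params = Parameters()
        params.add("base", value=float(y[0]))
        params.add("peak", value=float(y[ipeak]))
        params.add("plateau", value=float(y[-1]))
        params.add("ec_rise", value=float(max(c[ipeak] / 3.0, cpos.min() / 2)), min=1e-12)
        params.add("ic50", value=float(max(c[ipeak] * 2.0, cpos.min())), min=1e-12)
        params.add("h_rise", value=1.5, min=0.2, max=10.0)
        params.add("h_fall", value=1.5, min=0.2, max=10.0)

        def residual(p):
            return (
                bell_curve(
                    c, p["base"], p["peak"], p["plateau"],
                    p["ec_rise"], p["ic50"], p["h_rise"], p["h_fall"],
                )
                - y
            )

        out = minimize(residual, params)
        if not out.success:
            raise RuntimeError(f"bell fit did not converge: {out.message}")
        est = {k: float(v.value) for k, v in out.params.items()}
        err = {k: (float(v.stderr) if v.stderr is not None else None) for k, v in out.params.items()}
        return BindingResult(
            model="bell",
            params=est,
            stderr=err,
            converged=bool(out.success),
            residual_ss=float(np.sum(out.residual**2)),
            n_points=len(y),
            ic50=est["ic50"],
            hill_n=est["h_fall"],
        )


# ---------------------------------------------------------------------------
# tabular recomputation and file I/O

def recompute_binding_table(
    table: pd.DataFrame, temperature: float = DEFAULT_TEMPERATURE_K
) -> pd.DataFrame:
    """Add Cheng-Prusoff ``ki_uM`` and ``dg_kcal_mol`` columns to a table
    holding ``ic50_uM``, ``tracer_kd_uM`` and ``tracer_conc_uM``."""
    out = table.copy()
    out["ki_uM"] = [
        cheng_prusoff(r.ic50_uM, r.tracer_kd_uM, r.tracer_conc_uM)
        for r in out.itertuples()
    ]
    out["dg_kcal_mol"] = [binding_free_energy(k, temperature) for k in out["ki_uM"]]
    return out


_META_KEYS = ("protein", "protein_conc_uM", "tracer_conc_uM", "tracer_kd_uM", "buffer", "label")


def _read_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line.lstrip("#").split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_titration(path: str | Path) -> tuple[TitrationSeries, dict[str, str]]:
    """Read a delimited titration file with '# key: value' metadata headers."""
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    series = TitrationSeries(
        ligand_conc=tuple(df.iloc[:, 0].astype(float)),
        signal=tuple(df.iloc[:, 1].astype(float)),
        protein_conc=float(meta.get("protein_conc_uM", 0.0)),
        buffer=meta.get("buffer", ""),
        label=meta.get("label", meta.get("protein", "")),
    )
    return series, meta


def read_displacement(path: str | Path) -> tuple[DisplacementSeries, dict[str, str]]:
    meta = _read_metadata(path)
    if "tracer_conc_uM" not in meta or "tracer_kd_uM" not in meta:
        raise ValueError(f"{path}: displacement file needs tracer_conc_uM and tracer_kd_uM headers")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    series = DisplacementSeries(
        competitor_conc=tuple(df.iloc[:, 0].astype(float)),
        signal=tuple(df.iloc[:, 1].astype(float)),
        tracer_conc=float(meta["tracer_conc_uM"]),
        tracer_kd=float(meta["tracer_kd_uM"]),
        buffer=meta.get("buffer", ""),
        label=meta.get("label", meta.get("protein", "")),
    )
    return series, meta


def write_series(
    conc: Sequence[float], signal: Sequence[float], path: str | Path, **metadata
) -> None:
    with open(path, "w") as fh:
        for key in _META_KEYS:
            if key in metadata and metadata[key] is not None:
                fh.write(f"# {key}: {metadata[key]}\n")
        fh.write("concentration_uM\tsignal\n")
        for c, s in zip(conc, signal):
            fh.write(f"{c:.6g}\t{s:.6g}\n")
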