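"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and each
returns the generated object *together with* its ground truth, so recovery
tests can assert against what was actually simulated.  Noise models:

* fluorescence — multiplicative Gaussian noise (a coefficient of
  variation), since fluorescence error scales with signal;
* peak lists — ppm-scale Gaussian mass error on true fragment masses,
  plus "decoy" peaks placed uniformly in the acquisition range but kept at
  least five matching tolerances away from every true mass, so that
  unassignable peaks are unambiguous in tests;
* coordinate ensembles — independent per-axis Gaussian jitter per atom
  (known per-atom sigma), optionally composed with a random rigid motion
  per frame which alignment must remove.

Default parameter values mirror the fluorescence assay this package
models: a tracer Kd of 4.5 uM, twelve-point titrations reaching a few
multiples of Kd, 5% multiplicative noise (triplicate-scale scatter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding import DisplacementSeries, TitrationSeries, hyperbola
from .digestion import TheoreticalFragment, enumerate_fragments
from .mapping import PeakList
from .proteins import ProteinRecord
from .structure import FrameEnsemble, StructureModel


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@dataclass(frozen=True)
class GeneratorSpec:
    """Bundle of noise parameters shared across fixture generators."""

    seed: int = 0
    fluorescence_cv: float = 0.05
    mass_ppm_sigma: float = 50.0
    coord_sigma: float = 0.5
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fluorescence_cv", "mass_ppm_sigma", "coord_sigma", "decoy_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# binding fixtures

@dataclass(frozen=True)
class SyntheticTitration:
    series: TitrationSeries
    kd: float
    f0: float
    fmax: float
    cv: float
    seed: int


def gen_titration(
    kd: float = 4.5,
    fmax: float = 500.0,
    f0: float = 50.0,
    conc_grid: Sequence[float] | None = None,
    cv: float = 0.05,
    seed: int = 0,
    hill_n: float = 1.0,
) -> SyntheticTitration:
    """Saturation curve F = f0 + fmax c^n/(Kd^n + c^n) with multiplicative noise."""
    if conc_grid is None:
        conc_grid = np.concatenate([[0.0], np.geomspace(0.25, 8.0 * kd, 11)])
    c = np.asarray(conc_grid, float)
    if len(c) == 0:
        raise ValueError("concentration grid must be non-empty")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if hill_n == 1.0:
        signal = hyperbola(c, f0, fmax, kd)
    else:
        cn = np.power(c, hill_n, where=c > 0, out=np.zeros_like(c))
        signal = f0 + fmax * cn / (kd**hill_n + cn)
    rng = np.random.default_rng(seed)
    signal = signal * (1.0 + rng.normal(0.0, cv, size=len(c))) if cv > 0 else signal
    return SyntheticTitration(
        series=TitrationSeries(tuple(c), tuple(signal), buffer="synthetic"),
        kd=kd, f0=f0, fmax=fmax, cv=cv, seed=seed,
    )


@dataclass(frozen=True)
class SyntheticDisplacement:
    series: DisplacementSeries
    ki: float
    implied_ic50: float
    descending_midpoint: float
    shape: str
    cv: float
    seed: int


def displacement_curve(
    conc: np.ndarray,
    ki: float,
    tracer_kd: float,
    tracer_conc: float,
    f0: float,
    fmax: float,
    shape: str = "monotone",
    bell_boost: float = 0.8,
    bell_peak_conc: float | None = None,
) -> np.ndarray:
    """Noiseless displacement signal.

    The monotone form follows the competitive-equilibrium bound-tracer
    fraction B(c) = T / (Kd (1 + c/Ki) + T), rescaled so the signal runs
    from f0 + fmax (no competitor) towards f0; its midpoint sits exactly
    at the Cheng-Prusoff IC50 = Ki (1 + T/Kd).  The bell form multiplies
    in a transient co-occupancy enhancement peaking below the IC50.
    """
    c = np.asarray(conc, float)
    bound = tracer_conc / (tracer_kd * (1.0 + c / ki) + tracer_conc)
    rel = bound / (tracer_conc / (tracer_kd + tracer_conc))
    if shape == "bell":
        ic50 = ki * (1.0 + tracer_conc / tracer_kd)
        cpk = bell_peak_conc if bell_peak_conc is not None else ic50 / 3.0
        enhancement = 1.0 + bell_boost * (c / cpk) * np.exp(1.0 - c / cpk)
        rel = rel * enhancement
    elif shape != "monotone":
        raise ValueError("shape must be 'monotone' or 'bell'")
    return f0 + fmax * rel


def _descending_midpoint(conc: np.ndarray, signal: np.ndarray) -> float:
    """Concentration at which the post-peak limb crosses half-way between
    its maximum and its final plateau (log-linear interpolation)."""
    ipeak = int(np.argmax(signal))
    limb_c, limb_y = conc[ipeak:], signal[ipeak:]
    half = (limb_y[0] + limb_y[-1]) / 2.0
    below = np.nonzero(limb_y <= half)[0]
    if len(below) == 0 or below[0] == 0:
        raise ValueError("descending limb does not cross its midpoint")
    j = below[0]
    x0, x1 = np.log(limb_c[j - 1]), np.log(limb_c[j])
    y0, y1 = limb_y[j - 1], limb_y[j]
    return float(np.exp(x0 + (half - y0) / (y1 - y0) * (x1 - x0)))


def gen_displacement(
    ki: float = 3.6,
    tracer_kd: float = 4.5,
    tracer_conc: float = 2.0,
    conc_grid: Sequence[float] | None = None,
    cv: float = 0.05,
    seed: int = 0,
    shape: str = "monotone",
    f0: float = 50.0,
    fmax: float = 500.0,
    bell_boost: float = 0.8,
    bell_peak_conc: float | None = None,
) -> SyntheticDisplacement:
    """Displacement curve with known Ki and implied Cheng-Prusoff IC50."""
    if min(ki, tracer_kd, tracer_conc) <= 0:
        raise ValueError("ki, tracer_kd and tracer_conc must be positive")
    ic50 = ki * (1.0 + tracer_conc / tracer_kd)
    if conc_grid is None:
        conc_grid = np.concatenate([[0.0], np.geomspace(ic50 / 30.0, 40.0 * ic50, 14)])
    c = np.asarray(conc_grid, float)
    clean = displacement_curve(
        c, ki, tracer_kd, tracer_conc, f0, fmax, shape, bell_boost, bell_peak_conc
    )
    midpoint = ic50 if shape == "monotone" else _descending_midpoint(c, clean)
    rng = np.random.default_rng(seed)
    signal = clean * (1.0 + rng.normal(0.0, cv, size=len(c))) if cv > 0 else clean
    return SyntheticDisplacement(
        series=DisplacementSeries(
            tuple(c), tuple(signal), tracer_conc=tracer_conc, tracer_kd=tracer_kd,
            buffer="synthetic",
        ),
        ki=ki, implied_ic50=ic50, descending_midpoint=midpoint,
        shape=shape, cv=cv, seed=seed,
    )


# ---------------------------------------------------------------------------
# peak-list fixtures

@dataclass(frozen=True)
class SyntheticPeakList:
    peaklist: PeakList
    true_fragments: tuple[TheoreticalFragment, ...]
    true_boundaries: tuple[int, ...]
    decoy_mz: tuple[float, ...]
    ppm_sigma: float
    seed: int


def gen_peaklist(
    protein: ProteinRecord,
    true_boundaries: Sequence[int],
    intensity_map: Mapping[tuple[int, int], float] | None = None,
    ppm_sigma: float = 50.0,
    decoy_fraction: float = 0.0,
    seed: int = 0,
    mass_type: str = "average",
    matching_tolerance_ppm: float = 250.0,
    acquisition_range: tuple[float, float] | None = None,
) -> SyntheticPeakList:
    """Peak list for a limited digest with known cut boundaries.

    True peaks sit at the theoretical fragment masses perturbed by
    Normal(0, ppm_sigma) ppm.  If *intensity_map* is given, only the
    listed (start, end) fragments are emitted, at the stated intensities;
    otherwise every limited-digest fragment is emitted at intensity 100.
    Decoys are drawn uniformly in the acquisition range, rejected within
    5 x *matching_tolerance_ppm* of any true mass, and sized so that they
    make up *decoy_fraction* of the final list.
    """
    rng = np.random.default_rng(seed)
    fragments = enumerate_fragments(protein, true_boundaries, mode="limited")
    if intensity_map is not None:
        wanted = dict(intensity_map)
        fragments = [f for f in fragments if (f.start, f.end) in wanted]
        if len(fragments) < len(wanted):
            missing = set(wanted) - {(f.start, f.end) for f in fragments}
            raise ValueError(f"intensity_map intervals not producible: {sorted(missing)}")
    intensities = [
        (intensity_map[(f.start, f.end)] if intensity_map else 100.0) for f in fragments
    ]
    true_mz = np.array(
        [f.mass_avg if mass_type == "average" else f.mass_mono for f in fragments]
    )
    observed = true_mz * (1.0 + rng.normal(0.0, ppm_sigma * 1e-6, size=len(true_mz)))

    if acquisition_range is None:
        acquisition_range = (
            min(700.0, 0.9 * float(true_mz.min())),
            1.1 * float(true_mz.max()),
        )
    lo, hi = acquisition_range

    n_true = len(fragments)
    n_decoys = int(round(n_true * decoy_fraction / (1.0 - decoy_fraction))) if decoy_fraction > 0 else 0
    exclusion = 5.0 * matching_tolerance_ppm * 1e-6
    decoys: list[float] = []
    attempts = 0
    while len(decoys) < n_decoys:
        attempts += 1
        if attempts > 10000 * max(n_decoys, 1):
            raise RuntimeError("could not place decoys outside the exclusion zones")
        mz = rng.uniform(lo, hi)
        if np.all(np.abs(mz - true_mz) / true_mz > exclusion):
            decoys.append(float(mz))
    decoy_intensity = float(np.median(intensities)) if intensities else 100.0
    peaks = sorted(
        [(float(m), float(i)) for m, i in zip(observed, intensities)]
        + [(m, decoy_intensity) for m in decoys]
    )
    return SyntheticPeakList(
        peaklist=PeakList(tuple(peaks), label="synthetic digest", acquisition_range=(lo, hi)),
        true_fragments=tuple(fragments),
        true_boundaries=tuple(sorted(set(true_boundaries))),
        decoy_mz=tuple(decoys),
        ppm_sigma=ppm_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# structural fixtures

def helix_ca_structure(n_residues: int = 30, chain: str = "A") -> StructureModel:
    """Idealised C-alpha trace of an alpha-helix (rise 1.5 A, 100 deg/res)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    coord = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
    return StructureModel(
        chain=np.full(n_residues, chain, dtype="U4"),
        res_id=i + 1,
        res_name=np.full(n_residues, "ALA", dtype="U4"),
        atom_name=np.full(n_residues, "CA", dtype="U6"),
        element=np.full(n_residues, "C", dtype="U2"),
        coord=coord,
    )


@dataclass(frozen=True)
class SyntheticEnsemble:
    ensemble: FrameEnsemble
    per_atom_sigma: np.ndarray
    rigid_motion: bool
    seed: int

    @property
    def expected_rmsf(self) -> np.ndarray:
        """Closed form: isotropic per-axis sigma gives RMSF = sqrt(3) sigma."""
        return np.sqrt(3.0) * self.per_atom_sigma


def gen_ensemble(
    base: StructureModel,
    per_atom_sigma: float | Sequence[float] = 0.5,
    n_frames: int = 1000,
    rigid_motion: bool = False,
    seed: int = 0,
) -> SyntheticEnsemble:
    """Gaussian-jitter ensemble around a base structure.

    Frame f = base + N(0, sigma_i) per axis, optionally followed by a
    random rigid rotation+translation of the whole frame (which RMSF
    alignment must cancel).
    """
    sigma = np.broadcast_to(np.asarray(per_atom_sigma, float), (len(base),)).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames = base.coord[None, :, :] + rng.normal(
        0.0, 1.0, size=(n_frames, len(base), 3)
    ) * sigma[None, :, None]
    if rigid_motion:
        for f in range(n_frames):
            R = _rotation_matrix(rng)
            t = rng.uniform(-20.0, 20.0, size=3)
            frames[f] = frames[f] @ R.T + t
    return SyntheticEnsemble(
        ensemble=FrameEnsemble(base=base, frames=frames),
        per_atom_sigma=sigma,
        rigid_motion=rigid_motion,
        seed=seed,
    )
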