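"""Assignment of observed mass peaks to theoretical fragments and
per-residue coverage analysis.

An observed peak is matched to the theoretical fragment with the smallest
absolute mass error; the error can be bounded in ppm or Da.  Because
linear-mode spectra of small proteins produce a dense candidate space,
every within-tolerance candidate is recorded: a peak with two or more
candidates is flagged ``ambiguous`` rather than silently resolved, though
its best candidate is still used downstream.  Both the average and the
monoisotopic fragment mass are tried and the matching scale is recorded
per assignment.

Coverage maps sum assigned peak intensity over the residues each fragment
spans; cleavage-site calling scores each inter-residue boundary by the
number (and total intensity) of assigned fragments that start or end at
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .digestion import TheoreticalFragment, ppm_error
from .proteins import ProteinRecord


@dataclass(frozen=True)
class PeakList:
    """Observed (m/z, intensity) pairs for one condition."""

    peaks: tuple[tuple[float, float], ...]
    label: str = ""
    acquisition_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        lo, hi = self.acquisition_range
        for mz, inten in self.peaks:
            if not lo <= mz <= hi:
                raise ValueError(f"peak m/z {mz} outside acquisition range {lo}-{hi}")
            if inten < 0:
                raise ValueError(f"negative intensity at m/z {mz}")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


@dataclass(frozen=True)
class Candidate:
    fragment: TheoreticalFragment
    error_ppm: float
    error_da: float
    mass_type_used: str


@dataclass(frozen=True)
class PeakAssignment:
    """Link between one observed peak and its best theoretical fragment."""

    mz: float
    intensity: float
    fragment: TheoreticalFragment | None
    error_ppm: float | None
    error_da: float | None
    mass_type_used: str | None
    status: str  # "assigned" | "unassigned" | "ambiguous"
    candidates: tuple[Candidate, ...] = field(default_factory=tuple)


def read_peaklist(path: str | Path, label: str = "") -> PeakList:
    """Read a two-column delimited text file (m/z, intensity) with header."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    mz = df.iloc[:, 0].astype(float)
    inten = df.iloc[:, 1].astype(float)
    return PeakList(
        peaks=tuple(zip(mz, inten)),
        label=label or str(path),
        acquisition_range=(float(mz.min()), float(mz.max())),
    )


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    pd.DataFrame(peaks.peaks, columns=["mz", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def assign_peaks(
    peaks: PeakList,
    fragments: Sequence[TheoreticalFragment],
    tolerance: float = 250.0,
    tolerance_unit: Literal["ppm", "Da"] = "ppm",
    mass_types: Sequence[str] = ("average", "monoisotopic"),
) -> list[PeakAssignment]:
    """Match each observed peak to its nearest theoretical fragment.

    A fragment is a candidate if its average or monoisotopic mass lies
    within *tolerance* of the peak; the scale that matched is recorded.
    The best (smallest |error|) candidate becomes the assignment; peaks
    with no candidate stay ``unassigned``, peaks with several are
    ``ambiguous`` (best candidate first).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not fragments:
        raise ValueError("fragment list must be non-empty")
    out: list[PeakAssignment] = []
    for mz, inten in peaks.peaks:
        cands: list[Candidate] = []
        for frag in fragments:
            best: Candidate | None = None
            for mass_type in mass_types:
                calc = frag.mass_avg if mass_type == "average" else frag.mass_mono
                err_da = mz - calc
                err_ppm = ppm_error(mz, calc)
                within = (
                    abs(err_ppm) <= tolerance
                    if tolerance_unit == "ppm"
                    else abs(err_da) <= tolerance
                )
                if within and (best is None or abs(err_da) < abs(best.error_da)):
                    best = Candidate(frag, err_ppm, err_da, mass_type)
            if best is not None:
                cands.append(best)
        cands.sort(key=lambda c: abs(c.error_da))
        if not cands:
            out.append(
                PeakAssignment(mz, inten, None, None, None, None, "unassigned")
            )
        else:
            status = "assigned" if len(cands) == 1 else "ambiguous"
            top = cands[0]
            out.append(
                PeakAssignment(
                    mz,
                    inten,
                    top.fragment,
                    top.error_ppm,
                    top.error_da,
                    top.mass_type_used,
                    status,
                    tuple(cands),
                )
            )
    return out


def normalize_intensities(
    peaks: PeakList,
    method: str = "total_ion",
    scale: float = 1000.0,
) -> PeakList:
    """Rescale intensities: ``total_ion`` (sum = scale), ``max_peak``
    (max = scale) or ``external_scale`` (multiply by *scale*; use
    scale=1.0 as a passthrough for already-normalised published values)."""
    inten = peaks.intensity
    if method in ("total_ion", "max_peak") and not np.any(inten > 0):
        raise ValueError("cannot normalise an all-zero peak list")
    if method == "total_ion":
        factor = scale / inten.sum()
    elif method == "max_peak":
        factor = scale / inten.max()
    elif method == "external_scale":
        factor = scale
    else:
        raise ValueError(f"unknown normalisation method '{method}'")
    return PeakList(
        peaks=tuple((mz, i * factor) for (mz, _), i in zip(peaks.peaks, inten)),
        label=peaks.label,
        acquisition_range=peaks.acquisition_range,
    )


@dataclass(frozen=True)
class CoverageMap:
    """Per-residue summed intensity of assigned fragments."""

    per_residue_intensity: np.ndarray
    contributing: tuple[tuple[str, ...], ...]
    protein_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.per_residue_intensity) + 1),
                "intensity": self.per_residue_intensity,
                "fragments": ["|".join(c) for c in self.contributing],
            }
        )


def coverage_map(
    assignments: Iterable[PeakAssignment], protein: ProteinRecord
) -> CoverageMap:
    """Sum assigned peak intensities over the residues each fragment covers."""
    n = len(protein)
    values = np.zeros(n)
    contrib: list[list[str]] = [[] for _ in range(n)]
    for a in assignments:
        if a.fragment is None:
            continue
        if a.fragment.end > n:
            raise ValueError(
                f"fragment {a.fragment.label} does not fit protein of length {n}"
            )
        values[a.fragment.start - 1 : a.fragment.end] += a.intensity
        for i in range(a.fragment.start - 1, a.fragment.end):
            contrib[i].append(a.fragment.label)
    return CoverageMap(values, tuple(tuple(c) for c in contrib), protein.id)


def call_cleavage_sites(
    assignments: Sequence[PeakAssignment],
    min_support: int = 1,
    protein_length: int | None = None,
) -> pd.DataFrame:
    """Rank internal cut boundaries by fragment support.

    A boundary k is supported by every assigned fragment whose start-1 or
    end equals k (a fragment starting at k+1 or ending at k implies a cut
    between k and k+1).  Boundaries at the protein termini are excluded.
    Rank order: support count desc, summed intensity desc, position asc.
    """
    if not any(a.fragment is not None for a in assignments):
        raise ValueError("no assigned fragments to call cleavage sites from")
    if protein_length is None:
        protein_length = max(a.fragment.end for a in assignments if a.fragment)
    support: dict[int, list[PeakAssignment]] = {}
    for a in assignments:
        if a.fragment is None:
            continue
        for k in (a.fragment.start - 1, a.fragment.end):
            if 1 <= k <= protein_length - 1:
                support.setdefault(k, []).append(a)
    rows = [
        {
            "boundary": k,
            "n_fragments": len(v),
            "summed_intensity": sum(a.intensity for a in v),
            "fragments": "|".join(a.fragment.label for a in v),
        }
        for k, v in support.items()
        if len(v) >= min_support
    ]
    df = pd.DataFrame(rows, columns=["boundary", "n_fragments", "summed_intensity", "fragments"])
    if len(df):
        df = df.sort_values(
            ["n_fragments", "summed_intensity", "boundary"],
            ascending=[False, False, True],
        ).reset_index(drop=True)
    return df


def compare_conditions(
    a: Sequence[PeakAssignment],
    b: Sequence[PeakAssignment],
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Per-fragment intensity fold change between two conditions.

    Fold change = intensity_b / intensity_a for fragments assigned in both
    conditions; fragments absent (or zero) in one condition are flagged
    ``not_detected`` in that condition and given no numeric ratio.
    """
    def by_fragment(assignments: Sequence[PeakAssignment]) -> dict[str, float]:
        acc: dict[str, float] = {}
        for x in assignments:
            if x.fragment is not None:
                acc[x.fragment.label] = acc.get(x.fragment.label, 0.0) + x.intensity
        return acc

    ia, ib = by_fragment(a), by_fragment(b)
    rows = []
    for frag in sorted(set(ia) | set(ib), key=lambda s: tuple(map(int, s.split("-")))):
        va, vb = ia.get(frag), ib.get(frag)
        detected_a = va is not None and va > 0
        detected_b = vb is not None and vb > 0
        rows.append(
            {
                "fragment": frag,
                f"intensity_{label_a}": va if va is not None else np.nan,
                f"intensity_{label_b}": vb if vb is not None else np.nan,
                "fold_change": (vb / va) if (detected_a and detected_b) else np.nan,
                "flag": ""
                if (detected_a and detected_b)
                else f"not_detected_in_{label_b if not detected_b else label_a}",
            }
        )
    return pd.DataFrame(rows)
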