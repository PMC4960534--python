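"""Structural flexibility metrics: superposition RMSD, solvent-accessible
surface area, and per-residue fluctuation over coordinate ensembles.

Superposition uses the closed-form least-squares rigid transform (Kabsch):
paired atoms are centred, the covariance matrix is decomposed by SVD and
the rotation determinant is corrected to +1 so reflections are never
returned.  SASA follows Shrake-Rupley: each atom's sphere (vdW radius +
probe) is sampled with a deterministic quasi-uniform point set and the
fraction of points outside every neighbouring expanded sphere gives the
exposed area.  RMSF removes global translation/rotation by superposing
every frame onto a reference (first frame by convention, mean available)
before measuring fluctuations about the mean position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from ._config import default_config

Selection = str | Callable[["StructureModel", int], bool] | None


@dataclass(frozen=True)
class StructureModel:
    """Atomic model: parallel arrays of per-atom annotation plus coordinates."""

    chain: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    model_id: int | str = 1

    def __post_init__(self) -> None:
        n = len(self.coord)
        for name in ("chain", "res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation '{name}' length mismatch")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coord)

    def mask(self, selection: Selection) -> np.ndarray:
        """Boolean mask for a selection: None/'all', an atom name such as
        'CA', 'backbone', 'heavy', or a callable predicate."""
        if selection is None or selection == "all":
            return np.ones(len(self), bool)
        if callable(selection):
            return np.array([bool(selection(self, i)) for i in range(len(self))])
        if selection == "backbone":
            return np.isin(self.atom_name, ("N", "CA", "C", "O"))
        if selection == "heavy":
            return self.element != "H"
        if selection == "sidechain":
            return ~np.isin(self.atom_name, ("N", "CA", "C", "O")) & (self.element != "H")
        return self.atom_name == selection

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain[mask], self.res_id[mask], self.res_name[mask],
            self.atom_name[mask], self.element[mask], self.coord[mask],
            self.model_id,
        )

    def with_coord(self, coord: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain, self.res_id, self.res_name, self.atom_name,
            self.element, np.asarray(coord, float), self.model_id,
        )

    @classmethod
    def from_atom_array(cls, atoms: bst.AtomArray, model_id: int | str = 1) -> "StructureModel":
        return cls(
            chain=np.asarray(atoms.chain_id, dtype="U4"),
            res_id=np.asarray(atoms.res_id, int),
            res_name=np.asarray(atoms.res_name, dtype="U4"),
            atom_name=np.asarray(atoms.atom_name, dtype="U6"),
            element=np.asarray(atoms.element, dtype="U2"),
            coord=np.asarray(atoms.coord, float),
            model_id=model_id,
        )

    def to_atom_array(self) -> bst.AtomArray:
        atoms = bst.AtomArray(len(self))
        atoms.chain_id = self.chain
        atoms.res_id = self.res_id
        atoms.res_name = self.res_name
        atoms.atom_name = self.atom_name
        atoms.element = self.element
        atoms.coord = self.coord.astype(np.float32)
        atoms.hetero = np.zeros(len(self), bool)
        return atoms


def read_pdb(path: str | Path, model: int | None = 1) -> StructureModel:
    """Read one model from a PDB file (alternate locations resolved by
    highest occupancy)."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    return StructureModel.from_atom_array(atoms, model_id=model or 1)


def read_pdb_models(path: str | Path) -> list[StructureModel]:
    """Read every model of a (possibly multi-model NMR) PDB file."""
    pdb = PDBFile.read(str(path))
    count = pdb.get_model_count()
    return [
        StructureModel.from_atom_array(
            pdb.get_structure(model=i, altloc="occupancy"), model_id=i
        )
        for i in range(1, count + 1)
    ]


def write_pdb(path: str | Path, structures: StructureModel | Sequence[StructureModel]) -> None:
    if isinstance(structures, StructureModel):
        structures = [structures]
    stack = bst.stack([s.to_atom_array() for s in structures])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


@dataclass(frozen=True)
class FrameEnsemble:
    """Ordered coordinate frames over a constant atom roster."""

    base: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.base):
            raise ValueError("frames must be (n_frames, n_atoms, 3) over the base roster")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "FrameEnsemble":
        models = read_pdb_models(path)
        return cls(base=models[0], frames=np.stack([m.coord for m in models]))


# ---------------------------------------------------------------------------
# superposition

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform of *mobile* onto *target* (paired points).

    Returns (rotation, translation, rmsd) with ``x @ rotation.T +
    translation`` mapping mobile coordinates onto the target frame; the
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("at least 3 paired atoms are required")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    H = m0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = m0 @ R.T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def pair_atoms(
    mobile: StructureModel, target: StructureModel, selection: Selection = "CA"
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs matched on (residue number, atom name) within the
    selection; residues present in only one structure are dropped."""
    mm, tm = mobile.mask(selection), target.mask(selection)
    t_index = {
        (target.res_id[i], target.atom_name[i]): i
        for i in np.nonzero(tm)[0]
    }
    mi, ti = [], []
    for i in np.nonzero(mm)[0]:
        j = t_index.get((mobile.res_id[i], mobile.atom_name[i]))
        if j is not None:
            mi.append(i)
            ti.append(j)
    return np.array(mi, int), np.array(ti, int)


def superpose(
    mobile: StructureModel, target: StructureModel, selection: Selection = "CA"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of *mobile* onto *target*.

    Atoms are paired by residue number and atom name within *selection*
    (default: all C-alpha pairs).  Returns (rotation, translation, rmsd).
    """
    mi, ti = pair_atoms(mobile, target, selection)
    if len(mi) < 3:
        raise ValueError("fewer than 3 paired atoms in selection")
    return kabsch(mobile.coord[mi], target.coord[ti])


def transform(structure: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    return structure.with_coord(structure.coord @ rotation.T + translation)


# ---------------------------------------------------------------------------
# solvent-accessible surface area

@dataclass(frozen=True)
class ResidueSASA:
    chain: str
    residue_number: int
    residue_name: str
    area: float
    atom_areas: Mapping[str, float]
    probe_radius: float
    n_points: int
    radii_table_id: str


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def atom_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
    config: dict[str, Any] | None = None,
) -> np.ndarray:
    """Per-atom Shrake-Rupley accessible area (A^2); NaN for excluded atoms."""
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a stable estimate")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    cfg = config or default_config()
    table = dict(radii_table or cfg["vdw_radii"])
    table.pop("id", None)
    default = table.pop("default", None)
    keep = structure.mask("heavy") if not include_hydrogens else np.ones(len(structure), bool)
    sub = structure.subset(keep)

    radii = np.empty(len(sub))
    for i, el in enumerate(sub.element):
        el_key = el.capitalize() if el else ""
        if el_key in table:
            radii[i] = table[el_key]
        elif default is not None:
            radii[i] = default
        else:
            raise KeyError(f"no van der Waals radius for element '{el}'")
    expanded = radii + probe_radius

    pts = _sphere_points(n_points)
    tree = cKDTree(sub.coord)
    rmax = expanded.max()
    areas = np.empty(len(sub))
    for i in range(len(sub)):
        sphere = sub.coord[i] + expanded[i] * pts
        neighbors = [j for j in tree.query_ball_point(sub.coord[i], expanded[i] + rmax) if j != i]
        exposed = np.ones(n_points, bool)
        for j in neighbors:
            d2 = np.sum((sphere - sub.coord[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2

    out = np.full(len(structure), np.nan)
    out[keep] = areas
    return out


def sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
    config: dict[str, Any] | None = None,
) -> list[ResidueSASA]:
    """Per-residue solvent-accessible surface area (sum of atom areas)."""
    cfg = config or default_config()
    table_id = (radii_table or cfg["vdw_radii"]).get("id", "custom")
    per_atom = atom_sasa(
        structure, probe_radius, n_points, radii_table, include_hydrogens, config
    )
    results = []
    for chain, res_id in dict.fromkeys(zip(structure.chain, structure.res_id)):
        idx = np.nonzero((structure.chain == chain) & (structure.res_id == res_id))[0]
        atom_areas = {
            structure.atom_name[i]: float(per_atom[i])
            for i in idx
            if np.isfinite(per_atom[i])
        }
        results.append(
            ResidueSASA(
                chain=str(chain),
                residue_number=int(res_id),
                residue_name=str(structure.res_name[idx[0]]),
                area=float(sum(atom_areas.values())),
                atom_areas=atom_areas,
                probe_radius=probe_radius,
                n_points=n_points,
                radii_table_id=str(table_id),
            )
        )
    return results


def residue_sasa(
    structure: StructureModel,
    residue_number: int,
    chain: str | None = None,
    sidechain_only: bool = False,
    **kwargs,
) -> ResidueSASA:
    """SASA of a single residue computed in the context of the whole
    structure (optionally side-chain atoms only)."""
    per_atom = atom_sasa(structure, **kwargs)
    mask = structure.res_id == residue_number
    if chain is not None:
        mask &= structure.chain == chain
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise KeyError(f"residue {residue_number} (chain {chain}) not found")
    if sidechain_only:
        sc = structure.mask("sidechain")
        idx = [i for i in idx if sc[i]]
    atom_areas = {
        structure.atom_name[i]: float(per_atom[i]) for i in idx if np.isfinite(per_atom[i])
    }
    cfg = kwargs.get("config") or default_config()
    table_id = (kwargs.get("radii_table") or cfg["vdw_radii"]).get("id", "custom")
    return ResidueSASA(
        chain=str(structure.chain[idx[0]]) if len(idx) else (chain or ""),
        residue_number=residue_number,
        residue_name=str(structure.res_name[idx[0]]) if len(idx) else "",
        area=float(sum(atom_areas.values())),
        atom_areas=atom_areas,
        probe_radius=kwargs.get("probe_radius", 1.4),
        n_points=kwargs.get("n_points", 960),
        radii_table_id=str(table_id),
    )


def sasa_report_tyr79(
    structures: Mapping[str, Sequence[StructureModel]],
    residue_number: int = 79,
    sidechain_only: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Mean Tyr79 SASA per labelled set of structures (ensemble models or
    asymmetric-unit molecules); entries whose residue 79 is absent or not
    tyrosine are skipped with a warning."""
    rows = []
    for label, members in structures.items():
        areas = []
        for member in members:
            try:
                res = residue_sasa(
                    member, residue_number, sidechain_only=sidechain_only, **kwargs
                )
            except KeyError:
                warnings.warn(f"{label}: residue {residue_number} absent; entry skipped")
                continue
            if res.residue_name != "TYR":
                warnings.warn(
                    f"{label}: residue {residue_number} is {res.residue_name}, not TYR; skipped"
                )
                continue
            areas.append(res.area)
        if areas:
            rows.append(
                {
                    "label": label,
                    "n_models": len(areas),
                    "mean_sasa_A2": float(np.mean(areas)),
                    "sd_sasa_A2": float(np.std(areas, ddof=1)) if len(areas) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["label", "n_models", "mean_sasa_A2", "sd_sasa_A2"])


# ---------------------------------------------------------------------------
# fluctuations

@dataclass(frozen=True)
class RmsfProfile:
    residue_numbers: np.ndarray
    rmsf: np.ndarray  # per residue, Angstrom
    atom_rmsf: np.ndarray  # per reported atom
    align_selection: str
    reference: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.rmsf))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_numbers, "rmsf_A": self.rmsf})


def rmsf(
    ensemble: FrameEnsemble,
    align_selection: Selection = "CA",
    report_selection: Selection = None,
    reference: str = "first_frame",
) -> RmsfProfile:
    """Per-residue RMSF after removing rigid-body motion.

    Every frame is superposed onto the reference (first frame, or the
    mean structure after a first-frame pre-alignment) using the alignment
    selection; RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames, and residue
    values average their reported atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("fluctuation is undefined for a single frame")
    if reference not in ("first_frame", "mean"):
        raise ValueError("reference must be 'first_frame' or 'mean'")
    amask = ensemble.base.mask(align_selection)
    if amask.sum() < 3:
        raise ValueError("alignment selection must contain at least 3 atoms")
    frames = ensemble.frames.astype(float)

    def align_to(frames: np.ndarray, ref_coord: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames)
        for f in range(len(frames)):
            R, t, _ = kabsch(frames[f][amask], ref_coord[amask])
            out[f] = frames[f] @ R.T + t
        return out

    aligned = align_to(frames, frames[0])
    if reference == "mean":
        aligned = align_to(aligned, aligned.mean(axis=0))

    mean_coord = aligned.mean(axis=0)
    atom_fluct = np.sqrt(np.mean(np.sum((aligned - mean_coord) ** 2, axis=2), axis=0))

    rmask = ensemble.base.mask(report_selection)
    res_ids = ensemble.base.res_id
    residues = sorted(set(res_ids[rmask]))
    values = np.array(
        [np.mean(atom_fluct[(res_ids == r) & rmask]) for r in residues]
    )
    return RmsfProfile(
        residue_numbers=np.array(residues, int),
        rmsf=values,
        atom_rmsf=atom_fluct[rmask],
        align_selection=str(align_selection),
        reference=reference,
    )
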