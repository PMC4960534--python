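"""Limited-proteolysis model: cleavage sites, fragment enumeration, masses.

Limited proteolysis of a folded protein cuts only at a few exposed sites,
so the observed products are intervals bounded by *any* two cut points (or
a terminus), not just adjacent ones — a large N-terminal peptide can span
several internal canonical sites.  ``enumerate_fragments`` therefore
defaults to this "limited" model and also offers a conventional
``full_digest`` mode and a bounded missed-cleavage mode.

Masses are residue-additive: fragment mass = Σ residue masses + water,
with the protein's cysteine state applied (see
:mod:`ltpdigest.proteins`).  Both average and monoisotopic scales are
computed; linear-mode MALDI of peptides above ~3 kDa observes average
masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Literal, Sequence

import pandas as pd

from ._config import AMINO_ACIDS, default_config
from .proteins import ProteinRecord

MassType = Literal["average", "monoisotopic"]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut after `cleaves_after` unless the next
    residue is in `blocked_by_next`; `extra_sites` lists documented
    nonstandard cut positions (1-based boundary k = cut between k and k+1)."""

    name: str
    cleaves_after: frozenset[str] = frozenset()
    blocked_by_next: frozenset[str] = frozenset()
    extra_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for attr in ("cleaves_after", "blocked_by_next"):
            residues = getattr(self, attr)
            if not isinstance(residues, frozenset):
                object.__setattr__(self, attr, frozenset(residues))
            bad = set(getattr(self, attr)) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"{attr} contains non-residues: {sorted(bad)}")


def protease(name: str, config: dict[str, Any] | None = None, extra_sites: Sequence[int] = ()) -> ProteaseRule:
    """Build a named rule (``trypsin``, ``chymotrypsin``, ``pepsin``) from config."""
    cfg = config or default_config()
    try:
        entry = cfg["proteases"][name]
    except KeyError as exc:
        raise KeyError(f"no protease rule named '{name}' in config") from exc
    return ProteaseRule(
        name=name,
        cleaves_after=frozenset(entry.get("cleaves_after", [])),
        blocked_by_next=frozenset(entry.get("blocked_by_next", [])),
        extra_sites=tuple(extra_sites),
    )


@dataclass(frozen=True)
class TheoreticalFragment:
    """Residue interval [start, end] (1-based, inclusive) with its masses."""

    start: int
    end: int
    mass_avg: float
    mass_mono: float
    boundary_sites: tuple[str, str] = ("N-term", "C-term")

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def cleavage_sites(
    protein: ProteinRecord, rules: Sequence[ProteaseRule]
) -> list[tuple[int, str]]:
    """Predict inter-residue cut boundaries for a set of protease rules.

    Returns a strictly increasing list of ``(k, rule_names)`` pairs where
    boundary ``k`` means a cut between residues ``k`` and ``k+1``
    (1-based).  The C-terminal position ``len(protein)`` is never a
    boundary.
    """
    if not rules:
        raise ValueError("at least one protease rule is required")
    seq = protein.sequence
    hits: dict[int, list[str]] = {}
    for rule in rules:
        for k in range(1, len(seq)):  # boundary between k and k+1
            if seq[k - 1] in rule.cleaves_after and seq[k] not in rule.blocked_by_next:
                hits.setdefault(k, []).append(rule.name)
        for k in rule.extra_sites:
            if not 1 <= k <= len(seq) - 1:
                raise ValueError(f"extra site {k} outside 1..{len(seq) - 1}")
            hits.setdefault(k, []).append(f"{rule.name}(extra)")
    return [(k, "+".join(sorted(set(hits[k])))) for k in sorted(hits)]


def fragment_mass(
    protein: ProteinRecord,
    start: int,
    end: int,
    mass_type: MassType = "average",
    cys_state: str | None = None,
    config: dict[str, Any] | None = None,
) -> float:
    """Mass (Da) of residues [start, end] under the protein's cysteine state.

    ``cys_state`` overrides the record's own state when given.  Disulfide
    bridges subtract 2 H per bridge fully contained in the interval;
    carbamidomethylation adds one C2H3NO per cysteine.
    """
    if not (1 <= start <= end <= len(protein)):
        raise IndexError(
            f"interval {start}-{end} out of bounds for length {len(protein)}"
        )
    cfg = config or default_config()
    if mass_type not in ("average", "monoisotopic"):
        raise ValueError("mass_type must be 'average' or 'monoisotopic'")
    key = "average" if mass_type == "average" else "monoisotopic"
    table = cfg["residue_masses"][key]
    consts = cfg["constants"]
    state = cys_state if cys_state is not None else protein.cys_state
    segment = protein.sequence[start - 1 : end]
    total = sum(table[a] for a in segment) + consts[f"water_{key}"]
    if state == "disulfide":
        contained = sum(1 for i, j in protein.disulfides if start <= i and j <= end)
        total -= contained * consts[f"disulfide_{key}"]
    elif state == "carbamidomethyl":
        total += segment.count("C") * consts[f"carbamidomethyl_{key}"]
    return total


def enumerate_fragments(
    protein: ProteinRecord,
    boundaries: Sequence[int],
    mode: str = "limited",
    max_missed: int | None = None,
    config: dict[str, Any] | None = None,
    site_labels: dict[int, str] | None = None,
) -> list[TheoreticalFragment]:
    """Enumerate candidate fragments bounded by cut points and termini.

    ``mode='limited'`` yields every interval bounded by any two of
    {N-terminus, boundaries, C-terminus}: C(b+2, 2) fragments for b
    boundaries.  ``mode='full_digest'`` yields only adjacent-boundary
    intervals; ``mode='max_missed'`` (with ``max_missed=n``) allows up to
    n internal boundaries per fragment.
    """
    n = len(protein)
    bset = sorted(set(boundaries))
    if any(not 1 <= b <= n - 1 for b in bset):
        raise ValueError(f"boundaries must lie in 1..{n - 1}")
    if mode not in ("limited", "full_digest", "max_missed"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode == "max_missed" and (max_missed is None or max_missed < 0):
        raise ValueError("mode='max_missed' requires max_missed >= 0")
    cuts = [0, *bset, n]
    labels = dict(site_labels or {})
    labels.setdefault(0, "N-term")
    labels.setdefault(n, "C-term")

    def make(i: int, j: int) -> TheoreticalFragment:
        start, end = cuts[i] + 1, cuts[j]
        return TheoreticalFragment(
            start=start,
            end=end,
            mass_avg=fragment_mass(protein, start, end, "average", config=config),
            mass_mono=fragment_mass(protein, start, end, "monoisotopic", config=config),
            boundary_sites=(
                labels.get(cuts[i], str(cuts[i])),
                labels.get(cuts[j], str(cuts[j])),
            ),
        )

    out = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, len(cuts)):
            missed = j - i - 1
            if mode == "full_digest" and missed > 0:
                continue
            if mode == "max_missed" and missed > max_missed:
                continue
            out.append(make(i, j))
    return out


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return (observed - calculated) / calculated * 1e6


def fragments_to_frame(fragments: Iterable[TheoreticalFragment]) -> pd.DataFrame:
    """Tabulate fragments (columns: start, end, mass_avg, mass_mono, boundary_sites)."""
    return pd.DataFrame(
        [
            {
                "start": f.start,
                "end": f.end,
                "mass_avg": f.mass_avg,
                "mass_mono": f.mass_mono,
                "boundary_sites": "|".join(f.boundary_sites),
            }
            for f in fragments
        ]
    )


def write_fragments(fragments: Iterable[TheoreticalFragment], path: str | Path) -> None:
    fragments_to_frame(fragments).to_csv(path, sep="\t", index=False)
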