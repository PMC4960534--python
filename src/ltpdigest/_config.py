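"""Loader for the plain-text mass-table / protease-rule configuration.

The package ships a single YAML file (``config/masses.yaml``) holding the
average and monoisotopic amino-acid residue masses, the water / disulfide /
carbamidomethyl mass constants, the default protease specificity rules and
the van der Waals radii used for surface-area calculations.  Users may load
a modified copy with :func:`load_config` and pass the result to any
operation that accepts a ``config`` argument.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Any

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load the mass/rule configuration from *path* (or the bundled default)."""
    if path is None:
        text = (
            resources.files("ltpdigest").joinpath("config/masses.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    _validate(cfg)
    return cfg


@functools.lru_cache(maxsize=1)
def default_config() -> dict[str, Any]:
    return load_config(None)


def _validate(cfg: dict[str, Any]) -> None:
    for kind in ("average", "monoisotopic"):
        table = cfg["residue_masses"][kind]
        missing = set(AMINO_ACIDS) - set(table)
        if missing:
            raise ValueError(f"mass table '{kind}' missing residues: {sorted(missing)}")
        if any(v <= 0 for v in table.values()):
            raise ValueError(f"non-positive residue mass in '{kind}' table")
    for key in (
        "water_average",
        "water_monoisotopic",
        "disulfide_average",
        "disulfide_monoisotopic",
        "carbamidomethyl_average",
        "carbamidomethyl_monoisotopic",
    ):
        if key not in cfg["constants"]:
            raise ValueError(f"missing constant '{key}'")
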