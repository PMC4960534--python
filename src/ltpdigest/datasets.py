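"""Bundled reference data for the wheat LTP1 digestibility analyses.

The module exposes, as plain Python/pandas objects:

* the 90-residue mature wheat LTP1 chain (UniProt P24296 numbering, four
  disulfide bridges in the conserved LTP pattern);
* the published MALDI-ToF peak profile of the 120-min duodenal digest of
  wheat LTP, with and without linoleic acid, as observed m/z plus
  normalised relative intensities (the published normalisation is kept
  as-is and not re-scaled);
* the comparative fluorescence binding table for wheat and peach LTPs
  (tracer Kd, competitor IC50) together with the tracer concentrations
  used in each condition.

The MALDI table's calculated-mass column corresponds to
carbamidomethylated cysteines (+57.051 Da per Cys); the bundled wheat
record therefore defaults to ``cys_state="carbamidomethyl"`` so that
in-silico fragment masses line up with the published values.
"""

from __future__ import annotations

import pandas as pd

from .mapping import PeakList
from .proteins import ProteinRecord

#: Mature wheat LTP1 chain (90 residues, UniProt P24296 mature numbering).
WHEAT_LTP1_SEQUENCE = (
    "IDCGHVDSLVRPCLSYVQGGPGPSGQCCDGVKNLHNQARSQSDRQSACNC"
    "LKGIARGIHNLNEDNARSIPPKCGVNLPYTISLNIDCSRV"
)

#: Conserved LTP disulfide pattern (Cys pairs, 1-based mature numbering).
WHEAT_LTP1_DISULFIDES = ((3, 50), (13, 27), (28, 73), (48, 87))

#: Cut boundaries supported by the assigned digest fragments (boundary k =
#: cut between residues k and k+1).  7 is the documented nonstandard
#: chymotryptic Asp7-Ser8 site.
WHEAT_OBSERVED_BOUNDARIES = (7, 16, 34, 39, 56, 61, 67, 79, 89)


def wheat_ltp1(cys_state: str = "carbamidomethyl") -> ProteinRecord:
    """The bundled mature wheat LTP1 record."""
    disulfides = WHEAT_LTP1_DISULFIDES if cys_state == "disulfide" else ()
    return ProteinRecord(
        id="wheat_LTP1",
        sequence=WHEAT_LTP1_SEQUENCE,
        cys_state=cys_state,
        disulfides=disulfides,
    )


#: Fragments additionally confirmed by LC-MS/MS sequencing (the low-mass
#: subset accessible to fragmentation).
MSMS_CONFIRMED = ((17, 39), (57, 67), (68, 79), (80, 90))

# (fragment interval or None, observed m/z, normalised intensity LTP alone,
#  normalised intensity + linoleic acid; None intensity = not detected)
_MALDI_ROWS = [
    ((1, 90), 10063.22, 518.0, 705.0),
    ((1, 34), 3474.74, 160.0, 292.0),
    ((1, 39), 4310.6, 2546.0, 3290.0),
    ((1, 56), 6243.58, 537.0, 1047.0),
    ((1, 67), 7477.3, 214.0, 290.0),
    ((1, 79), 8803.44, 270.0, 2300.0),
    ((17, 39), 2436.75, 805.0, 1290.0),
    ((17, 56), 4370.01, 533.0, None),
    ((17, 61), 4904.39, 90.0, 90.0),
    ((40, 56), 1951.23, 292.0, None),
    ((40, 67), 3185.43, 248.0, 340.0),
    ((40, 79), 4512.11, 128.0, 656.0),
    ((57, 67), 1252.34, 450.0, None),
    ((57, 89), 3739.16, 110.0, 130.0),
    ((68, 79), 1344.71, 334.0, None),
    ((80, 90), 1277.74, 1550.0, 1200.0),
    (None, 3514.0, 2833.0, 1668.0),
    (None, 1098.54, 1320.0, None),
    (None, 2679.24, 1373.0, 1927.0),
    (None, 4334.4, 1027.0, 1070.0),
    (None, 5032.13, 435.0, None),
    (None, 5379.31, 479.0, None),
    (None, 5794.72, 1004.0, None),
    (None, 8673.0, 312.0, 400.0),
]


def wheat_digest_profile() -> pd.DataFrame:
    """Published MALDI-ToF digest profile of wheat LTP1 (both conditions).

    Columns: ``fragment`` ("start-end" or empty for unassigned peaks),
    ``mz_observed``, ``intensity_alone``, ``intensity_linoleic`` (NaN =
    not detected in that condition).
    """
    return pd.DataFrame(
        [
            {
                "fragment": f"{f[0]}-{f[1]}" if f else "",
                "mz_observed": mz,
                "intensity_alone": a,
                "intensity_linoleic": b,
                "msms_confirmed": f in MSMS_CONFIRMED if f else False,
            }
            for f, mz, a, b in _MALDI_ROWS
        ]
    )


def wheat_digest_peaklist(condition: str = "alone") -> PeakList:
    """Observed peak list for one condition ('alone' or 'linoleic')."""
    if condition not in ("alone", "linoleic"):
        raise ValueError("condition must be 'alone' or 'linoleic'")
    idx = 2 if condition == "alone" else 3
    peaks = [(row[1], row[idx]) for row in _MALDI_ROWS if row[idx] is not None]
    label = "LTP alone" if condition == "alone" else "+linoleic acid"
    return PeakList(peaks=tuple(peaks), label=label, acquisition_range=(700.0, 12000.0))


# Comparative binding table: tracer (CPA) Kd per protein/buffer and
# competitor IC50 per ligand, with the tracer concentrations used in each
# displacement experiment (2/1 uM CPA for wheat and 1/0.5 uM for peach at
# pH 7.5 / pH 2.5 respectively).
_BINDING_ROWS = [
    # ligand, buffer, protein, tracer_kd_uM, tracer_conc_uM, ic50_uM, ki_published, dg_published
    ("palmitic acid", "pH 7.5", "wheat", 4.5, 2.0, 5.2, 3.6, 7.41),
    ("palmitic acid", "pH 7.5", "peach", 1.0, 1.0, 1.4, 0.7, 8.39),
    ("linoleic acid", "pH 7.5", "wheat", 4.5, 2.0, 7.6, 5.3, 7.19),
    ("linoleic acid", "pH 7.5", "peach", 1.0, 1.0, 1.6, 0.8, 8.29),
    ("phosphatidyl choline", "pH 7.5", "wheat", 4.5, 2.0, 6.7, 4.6, 7.27),
    ("phosphatidyl choline", "pH 7.5", "peach", 1.0, 1.0, 2.2, 1.1, 8.13),
    ("phosphatidyl choline", "pH 2.5", "wheat", 1.2, 1.0, 5.3, 2.8, 7.55),
    ("phosphatidyl choline", "pH 2.5", "peach", 0.6, 0.5, 1.8, 1.0, 8.17),
    ("phosphatidyl choline (vesicular)", "pH 7.5", "wheat", 4.5, 2.0, 5.6, 3.9, 7.37),
    ("phosphatidyl choline (vesicular)", "pH 7.5", "peach", 1.0, 1.0, 1.5, 0.7, 8.35),
    ("phosphatidyl choline (vesicular)", "pH 2.5", "wheat", 1.2, 1.0, 6.8, 3.6, 7.41),
    ("phosphatidyl choline (vesicular)", "pH 2.5", "peach", 0.6, 0.5, 1.5, 0.8, 8.29),
]


def binding_table() -> pd.DataFrame:
    """Published comparative displacement data for wheat and peach LTPs.

    ``ki_published`` / ``dg_published`` columns carry the printed values
    for comparison; ``ki`` and ``dg`` are meant to be recomputed with
    :func:`ltpdigest.binding.cheng_prusoff` and
    :func:`ltpdigest.binding.binding_free_energy`.
    """
    return pd.DataFrame(
        _BINDING_ROWS,
        columns=[
            "ligand",
            "buffer",
            "protein",
            "tracer_kd_uM",
            "tracer_conc_uM",
            "ic50_uM",
            "ki_published",
            "dg_published",
        ],
    )
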