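"""Normative reference values and comparisons against them.

The package ships a normative table for healthy adults aged 20–69:
mean ± SD of the eight parameters (Z, R, fc, PA, Ri, Re, Xc, Mc) for each
of 8 muscles × 2 genders, n = 25 per cell, plus the published
women-versus-men contrast table (direction, integer percent change with
the men's mean as baseline, and significance band).

Two caveats travel with the data and are exposed rather than hidden:

* Mc entries carry their original unit label "pF" although the defining
  relation applied to the tabulated fc/Re/Ri means yields tens of nF;
  Mc values are therefore only used dimensionlessly (percent change,
  z-scores) — see ``DerivedParameters.mc_reported``.
* The women-triceps fc SD (95.4) exceeds its mean (63.3); the entry is
  stored verbatim and flagged.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import pandas as pd

from .cole import DerivedParameters
from .exceptions import DomainError, LookupError_
from .spectra import GENDERS, MUSCLES

__all__ = [
    "PARAMETERS",
    "ReferenceEntry",
    "ContrastCell",
    "load_reference",
    "reference_entry",
    "percent_change",
    "gender_contrast_table",
    "zscore_against_reference",
]

#: Reported parameters, in the column order of the published contrast table.
PARAMETERS = ("Z", "R", "fc", "PA", "Ri", "Re", "Xc", "Mc")

#: Cells whose printed SD exceeds the printed mean (possible typo or
#: extreme skew in the source table); stored verbatim, flagged here.
FLAGGED_CELLS = (
    ("triceps", "women", "fc"),
    ("rectus_femoris", "women", "fc"),
)


@dataclass(frozen=True)
class ReferenceEntry:
    """One normative cell: muscle × gender × parameter."""

    muscle: str
    gender: str
    parameter: str
    mean: float
    sd: float
    n: int
    unit: str

    @property
    def flagged(self) -> bool:
        return (self.muscle, self.gender, self.parameter) in FLAGGED_CELLS


@dataclass(frozen=True)
class ContrastCell:
    """One women-versus-men contrast: published values plus recomputation."""

    muscle: str
    parameter: str
    direction: str            # increase / decrease / NS
    printed_percent: int | None
    p_band: str               # e.g. "<0.001", "NS"
    recomputed_percent: int
    rounding_mismatch: bool   # printed differs from mean-derived recomputation


def _read_resource(name: str) -> pd.DataFrame:
    with importlib.resources.files("mfbia.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference() -> pd.DataFrame:
    """The full normative table, indexed by (muscle, gender, parameter).

    Returns a DataFrame with columns mean, sd, n, unit; exactly
    8 muscles × 2 genders × 8 parameters = 128 rows.
    """
    df = _read_resource("reference_values.tsv")
    df = df.set_index(["muscle", "gender", "parameter"]).sort_index()
    assert len(df) == len(MUSCLES) * len(GENDERS) * len(PARAMETERS)
    return df


def reference_entry(muscle: str, gender: str, parameter: str, reference=None) -> ReferenceEntry:
    """Look up one normative cell; raises on unknown keys."""
    if reference is None:
        reference = load_reference()
    try:
        row = reference.loc[(muscle, gender, parameter)]
    except KeyError:
        raise LookupError_(f"no reference entry for ({muscle}, {gender}, {parameter})") from None
    return ReferenceEntry(
        muscle=muscle, gender=gender, parameter=parameter,
        mean=float(row["mean"]), sd=float(row["sd"]), n=int(row["n"]), unit=str(row["unit"]),
    )


def percent_change(men_mean: float, women_mean: float) -> int:
    """Signed integer percent change of women relative to the men's baseline.

    100·(women − men)/men, rounded half away from zero (matching the
    integer style of the published contrast table).
    """
    if men_mean <= 0.0:
        raise DomainError("baseline (men) mean must be positive")
    pct = 100.0 * (women_mean - men_mean) / men_mean
    return int(_round_half_away(pct))


def _round_half_away(x: float) -> float:
    # Python's round() rounds half to even; the table style is half away from zero.
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def gender_contrast_table(reference: pd.DataFrame | None = None) -> list[ContrastCell]:
    """Recompute the women-vs-men percent column from the packaged means.

    Each cell carries both the recomputed integer and the published one;
    cells that differ (the source rounded from unrounded subject-level
    data) are flagged, not silently reconciled.  The published value is
    authoritative for display, the recomputed one for exact checks.
    """
    if reference is None:
        reference = load_reference()
    printed = _read_resource("gender_contrasts.tsv")
    cells = []
    for _, row in printed.iterrows():
        muscle, parameter = row["muscle"], row["parameter"]
        men = reference.loc[(muscle, "men", parameter), "mean"]
        women = reference.loc[(muscle, "women", parameter), "mean"]
        recomputed = percent_change(float(men), float(women))
        has_pct = pd.notna(row["printed_percent"])
        printed_pct = None
        if has_pct:
            sign = -1 if row["direction"] == "decrease" else 1
            printed_pct = sign * int(row["printed_percent"])
        cells.append(
            ContrastCell(
                muscle=muscle,
                parameter=parameter,
                direction=str(row["direction"]),
                printed_percent=printed_pct,
                p_band=str(row["p_band"]),
                recomputed_percent=recomputed,
                rounding_mismatch=(printed_pct is not None and printed_pct != recomputed),
            )
        )
    return cells


def zscore_against_reference(
    derived: DerivedParameters,
    muscle: str,
    gender: str,
    reference: pd.DataFrame | None = None,
    flag_threshold: float = 2.0,
) -> dict[str, dict]:
    """Per-parameter z-scores of one recording against its normative cell.

    z = (value − mean)/sd on the table's own scale (Mc compared on the
    tabulated scale, see module docstring).  Each entry carries the value,
    z, and an ``outside_range`` flag for |z| > ``flag_threshold``.
    """
    if reference is None:
        reference = load_reference()
    values = derived.as_dict(mc_scale="reported")
    out = {}
    for parameter in PARAMETERS:
        entry = reference_entry(muscle, gender, parameter, reference)
        z = (values[parameter] - entry.mean) / entry.sd
        out[parameter] = {
            "value": values[parameter],
            "reference_mean": entry.mean,
            "reference_sd": entry.sd,
            "unit": entry.unit,
            "z": z,
            "outside_range": abs(z) > flag_threshold,
        }
    return out
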