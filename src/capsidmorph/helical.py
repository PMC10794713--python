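"""Helical-filament geometry derived from refined symmetry parameters.

A helical assembly is described by its rise (axial translation per
asymmetric unit, in Å), twist (rotation per asymmetric unit, in degrees;
negative = left-handed) and an optional cyclic symmetry Cn.  From these
we derive the number of subunits per turn, the helix pitch, an explicit
lattice of subunit reference points, a theoretical filament length for a
given encapsidated ssRNA (assuming a fixed number of nucleotides bound
per coat-protein subunit), and the change in axial ring separation
between two filament classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "HelicalParams",
    "LengthPrediction",
    "AxialSeparationChange",
    "units_per_turn",
    "pitch",
    "expected_filament_length",
    "axial_repeat_difference",
    "build_filament_lattice",
    "classify_architecture",
    "load_helical_params",
    "lattice_to_cartesian",
]


def _round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention used for printed values."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry of one filament class.

    rise : Å per asymmetric unit (per ring when cyclic_symmetry > 1)
    twist : degrees per asymmetric unit; negative means left-handed
    cyclic_symmetry : Cn point symmetry of the cross-section (n ≥ 1)
    """

    rise: float
    twist: float
    cyclic_symmetry: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError(f"rise must be > 0, got {self.rise}")
        if abs(self.twist) > 360:
            raise ValueError(f"|twist| must be <= 360 deg, got {self.twist}")
        if self.cyclic_symmetry < 1 or int(self.cyclic_symmetry) != self.cyclic_symmetry:
            raise ValueError(
                f"cyclic_symmetry must be an integer >= 1, got {self.cyclic_symmetry}"
            )

    @property
    def handedness(self) -> str:
        if self.twist < 0:
            return "left"
        if self.twist > 0:
            return "right"
        return "none"


@dataclass(frozen=True)
class LengthPrediction:
    """Theoretical filament length for an RNA of ``n_nt`` nucleotides.

    With ``nt_per_subunit`` nucleotides bound per coat-protein unit and a
    helical rise ``rise`` (Å), the filament that exactly encapsidates the
    RNA contains ``n_nt / nt_per_subunit`` subunits and spans
    ``n_subunits * rise`` Å = ``length_nm`` nm.
    """

    n_nt: int
    nt_per_subunit: float
    rise: float
    n_subunits: float = field(init=False)
    length_nm: float = field(init=False)
    length_nm_rounded: int = field(init=False)

    def __post_init__(self) -> None:
        if self.n_nt <= 0 or self.nt_per_subunit <= 0 or self.rise <= 0:
            raise ValueError("n_nt, nt_per_subunit and rise must all be > 0")
        n_sub = self.n_nt / self.nt_per_subunit
        object.__setattr__(self, "n_subunits", n_sub)
        object.__setattr__(self, "length_nm", n_sub * self.rise / 10.0)
        object.__setattr__(self, "length_nm_rounded", int(_round_half_away(self.length_nm)))


@dataclass(frozen=True)
class AxialSeparationChange:
    """Signed rise difference between two filament classes (Å)."""

    signed: float
    magnitude_rounded: float  # |signed| rounded to one decimal, printing convention


def units_per_turn(hp: HelicalParams) -> float:
    """Number of asymmetric units per full helical turn, 360/|twist|."""
    if hp.twist == 0:
        raise ValueError("not a helix: twist is zero")
    return 360.0 / abs(hp.twist)


def pitch(hp: HelicalParams) -> float:
    """Helix pitch in Å: rise × units per turn."""
    return hp.rise * units_per_turn(hp)


def expected_filament_length(
    n_nt: int, nt_per_subunit: float = 5, rise: float = 4.01
) -> LengthPrediction:
    """Theoretical length (nm) of a filament encapsidating an ``n_nt``-long RNA.

    Defaults assume 5 nt bound per coat-protein unit and the rise of the
    RNA-encapsidating helical filament class (4.01 Å).
    """
    return LengthPrediction(n_nt=n_nt, nt_per_subunit=nt_per_subunit, rise=rise)


def axial_repeat_difference(a: HelicalParams, b: HelicalParams) -> AxialSeparationChange:
    """Change in axial repeat (ring separation) between two filament classes."""
    signed = a.rise - b.rise
    return AxialSeparationChange(signed=signed, magnitude_rounded=_round_half_away(abs(signed), 1))


def build_filament_lattice(
    hp: HelicalParams,
    n_units: int,
    radius: float = 45.0,
    start_phase: float = 0.0,
) -> pd.DataFrame:
    """Subunit reference points of a filament as cylindrical coordinates.

    ``n_units`` counts helical repeats along the axis: individual subunits
    for C1, rings of ``cyclic_symmetry`` symmetry mates for Cn > 1.  Repeat
    ``j`` sits at z = j*rise with azimuthal offset j*twist; within a ring the
    mates are spaced by 360/Cn.  Azimuths are canonicalized to [0, 360).

    Returns a DataFrame with columns subunit, ring, z, azimuth, radius.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rows = []
    idx = 0
    n_mates = hp.cyclic_symmetry
    for j in range(n_units):
        base_az = start_phase + j * hp.twist
        for m in range(n_mates):
            rows.append(
                {
                    "subunit": idx,
                    "ring": j,
                    "z": j * hp.rise,
                    "azimuth": (base_az + m * 360.0 / n_mates) % 360.0,
                    "radius": radius,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def lattice_to_cartesian(lattice: pd.DataFrame) -> pd.DataFrame:
    """Convert a cylindrical lattice table to Cartesian x, y, z (Å)."""
    az = np.deg2rad(lattice["azimuth"].to_numpy())
    r = lattice["radius"].to_numpy()
    out = lattice[["subunit", "ring"]].copy()
    out["x"] = r * np.cos(az)
    out["y"] = r * np.sin(az)
    out["z"] = lattice["z"].to_numpy()
    return out


def classify_architecture(hp: HelicalParams, subunit_axial_extent: float = 30.0) -> str:
    """Classify a filament as ``stacked_ring`` or ``one_start_helix``.

    Stacked-ring filaments are Cn-symmetric (n > 1) with a per-ring rise on
    the order of a full ring height, so consecutive rings sit on top of each
    other; one-start helices advance by a small per-subunit rise.  The
    ``subunit_axial_extent`` threshold (Å) is a heuristic: rings pulled
    closer by interface engineering still stack, so the default sits
    somewhat below the ~40 Å ring height.
    """
    if subunit_axial_extent <= 0:
        raise ValueError("subunit_axial_extent must be > 0")
    if hp.cyclic_symmetry > 1 and hp.rise >= subunit_axial_extent:
        return "stacked_ring"
    return "one_start_helix"


def load_helical_params(path: Union[str, Path]) -> dict[str, HelicalParams]:
    """Read a symmetry table (TSV or JSON) into HelicalParams keyed by label.

    TSV columns: label, rise, twist, symmetry (Cn as integer, e.g. 8).
    JSON: list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, sep="\t").to_dict("records")
    out: dict[str, HelicalParams] = {}
    for rec in records:
        label = str(rec["label"])
        out[label] = HelicalParams(
            rise=float(rec["rise"]),
            twist=float(rec["twist"]),
            cyclic_symmetry=int(rec.get("symmetry", rec.get("cyclic_symmetry", 1))),
            label=label,
        )
    return out
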