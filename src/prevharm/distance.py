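"""Cut-off distances on the z-score scale and the age/sex look-up table.

Two cut-offs A and B (each a z-score on its own reference) are placed on a
common scale by scoring each cut-off's BMI value on *both* references.  The
symmetric mean z-scores

    zbar_A = (z_A + z_A_onB) / 2        zbar_B = (z_B + z_B_onA) / 2

give the cut-off distance

    dz = zbar_B - zbar_A = ((z_B - z_A) + (z_B_onA - z_A_onB)) / 2

which is exactly antisymmetric in A and B.  For the WHO +1 vs IOTF 25
overweight pair in boys aged 8 the published reference tables give
z_A = 1.00, z_B = 1.31, z_B_onA = 1.47, z_A_onB = 0.91, hence dz = 0.43.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    SEXES,
    AgeRangeError,
    CutoffLookupError,
    CutoffRegistry,
    CutoffSpec,
    ParseError,
    ReferenceTable,
    measurement_from_z,
    normalize_sex,
    z_from_measurement,
)

__all__ = [
    "CutoffDistance",
    "dz_from_components",
    "cross_z",
    "cutoff_distance",
    "default_age_grid",
    "build_lookup_table",
    "write_distance_table",
    "read_distance_table",
    "lookup_dz",
]

_TABLE_COLUMNS = [
    "pair_A", "pair_B", "sex", "age",
    "z_A", "z_B", "z_B_onA", "z_A_onB", "dz",
]


def dz_from_components(z_A: float, z_B: float, z_A_onB: float, z_B_onA: float) -> float:
    """Cut-off distance from the four component z-scores."""
    return 0.5 * ((z_B - z_A) + (z_B_onA - z_A_onB))


@dataclass(frozen=True)
class CutoffDistance:
    """The paired cross z-scores and distance for one cut-off pair at one age."""

    label_A: str
    label_B: str
    sex: str
    age: float
    z_A: float
    z_B: float
    z_A_onB: float
    z_B_onA: float

    @property
    def zbar_A(self) -> float:
        return 0.5 * (self.z_A + self.z_A_onB)

    @property
    def zbar_B(self) -> float:
        return 0.5 * (self.z_B + self.z_B_onA)

    @property
    def dz(self) -> float:
        return dz_from_components(self.z_A, self.z_B, self.z_A_onB, self.z_B_onA)

    def reversed(self) -> "CutoffDistance":
        """The B-to-A view; its dz is exactly the negation."""
        return CutoffDistance(
            label_A=self.label_B, label_B=self.label_A,
            sex=self.sex, age=self.age,
            z_A=self.z_B, z_B=self.z_A,
            z_A_onB=self.z_B_onA, z_B_onA=self.z_A_onB,
        )


def cross_z(
    cutoff: CutoffSpec,
    scoring_ref: ReferenceTable,
    sex: str,
    age: float,
    refs: Mapping[str, ReferenceTable],
) -> float:
    """Score a cut-off's BMI value as a z-score on another reference.

    The cut-off's own reference (found in ``refs``) converts its z to a BMI;
    ``scoring_ref`` converts that BMI back to a z-score.  Scoring on the
    cut-off's own reference returns its z exactly.
    """
    if scoring_ref.name == cutoff.reference:
        return float(cutoff.z)
    try:
        own = refs[cutoff.reference]
    except KeyError:
        raise CutoffLookupError(
            f"reference '{cutoff.reference}' for cut-off '{cutoff.label}' "
            "not among the supplied tables"
        ) from None
    try:
        L, M, S = own.lms_at(sex, age)
        bmi = measurement_from_z(cutoff.z, L, M, S)
    except (AgeRangeError, ValueError) as exc:
        raise type(exc)(f"[reference '{own.name}'] {exc}") from exc
    try:
        Ls, Ms, Ss = scoring_ref.lms_at(sex, age)
        return float(z_from_measurement(bmi, Ls, Ms, Ss))
    except (AgeRangeError, ValueError) as exc:
        raise type(exc)(f"[reference '{scoring_ref.name}'] {exc}") from exc


def cutoff_distance(
    label_A: str,
    label_B: str,
    sex: str,
    age: float,
    refs: Mapping[str, ReferenceTable],
    registry: CutoffRegistry,
) -> CutoffDistance:
    """Full :class:`CutoffDistance` between two named cut-offs at (sex, age)."""
    sex = normalize_sex(sex)
    spec_A = registry.resolve(label_A, sex, age)
    spec_B = registry.resolve(label_B, sex, age)
    ref_A = refs[spec_A.reference]
    ref_B = refs[spec_B.reference]
    return CutoffDistance(
        label_A=label_A, label_B=label_B, sex=sex, age=float(age),
        z_A=float(spec_A.z), z_B=float(spec_B.z),
        z_A_onB=cross_z(spec_A, ref_B, sex, age, refs),
        z_B_onA=cross_z(spec_B, ref_A, sex, age, refs),
    )


def default_age_grid(
    age_min: float = 2.0, age_max: float = 18.0, step: float = 0.5
) -> np.ndarray:
    """Half-year ages 2-18 inclusive (33 points) unless overridden."""
    n = int(round((age_max - age_min) / step))
    return age_min + step * np.arange(n + 1)


def build_lookup_table(
    refs: Mapping[str, ReferenceTable],
    registry: CutoffRegistry,
    pairs: Sequence[tuple[str, str]],
    ages: Iterable[float] | None = None,
    sexes: Sequence[str] = SEXES,
) -> pd.DataFrame:
    """Distance look-up table: one row per (pair, sex, age).

    Grid points where a cut-off does not apply (outside its age range or its
    reference's span) are omitted rather than raising.
    """
    if not pairs:
        raise ValueError("at least one cut-off pair is required")
    if ages is None:
        ages = default_age_grid()
    rows = []
    for label_A, label_B in pairs:
        for sex in sexes:
            for age in ages:
                try:
                    d = cutoff_distance(label_A, label_B, sex, float(age),
                                        refs, registry)
                except (CutoffLookupError, AgeRangeError):
                    continue
                rows.append({
                    "pair_A": label_A, "pair_B": label_B,
                    "sex": d.sex, "age": d.age,
                    "z_A": d.z_A, "z_B": d.z_B,
                    "z_B_onA": d.z_B_onA, "z_A_onB": d.z_A_onB,
                    "dz": d.dz,
                })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_distance_table(table: pd.DataFrame, path) -> None:
    """Write the look-up table as CSV, dz at 3 dp (cross z-scores at 4 dp)."""
    out = table.loc[:, _TABLE_COLUMNS].copy()
    for col in ("z_A", "z_B", "z_B_onA", "z_A_onB"):
        out[col] = out[col].round(4)
    out["dz"] = out["dz"].round(3)
    out.to_csv(path, index=False)


def read_distance_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df["sex"] = [normalize_sex(s) for s in df["sex"]]
    return df.loc[:, _TABLE_COLUMNS]


def lookup_dz(
    table: pd.DataFrame,
    pair: tuple[str, str],
    sex: str,
    group_mean_age: float,
) -> float:
    """dz at the grid age nearest the group's mean age (ties to the younger).

    If only the reversed pair is tabulated its negated dz is returned.
    """
    sex = normalize_sex(sex)
    label_A, label_B = pair
    sub = table[
        (table["pair_A"] == label_A)
        & (table["pair_B"] == label_B)
        & (table["sex"] == sex)
    ]
    flip = 1.0
    if sub.empty:
        sub = table[
            (table["pair_A"] == label_B)
            & (table["pair_B"] == label_A)
            & (table["sex"] == sex)
        ]
        flip = -1.0
    if sub.empty:
        raise CutoffLookupError(
            f"pair {label_A}/{label_B} (sex {sex}) not in the look-up table"
        )
    ages = sub["age"].to_numpy(dtype=float)
    diffs = np.abs(ages - group_mean_age)
    near = ages[diffs <= diffs.min() + 1e-9]
    age = near.min()  # exact-midpoint ties round to the younger age
    row = sub[sub["age"] == age].iloc[0]
    return flip * float(row["dz"])
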