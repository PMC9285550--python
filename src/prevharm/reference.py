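"""LMS growth references, BMI z-score transforms, and named cut-offs.

The LMS method summarises an age-sex-conditional BMI distribution with three
curves: L (Box-Cox power, skewness), M (median, kg/m**2) and S (coefficient
of variation).  A measurement x maps to a z-score via

    z = ((x/M)**L - 1) / (L*S)        for L != 0
    z = ln(x/M) / S                   for L == 0

and category cut-offs (thinness, overweight, obesity) are fixed z-scores on a
named reference (e.g. WHO overweight = +1 SD from age 5).  This module houses
the reference tables, the forward/inverse transforms, and a registry of the
standard IOTF/WHO/CDC cut-off definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "L_TOL",
    "SEXES",
    "CATEGORIES",
    "ParseError",
    "AgeRangeError",
    "CutoffLookupError",
    "SupportError",
    "normalize_sex",
    "z_from_measurement",
    "measurement_from_z",
    "ReferenceTable",
    "lms_at",
    "read_reference_csv",
    "write_reference_csv",
    "CutoffSpec",
    "CutoffRegistry",
    "resolve_cutoff",
    "default_registry",
    "iotf_exact_z",
]

#: |L| below this is treated as the log-normal (L = 0) branch.
L_TOL = 1e-7

SEXES = ("male", "female")
CATEGORIES = ("thinness", "overweight", "obesity")

_REFERENCE_COLUMNS = ["sex", "age", "L", "M", "S"]
_REGISTRY_COLUMNS = ["label", "reference", "sex", "category", "z", "age_min", "age_max"]


class ParseError(ValueError):
    """A CSV file violates its documented schema."""


class AgeRangeError(ValueError):
    """Requested age lies outside a reference's tabulated span."""


class CutoffLookupError(KeyError):
    """No unique cut-off matches the requested label/sex/age."""


class SupportError(ValueError):
    """A z-score lies outside the support of the Box-Cox distribution."""


_SEX_ALIASES = {
    "male": "male", "m": "male", "boy": "male", "boys": "male",
    "female": "female", "f": "female", "girl": "female", "girls": "female",
    "both": "both", "b": "both", "all": "both",
}


def normalize_sex(sex: str, allow_both: bool = False) -> str:
    """Map common sex spellings ('M', 'girls', ...) to 'male'/'female'/'both'."""
    try:
        out = _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}") from None
    if out == "both" and not allow_both:
        raise ValueError("sex must be 'male' or 'female' here, not 'both'")
    return out


def _as_float_arrays(*vals):
    arrs = np.broadcast_arrays(*[np.asarray(v, dtype=float) for v in vals])
    return arrs


def z_from_measurement(x, L, M, S):
    """BMI (or any measurement) to z-score under LMS parameters.

    Strictly increasing in ``x``; the median maps to 0.  Scalars or
    broadcastable arrays accepted.
    """
    x, L, M, S = _as_float_arrays(x, L, M, S)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("x, M and S must all be positive")
    ratio = x / M
    z = np.empty_like(ratio)
    pw = np.abs(L) > L_TOL
    z[pw] = (np.power(ratio[pw], L[pw]) - 1.0) / (L[pw] * S[pw])
    z[~pw] = np.log(ratio[~pw]) / S[~pw]
    return float(z) if z.ndim == 0 else z


def measurement_from_z(z, L, M, S):
    """Inverse of :func:`z_from_measurement`: z-score back to measurement units.

    Raises :class:`SupportError` when ``1 + L*S*z <= 0`` (the z-score lies
    beyond the Box-Cox support boundary).
    """
    z, L, M, S = _as_float_arrays(z, L, M, S)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    x = np.empty_like(z)
    pw = np.abs(L) > L_TOL
    base = 1.0 + L[pw] * S[pw] * z[pw]
    if np.any(base <= 0):
        bad = np.asarray(z[pw])[np.asarray(base) <= 0]
        raise SupportError(
            f"z-score(s) {np.atleast_1d(bad).tolist()} outside the Box-Cox "
            "support (1 + L*S*z <= 0)"
        )
    x[pw] = M[pw] * np.power(base, 1.0 / L[pw])
    x[~pw] = M[~pw] * np.exp(S[~pw] * z[~pw])
    return float(x) if x.ndim == 0 else x


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """An age/sex grid of L, M, S values defining one BMI reference.

    ``data`` holds columns sex, age, L, M, S with ages strictly increasing
    within each sex.  Rows with sex 'both' should be duplicated into male and
    female before construction (the CSV reader does this).
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REFERENCE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"reference '{self.name}' missing column(s) {missing}")
        df = self.data.loc[:, _REFERENCE_COLUMNS].copy()
        df["sex"] = [normalize_sex(s) for s in df["sex"]]
        for col in ("age", "L", "M", "S"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df.empty:
            raise ParseError(f"reference '{self.name}' has no rows")
        if (df["M"] <= 0).any() or (df["S"] <= 0).any():
            raise ParseError(f"reference '{self.name}': M and S must be positive")
        df = df.sort_values(["sex", "age"], kind="stable").reset_index(drop=True)
        for sex, grp in df.groupby("sex"):
            ages = grp["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ParseError(
                    f"reference '{self.name}': duplicated age in sex '{sex}'"
                )
        self.data = df

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["sex"].unique()))

    @property
    def single_sex(self) -> bool:
        return len(self.sexes) == 1

    def age_span(self, sex: str) -> tuple[float, float]:
        sex = normalize_sex(sex)
        grp = self.data[self.data["sex"] == sex]
        if grp.empty:
            raise ValueError(f"reference '{self.name}' has no rows for sex '{sex}'")
        ages = grp["age"]
        return float(ages.min()), float(ages.max())

    def lms_at(self, sex: str, age: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at an age inside the covered span."""
        sex = normalize_sex(sex)
        grp = self.data[self.data["sex"] == sex]
        if grp.empty:
            raise ValueError(f"reference '{self.name}' has no rows for sex '{sex}'")
        ages = grp["age"].to_numpy()
        lo, hi = ages[0], ages[-1]
        if not (lo <= age <= hi):
            raise AgeRangeError(
                f"age {age} outside span [{lo}, {hi}] of reference "
                f"'{self.name}' ({sex})"
            )
        return tuple(
            float(np.interp(age, ages, grp[col].to_numpy())) for col in ("L", "M", "S")
        )


def lms_at(table: ReferenceTable, sex: str, age: float) -> tuple[float, float, float]:
    """Module-level convenience wrapper for :meth:`ReferenceTable.lms_at`."""
    return table.lms_at(sex, age)


def read_reference_csv(path, name: str | None = None) -> ReferenceTable:
    """Read a reference from CSV with header ``sex,age,L,M,S``.

    Sex 'both' rows are duplicated into male and female.  Parse errors name
    the first offending file row (header = row 1).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in _REFERENCE_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = raw.loc[:, _REFERENCE_COLUMNS].copy()
    for col in ("age", "L", "M", "S"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}: non-numeric or missing '{col}' at row {row}")
        df[col] = vals
    try:
        df["sex"] = [normalize_sex(s, allow_both=True) for s in df["sex"]]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    # duplicate 'both' rows into each sex
    both = df[df["sex"] == "both"]
    if not both.empty:
        df = pd.concat(
            [df[df["sex"] != "both"]]
            + [both.assign(sex=s) for s in SEXES],
            ignore_index=True,
        )
    # require ages sorted/unique per sex as given (catch unsorted input)
    for sex, grp in df.groupby("sex", sort=False):
        ages = grp["age"].to_numpy()
        steps = np.diff(ages)
        if np.any(steps <= 0):
            row = int(grp.index[np.flatnonzero(steps <= 0)[0] + 1]) + 2
            raise ParseError(f"{path}: ages not strictly increasing at row {row}")
    if name is None:
        name = path.stem
        if name.startswith("synthetic_"):
            name = name[len("synthetic_"):]
    return ReferenceTable(name=name, data=df)


def write_reference_csv(table: ReferenceTable, path) -> None:
    """Write a reference table in the canonical ``sex,age,L,M,S`` schema."""
    table.data.loc[:, _REFERENCE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cut-off specs and registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffSpec:
    """A named z-score cut-off tied to a reference, sex, and age range.

    ``sex`` is 'both' for shared cut-offs (WHO, CDC) or 'male'/'female' for
    sex-specific ones (IOTF).  The age interval is closed; where two bands of
    the same label meet (WHO at age 5) the boundary age belongs to the older
    band.
    """

    label: str
    reference: str
    category: str
    sex: str
    z: float
    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.z == 0:
            raise ValueError("cut-off z must be non-zero")
        want = -1 if self.category == "thinness" else +1
        if np.sign(self.z) != want:
            raise ValueError(
                f"{self.label}: z={self.z} has the wrong sign for {self.category}"
            )
        object.__setattr__(self, "sex", normalize_sex(self.sex, allow_both=True))
        if self.age_min >= self.age_max:
            raise ValueError(f"{self.label}: empty age range")

    @property
    def sign(self) -> int:
        """+1 for overweight/obesity (upper tail), -1 for thinness."""
        return -1 if self.category == "thinness" else +1

    def applies_to(self, sex: str, age: float) -> bool:
        sex = normalize_sex(sex)
        if self.sex != "both" and self.sex != sex:
            return False
        return self.age_min <= age <= self.age_max


def _canon_label(label: str) -> str:
    return "".join(str(label).split()).upper()


class CutoffRegistry:
    """Mapping from label to one or more :class:`CutoffSpec` entries.

    ``resolve(label, sex, age)`` returns the unique age/sex-appropriate spec.
    Besides exact labels ('WHO+1', 'IOTF25'), '<REF> <category>' aliases are
    accepted ('WHO overweight' gives +2 below age 5 and +1 from age 5);
    generic 'IOTF thinness' resolves to grade 2 (IOTF17) with a warning.
    """

    def __init__(self, specs: Iterable[CutoffSpec] = ()) -> None:
        self._specs: dict[str, list[CutoffSpec]] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: CutoffSpec) -> None:
        key = _canon_label(spec.label)
        for other in self._specs.get(key, []):
            sexes_clash = (
                spec.sex == "both" or other.sex == "both" or spec.sex == other.sex
            )
            overlap = (
                spec.age_min < other.age_max and other.age_min < spec.age_max
            )
            if sexes_clash and overlap:
                raise ValueError(
                    f"cut-off '{spec.label}' overlaps an existing entry "
                    f"({other.age_min}-{other.age_max} y, sex {other.sex})"
                )
        self._specs.setdefault(key, []).append(spec)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self._specs))

    def __iter__(self):
        for specs in self._specs.values():
            yield from specs

    def resolve(self, label: str, sex: str, age: float) -> CutoffSpec:
        sex = normalize_sex(sex)
        key = _canon_label(label)
        if key in self._specs:
            cands = [s for s in self._specs[key] if s.applies_to(sex, age)]
        else:
            cands = self._resolve_alias(label, sex, age)
        if not cands:
            raise CutoffLookupError(
                f"no cut-off '{label}' applies at sex={sex}, age={age}"
            )
        if len(cands) > 1:
            # boundary age shared by two bands: the older band wins
            top = max(s.age_min for s in cands)
            cands = [s for s in cands if s.age_min == top]
            sexed = [s for s in cands if s.sex == sex]
            if sexed:
                cands = sexed
        if len(cands) != 1:
            raise CutoffLookupError(
                f"cut-off '{label}' is ambiguous at sex={sex}, age={age}"
            )
        return cands[0]

    def _resolve_alias(self, label: str, sex: str, age: float) -> list[CutoffSpec]:
        parts = str(label).strip().split()
        if len(parts) != 2:
            raise CutoffLookupError(f"unknown cut-off label {label!r}")
        ref, category = parts[0].lower(), parts[1].lower()
        if category not in CATEGORIES:
            raise CutoffLookupError(f"unknown cut-off label {label!r}")
        cands = [
            s
            for s in self
            if s.reference == ref and s.category == category and s.applies_to(sex, age)
        ]
        if ref == "iotf" and category == "thinness" and len(cands) > 1:
            grade2 = [s for s in cands if _canon_label(s.label) == "IOTF17"]
            if grade2:
                warnings.warn(
                    "generic 'IOTF thinness' resolved to grade 2 (IOTF17); "
                    "use 'IOTF18.5' explicitly for grade 1",
                    stacklevel=3,
                )
                return grade2
        return cands

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": s.label, "reference": s.reference, "sex": s.sex,
                "category": s.category, "z": s.z,
                "age_min": s.age_min, "age_max": s.age_max,
            }
            for s in self
        ]
        return pd.DataFrame(rows, columns=_REGISTRY_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CutoffRegistry":
        df = pd.read_csv(path)
        missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        return cls(
            CutoffSpec(
                label=row.label, reference=row.reference, sex=row.sex,
                category=row.category, z=float(row.z),
                age_min=float(row.age_min), age_max=float(row.age_max),
            )
            for row in df.itertuples()
        )


def resolve_cutoff(
    registry: CutoffRegistry, label: str, sex: str, age: float
) -> CutoffSpec:
    """Return the unique age/sex-appropriate cut-off for ``label``."""
    return registry.resolve(label, sex, age)


def default_registry() -> CutoffRegistry:
    """The standard IOTF / WHO / CDC cut-off definitions.

    IOTF cut-offs are the published two-decimal z values (sex-specific,
    2-18 y); WHO uses -2/+1/+2 from age 5 and -2/+2/+3 below (BMI-for-age
    throughout -- the under-5 weight-for-height distinction is documented as
    an approximation, not implemented); CDC uses the 5th/85th/95th centiles.
    """
    specs: list[CutoffSpec] = []

    def iotf(label, category, z_m, z_f):
        specs.append(CutoffSpec(label, "iotf", category, "male", z_m, 2.0, 18.0))
        specs.append(CutoffSpec(label, "iotf", category, "female", z_f, 2.0, 18.0))

    iotf("IOTF18.5", "thinness", -1.01, -0.98)   # grade 1
    iotf("IOTF17", "thinness", -1.88, -1.79)     # grade 2
    iotf("IOTF16", "thinness", -2.56, -2.44)     # grade 3
    iotf("IOTF25", "overweight", +1.31, +1.24)
    iotf("IOTF30", "obesity", +2.29, +2.19)

    specs += [
        CutoffSpec("WHO-2", "who", "thinness", "both", -2.0, 2.0, 19.0),
        CutoffSpec("WHO+1", "who", "overweight", "both", +1.0, 5.0, 19.0),
        CutoffSpec("WHO+2", "who", "overweight", "both", +2.0, 2.0, 5.0),
        CutoffSpec("WHO+2", "who", "obesity", "both", +2.0, 5.0, 19.0),
        CutoffSpec("WHO+3", "who", "obesity", "both", +3.0, 2.0, 5.0),
        CutoffSpec("CDC5", "cdc", "thinness", "both", -1.64, 2.0, 20.0),
        CutoffSpec("CDC85", "cdc", "overweight", "both", +1.04, 2.0, 20.0),
        CutoffSpec("CDC95", "cdc", "obesity", "both", +1.64, 2.0, 20.0),
    ]
    return CutoffRegistry(specs)


def iotf_exact_z(
    table: ReferenceTable, sex: str, bmi_at_18: float
) -> float:
    """z such that the reference BMI at age 18 equals ``bmi_at_18``.

    The IOTF cut-offs are defined by the adult BMI values 16/17/18.5/25/30 at
    age 18; given a loaded IOTF table covering age 18 this recovers the exact
    z instead of the published two-decimal value.
    """
    L, M, S = table.lms_at(sex, 18.0)
    return z_from_measurement(bmi_at_18, L, M, S)
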