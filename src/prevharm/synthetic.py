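"""Synthetic LMS references and grouped prevalence data.

No published IOTF/WHO/CDC LMS tables are shipped (they are not
redistributable), so this module generates stand-in references with realistic
smooth L/M/S curves, plus grouped binomial prevalence datasets whose
underlying truth is controlled exactly.

The population model lives in the z-metric of a chosen base reference: a
child's z-score is Normal(z_shift, s_inflation**2).  With s_inflation = 1 the
population differs from the references only by a shift on the z-score scale -
the conversion algorithm's key assumption - so every simulated prevalence has
the analytic value PHI(-sign * (z_cut - z_shift) / s_inflation), and the
fitted slope b has expectation 1.  s_inflation > 1 makes the tails heavier
than the references', the documented mechanism for b < 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .distance import cross_z, cutoff_distance
from .reference import (
    SEXES,
    CutoffRegistry,
    CutoffSpec,
    ReferenceTable,
    default_registry,
)
from .validation import DATASET_COLUMNS

__all__ = [
    "SyntheticReferenceSpec",
    "PopulationSpec",
    "make_reference",
    "default_reference_specs",
    "default_refs",
    "true_group_prevalence",
    "simulate_prevalence_dataset",
    "paper_shaped_pairs",
    "paper_shaped_design",
    "zshift_setup",
    "WorkedExample",
    "worked_example_fixture",
]

Coeffs = tuple[float, ...]


@dataclass(frozen=True)
class SyntheticReferenceSpec:
    """Smooth parametric L/M/S curves (ascending-power polynomials in age).

    ``L``, ``M``, ``S`` map sex to coefficient tuples; a single tuple is
    shared between the sexes.
    """

    name: str
    L: Mapping[str, Coeffs] | Coeffs
    M: Mapping[str, Coeffs] | Coeffs
    S: Mapping[str, Coeffs] | Coeffs
    age_min: float = 2.0
    age_max: float = 18.0
    step: float = 0.5
    seed: int = 0

    def coeffs(self, which: str, sex: str) -> Coeffs:
        curve = getattr(self, which)
        if isinstance(curve, Mapping):
            return tuple(curve[sex])
        return tuple(curve)


def _polyval(coeffs: Coeffs, age: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(age, list(coeffs))


def make_reference(spec: SyntheticReferenceSpec) -> ReferenceTable:
    """Tabulate a synthetic reference on its age grid (deterministic)."""
    n = int(round((spec.age_max - spec.age_min) / spec.step))
    ages = spec.age_min + spec.step * np.arange(n + 1)
    frames = []
    for sex in SEXES:
        S = _polyval(spec.coeffs("S", sex), ages)
        M = _polyval(spec.coeffs("M", sex), ages)
        if np.any(S <= 0) or np.any(M <= 0):
            raise ValueError(
                f"spec '{spec.name}': M and S must stay positive over the span"
            )
        frames.append(pd.DataFrame({
            "sex": sex, "age": ages,
            "L": _polyval(spec.coeffs("L", sex), ages), "M": M, "S": S,
        }))
    return ReferenceTable(name=spec.name, data=pd.concat(frames, ignore_index=True))


def default_reference_specs() -> dict[str, SyntheticReferenceSpec]:
    """Stand-ins for the WHO, IOTF and CDC BMI references (synthetic).

    The curves mimic real child BMI references: median BMI dipping to ~15
    kg/m**2 around age 5-6 then rising to ~21 at 18, coefficient of variation
    growing from ~0.08 to ~0.13, and a negative Box-Cox power (right skew).
    The three stand-ins differ by small median shifts and S scalings, giving
    overweight cut-off distances of roughly the size seen between the real
    references (WHO+1 vs IOTF25 near +0.4 z at age 8), with the iotf stand-in
    slightly more variable so that obesity cut-offs sit further apart than
    overweight ones.
    """
    boys_M = (17.0, -0.5, 0.04)
    boys_S = (0.075, 0.003)
    L = (-0.9, -0.025)

    def sexed(coeffs: Coeffs, factor: float) -> dict[str, Coeffs]:
        return {
            "male": tuple(c * factor for c in coeffs),
            "female": tuple(c * factor * 0.99 for c in coeffs),
        }

    def sexed_S(coeffs: Coeffs, factor: float) -> dict[str, Coeffs]:
        return {
            "male": tuple(c * factor for c in coeffs),
            "female": tuple(c * factor * 1.04 for c in coeffs),
        }

    return {
        "who": SyntheticReferenceSpec(
            "who", L=L, M=sexed(boys_M, 1.0), S=sexed_S(boys_S, 1.0)),
        "iotf": SyntheticReferenceSpec(
            "iotf", L=L, M=sexed(boys_M, 1.025), S=sexed_S(boys_S, 1.06)),
        "cdc": SyntheticReferenceSpec(
            "cdc", L=L, M=sexed(boys_M, 1.012), S=sexed_S(boys_S, 1.02),
            age_max=18.0),
    }


def default_refs() -> dict[str, ReferenceTable]:
    """The three default synthetic stand-in references, tabulated."""
    return {name: make_reference(spec)
            for name, spec in default_reference_specs().items()}


# ---------------------------------------------------------------------------
# Grouped prevalence simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """A target population defined in the base reference's z-metric.

    z-scores are Normal(z_shift, s_inflation**2): z_shift moves the whole
    distribution (secular trend), s_inflation > 1 fattens both tails relative
    to the references, violating the pure-shift assumption.  ``groups`` lists
    (sex, mean_age, n) triples.  ``extra_dispersion`` is the c of the
    beta-binomial generator (rho = c*|dz| on the B-side counts); 0 keeps
    sampling plain binomial.
    """

    base_reference: str
    groups: Sequence[tuple[str, float, int]]
    z_shift: float = 0.0
    s_inflation: float = 1.0
    extra_dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_inflation <= 0:
            raise ValueError("s_inflation must be positive")
        if any(n < 1 for _, _, n in self.groups):
            raise ValueError("every group needs n >= 1")


def true_group_prevalence(
    cutoff: CutoffSpec,
    pop: PopulationSpec,
    refs: Mapping[str, ReferenceTable],
    sex: str,
    age: float,
) -> float:
    """Analytic exceedance probability of a cut-off in the population.

    The cut-off is re-expressed in the base reference's z-metric via
    :func:`cross_z`; the tail area of Normal(z_shift, s_inflation**2) beyond
    it follows in closed form.
    """
    z_cut = cross_z(cutoff, refs[pop.base_reference], sex, age, refs)
    return float(norm.cdf(-cutoff.sign * (z_cut - pop.z_shift) / pop.s_inflation))


def _sample_count(rng, n: int, p: float, rho: float) -> int:
    if rho > 1e-9:
        k = 1.0 / rho - 1.0
        p = rng.beta(p * k, (1.0 - p) * k)
    return int(rng.binomial(n, p))


def simulate_prevalence_dataset(
    pop: PopulationSpec,
    refs: Mapping[str, ReferenceTable],
    registry: CutoffRegistry,
    pairs: Sequence[tuple[str, str]],
    source: str = "synthetic",
    group_prefix: str = "g",
) -> pd.DataFrame:
    """Simulate a grouped prevalence dataset in the validation CSV schema.

    For every group and cut-off pair the true exceedance probabilities are
    evaluated analytically, counts are drawn binomially (beta-binomially on
    the B side when ``extra_dispersion`` > 0), and prevalences are reported in
    percent.  Deterministic given ``pop.seed``.
    """
    rng = np.random.default_rng(pop.seed)
    rows = []
    for gi, (sex, age, n) in enumerate(pop.groups):
        group = f"{group_prefix}{gi:03d}"
        for label_A, label_B in pairs:
            spec_A = registry.resolve(label_A, sex, age)
            spec_B = registry.resolve(label_B, sex, age)
            if spec_A.category != spec_B.category:
                raise ValueError(
                    f"pair {label_A}/{label_B} mixes categories "
                    f"({spec_A.category} vs {spec_B.category}) at age {age}"
                )
            p_A = true_group_prevalence(spec_A, pop, refs, sex, age)
            p_B = true_group_prevalence(spec_B, pop, refs, sex, age)
            clip = lambda p: min(max(p, 1e-12), 1 - 1e-12)
            if not (0 < p_A < 1 and 0 < p_B < 1):
                warnings.warn(
                    f"group {group} pair {label_A}/{label_B}: true prevalence "
                    "at machine 0/1, clamped", stacklevel=2,
                )
                p_A, p_B = clip(p_A), clip(p_B)
            rho = 0.0
            if pop.extra_dispersion > 0:
                dz = cutoff_distance(label_A, label_B, sex, age,
                                     refs, registry).dz
                rho = min(pop.extra_dispersion * abs(dz), 0.99)
            y_A = rng.binomial(n, p_A)
            y_B = _sample_count(rng, n, p_B, rho)
            rows.append({
                "group": group, "source": source, "sex": sex,
                "mean_age": age, "n": n, "category": spec_A.category,
                "cutoff_A": label_A, "cutoff_B": label_B,
                "prev_A": 100.0 * y_A / n, "prev_B": 100.0 * y_B / n,
                "overweight_is_net": False,
            })
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


# ---------------------------------------------------------------------------
# Ready-made study designs
# ---------------------------------------------------------------------------

def paper_shaped_pairs() -> dict[str, list[tuple[str, str]]]:
    """Cut-off pairs of the two-survey design: the school-survey arm compares
    IOTF and WHO for overweight and obesity (2 pairs); the cohort arm compares
    all three references within each category (9 pairs)."""
    return {
        "survey": [("IOTF25", "WHO+1"), ("IOTF30", "WHO+2")],
        "cohort": [
            ("IOTF17", "WHO-2"), ("WHO-2", "CDC5"), ("CDC5", "IOTF17"),
            ("IOTF25", "WHO+1"), ("WHO+1", "CDC85"), ("CDC85", "IOTF25"),
            ("IOTF30", "WHO+2"), ("WHO+2", "CDC95"), ("CDC95", "IOTF30"),
        ],
    }


def paper_shaped_design(
    seed: int = 0,
    refs: Mapping[str, ReferenceTable] | None = None,
    registry: CutoffRegistry | None = None,
    s_inflation_survey: float = 1.0,
    s_inflation_cohort: float = 1.0,
) -> pd.DataFrame:
    """A two-source dataset shaped like the published validation data.

    52 school-survey groups (13 regions x 2 sexes x ages 7.5/8.5, median
    n ~ 1350) each contribute 2 cut-off pairs; 22 cohort groups (2 sexes x 11
    ages 6.5-16.5, n ~ 930) contribute 9 pairs: 52*2 + 22*9 = 302 records.
    The survey population sits higher on the z-scale (more overweight) than
    the cohort one.
    """
    if refs is None:
        refs = default_refs()
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(seed)
    pairs = paper_shaped_pairs()

    survey_groups = [
        (sex, age, int(rng.lognormal(np.log(1350), 0.6)) + 400)
        for _ in range(13) for sex in SEXES for age in (7.5, 8.5)
    ]
    cohort_groups = [
        (sex, 6.5 + a, int(rng.integers(700, 1150)))
        for sex in SEXES for a in range(11)
    ]
    df_a = simulate_prevalence_dataset(
        PopulationSpec("who", survey_groups, z_shift=0.55,
                       s_inflation=s_inflation_survey,
                       seed=int(rng.integers(2 ** 31))),
        refs, registry, pairs["survey"], source="survey", group_prefix="a",
    )
    df_b = simulate_prevalence_dataset(
        PopulationSpec("who", cohort_groups, z_shift=0.15,
                       s_inflation=s_inflation_cohort,
                       seed=int(rng.integers(2 ** 31))),
        refs, registry, pairs["cohort"], source="cohort", group_prefix="b",
    )
    return pd.concat([df_a, df_b], ignore_index=True)


def zshift_setup(
    delta_z: float = 0.45,
) -> tuple[dict[str, ReferenceTable], CutoffRegistry, list[tuple[str, str]]]:
    """Two log-normal references that are an exact z-shift of one another.

    With L = 0 and identical S, every BMI value scores ``delta_z`` higher on
    'alt' than on 'base', so cut-off distances are exact and a simulated
    population recovers slope b = 1/s_inflation with no approximation error -
    the cleanest possible bench for slope-recovery experiments.
    """
    S = 0.1
    base = SyntheticReferenceSpec("base", L=(0.0,), M=(15.0, 0.25), S=(S,))
    alt = SyntheticReferenceSpec(
        "alt", L=(0.0,),
        M=tuple(c * float(np.exp(S * delta_z)) for c in (15.0, 0.25)),
        S=(S,),
    )
    refs = {"base": make_reference(base), "alt": make_reference(alt)}
    registry = CutoffRegistry([
        CutoffSpec("BASE+1", "base", "overweight", "both", +1.0, 2.0, 18.0),
        CutoffSpec("BASE+2", "base", "obesity", "both", +2.0, 2.0, 18.0),
        CutoffSpec("BASE-2", "base", "thinness", "both", -2.0, 2.0, 18.0),
        CutoffSpec("ALT+1.2", "alt", "overweight", "both", +1.2, 2.0, 18.0),
        CutoffSpec("ALT+2.2", "alt", "obesity", "both", +2.2, 2.0, 18.0),
        CutoffSpec("ALT-1.7", "alt", "thinness", "both", -1.7, 2.0, 18.0),
    ])
    pairs = [("BASE+1", "ALT+1.2"), ("BASE+2", "ALT+2.2")]
    return refs, registry, pairs


# ---------------------------------------------------------------------------
# The boys-aged-8 worked example
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkedExample:
    """The WHO+1 vs IOTF25 overweight example for boys aged 8.

    The four component z-scores come from the published reference tables
    (WHO cut-off 17.4 kg/m**2 scores 0.91 on IOTF; IOTF cut-off 18.4 kg/m**2
    scores 1.47 on WHO), and the observed prevalences are those of a target
    group of 8-year-old boys: 29.3% (WHO) and 18.0% (IOTF).
    """

    sex: str = "male"
    age: float = 8.0
    label_A: str = "WHO+1"
    label_B: str = "IOTF25"
    z_A: float = 1.00
    z_B: float = 1.31
    z_A_onB: float = 0.91
    z_B_onA: float = 1.47
    p_A: float = 0.293
    p_B: float = 0.180
    category: str = "overweight"

    def distance(self):
        from .distance import CutoffDistance

        return CutoffDistance(
            label_A=self.label_A, label_B=self.label_B,
            sex=self.sex, age=self.age,
            z_A=self.z_A, z_B=self.z_B,
            z_A_onB=self.z_A_onB, z_B_onA=self.z_B_onA,
        )

    @property
    def dz(self) -> float:
        return self.distance().dz

    def lookup_row(self) -> pd.DataFrame:
        """The example as a one-row distance look-up table."""
        d = self.distance()
        return pd.DataFrame([{
            "pair_A": d.label_A, "pair_B": d.label_B, "sex": d.sex,
            "age": d.age, "z_A": d.z_A, "z_B": d.z_B,
            "z_B_onA": d.z_B_onA, "z_A_onB": d.z_A_onB, "dz": d.dz,
        }])


def worked_example_fixture() -> WorkedExample:
    """The bundled boys-aged-8 WHO+1 / IOTF25 record for tests and docs."""
    return WorkedExample()
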