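"""Reversible probit prevalence conversion between cut-offs.

A prevalence p beyond a z-score cut-off z corresponds to the probit

    Z = -sign(z) * PHI^-1(p)

(the sign makes Z positive for typical upper-tail and lower-tail rates
alike).  Under the assumption that the target population's BMI distribution
differs from the references only by a shift on the z-score scale, the
prevalence under cut-off B follows from that under cut-off A by shifting the
probit by the cut-off distance dz:

    p_B = PHI(-sign(z_B) * (Z_A + b*dz))

with b = 1 by default.  Converting back uses -dz, so the round trip is exact:
the algorithm is reversible.  The bias-adjusted variant multiplies dz by
b = 0.84, compensating for target distributions with heavier tails than the
references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "BIAS_ADJUSTED_B",
    "category_sign",
    "prevalence_to_Z",
    "Z_to_prevalence",
    "ConversionResult",
    "convert_prevalence",
    "overweight_including_obesity",
]

#: Equal-weight mean of the five source-by-category regression slopes;
#: the preset multiplier of the bias-adjusted conversion.
BIAS_ADJUSTED_B = 0.84


def category_sign(category: str) -> int:
    """-1 for thinness (lower tail), +1 for overweight/obesity (upper tail)."""
    if category == "thinness":
        return -1
    if category in ("overweight", "obesity"):
        return +1
    raise ValueError(f"unknown category {category!r}")


def _check_sign(sign: int, name: str = "cutoff_sign") -> int:
    if sign not in (-1, 1):
        raise ValueError(f"{name} must be +1 or -1, got {sign!r}")
    return sign


def prevalence_to_Z(p: float, cutoff_sign: int, n: int | None = None) -> float:
    """Probit z-score Z = -sign * PHI^-1(p) for a prevalence proportion.

    Boundary prevalences (0 or 1) have an infinite probit; with a known
    denominator ``n`` they are continuity-corrected to 1/(2n) and 1 - 1/(2n),
    without one they raise.
    """
    _check_sign(cutoff_sign)
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence {p} outside [0, 1]")
    if p in (0.0, 1.0):
        if n is None:
            raise ValueError(
                f"prevalence {p} has an infinite probit; supply the "
                "denominator n for a continuity correction"
            )
        if n < 1:
            raise ValueError("denominator n must be >= 1")
        p = 1.0 / (2.0 * n) if p == 0.0 else 1.0 - 1.0 / (2.0 * n)
    return -cutoff_sign * float(norm.ppf(p))


def Z_to_prevalence(Z: float, cutoff_sign: int) -> float:
    """Prevalence proportion p = PHI(-sign * Z); exact inverse of the probit."""
    _check_sign(cutoff_sign)
    Z = float(Z)
    if not math.isfinite(Z):
        raise ValueError("Z must be finite")
    return float(norm.cdf(-cutoff_sign * Z))


@dataclass(frozen=True)
class ConversionResult:
    """Outcome of one prevalence conversion (all prevalences as proportions)."""

    p_in: float
    p_converted: float
    Z_in: float
    Z_out: float
    dz_used: float
    b_used: float
    sign_in: int
    sign_out: int

    @property
    def dZ(self) -> float:
        return self.Z_out - self.Z_in

    @property
    def percent(self) -> float:
        """Converted prevalence in percent, rounded to 1 dp for reporting."""
        return round(100.0 * self.p_converted, 1)


def convert_prevalence(
    p_in: float,
    dz: float,
    sign_in: int,
    sign_out: int | None = None,
    b: float = 1.0,
    n: int | None = None,
) -> ConversionResult:
    """Convert a prevalence from cut-off A to cut-off B shifted by ``dz``.

    The reverse conversion uses ``-dz``; with ``b=1`` forward then reverse is
    the identity.  Conversions only make sense within a category family, so a
    thinness/overweight sign mismatch raises.
    """
    if sign_out is None:
        sign_out = sign_in
    _check_sign(sign_in, "sign_in")
    _check_sign(sign_out, "sign_out")
    if sign_in != sign_out:
        raise ValueError(
            "cannot convert across category families (thinness vs "
            "overweight/obesity): cut-off signs differ"
        )
    if not math.isfinite(dz):
        raise ValueError("dz must be finite")
    if not b > 0:
        raise ValueError("slope multiplier b must be positive")
    Z_in = prevalence_to_Z(p_in, sign_in, n=n)
    Z_out = Z_in + b * dz
    p_out = Z_to_prevalence(Z_out, sign_out)
    return ConversionResult(
        p_in=float(p_in), p_converted=p_out, Z_in=Z_in, Z_out=Z_out,
        dz_used=float(dz), b_used=float(b), sign_in=sign_in, sign_out=sign_out,
    )


def overweight_including_obesity(p_ow_net: float, p_ob: float) -> float:
    """Inclusive overweight prevalence: net overweight plus obesity.

    Cut-offs define tail areas, so conversion of the overweight category
    requires the prevalence of everyone above the overweight cut-off.
    """
    if p_ow_net < 0 or p_ob < 0:
        raise ValueError("prevalences must be non-negative")
    total = p_ow_net + p_ob
    if total > 1.0 + 1e-12:
        raise ValueError(
            f"net overweight {p_ow_net} + obesity {p_ob} exceeds 1"
        )
    return min(total, 1.0)
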