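"""Triple-oxygen isotope algebra.

Delta values (δ¹⁷O, δ¹⁸O) are per mil (‰) relative to VSMOW; linearized
deltas are δ′ = 1000·ln(1 + δ/1000); the ¹⁷O excess Δ′¹⁷O is reported in
per meg (10⁻⁶), defined against a reference slope of 0.528:

    Δ′¹⁷O = 10⁶ · (ln(1 + δ¹⁷O/1000) − 0.528 · ln(1 + δ¹⁸O/1000))

Fractionation factors relate via the triple-isotope exponent θ:
¹⁷/¹⁶α = (¹⁸/¹⁶α)^θ.  Absolute ratios only enter when mixing pools of
different isotopic composition; Δ′¹⁷O is invariant to the absolute
VSMOW ratios adopted, which are therefore configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LAMBDA_REF",
    "TripleOxygenComposition",
    "FractionationFactor",
    "ReferenceRatios",
    "linearize",
    "from_linearized",
    "cap_delta17",
    "d17O_from_cap",
    "alpha17_from_theta",
    "ratios_from_composition",
    "composition_from_ratios",
]

#: Reference slope of the δ′¹⁷O–δ′¹⁸O relationship for meteoric waters.
LAMBDA_REF = 0.528


def _check_delta(delta_permil: float, name: str = "delta") -> None:
    if not delta_permil > -1000.0:
        raise ValueError(
            f"{name} = {delta_permil} ‰ implies a non-positive isotope ratio; "
            "delta values must exceed −1000 ‰"
        )


def linearize(delta_permil: float) -> float:
    """Return the linearized delta δ′ = 1000·ln(1 + δ/1000), in ‰."""
    _check_delta(delta_permil)
    return 1000.0 * math.log1p(delta_permil / 1000.0)


def from_linearized(delta_prime_permil: float) -> float:
    """Inverse of :func:`linearize`: δ = 1000·(exp(δ′/1000) − 1)."""
    return 1000.0 * math.expm1(delta_prime_permil / 1000.0)


def cap_delta17(d17O: float, d18O: float, slope: float = LAMBDA_REF) -> float:
    """Δ′¹⁷O in per meg from classical δ¹⁷O and δ¹⁸O in ‰."""
    _check_delta(d17O, "d17O")
    _check_delta(d18O, "d18O")
    return 1e6 * (
        math.log1p(d17O / 1000.0) - slope * math.log1p(d18O / 1000.0)
    )


def d17O_from_cap(d18O: float, cap17O_permeg: float,
                  slope: float = LAMBDA_REF) -> float:
    """Closed-form inverse of :func:`cap_delta17`.

    Returns the δ¹⁷O (‰) that yields the requested Δ′¹⁷O (per meg) at the
    given δ¹⁸O.  Used to build source compositions from (δ¹⁸O, Δ′¹⁷O)
    pairs as they are conventionally reported.
    """
    _check_delta(d18O, "d18O")
    return 1000.0 * math.expm1(
        slope * math.log1p(d18O / 1000.0) + cap17O_permeg / 1e6
    )


def alpha17_from_theta(alpha18: float, theta: float) -> float:
    """¹⁷/¹⁶α = exp(θ · ln(¹⁸/¹⁶α))."""
    if not alpha18 > 0:
        raise ValueError(f"alpha18 must be positive, got {alpha18}")
    return math.exp(theta * math.log(alpha18))


@dataclass(frozen=True)
class TripleOxygenComposition:
    """A (δ¹⁷O, δ¹⁸O) pair in ‰ vs VSMOW.

    Δ′¹⁷O and the linearized deltas are always derived from the stored
    δ values, never stored independently, so the defining relation holds
    by construction.  δ²H is carried as an optional passenger for
    serialization; nothing in the model consumes it.
    """

    d17O: float
    d18O: float
    d2H: float | None = None

    def __post_init__(self) -> None:
        _check_delta(self.d17O, "d17O")
        _check_delta(self.d18O, "d18O")

    @property
    def d17O_prime(self) -> float:
        return linearize(self.d17O)

    @property
    def d18O_prime(self) -> float:
        return linearize(self.d18O)

    @property
    def cap17O(self) -> float:
        """Δ′¹⁷O in per meg."""
        return cap_delta17(self.d17O, self.d18O)

    @classmethod
    def from_cap17(cls, d18O: float, cap17O_permeg: float,
                   d2H: float | None = None) -> "TripleOxygenComposition":
        """Build a composition from the (δ¹⁸O, Δ′¹⁷O) pair."""
        return cls(d17O_from_cap(d18O, cap17O_permeg), d18O, d2H)


@dataclass(frozen=True)
class FractionationFactor:
    """A ¹⁸/¹⁶α with its triple-isotope exponent θ; ¹⁷/¹⁶α is derived."""

    alpha18: float
    theta: float

    def __post_init__(self) -> None:
        if not self.alpha18 > 0:
            raise ValueError(f"alpha18 must be positive, got {self.alpha18}")

    @property
    def alpha17(self) -> float:
        return alpha17_from_theta(self.alpha18, self.theta)


#: No fractionation: α18 = α17 = 1 for any θ.
IDENTITY_FRACTIONATION = FractionationFactor(alpha18=1.0, theta=LAMBDA_REF)


@dataclass(frozen=True)
class ReferenceRatios:
    """Absolute ¹⁸O/¹⁶O and ¹⁷O/¹⁶O of VSMOW.

    Defaults are the commonly adopted literature values; any consistent
    positive pair yields identical delta values and Δ′¹⁷O after a
    round trip through ratio space (the reference cancels).
    """

    r18_vsmow: float = 0.0020052
    r17_vsmow: float = 0.0003799

    def __post_init__(self) -> None:
        if not (self.r18_vsmow > 0 and self.r17_vsmow > 0):
            raise ValueError("reference ratios must be strictly positive")


def ratios_from_composition(
    comp: TripleOxygenComposition,
    ref: ReferenceRatios = ReferenceRatios(),
) -> tuple[float, float]:
    """Absolute (¹⁸O/¹⁶O, ¹⁷O/¹⁶O) ratios of a composition."""
    r18 = ref.r18_vsmow * (1.0 + comp.d18O / 1000.0)
    r17 = ref.r17_vsmow * (1.0 + comp.d17O / 1000.0)
    return r18, r17


def composition_from_ratios(
    r18: float,
    r17: float,
    ref: ReferenceRatios = ReferenceRatios(),
) -> TripleOxygenComposition:
    """Inverse of :func:`ratios_from_composition`."""
    return TripleOxygenComposition(
        d17O=1000.0 * (r17 / ref.r17_vsmow - 1.0),
        d18O=1000.0 * (r18 / ref.r18_vsmow - 1.0),
    )
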