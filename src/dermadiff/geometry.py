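"""Brick-and-mortar stratum-corneum geometry and its single-capillary reduction.

The outermost epidermal layer (stratum corneum) is idealised as rectangular
keratinocyte "bricks" of footprint ``a x b`` and height ``h_k`` laid out on a
skin patch of size ``L1 x L2`` and separated by lipid "mortar" channels of
widths ``d1`` and ``d2``.  Diffusion of nanoparticles proceeds through the
lipid channels only, so the transport problem on the patch reduces, in the
spirit of the Kozeny-Carman treatment of granular beds, to a single
equivalent capillary of hydraulic radius

    r_h = epsilon / (a_p * (1 - epsilon))

where ``epsilon`` is the areal fraction of the patch occupied by lipid
channels and ``a_p`` is the specific surface (wall area over volume) of one
keratinocyte.  All lengths are in metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BrickMortarGeometry",
    "CapillaryEquivalent",
    "keratinocyte_count",
    "lipid_area_fraction",
    "lipid_area_fraction_square",
    "specific_surface",
    "hydraulic_radius",
    "build_capillary",
]


def _require_finite_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and positive, got {value!r}")


@dataclass(frozen=True)
class BrickMortarGeometry:
    """Dimensions of the brick-and-mortar skin patch (SI, metres).

    Attributes
    ----------
    L1, L2
        Patch length and width — the skin area over which the substance is
        applied and from which diffusion into the body proceeds.
    a, b
        Keratinocyte footprint dimensions along ``L1`` and ``L2``.
    d1, d2
        Lipid channel widths along ``L1`` and ``L2``.
    h_k
        Keratinocyte height, i.e. thickness of a single keratinocyte layer.
    """

    L1: float
    L2: float
    a: float
    b: float
    d1: float
    d2: float
    h_k: float

    def __post_init__(self) -> None:
        _require_positive(L1=self.L1, L2=self.L2, a=self.a, b=self.b, h_k=self.h_k)
        _require_finite_nonnegative(d1=self.d1, d2=self.d2)
        if not (self.a < self.L1 and self.b < self.L2):
            raise ValueError(
                "patch must fit at least one keratinocyte (a < L1 and b < L2)"
            )

    @classmethod
    def square(cls, L: float, a: float, d: float, h_k: float) -> "BrickMortarGeometry":
        """Symmetric patch: L1 = L2, a = b, d1 = d2."""
        return cls(L1=L, L2=L, a=a, b=a, d1=d, d2=d, h_k=h_k)


@dataclass(frozen=True)
class CapillaryEquivalent:
    """Derived equivalent-capillary record.

    Attributes
    ----------
    epsilon
        Lipid area fraction of the patch surface, dimensionless.
    a_p
        Specific surface of a keratinocyte, 1/m.
    r_h
        Hydraulic radius of the model capillary, m.
    d_c
        Capillary diameter, exactly ``2 * r_h``, m.
    length
        Capillary length, m — the diffusion distance, taken equal to the
        thickness of the keratinocyte layer that controls the resistance.
    """

    epsilon: float
    a_p: float
    r_h: float
    d_c: float
    length: float

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon!r}")
        _require_positive(a_p=self.a_p, r_h=self.r_h, length=self.length)
        if self.d_c != 2.0 * self.r_h:
            raise ValueError("d_c must equal 2 * r_h exactly")


def keratinocyte_count(L: float, a: float, d: float) -> float:
    """Number of keratinocytes fitting along one patch dimension.

    A row of ``n`` bricks of size ``a`` alternating with ``n - 1`` channels of
    width ``d`` spans ``L = a*n + (n - 1)*d``, hence ``n = (L + d)/(a + d)``.
    The count is returned real-valued, NOT rounded: the downstream area
    algebra assumes the exact ratio, so that ``a*n + (n - 1)*d`` recovers
    ``L`` to machine precision.
    """
    _require_finite_nonnegative(L=L, a=a, d=d)
    if a + d <= 0:
        raise ValueError("a + d must be positive")
    return (L + d) / (a + d)


def lipid_area_fraction(geom: BrickMortarGeometry) -> float:
    """Fraction of the patch surface occupied by lipid channels.

    epsilon = (S - S_n) / S with total surface ``S = L1 * L2`` and
    keratinocyte-covered surface ``S_n = (a*n1) * (b*n2)``, the counts being
    the exact real-valued ratios of :func:`keratinocyte_count`.
    """
    n1 = keratinocyte_count(geom.L1, geom.a, geom.d1)
    n2 = keratinocyte_count(geom.L2, geom.b, geom.d2)
    side1 = geom.a * n1 + (n1 - 1.0) * geom.d1
    side2 = geom.b * n2 + (n2 - 1.0) * geom.d2
    s_total = side1 * side2
    s_kerat = (geom.a * n1) * (geom.b * n2)
    return (s_total - s_kerat) / s_total


def lipid_area_fraction_square(L: float, a: float, d: float) -> float:
    """Symmetric-patch special case of :func:`lipid_area_fraction`.

    Thin wrapper for the common ``L1 = L2, a = b, d1 = d2`` layout; equals
    the general form on the corresponding square geometry.
    """
    n = keratinocyte_count(L, a, d)
    side = a * n + (n - 1.0) * d
    return (side * side - (a * n) ** 2) / (side * side)


def specific_surface(a: float, b: float, h_k: float) -> float:
    """Specific surface a_p = S_p / V_p of one keratinocyte brick, 1/m.

    For a rectangular brick, ``S_p = 2*(a*b + b*h_k + a*h_k)`` and
    ``V_p = a*b*h_k``.  The factor 2 (all six faces) is retained; with the
    reference patch parameters this yields a_p = 4.0e5 1/m and, downstream,
    the hydraulic radius r_h = 12.5 nm of the equivalent capillary.
    """
    _require_positive(a=a, b=b, h_k=h_k)
    return 2.0 * (a * b + b * h_k + a * h_k) / (a * b * h_k)


def hydraulic_radius(
    geom: BrickMortarGeometry, *, half_specific_surface: bool = False
) -> float:
    """Kozeny-Carman hydraulic radius r_h = epsilon / (a_p * (1 - epsilon)).

    Parameters
    ----------
    geom
        Brick-and-mortar patch geometry.
    half_specific_surface
        Use ``a_p / 2`` (three faces instead of six), an alternative surface
        convention retained for comparison only; it doubles ``r_h``.
    """
    eps = lipid_area_fraction(geom)
    if eps >= 1.0:
        raise ValueError("degenerate geometry: lipid fraction is 1")
    a_p = specific_surface(geom.a, geom.b, geom.h_k)
    if half_specific_surface:
        a_p /= 2.0
    return eps / (a_p * (1.0 - eps))


def build_capillary(
    geom: BrickMortarGeometry,
    length: float,
    *,
    half_specific_surface: bool = False,
) -> CapillaryEquivalent:
    """Assemble the equivalent-capillary record for a patch geometry.

    ``length`` is the capillary length (diffusion distance), supplied
    independently of the patch dimensions.  Raises ``ValueError`` for
    degenerate geometries (no lipid channels: epsilon = 0).
    """
    _require_positive(length=length)
    eps = lipid_area_fraction(geom)
    if eps <= 0.0:
        raise ValueError("degenerate geometry: no lipid channels (epsilon = 0)")
    a_p = specific_surface(geom.a, geom.b, geom.h_k)
    if half_specific_surface:
        a_p /= 2.0
    r_h = eps / (a_p * (1.0 - eps))
    return CapillaryEquivalent(
        epsilon=eps, a_p=a_p, r_h=r_h, d_c=2.0 * r_h, length=length
    )
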