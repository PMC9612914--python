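"""Scaling normalized relationships to absolute SI units, and Rall
equivalent-cylinder quantities.

The normalized laws only constrain exponents; absolute intercepts come from
typical property ranges. For each property A the empirical fold range q_E
(study-averaged max/min) is compared with the theoretical fold q_T =
q_S**|c| implied by the size exponent c, a theoretical [A_min, A_max] range
is built so that A_max/A_min = q_T while the midpoint matches the
study-averaged empirical midpoint, and the intercept is anchored so that
the law maps the smallest size onto the appropriate extreme of A's range
(A_min for c > 0, A_max for c < 0; the same rule anchors a law between two
electrophysiological properties at B_min).

The Rall helpers implement the passive equivalent-cylinder identities
L = pi * (tau/tau1 - 1)**(-1/2), C = (tau/R) * L/tanh(L),
R_m = R * S_neuron * tanh(L)/L and C_m = C / S_neuron, so that
R_m * C_m = tau holds for any jointly derived set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .powerlaw import LawError, PowerLaw


class RangeError(ValueError):
    """Degenerate or inconsistent property range."""


@dataclass(frozen=True)
class PropertyRange:
    """Positive [min, max] interval in SI units."""

    min: float
    max: float
    provenance: str = "empirical"

    def __post_init__(self) -> None:
        if not (0 < self.min < self.max):
            raise RangeError(f"need 0 < min < max, got [{self.min}, {self.max}]")

    @property
    def fold(self) -> float:
        return self.max / self.min

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min + self.max)


@dataclass(frozen=True)
class QRatios:
    """Empirical and theoretical fold ranges of one property."""

    prop: str
    q_e: float | None
    q_t: float | None

    def __post_init__(self) -> None:
        for q in (self.q_e, self.q_t):
            if q is not None and q < 1:
                raise RangeError("fold ranges must be >= 1")


#: typical adult-cat ranges published for the bundled framework
CAT_RANGES: dict[str, PropertyRange] = {
    "S_neuron": PropertyRange(0.18e-6, 0.44e-6, "published cat range"),
    "R": PropertyRange(0.5e6, 4.0e6, "published cat theoretical range"),
    "I_th": PropertyRange(3.9e-9, 35.0e-9, "published cat theoretical range"),
}

#: study-averaged fold range of cat MN size (soma diameter / surface area)
CAT_SIZE_FOLD = 2.4


def empirical_fold_ratio(studies) -> float:
    """Average across studies of the per-study max/min ratio.

    ``studies`` is an iterable of (min, max) pairs, one per study.
    """
    ratios = []
    for lo, hi in studies:
        if not (0 < lo < hi):
            raise RangeError(f"study min/max invalid: ({lo}, {hi})")
        ratios.append(hi / lo)
    if not ratios:
        raise RangeError("no studies provided")
    return float(np.mean(ratios))


def theoretical_fold(q_s: float, c: float) -> float:
    """Theoretical fold range q_T = q_S**|c| propagated through a size law."""
    if q_s < 1:
        raise RangeError("size fold must be >= 1")
    return q_s ** abs(c)


def theoretical_range(
    q_t: float, a_min_e: float, a_max_e: float
) -> PropertyRange:
    """Closed-form range with fold q_T and the empirical midpoint.

    A_min = (A_min_E + A_max_E) / (1 + q_T), A_max = q_T * A_min, so both
    the fold and midpoint constraints hold exactly.
    """
    if q_t <= 1:
        raise RangeError("theoretical fold must exceed 1")
    if not (0 < a_min_e < a_max_e):
        raise RangeError("need 0 < A_min_E < A_max_E")
    a_min = (a_min_e + a_max_e) / (1.0 + q_t)
    return PropertyRange(a_min, q_t * a_min, provenance="theoretical")


def scale_intercept(
    c: float,
    a_range: PropertyRange,
    s_range: PropertyRange,
    prop_y: str = "y",
    prop_x: str = "S_neuron",
) -> PowerLaw:
    """Absolute-SI law anchored at the small end of the reference range.

    k = A_min / S_min**c for c > 0 (smallest size maps to the smallest A),
    k = A_max / S_min**c for c < 0 (smallest size maps to the largest A).
    The same rule applies between two electrophysiological properties with
    the reference range at B_min.
    """
    if c == 0:
        raise LawError("cannot anchor a law with zero exponent")
    anchor = a_range.min if c > 0 else a_range.max
    return PowerLaw(
        prop_y=prop_y,
        prop_x=prop_x,
        k=anchor / s_range.min**c,
        a=c,
        space="absolute",
        provenance="scale_intercept",
    )


def scale_law(
    law: PowerLaw,
    a_range: PropertyRange,
    x_range: PropertyRange,
) -> PowerLaw:
    """Rescale a normalized law to absolute SI keeping its exponent."""
    scaled = scale_intercept(law.a, a_range, x_range,
                             prop_y=law.prop_y, prop_x=law.prop_x)
    return replace(scaled, n=law.n,
                   provenance=f"scaled({law.provenance})")


# ---------------------------------------------------------------------------
# Rall equivalent-cylinder quantities
# ---------------------------------------------------------------------------

#: standard value of tanh(L)/L for adult cat MNs; 0.5 also appears in the
#: literature for the capacitance identity.
DEFAULT_TANHL_OVER_L = 0.6


@dataclass(frozen=True)
class RallParams:
    """Jointly derived passive cable quantities."""

    L: float                    # electrotonic length, dimensionless
    tanhL_over_L: float
    C: float | None = None      # total capacitance [F]
    C_m: float | None = None    # specific capacitance [F/m^2]
    R_m: float | None = None    # specific resistivity [ohm*m^2]
    tau: float | None = None    # membrane time constant [s]


def electrotonic_length(tau: float, tau1: float) -> float:
    """L = pi * (tau/tau1 - 1)**(-1/2) from the two slowest time constants."""
    if not (tau > tau1 > 0):
        raise LawError("electrotonic length requires tau > tau1 > 0")
    return math.pi * (tau / tau1 - 1.0) ** -0.5


def rall_quantities(
    tau: float,
    R: float,
    L: float | None = None,
    tau1: float | None = None,
    S_neuron: float | None = None,
) -> RallParams:
    """Capacitance and specific membrane quantities from tau, R and L.

    Provide either L directly or tau1 (from which L is computed). With
    S_neuron given, R_m = R * S * tanh(L)/L and C_m = C / S are attached;
    these satisfy R_m * C_m = tau identically.
    """
    if L is None:
        if tau1 is None:
            raise LawError("provide L or tau1")
        L = electrotonic_length(tau, tau1)
    if L <= 0:
        raise LawError("electrotonic length must be positive")
    if tau <= 0 or R <= 0:
        raise LawError("tau and R must be positive")
    f = math.tanh(L) / L
    C = (tau / R) * (1.0 / f)
    R_m = C_m = None
    if S_neuron is not None:
        if S_neuron <= 0:
            raise LawError("surface area must be positive")
        R_m = R * S_neuron * f
        C_m = C / S_neuron
    return RallParams(L=L, tanhL_over_L=f, C=C, C_m=C_m, R_m=R_m, tau=tau)


def rm_law_from_r_law(
    r_law: PowerLaw, tanhL_over_L: float = DEFAULT_TANHL_OVER_L
) -> PowerLaw:
    """Specific-resistivity law R_m = tanh(L)/L * k_R * S**(c_R + 1).

    Derived from R = R_m / S * L/tanh(L) applied to an absolute R(S) law
    with S the neuron surface area.
    """
    if r_law.prop_y != "R":
        raise LawError("expected a law for R")
    return PowerLaw(
        prop_y="R_m",
        prop_x=r_law.prop_x,
        k=tanhL_over_L * r_law.k,
        a=r_law.a + 1.0,
        space=r_law.space,
        provenance=f"rall({r_law.provenance})",
    )


def delta_vth(law_ith_r: PowerLaw, tol: float = 0.1) -> float:
    """Voltage threshold amplitude from a near-Ohmic I_th(R) law, in volts.

    When I_th = k * R**a with a within ``tol`` of -1, Ohm's law makes the
    intercept k the depolarization I_th * R needed to reach threshold.
    """
    if abs(law_ith_r.a + 1.0) > tol:
        raise LawError(
            f"I_th(R) exponent {law_ith_r.a:.3f} is not near-Ohmic "
            f"(|a + 1| > {tol})"
        )
    return float(law_ith_r.k)
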