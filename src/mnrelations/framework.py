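"""Bundled adult-cat relationship framework, motoneuron profiles and pools.

The framework is the published 9-property grid of absolute-SI power laws
(neuron surface area, soma diameter, input resistance, specific resistivity,
capacitance, time constant, rheobase, AHP duration, axonal conduction
velocity): given any single measured property, every other property of the
same motoneuron can be reconstructed from the pertinent line of the grid.
Constants are stored as printed (2 significant figures), so chained
round-trips agree only to ~10%; a framework recomputed without rounding can
be substituted wherever a :class:`RelationshipSet` is accepted.

Pools are built by drawing neuron surface areas from a right-skewed
distribution over the typical cat range (many small motoneurons, few large
ones) and reconstructing one full profile per size, which makes every
property column monotone in size by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import powerlaw as pw
from .pipeline import RelationshipSet
from .powerlaw import PowerLaw
from .properties import get_property
from .scaling import CAT_RANGES, PropertyRange
from .datasets import GlobalDataset
from .pipeline import prediction_metrics

FRAMEWORK_PROPS = (
    "S_neuron", "D_soma", "R", "R_m", "C", "tau", "I_th", "AHP", "ACV",
)

# Published grid: magnitude of intercept and exponent of y = k * x**a for
# each (y given x) entry; the exponent sign is the product of the two
# properties' orientations with respect to motoneuron size.
_GRID_MAGNITUDES: dict[str, dict[str, tuple[float, float]]] = {
    # x = S_neuron
    "S_neuron": {
        "D_soma": (1.8e2, 1.0),
        "R": (1.7e-10, 2.43),
        "R_m": (1.0e-10, 1.43),
        "C": (1.3e-2, 1.0),
        "tau": (1.0e-12, 1.48),
        "I_th": (3.8e8, 2.52),
        "AHP": (1.0e-11, 1.51),
        "ACV": (3.0e6, 0.69),
    },
    "D_soma": {
        "S_neuron": (5.5e-3, 1.0),
        "R": (5.1e-5, 2.43),
        "R_m": (1.7e-7, 1.43),
        "C": (7.9e-5, 1.0),
        "tau": (2.3e-9, 1.48),
        "I_th": (7.8e2, 2.52),
        "AHP": (2.7e-8, 1.51),
        "ACV": (8.1e4, 0.69),
    },
    "R": {
        "S_neuron": (9.5e-5, 0.41),
        "D_soma": (1.7e-2, 0.41),
        "R_m": (5.7e-5, 0.59),
        "C": (1.5e-6, 0.40),
        "tau": (9.6e-7, 0.61),
        "I_th": (2.7e-2, 1.04),
        "AHP": (1.3e-5, 0.62),
        "ACV": (4.9e3, 0.29),
    },
    "R_m": {
        "S_neuron": (1.5e-7, 0.70),
        "D_soma": (2.6e-5, 0.70),
        "R": (6.8e6, 1.70),
        "C": (1.8e-9, 0.69),
        "tau": (1.4e-2, 1.04),
        "I_th": (2.2e-9, 1.76),
        "AHP": (2.2e-1, 1.06),
        "ACV": (5.4e1, 0.48),
    },
    "C": {
        "S_neuron": (1.2e2, 1.0),
        "D_soma": (2.1e4, 1.0),
        "R": (1.5e-15, 2.48),
        "R_m": (1.7e-13, 1.46),
        "tau": (8.6e-16, 1.51),
        "I_th": (6.5e13, 2.57),
        "AHP": (7.7e-15, 1.54),
        "ACV": (8.2e7, 0.71),
    },
    "tau": {
        "S_neuron": (8.4e-9, 0.67),
        "D_soma": (1.5e-6, 0.67),
        "R": (7.1e9, 1.64),
        "R_m": (3.6e1, 0.96),
        "C": (1.6e-10, 0.66),
        "I_th": (1.6e-12, 1.70),
        "AHP": (1.7e1, 1.02),
        "ACV": (7.5, 0.47),
    },
    "I_th": {
        "S_neuron": (4.0e-4, 0.40),
        "D_soma": (7.1e-2, 0.40),
        "R": (3.1e-2, 0.96),
        "R_m": (7.4e-6, 0.57),
        "C": (5.9e-6, 0.39),
        "tau": (1.2e-7, 0.59),
        "AHP": (1.5e-6, 0.60),
        "ACV": (1.3e4, 0.27),
    },
    "AHP": {
        "S_neuron": (5.5e-8, 0.66),
        "D_soma": (9.8e-6, 0.66),
        "R": (7.5e7, 1.61),
        "R_m": (2.5, 0.95),
        "C": (9.7e-10, 0.65),
        "tau": (6.2e-2, 0.98),
        "I_th": (1.8e-10, 1.67),
        "ACV": (2.7e1, 0.46),
    },
    "ACV": {
        "S_neuron": (4.6e-10, 1.44),
        "D_soma": (8.3e-8, 1.44),
        "R": (8.3e12, 3.50),
        "R_m": (2.3e3, 2.06),
        "C": (9.0e-12, 1.41),
        "tau": (7.4e1, 2.14),
        "I_th": (1.1e-15, 3.64),
        "AHP": (1.4e3, 2.18),
    },
}


def _signed_exponent(prop_y: str, prop_x: str, magnitude: float) -> float:
    sign = get_property(prop_y).orientation * get_property(prop_x).orientation
    return sign * magnitude


def cat_framework() -> RelationshipSet:
    """The published cat framework as an absolute-SI RelationshipSet.

    Size laws are referenced to neuron surface area; every ordered pair of
    framework properties has a pairwise law taken verbatim from the
    published grid.
    """
    rs = RelationshipSet(space="absolute", order=FRAMEWORK_PROPS)
    for x, row in _GRID_MAGNITUDES.items():
        for y, (k, mag) in row.items():
            law = PowerLaw(
                prop_y=y, prop_x=x, k=k,
                a=_signed_exponent(y, x, mag),
                space="absolute", provenance="published-grid",
            )
            rs.pairwise[(y, x)] = law
            if x == "S_neuron":
                rs.size_laws[y] = law
            if y == "S_neuron":
                rs.inverse_laws[x] = law
    return rs


#: admissible seed ranges, propagated from the cat surface-area range
def property_range(prop: str, framework: RelationshipSet | None = None
                   ) -> PropertyRange:
    """Typical cat range of a framework property.

    Bundled ranges are used where published; otherwise the surface-area
    range is propagated through the framework law for the property.
    """
    if prop in CAT_RANGES:
        return CAT_RANGES[prop]
    fw = framework if framework is not None else cat_framework()
    if prop == "S_neuron":
        return CAT_RANGES["S_neuron"]
    law = fw.law(prop, "S_neuron")
    s = CAT_RANGES["S_neuron"]
    lo, hi = sorted((pw.evaluate(law, s.min), pw.evaluate(law, s.max)))
    return PropertyRange(lo, hi, provenance="propagated from S_neuron range")


@dataclass(frozen=True)
class MNProfile:
    """One inter-consistent vector of motoneuron properties (SI units)."""

    S_neuron: float
    D_soma: float
    R: float
    R_m: float
    C: float
    C_m: float
    tau: float
    I_th: float
    AHP: float
    ACV: float
    dV_th: float
    seed_property: str = "S_neuron"

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in (
            "S_neuron", "D_soma", "R", "R_m", "C", "C_m", "tau",
            "I_th", "AHP", "ACV", "dV_th",
        )}


class ProfileError(ValueError):
    """Invalid seed property or value."""


def build_profile(
    seed_property: str,
    value: float,
    framework: RelationshipSet | None = None,
    range_tolerance: float | None = 3.0,
) -> MNProfile:
    """Reconstruct a complete motoneuron profile from one known property.

    Every other property is computed through the framework law seeded at
    ``seed_property``; the seed value itself is returned unchanged. The
    voltage threshold is attached as I_th * R (near-Ohmic product), and the
    specific capacitance as C / S_neuron. ``range_tolerance`` rejects seed
    values further than that multiple outside the typical cat range
    (None disables the check).
    """
    if seed_property not in FRAMEWORK_PROPS:
        raise ProfileError(
            f"unknown seed property {seed_property!r}; "
            f"expected one of {FRAMEWORK_PROPS}"
        )
    if not (np.isfinite(value) and value > 0):
        raise ProfileError("seed value must be a positive finite number")
    fw = framework if framework is not None else cat_framework()
    if range_tolerance is not None:
        rng = property_range(seed_property, fw)
        if not (rng.min / range_tolerance <= value
                <= rng.max * range_tolerance):
            raise ProfileError(
                f"{seed_property}={value:g} outside {range_tolerance}x the "
                f"typical cat range [{rng.min:g}, {rng.max:g}]"
            )
    values = {seed_property: float(value)}
    for prop in FRAMEWORK_PROPS:
        if prop == seed_property:
            continue
        values[prop] = pw.evaluate(fw.law(prop, seed_property), value)
    return MNProfile(
        **values,
        C_m=values["C"] / values["S_neuron"],
        dV_th=values["I_th"] * values["R"],
        seed_property=seed_property,
    )


@dataclass(frozen=True)
class MNPool:
    """A sampled population of inter-consistent motoneuron profiles."""

    profiles: tuple[MNProfile, ...]
    size_dist: str
    seed: int
    s_range: PropertyRange = field(default_factory=lambda: CAT_RANGES["S_neuron"])

    def __len__(self) -> int:
        return len(self.profiles)

    def column(self, prop: str) -> np.ndarray:
        return np.array([getattr(p, prop) for p in self.profiles])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_dict() for p in self.profiles])


def _draw_sizes(
    n: int,
    rng: np.random.Generator,
    s_range: PropertyRange,
    dist: str,
) -> np.ndarray:
    """Right-skewed sizes over [S_min, S_max] (many small, few large)."""
    log_lo, log_hi = np.log(s_range.min), np.log(s_range.max)
    span = log_hi - log_lo
    if dist == "lognormal":
        # truncated lognormal, mode in the lower third of the log range
        mu, sigma = log_lo + 0.35 * span, 0.45 * span
        out = np.empty(0)
        while out.size < n:
            draw = rng.normal(mu, sigma, size=4 * n)
            draw = draw[(draw >= log_lo) & (draw <= log_hi)]
            out = np.concatenate([out, draw])
        return np.exp(out[:n])
    if dist == "loguniform":
        return np.exp(rng.uniform(log_lo, log_hi, size=n))
    raise ValueError(f"unknown size distribution {dist!r}")


def generate_pool(
    n: int,
    size_dist: str = "lognormal",
    seed: int = 0,
    s_range: PropertyRange | None = None,
    framework: RelationshipSet | None = None,
) -> MNPool:
    """Sample a motoneuron pool of ``n`` inter-consistent profiles.

    Sizes (neuron surface areas) are drawn from the requested distribution
    over the typical cat range, sorted ascending, and expanded into full
    profiles; the result is deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    s_range = s_range if s_range is not None else CAT_RANGES["S_neuron"]
    if not (s_range.min >= CAT_RANGES["S_neuron"].min / 10
            and s_range.max <= CAT_RANGES["S_neuron"].max * 10):
        raise ValueError("requested size range far outside admissible bounds")
    fw = framework if framework is not None else cat_framework()
    rng = np.random.default_rng(seed)
    sizes = np.sort(_draw_sizes(n, rng, s_range, size_dist))
    profiles = tuple(
        build_profile("S_neuron", s, framework=fw, range_tolerance=None)
        for s in sizes
    )
    return MNPool(profiles=profiles, size_dist=size_dist, seed=seed,
                  s_range=s_range)


def score_external(
    dataset: GlobalDataset,
    framework: RelationshipSet | None = None,
    nme_mode: str = "relative",
    r2_mode: str = "pearson",
) -> dict[str, float]:
    """Score framework predictions on an absolute-SI external dataset.

    The framework law for the dataset's pair predicts y from x without any
    refitting; nME, nRMSE and r2 are returned. The result is invariant to
    dataset row order.
    """
    fw = framework if framework is not None else cat_framework()
    try:
        law = fw.law(dataset.prop_y, dataset.prop_x)
    except KeyError:
        raise KeyError(
            f"pair ({dataset.prop_y}; {dataset.prop_x}) not covered by the "
            "framework"
        ) from None
    pred = pw.evaluate(law, dataset.x)
    return prediction_metrics(dataset.y, pred, nme_mode=nme_mode,
                              r2_mode=r2_mode)
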