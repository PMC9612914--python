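"""Muscle-unit vs motoneuron couplings and the size-principle summary.

A study measuring a muscle-unit size index A_mU (tetanic or twitch force,
innervation ratio, fibre cross-sectional area) against a motoneuron
property B_MN yields a power fit A_mU = k * B_MN**b. Because the mU size
indices are linearly related to mU size, and B_MN relates to MN size
through its size exponent c_B, the fit transforms into a coupling
S_mU proportional to S_MN**c with c = b * c_B. Same-sign c values across
studies support a monotonic motor-unit size coupling (the size principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import GlobalDataset, InsufficientDataError
from .pipeline import RelationshipSet
from .powerlaw import PowerLaw, fit_power
from .properties import get_property

#: size exponents of the motoneuron reference properties as printed with
#: the published coupling table (ACV from the normalized final column at
#: one decimal; R and I_th from the absolute grid at two decimals; a size
#: index itself has exponent 1).
PRINTED_SIZE_EXPONENTS = {
    "ACV": 0.7,
    "R": -2.43,
    "I_th": 2.52,
    "S_MN": 1.0,
    "S_neuron": 1.0,
    "D_soma": 1.0,
}

#: published per-study fits (species, mU property, MN property, exponent b)
PUBLISHED_MU_FITS: tuple[tuple[str, str, str, float], ...] = (
    ("rat", "IR", "ACV", 3.4),
    ("cat", "F_tw", "ACV", 9.4),
    ("cat", "F_tet", "ACV", 7.2),
    ("cat", "F_tet", "R", -1.3),
    ("cat", "F_tet", "S_MN", 2.0),
    ("mouse", "F_tw", "R", -2.1),
    ("mouse", "F_tw", "I_th", 1.3),
    ("mouse", "F_tet", "I_th", 1.0),
)


class MULinkError(ValueError):
    """Invalid muscle-unit coupling input."""


@dataclass(frozen=True)
class MULinkResult:
    """One study's mU-MN fit and its size-coupling exponent."""

    species: str
    prop_mu: str
    prop_mn: str
    law: PowerLaw | None     # fitted A_mU = k * B_MN**b (None if b supplied)
    b: float                 # fitted exponent
    c_b: float               # size exponent of the MN reference property
    c: float                 # final coupling exponent, b * c_b

    def __post_init__(self) -> None:
        if not np.isfinite(self.c):
            raise MULinkError("coupling exponent must be finite")


def remove_outliers(
    x,
    y,
    on: str = "x",
    threshold_sd: float = 2.0,
):
    """Single-pass mean +/- threshold*sd filter on one axis.

    The mean and sample sd are computed once on the raw scale of the chosen
    axis; points outside the band are removed (no re-iteration). Returns
    (x_kept, y_kept, removed_indices).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MULinkError("x and y must be 1-d arrays of equal length")
    if x.size < 4:
        raise InsufficientDataError("need >= 4 points for outlier removal")
    if on not in ("x", "y"):
        raise MULinkError("axis must be 'x' or 'y'")
    axis = x if on == "x" else y
    mean, sd = axis.mean(), axis.std(ddof=1)
    keep = np.abs(axis - mean) <= threshold_sd * sd
    removed = np.flatnonzero(~keep)
    if not keep.any():
        raise MULinkError("outlier filter removed every point")
    return x[keep], y[keep], removed


def _size_exponent(prop_mn: str, size_laws: RelationshipSet | None) -> float:
    if size_laws is not None:
        if get_property(prop_mn).is_size_index:
            return 1.0
        try:
            return size_laws.law(prop_mn, "S_MN").a
        except KeyError:
            try:
                return size_laws.law(prop_mn, "S_neuron").a
            except KeyError:
                pass
        raise MULinkError(f"{prop_mn} not covered by the size laws")
    try:
        return PRINTED_SIZE_EXPONENTS[prop_mn]
    except KeyError:
        raise MULinkError(
            f"no printed size exponent for {prop_mn}; pass size_laws"
        ) from None


def mu_coupling(
    dataset: GlobalDataset,
    size_laws: RelationshipSet | None = None,
) -> MULinkResult:
    """Fit A_mU = k * B_MN**b and transform into the size coupling c = b*c_B.

    The mU property must be a linear size index (the linearity means any
    positive rescaling of the index changes k but not b, so c is invariant
    to the index's units).
    """
    p_mu = get_property(dataset.prop_y)
    if p_mu.role != "mU" or not p_mu.is_size_index:
        raise MULinkError(
            f"{dataset.prop_y} is not a muscle-unit size index"
        )
    law = fit_power(dataset.x, dataset.y, prop_x=dataset.prop_x,
                    prop_y=dataset.prop_y,
                    space="normalized" if dataset.normalized else "absolute")
    c_b = _size_exponent(dataset.prop_x, size_laws)
    return MULinkResult(
        species=dataset.species,
        prop_mu=dataset.prop_y,
        prop_mn=dataset.prop_x,
        law=law,
        b=law.a,
        c_b=c_b,
        c=law.a * c_b,
    )


def coupling_from_exponent(
    species: str, prop_mu: str, prop_mn: str, b: float,
    size_laws: RelationshipSet | None = None,
) -> MULinkResult:
    """Size coupling from an already-fitted exponent b (no raw data)."""
    c_b = _size_exponent(prop_mn, size_laws)
    return MULinkResult(species=species, prop_mu=prop_mu, prop_mn=prop_mn,
                        law=None, b=b, c_b=c_b, c=b * c_b)


def published_couplings() -> list[MULinkResult]:
    """The published eight study couplings, recomputed as c = b * c_B."""
    return [coupling_from_exponent(sp, a, bmn, b)
            for sp, a, bmn, b in PUBLISHED_MU_FITS]


@dataclass(frozen=True)
class CouplingSummary:
    """Across-study summary of coupling exponents."""

    mean: float
    sd: float          # population (n) standard deviation
    fold: float        # max/min of the exponents
    n: int
    monotonic: bool    # all exponents share one sign

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "fold": self.fold,
                "n": self.n, "monotonic": self.monotonic}


def coupling_summary(results: list[MULinkResult]) -> CouplingSummary:
    """Mean, population sd and fold range of the coupling exponents.

    The population (divide-by-n) sd is used here, unlike the sample sd
    convention elsewhere in the package: the across-study spread describes
    the full set of retrieved couplings, not a sample from a larger pool.
    """
    if len(results) < 2:
        raise InsufficientDataError("need >= 2 coupling results")
    c = np.array([r.c for r in results])
    return CouplingSummary(
        mean=float(c.mean()),
        sd=float(c.std(ddof=0)),
        fold=float(c.max() / c.min()) if c.min() != 0 else float("inf"),
        n=c.size,
        monotonic=bool(np.all(c > 0) or np.all(c < 0)),
    )
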