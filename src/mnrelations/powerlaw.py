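"""Power laws A = k * B**a: fitting in log-log space, analytic inversion,
composition, evaluation and JSON round-tripping.

Fitting is ordinary least squares of ln(y) on ln(x) (natural logs), so k is
the exponentiated intercept and a the slope. r2 is the squared Pearson
correlation of the logs, the p-value a two-sided t-test of slope != 0, and
the 95% confidence bounds come from the t distribution on slope and
log-intercept (the intercept bound exponentiated).

Inverse relationships are obtained analytically (B = k**(-1/a) * A**(1/a)),
not by swapping axes and refitting: an axis-swapped OLS refit estimates
r2/a, not 1/a, and contradicts published inverse constants. A refit-based
inverse is available separately for diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


class FitError(ValueError):
    """Degenerate input for a regression."""


class LawError(ValueError):
    """Invalid analytic manipulation of a power law."""


@dataclass(frozen=True)
class PowerLaw:
    """A fitted or derived relation y = k * x**a.

    ``space`` is "normalized" (percent-of-maximum units) or "absolute"
    (SI base units). Derived laws produced by :func:`compose` carry no
    r2/p (consumers must not gate on them); analytically inverted laws keep
    the statistics of the fit they came from.
    """

    prop_y: str
    prop_x: str
    k: float
    a: float
    k_ci: tuple[float, float] | None = None
    a_ci: tuple[float, float] | None = None
    r2: float | None = None
    p: float | None = None
    n: int | None = None
    space: str = "normalized"
    provenance: str = "fit"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise LawError("intercept k must be positive")
        if self.space not in ("normalized", "absolute"):
            raise LawError(f"unknown space {self.space!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.prop_y, self.prop_x)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pair": [self.prop_y, self.prop_x],
            "k": self.k,
            "a": self.a,
            "k_ci": list(self.k_ci) if self.k_ci else None,
            "a_ci": list(self.a_ci) if self.a_ci else None,
            "r2": self.r2,
            "p": self.p,
            "n": self.n,
            "space": self.space,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLaw":
        return cls(
            prop_y=d["pair"][0],
            prop_x=d["pair"][1],
            k=d["k"],
            a=d["a"],
            k_ci=tuple(d["k_ci"]) if d.get("k_ci") else None,
            a_ci=tuple(d["a_ci"]) if d.get("a_ci") else None,
            r2=d.get("r2"),
            p=d.get("p"),
            n=d.get("n"),
            space=d.get("space", "normalized"),
            provenance=d.get("provenance", "fit"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PowerLaw":
        return cls.from_dict(json.loads(s))


def fit_power(
    x,
    y,
    prop_x: str = "x",
    prop_y: str = "y",
    space: str = "normalized",
    provenance: str = "fit",
) -> PowerLaw:
    """Least-squares power fit y = k * x**a in ln-ln space."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("power fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise FitError("degenerate x variance")
    res = stats.linregress(lx, ly)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    a_ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    lnk_lo = res.intercept - tcrit * res.intercept_stderr
    lnk_hi = res.intercept + tcrit * res.intercept_stderr
    return PowerLaw(
        prop_y=prop_y,
        prop_x=prop_x,
        k=math.exp(res.intercept),
        a=res.slope,
        k_ci=(math.exp(lnk_lo), math.exp(lnk_hi)),
        a_ci=a_ci,
        r2=res.rvalue**2,
        p=res.pvalue,
        n=int(n),
        space=space,
        provenance=provenance,
    )


def fit_inverse_refit(x, y, **kwargs) -> PowerLaw:
    """Diagnostic inverse by axis swap and OLS refit (slope -> r2/a)."""
    kw = dict(kwargs)
    kw["prop_x"], kw["prop_y"] = (
        kwargs.get("prop_y", "y"),
        kwargs.get("prop_x", "x"),
    )
    return fit_power(y, x, **kw)


def _map_interval(ci, f) -> tuple[float, float]:
    lo, hi = f(ci[0]), f(ci[1])
    return (min(lo, hi), max(lo, hi))


def invert(pl: PowerLaw) -> PowerLaw:
    """Analytic inverse: x = k**(-1/a) * y**(1/a).

    The inverse exponent interval is the image of the forward interval under
    t -> 1/t (valid when the forward interval excludes 0); the intercept
    interval maps ln k -> -ln k / a. Fit statistics are carried over
    unchanged (same dataset, r2 symmetric under axis swap).
    """
    if pl.a == 0:
        raise LawError("law with zero exponent is not invertible")
    a_ci = None
    if pl.a_ci is not None and pl.a_ci[0] * pl.a_ci[1] > 0:
        a_ci = _map_interval(pl.a_ci, lambda t: 1.0 / t)
    k_ci = None
    if pl.k_ci is not None:
        k_ci = _map_interval(pl.k_ci,
                             lambda t: math.exp(-math.log(t) / pl.a))
    return PowerLaw(
        prop_y=pl.prop_x,
        prop_x=pl.prop_y,
        k=pl.k ** (-1.0 / pl.a),
        a=1.0 / pl.a,
        k_ci=k_ci,
        a_ci=a_ci,
        r2=pl.r2,
        p=pl.p,
        n=pl.n,
        space=pl.space,
        provenance=f"invert({pl.provenance})",
    )


def compose(outer: PowerLaw, inner: PowerLaw) -> PowerLaw:
    """Chain y = f(u), u = g(x) into y = (k_f * k_g**a_f) * x**(a_f*a_g).

    ``outer.prop_x`` must equal ``inner.prop_y``. The result is a derived
    law: exponents multiply, intercepts combine, n is the smaller of the
    inputs, and no r2/p is attached.
    """
    if outer.prop_x != inner.prop_y:
        raise LawError(
            f"cannot chain {outer.pair} with {inner.pair}: "
            f"{outer.prop_x!r} != {inner.prop_y!r}"
        )
    if outer.space != inner.space:
        raise LawError("cannot compose laws from different spaces")
    ns = [m for m in (outer.n, inner.n) if m is not None]
    return PowerLaw(
        prop_y=outer.prop_y,
        prop_x=inner.prop_x,
        k=outer.k * inner.k**outer.a,
        a=outer.a * inner.a,
        n=min(ns) if ns else None,
        space=outer.space,
        provenance=f"compose({outer.provenance},{inner.provenance})",
    )


def evaluate(pl: PowerLaw, x):
    """Evaluate y = k * x**a elementwise for positive x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise LawError("evaluate requires strictly positive x")
    y = pl.k * x**pl.a
    return float(y) if y.ndim == 0 else y


def with_pair(pl: PowerLaw, prop_y: str, prop_x: str) -> PowerLaw:
    """Relabel a law's variables (e.g. after a size-index substitution)."""
    return replace(pl, prop_y=prop_y, prop_x=prop_x)
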