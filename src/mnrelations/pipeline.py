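"""Iterative derivation of size-referenced relationships and fivefold
cross-validation.

Every global dataset {A;B} is converted into an {A;S_MN} dataset: if B is
already the size reference the dataset passes through unchanged, otherwise
the B values are mapped through the previously admitted inverse size law
S_MN = f(B). The per-property converted datasets are merged into a "final"
{A;S_MN} dataset and fitted, processing the electrophysiological properties
in the order ACV, AHP, R, I_th, C, tau so that every needed inverse law
exists when it is first used. An inverse law is admitted for downstream use
only if the forward final fit satisfies r2 > 0.3 and p < 0.01.

Once all size laws exist, every pairwise law between processed properties
is produced exactly by composing one size law with the analytic inverse of
the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import GlobalDataset, InsufficientDataError
from . import powerlaw as pw
from .powerlaw import PowerLaw

SIZE = "S_MN"
DEFAULT_ORDER = ("ACV", "AHP", "R", "I_th", "C", "tau")

#: source property pairs per processed property, mirroring the published
#: cat-corpus wiring (each entry: property A -> reference properties B of
#: the available {A;B} global datasets).
DEFAULT_SOURCES = {
    "ACV": (SIZE,),
    "AHP": (SIZE, "ACV"),
    "R": (SIZE, "ACV", "AHP"),
    "I_th": ("R", "ACV", "AHP"),
    "C": ("R", "I_th", "AHP", "ACV"),
    "tau": ("R", "AHP", "I_th", "ACV"),
}


class PipelineError(RuntimeError):
    """Ordering, reachability or admission-gate failure."""


@dataclass(frozen=True)
class FinalDataset:
    """Merged {A; S_MN} points with per-point provenance."""

    prop: str
    s: np.ndarray
    a: np.ndarray
    source_pair: np.ndarray  # reference property B each point came through
    study: np.ndarray

    def __len__(self) -> int:
        return int(self.s.size)


@dataclass
class RelationshipSet:
    """Directed network of size-referenced power laws.

    ``size_laws`` maps property -> law A = f(S_MN); ``inverse_laws`` holds
    the admitted inverses S_MN = f(A); ``pairwise`` maps (A, B) -> law
    A = f(B) for every ordered pair of processed properties.
    """

    space: str = "normalized"
    order: tuple[str, ...] = ()
    size_laws: dict[str, PowerLaw] = field(default_factory=dict)
    inverse_laws: dict[str, PowerLaw] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], PowerLaw] = field(default_factory=dict)
    final_datasets: dict[str, FinalDataset] = field(default_factory=dict)
    gates: dict[str, dict] = field(default_factory=dict)

    def law(self, prop_y: str, prop_x: str) -> PowerLaw:
        """Law for prop_y as a function of prop_x."""
        if prop_x == SIZE and prop_y in self.size_laws:
            return self.size_laws[prop_y]
        if prop_y == SIZE and prop_x in self.inverse_laws:
            return self.inverse_laws[prop_x]
        if (prop_y, prop_x) in self.pairwise:
            return self.pairwise[(prop_y, prop_x)]
        raise KeyError(f"no law for pair ({prop_y}; {prop_x})")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "space": self.space,
            "order": list(self.order),
            "size_laws": {p: l.to_dict() for p, l in self.size_laws.items()},
            "inverse_laws": {p: l.to_dict()
                             for p, l in self.inverse_laws.items()},
            "pairwise": {f"{a};{b}": l.to_dict()
                         for (a, b), l in self.pairwise.items()},
            "gates": self.gates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelationshipSet":
        rs = cls(space=d["space"], order=tuple(d["order"]))
        rs.size_laws = {p: PowerLaw.from_dict(v)
                        for p, v in d["size_laws"].items()}
        rs.inverse_laws = {p: PowerLaw.from_dict(v)
                           for p, v in d["inverse_laws"].items()}
        for key, v in d["pairwise"].items():
            a, b = key.split(";")
            rs.pairwise[(a, b)] = PowerLaw.from_dict(v)
        rs.gates = d.get("gates", {})
        return rs

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "RelationshipSet":
        return cls.from_dict(json.loads(s))


def transform_to_size(
    gds: GlobalDataset, inv: PowerLaw | None
) -> FinalDataset:
    """Convert a global {A;B} dataset to {A;S_MN} points.

    If B is the size reference the values pass through unchanged; otherwise
    every B value is mapped through the inverse size law. A values are never
    touched and the point count is conserved.
    """
    if gds.prop_x == SIZE:
        s = gds.x
    else:
        if inv is None:
            raise PipelineError(
                f"no inverse size law available for {gds.prop_x}"
            )
        if inv.prop_x != gds.prop_x or inv.prop_y != SIZE:
            raise PipelineError(
                f"inverse law {inv.pair} does not convert {gds.prop_x}"
            )
        s = pw.evaluate(inv, gds.x)
    return FinalDataset(
        prop=gds.prop_y,
        s=np.asarray(s, dtype=float),
        a=gds.y.copy(),
        source_pair=np.full(len(gds), gds.prop_x, dtype=object),
        study=gds.study.copy(),
    )


def _merge_final(parts: list[FinalDataset]) -> FinalDataset:
    return FinalDataset(
        prop=parts[0].prop,
        s=np.concatenate([p.s for p in parts]),
        a=np.concatenate([p.a for p in parts]),
        source_pair=np.concatenate([p.source_pair for p in parts]),
        study=np.concatenate([p.study for p in parts]),
    )


def derive_relationships(
    globals_: list[GlobalDataset],
    order: tuple[str, ...] = DEFAULT_ORDER,
    r2_gate: float = 0.3,
    p_gate: float = 0.01,
    inverse_method: str = "analytic",
    on_gate_failure: str = "halt",
) -> RelationshipSet:
    """Run the full step-by-step derivation over a corpus of global datasets.

    Parameters
    ----------
    globals_
        Normalized global datasets; the first processed property must have
        a dataset referenced directly to S_MN.
    r2_gate, p_gate
        Admission thresholds for an inverse law to be used downstream.
    inverse_method
        "analytic" (default) inverts the forward final fit exactly;
        "refit" swaps axes and refits OLS (diagnostic only).
    on_gate_failure
        "halt" raises listing the affected downstream pairs; "continue"
        records the failure and skips datasets that need the inverse.
    """
    if inverse_method not in ("analytic", "refit"):
        raise ValueError(f"unknown inverse_method {inverse_method!r}")
    if on_gate_failure not in ("halt", "continue"):
        raise ValueError(f"unknown on_gate_failure {on_gate_failure!r}")

    by_prop: dict[str, list[GlobalDataset]] = {}
    for g in globals_:
        by_prop.setdefault(g.prop_y, []).append(g)
    space = "normalized"

    rs = RelationshipSet(space=space, order=tuple(order))
    for prop in order:
        sources = by_prop.get(prop, [])
        if not sources:
            continue
        parts: list[FinalDataset] = []
        skipped: list[str] = []
        for g in sources:
            ref = g.prop_x
            if ref != SIZE:
                if ref not in order or order.index(ref) >= order.index(prop):
                    raise PipelineError(
                        f"{{{prop};{ref}}}: reference {ref} is not processed "
                        f"before {prop} (processing order {order})"
                    )
                if ref not in rs.inverse_laws:
                    if on_gate_failure == "continue":
                        skipped.append(ref)
                        continue
                    raise PipelineError(
                        f"{{{prop};{ref}}}: inverse size law for {ref} was "
                        "not admitted; affected downstream pairs: "
                        + ", ".join(
                            f"{{{p};{r}}}"
                            for p in order[order.index(prop):]
                            for r in (DEFAULT_SOURCES.get(p) or ())
                            if r == ref
                        )
                    )
            parts.append(transform_to_size(g, rs.inverse_laws.get(g.prop_x)))
        if not parts:
            if on_gate_failure == "continue":
                rs.gates[prop] = {
                    "r2": None, "p": None, "admitted": False,
                    "skipped_references": skipped,
                }
                continue
            raise PipelineError(
                f"{prop}: no usable source datasets (skipped refs {skipped})"
            )
        final = _merge_final(parts)
        rs.final_datasets[prop] = final
        law = pw.fit_power(final.s, final.a, prop_x=SIZE, prop_y=prop,
                           space=space, provenance=f"final:{prop}")
        rs.size_laws[prop] = law
        admitted = bool(law.r2 > r2_gate and law.p < p_gate)
        rs.gates[prop] = {
            "r2": law.r2, "p": law.p, "admitted": admitted,
            "skipped_references": skipped,
        }
        if admitted:
            if inverse_method == "analytic":
                rs.inverse_laws[prop] = pw.invert(law)
            else:
                rs.inverse_laws[prop] = pw.fit_power(
                    final.a, final.s, prop_x=prop, prop_y=SIZE,
                    space=space, provenance=f"refit-inverse:{prop}",
                )

    # pairwise laws by exact composition of the size laws
    props = [p for p in order if p in rs.size_laws]
    for a in props:
        for b in props:
            if a == b:
                continue
            rs.pairwise[(a, b)] = pw.compose(
                rs.size_laws[a], pw.invert(rs.size_laws[b])
            )
    return rs


# ---------------------------------------------------------------------------
# fivefold cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    """Validation metrics averaged over the fold permutations."""

    prop_y: str
    prop_x: str
    nme: float
    nrmse: float
    r2_pred: float
    r2_exp: float
    folds: int
    seed: int
    per_fold: tuple[dict, ...] = ()


def prediction_metrics(
    observed,
    predicted,
    nme_mode: str = "relative",
    r2_mode: str = "pearson",
) -> dict[str, float]:
    """nME, nRMSE and r2 between predicted and observed values.

    nME is the maximum per-point relative error in percent (values above
    100% are possible); the "range" variant divides by the observed range
    instead. nRMSE is the RMSE divided by the mean observed value, in
    percent. r2 is the squared Pearson correlation between predicted and
    observed ("ss" gives 1 - SS_res/SS_tot instead).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    err = pred - obs
    if nme_mode == "relative":
        nme = float(np.max(np.abs(err) / obs) * 100.0)
    elif nme_mode == "range":
        nme = float(np.max(np.abs(err)) / np.ptp(obs) * 100.0)
    else:
        raise ValueError(f"unknown nme_mode {nme_mode!r}")
    nrmse = float(np.sqrt(np.mean(err**2)) / np.mean(obs) * 100.0)
    if r2_mode == "pearson":
        if np.ptp(pred) == 0 or np.ptp(obs) == 0:
            r2 = 1.0 if np.allclose(pred, obs) else 0.0
        else:
            r2 = float(stats.pearsonr(pred, obs).statistic ** 2)
    elif r2_mode == "ss":
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot else 1.0
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return {"nme": nme, "nrmse": nrmse, "r2": r2}


def _fold_indices(n: int, folds: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def crossvalidate(
    gds: GlobalDataset,
    folds: int = 5,
    seed: int = 0,
    nme_mode: str = "relative",
    r2_mode: str = "pearson",
) -> CVReport:
    """Fivefold cross-validation of the power law fitted to one dataset.

    Points are shuffled with the given seed and split into ``folds``
    non-overlapping partitions; for each permutation the law is refitted on
    the remaining 80% and scored on the held-out 20%; metrics are averaged
    over the permutations. r2_exp comes from the full-dataset fit.
    """
    n = len(gds)
    if n < 2 * folds:
        raise InsufficientDataError(
            f"{n} points is too few for {folds}-fold CV"
        )
    rng = np.random.default_rng(seed)
    parts = _fold_indices(n, folds, rng)
    per_fold = []
    for i in range(folds):
        test = parts[i]
        train = np.concatenate([parts[j] for j in range(folds) if j != i])
        law = pw.fit_power(gds.x[train], gds.y[train],
                           prop_x=gds.prop_x, prop_y=gds.prop_y)
        pred = pw.evaluate(law, gds.x[test])
        per_fold.append(prediction_metrics(gds.y[test], pred,
                                           nme_mode=nme_mode,
                                           r2_mode=r2_mode))
    full = pw.fit_power(gds.x, gds.y, prop_x=gds.prop_x, prop_y=gds.prop_y)
    return CVReport(
        prop_y=gds.prop_y,
        prop_x=gds.prop_x,
        nme=float(np.mean([f["nme"] for f in per_fold])),
        nrmse=float(np.mean([f["nrmse"] for f in per_fold])),
        r2_pred=float(np.mean([f["r2"] for f in per_fold])),
        r2_exp=float(full.r2),
        folds=folds,
        seed=seed,
        per_fold=tuple(per_fold),
    )


def crossvalidate_corpus(
    globals_: list[GlobalDataset],
    folds: int = 5,
    seed: int = 0,
    order: tuple[str, ...] = DEFAULT_ORDER,
    nme_mode: str = "relative",
    r2_mode: str = "pearson",
    **derive_kw,
) -> dict[tuple[str, str], CVReport]:
    """Cross-validate the full derivation pipeline over a corpus.

    For each permutation the entire relationship set is rebuilt from the
    80% training slices of every global dataset, then each dataset's
    held-out 20% is scored with the pipeline law for its pair (the size law
    when the reference is S_MN, the composed pairwise law otherwise).
    """
    rng = np.random.default_rng(seed)
    folds_per_ds = {id(g): _fold_indices(len(g), folds, rng)
                    for g in globals_}
    collected: dict[tuple[str, str], list[dict]] = {
        g.pair: [] for g in globals_
    }
    for i in range(folds):
        train_sets = []
        for g in globals_:
            parts = folds_per_ds[id(g)]
            train = np.concatenate(
                [parts[j] for j in range(folds) if j != i]
            )
            train_sets.append(
                GlobalDataset(prop_x=g.prop_x, prop_y=g.prop_y,
                              x=g.x[train], y=g.y[train],
                              study=g.study[train], species=g.species)
            )
        rs = derive_relationships(train_sets, order=order, **derive_kw)
        for g in globals_:
            test = folds_per_ds[id(g)][i]
            law = rs.law(g.prop_y, g.prop_x)
            pred = pw.evaluate(law, g.x[test])
            collected[g.pair].append(
                prediction_metrics(g.y[test], pred, nme_mode=nme_mode,
                                   r2_mode=r2_mode)
            )
    reports = {}
    for g in globals_:
        per_fold = collected[g.pair]
        full = pw.fit_power(g.x, g.y, prop_x=g.prop_x, prop_y=g.prop_y)
        reports[g.pair] = CVReport(
            prop_y=g.prop_y,
            prop_x=g.prop_x,
            nme=float(np.mean([f["nme"] for f in per_fold])),
            nrmse=float(np.mean([f["nrmse"] for f in per_fold])),
            r2_pred=float(np.mean([f["r2"] for f in per_fold])),
            r2_exp=float(full.r2),
            folds=folds,
            seed=seed,
            per_fold=tuple(per_fold),
        )
    return reports
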