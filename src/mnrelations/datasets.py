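"""Study datasets, percent-of-maximum normalization, merging, and
distribution-variability metrics.

The cross-study analysis rests on one mechanism: each retrieved study's
property columns are rescaled to percent of the within-study maximum, which
absorbs per-study multiplicative calibration offsets before studies are
concatenated into a "global" dataset per property pair. This module holds
the containers for that flow and the four distribution metrics (range, mean,
coefficient of variation, median/mean ratio) used to gate whether studies
are homogeneous enough to merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .properties import SPECIES, get_property, to_si

logger = logging.getLogger(__name__)

#: canonical CSV schema (documented external interface, version 1)
CSV_COLUMNS = (
    "study_id",
    "species",
    "prop_x",
    "prop_y",
    "x",
    "y",
    "unit_x",
    "unit_y",
)


class DatasetError(ValueError):
    """Invalid dataset content or state."""


class EmptyDatasetError(DatasetError):
    """No usable rows."""


class StateError(DatasetError):
    """Operation incompatible with the dataset's normalization state."""


class PairMismatchError(DatasetError):
    """Datasets do not share the same property pair."""


class InsufficientDataError(DatasetError):
    """Too few values for the requested statistic."""


@dataclass(frozen=True)
class StudyDataset:
    """Paired (x, y) samples of two properties measured in one study."""

    study_id: str
    species: str
    prop_x: str
    prop_y: str
    x: np.ndarray
    y: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DatasetError(f"unknown species {self.species!r}")
        get_property(self.prop_x)
        get_property(self.prop_y)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise DatasetError("x and y must be 1-d arrays of equal length")
        if x.size == 0:
            raise EmptyDatasetError("empty dataset")
        if not (np.all(x > 0) and np.all(y > 0)):
            raise DatasetError("all values must be strictly positive")
        if self.normalized:
            for col in (x, y):
                if not np.isclose(col.max(), 100.0):
                    raise DatasetError("normalized dataset must have max 100")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.prop_y, self.prop_x)

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class GlobalDataset:
    """Concatenation of normalized studies sharing one property pair."""

    prop_x: str
    prop_y: str
    x: np.ndarray
    y: np.ndarray
    study: np.ndarray  # per-point study_id provenance
    species: str
    members: tuple[StudyDataset, ...] = field(default=(), repr=False)
    normalized: bool = True

    @property
    def pair(self) -> tuple[str, str]:
        return (self.prop_y, self.prop_x)

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class DistributionMetrics:
    """Range, mean, CoV (sd/mean) and median/mean ratio of one sample."""

    range: float
    mean: float
    cov: float
    me_md: float

    def as_dict(self) -> dict[str, float]:
        return {
            "range": self.range,
            "mean": self.mean,
            "cov": self.cov,
            "me_md": self.me_md,
        }


@dataclass(frozen=True)
class AggregateMetrics:
    """Across-study (or across-global-dataset) spread of each metric.

    A metric is flagged homogeneous when sd_g < 10 (percent units) and
    sd_g / mean_g < 0.15.
    """

    mean_g: dict[str, float]
    sd_g: dict[str, float]
    homogeneous: dict[str, bool]
    n_studies: int

    @property
    def all_homogeneous(self) -> bool:
        return all(self.homogeneous.values())


def load_datasets(
    path,
    schema: dict[str, str] | None = None,
) -> list[StudyDataset]:
    """Read a dataset CSV and return one StudyDataset per
    (study_id, species, prop_y, prop_x) block.

    ``schema`` optionally maps canonical column names to the file's column
    names. Values are converted to SI; rows with missing or non-positive
    entries are dropped with a logged count.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")

    n_raw = len(df)
    df = df.dropna(subset=["x", "y"])
    df = df[(df["x"] > 0) & (df["y"] > 0)]
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning(
            "%s: dropped %d/%d rows (missing or non-positive values)",
            path, n_dropped, n_raw,
        )
    if df.empty:
        raise EmptyDatasetError(f"{path}: no usable rows")

    out: list[StudyDataset] = []
    for (study_id, species, prop_y, prop_x), block in df.groupby(
        ["study_id", "species", "prop_y", "prop_x"], sort=False
    ):
        x = np.array(
            [to_si(v, u, prop_x) for v, u in zip(block["x"], block["unit_x"])]
        )
        y = np.array(
            [to_si(v, u, prop_y) for v, u in zip(block["y"], block["unit_y"])]
        )
        out.append(
            StudyDataset(str(study_id), str(species), str(prop_x),
                         str(prop_y), x, y)
        )
    logger.info("%s: loaded %d dataset block(s), %d points", path, len(out),
                sum(len(d) for d in out))
    return out


def load_dataset(path, schema: dict[str, str] | None = None) -> StudyDataset:
    """Read a CSV expected to contain a single study/pair block."""
    blocks = load_datasets(path, schema=schema)
    if len(blocks) != 1:
        raise DatasetError(
            f"{path}: expected a single (study, pair) block, found {len(blocks)}"
        )
    return blocks[0]


def save_datasets(datasets: list[StudyDataset], path) -> None:
    """Write StudyDatasets to the canonical CSV schema (SI units)."""
    rows = []
    for ds in datasets:
        unit_x = "percent" if ds.normalized else get_property(ds.prop_x).si_unit
        unit_y = "percent" if ds.normalized else get_property(ds.prop_y).si_unit
        for xv, yv in zip(ds.x, ds.y):
            rows.append(
                dict(study_id=ds.study_id, species=ds.species,
                     prop_x=ds.prop_x, prop_y=ds.prop_y, x=xv, y=yv,
                     unit_x=unit_x, unit_y=unit_y)
            )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def normalize_study(ds: StudyDataset) -> StudyDataset:
    """Rescale each column to percent of its own within-study maximum.

    Columns are normalized independently; point order is preserved. The
    operation is scale-invariant (normalize(c*X) == normalize(X) for c > 0),
    which is what absorbs per-study calibration offsets. Normalizing an
    already-normalized dataset is a state error.
    """
    if ds.normalized:
        raise StateError(f"{ds.study_id}: already normalized")
    return replace(
        ds,
        x=100.0 * ds.x / ds.x.max(),
        y=100.0 * ds.y / ds.y.max(),
        normalized=True,
    )


def merge_global(members: list[StudyDataset]) -> GlobalDataset:
    """Concatenate normalized studies of one pair with per-point provenance."""
    if not members:
        raise DatasetError("merge_global requires at least one member")
    pair = members[0].pair
    species = members[0].species
    for m in members:
        if m.pair != pair:
            raise PairMismatchError(f"mixed pairs {pair} vs {m.pair}")
        if not m.normalized:
            raise StateError(f"{m.study_id}: member not normalized")
        if m.species != species:
            raise DatasetError("species is a hard filter; mixed species")
    return GlobalDataset(
        prop_x=pair[1],
        prop_y=pair[0],
        x=np.concatenate([m.x for m in members]),
        y=np.concatenate([m.y for m in members]),
        study=np.concatenate([np.full(len(m), m.study_id, dtype=object)
                              for m in members]),
        species=species,
        members=tuple(members),
    )


def build_globals(studies: list[StudyDataset]) -> list[GlobalDataset]:
    """Normalize every study and merge them into per-pair global datasets.

    Studies are grouped by (prop_y, prop_x); already-normalized studies are
    merged as-is. Order of first appearance is preserved.
    """
    groups: dict[tuple[str, str], list[StudyDataset]] = {}
    for ds in studies:
        norm = ds if ds.normalized else normalize_study(ds)
        groups.setdefault(norm.pair, []).append(norm)
    return [merge_global(members) for members in groups.values()]


def distribution_metrics(values) -> DistributionMetrics:
    """Range, mean, CoV and median/mean ratio of a positive sample.

    sd is the sample (n-1) standard deviation; the median uses the midpoint
    convention for even n. At least two values are required (CoV undefined
    otherwise).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 values for CoV")
    mean = float(v.mean())
    return DistributionMetrics(
        range=float(v.max() - v.min()),
        mean=mean,
        cov=float(v.std(ddof=1) / mean),
        me_md=float(np.median(v) / mean),
    )


_METRICS = ("range", "mean", "cov", "me_md")


def homogeneity_check(
    metric_sets: list[DistributionMetrics],
    sd_threshold: float = 10.0,
    ratio_threshold: float = 0.15,
) -> AggregateMetrics:
    """Across-study mean_g +/- sd_g of each metric, with homogeneity flags.

    Applies to metrics computed on normalized (percent) distributions; the
    inter-global-dataset variant (sd_G, mean_G) uses the same thresholds by
    passing per-global-dataset metrics instead. With a single study sd_g is
    undefined and every flag is False (not assessable).
    """
    if not metric_sets:
        raise InsufficientDataError("no metric sets")
    table = {m: np.array([getattr(s, m) for s in metric_sets])
             for m in _METRICS}
    mean_g = {m: float(t.mean()) for m, t in table.items()}
    if len(metric_sets) < 2:
        sd_g = {m: float("nan") for m in _METRICS}
        flags = {m: False for m in _METRICS}
    else:
        sd_g = {m: float(t.std(ddof=1)) for m, t in table.items()}
        flags = {
            m: bool(sd_g[m] < sd_threshold
                    and sd_g[m] / mean_g[m] < ratio_threshold)
            for m in _METRICS
        }
    return AggregateMetrics(mean_g=mean_g, sd_g=sd_g, homogeneous=flags,
                            n_studies=len(metric_sets))
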