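"""Occupancy-redundancy index and core-taxon classification.

For one algal tissue, each taxon's presence (abundance above a detection
threshold) is recorded per month and replicate.  For month m:

* occupancy term  O_m = mean presence over the month's available replicates
  (a value in [0, 1]);
* redundancy term R_m = 1 if the taxon is present in every available
  replicate of that month, else 0.

The index is the monthly sum scaled to a theoretical maximum of 1:

    index = sum_m (O_m + R_m) / (2 * n_months)

so a taxon present in every replicate slot of every month scores exactly 1.
Months with a replicate deficit (two swabs instead of three) use all
available replicates in both terms: a missing swab never caps a taxon
below 1.  A taxon is "core" when its index exceeds a threshold (default
0.65, strict inequality) on every algal species.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from epiquant.io_model import SampleMetadata
from epiquant.preprocess import AbsoluteAbundanceMatrix

DEFAULT_CORE_THRESHOLD = 0.65
DEFAULT_DETECTION_THRESHOLD = 1.0

#: Display aggregation used for core classification: the three Ldig blade
#: regions average into a single host column.
DEFAULT_TISSUE_AGGREGATION: Mapping[str, tuple[str, ...]] = {
    "Anod": ("Anod",),
    "Fser": ("Fser",),
    "Ldig": ("LdigB", "LdigM", "LdigO"),
    "Ppal": ("Ppal",),
    "Ulva": ("Ulva",),
}


@dataclasses.dataclass
class PresenceCube:
    """Taxon x (month, replicate) binary presence for one tissue.

    ``values`` has a two-level column index (month, replicate); design
    slots with no sample are NaN ("missing"), never 0.
    """

    values: pd.DataFrame
    tissue: str

    @property
    def months(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)


def presence_cube(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    metadata: SampleMetadata,
    tissue: str,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> PresenceCube:
    """Binary presence per taxon, month and replicate for one tissue.

    Presence means abundance >= ``detection_threshold`` (default 1, i.e.,
    one read for count tables; set a positive copy density for absolute
    matrices).
    """
    if detection_threshold <= 0:
        raise ValueError("detection_threshold must be > 0")
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    meta = metadata.table
    sel = meta.index[(meta["tissue"] == tissue) & (~meta["is_negative_control"])]
    sel = [s for s in sel if s in df.index]
    if not sel:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = df.loc[sel]
    months = [m for m in dict.fromkeys(meta.loc[sel, "month"])]
    reps = sorted(meta.loc[sel, "replicate"].astype(int).unique())
    columns = pd.MultiIndex.from_product([months, reps], names=["month", "replicate"])
    cube = pd.DataFrame(np.nan, index=df.columns, columns=columns)
    for sample_id in sel:
        month = meta.loc[sample_id, "month"]
        rep = int(meta.loc[sample_id, "replicate"])
        cube[(month, rep)] = (sub.loc[sample_id] >= detection_threshold).astype(float)
    # drop replicate slots absent from the design entirely
    cube = cube.dropna(axis=1, how="all")
    return PresenceCube(cube, tissue)


def _month_block(cube: PresenceCube, taxon: str, month: str) -> np.ndarray:
    if month not in cube.values.columns.get_level_values(0):
        raise KeyError(f"month {month!r} not in cube")
    row = cube.values.loc[taxon, month].to_numpy(float)
    row = row[~np.isnan(row)]
    if row.size == 0:
        raise ValueError(f"month {month!r} has no available replicates")
    return row


def occupancy_term(cube: PresenceCube, taxon: str, month: str) -> float:
    """Fraction of the month's available replicates in which the taxon occurs."""
    return float(_month_block(cube, taxon, month).mean())


def redundancy_term(cube: PresenceCube, taxon: str, month: str) -> int:
    """1 iff the taxon occurs in every available replicate of the month."""
    return int(_month_block(cube, taxon, month).min() == 1.0)


def occupancy_redundancy_index(cube: PresenceCube, taxon: str) -> float:
    """Scaled sum of monthly occupancy and redundancy terms, in [0, 1]."""
    months = cube.months
    if not months:
        raise ValueError("empty presence cube")
    total = 0.0
    for month in months:
        total += occupancy_term(cube, taxon, month) + redundancy_term(cube, taxon, month)
    return total / (2.0 * len(months))


def core_index_table(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    metadata: SampleMetadata,
    tissues: Sequence[str] | None = None,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Taxon x tissue table of occupancy-redundancy indices."""
    meta = metadata.table
    if tissues is None:
        tissues = [t for t in dict.fromkeys(meta.loc[~meta["is_negative_control"], "tissue"])]
    out = {}
    for tissue in tissues:
        cube = presence_cube(matrix, metadata, tissue, detection_threshold)
        vals = cube.values.to_numpy(float)  # taxa x (month, rep)
        months = cube.months
        n_months = len(months)
        total = np.zeros(vals.shape[0])
        for month in months:
            block = cube.values.loc[:, month].to_numpy(float)
            avail = ~np.isnan(block)
            present = np.nan_to_num(block)
            occ = present.sum(axis=1) / avail.sum(axis=1)
            red = (present.sum(axis=1) == avail.sum(axis=1)).astype(float)
            total += occ + red
        out[tissue] = pd.Series(total / (2.0 * n_months), index=cube.values.index)
    table = pd.DataFrame(out)
    table.index.name = "taxon"
    return table


def classify_core(
    index_table: pd.DataFrame,
    threshold: float = DEFAULT_CORE_THRESHOLD,
    tissue_aggregation: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate tissue columns per host and classify core taxa.

    A taxon is core iff its aggregated index strictly exceeds ``threshold``
    on every host column (ties at the threshold are non-core).  The default
    aggregation averages the three Ldig blade regions into one column.
    Returns the aggregated table (with a ``core`` flag column) and the list
    of core taxa.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if tissue_aggregation is None:
        tissue_aggregation = {
            host: cols
            for host, cols in DEFAULT_TISSUE_AGGREGATION.items()
            if all(c in index_table.columns for c in cols)
        }
        if not tissue_aggregation:
            tissue_aggregation = {c: (c,) for c in index_table.columns}
    agg = pd.DataFrame(
        {
            host: index_table[list(cols)].mean(axis=1)
            for host, cols in tissue_aggregation.items()
        }
    )
    agg["core"] = (agg > threshold).all(axis=1)
    core = list(agg.index[agg["core"]])
    return agg, core
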