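"""Filtering and rescaling of amplicon count tables.

Order of operations mirrors standard quantitative-profiling practice:

1. drop ASVs whose lineage marks them as organellar or eukaryotic
   (cyanobacteria including chloroplasts, mitochondria, Eukaryota);
2. drop reagent contaminants identified from negative controls — an ASV is
   a contaminant iff it occurs in at least one control AND is both rare
   (frequency among real samples <= max_freq) and low-abundance (maximum
   per-sample relative abundance <= max_relab) in real samples;
3. rescale each sample's relative composition by its qPCR total load N to
   obtain absolute abundances in 16S copies cm^-2;
4. optionally pool ASV columns by a taxonomic rank (typically genus).

Relative abundance for the contaminant filter is reads-based (pre-scaling):
negative controls have no qPCR load, so only read proportions are
comparable across them and the real samples.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from epiquant.io_model import RANKS, AsvTable, TaxonomyTable

#: Lineage labels whose presence at any rank removes an ASV.
ORGANELLAR_LABELS: tuple[str, ...] = (
    "Cyanobacteria",
    "Chloroplast",
    "Mitochondria",
    "Eukaryota",
)

DEFAULT_MAX_FREQ = 11        # max occurrences among real samples
DEFAULT_MAX_RELAB = 0.015    # max per-sample relative abundance


def remove_organellar(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    labels: Sequence[str] = ORGANELLAR_LABELS,
) -> tuple[AsvTable, list[str]]:
    """Remove ASVs whose lineage contains an organellar/eukaryote label.

    Matching is case-insensitive and applies at any rank.  Returns the
    filtered table and the list of removed ASV ids.
    """
    lowered = {lab.lower() for lab in labels}
    lineages = taxonomy.lineages
    missing = [a for a in table.asv_ids if a not in lineages.index]
    if missing:
        raise KeyError(f"ASVs missing from taxonomy: {missing[:5]}")
    sub = lineages.loc[table.asv_ids, list(RANKS)]
    hit = sub.apply(lambda col: col.str.lower().isin(lowered)).any(axis=1)
    removed = list(sub.index[hit])
    return table.drop_asvs(removed), removed


@dataclasses.dataclass
class ContaminantReport:
    """Per-ASV evidence backing the contaminant classification.

    One row per ASV present in at least one negative control, with its
    frequency among real samples, maximum reads-based relative abundance
    among real samples, and the resulting flag.
    """

    table: pd.DataFrame
    max_freq: int
    max_relab: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def flag_contaminants(
    table: AsvTable,
    control_ids: Sequence[str],
    max_freq: int = DEFAULT_MAX_FREQ,
    max_relab: float = DEFAULT_MAX_RELAB,
) -> tuple[ContaminantReport, AsvTable]:
    """Identify reagent contaminants from negative controls and remove them.

    An ASV is flagged iff all three clauses hold: (i) nonzero reads in at
    least one control; (ii) nonzero in at most ``max_freq`` real samples;
    (iii) maximum per-sample reads-based relative abundance among real
    samples at most ``max_relab``.  Flagged ASVs and the control samples
    themselves are dropped from the returned table.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("contaminant filtering requires at least one negative control")
    unknown = [s for s in control_ids if s not in table.counts.index]
    if unknown:
        raise KeyError(f"control samples absent from table: {unknown}")
    counts = table.counts
    real = counts.drop(index=control_ids)
    controls = counts.loc[control_ids]

    in_controls = (controls > 0).any(axis=0)
    freq = (real > 0).sum(axis=0)
    totals = real.sum(axis=1).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        relab = real.to_numpy(float) / totals[:, None]
    relab = np.nan_to_num(relab)
    max_rel = pd.Series(relab.max(axis=0) if len(real) else 0.0, index=counts.columns)

    candidates = counts.columns[in_controls]
    flagged_mask = in_controls & (freq <= max_freq) & (max_rel <= max_relab)
    report = pd.DataFrame(
        {
            "in_controls": in_controls.loc[candidates],
            "frequency": freq.loc[candidates],
            "max_relative_abundance": max_rel.loc[candidates],
            "flagged": flagged_mask.loc[candidates],
        }
    )
    report.index.name = "asv_id"
    flagged = list(counts.columns[flagged_mask])
    filtered = AsvTable(real.drop(columns=flagged))
    return ContaminantReport(report, max_freq, max_relab), filtered


@dataclasses.dataclass
class AbsoluteAbundanceMatrix:
    """Samples x taxa matrix of absolute abundances (16S copies cm^-2).

    Row sums equal the per-sample total load N used for scaling (to within
    floating-point tolerance).  ``provenance`` records whether columns are
    ASV-level or pooled at a taxonomic rank.
    """

    values: pd.DataFrame
    provenance: str = "ASV"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("absolute abundances must be non-negative")
        self.values.index.name = "sample_id"

    @property
    def loads(self) -> pd.Series:
        return self.values.sum(axis=1)


def scale_to_absolute(table: AsvTable, loads: pd.Series) -> AbsoluteAbundanceMatrix:
    """Rescale read counts to absolute abundances using per-sample loads.

    entry(s, a) = reads(s, a) / total_reads(s) * N(s).  A sample with zero
    total reads but positive N cannot be resolved and raises; N = 0 yields
    an all-zero row regardless of reads.
    """
    counts = table.counts
    missing = [s for s in counts.index if s not in loads.index]
    if missing:
        raise KeyError(f"samples lacking a total load N: {missing[:5]}")
    N = loads.loc[counts.index].to_numpy(float)
    if np.any(N < 0):
        raise ValueError("total loads must be non-negative")
    totals = counts.sum(axis=1).to_numpy(float)
    dead = (totals == 0) & (N > 0)
    if dead.any():
        bad = counts.index[dead].tolist()
        raise ValueError(f"unresolvable samples with zero reads but positive load: {bad[:5]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts.to_numpy(float) / totals[:, None]
    rel = np.nan_to_num(rel)
    values = pd.DataFrame(rel * N[:, None], index=counts.index, columns=counts.columns)
    return AbsoluteAbundanceMatrix(values, provenance="ASV")


def pool_by_rank(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    taxonomy: TaxonomyTable,
    rank: str = "genus",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum columns over taxa sharing the label at ``rank``.

    Columns with an empty label at that rank are excluded from the pooled
    matrix and returned separately so that mass is conserved up to the
    reported excluded part.  Works on count and on absolute matrices.
    """
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    labels = taxonomy.rank_labels(list(df.columns), rank)
    assigned = labels != ""
    pooled = df.loc[:, labels.index[assigned]].T.groupby(
        labels[assigned].to_numpy()
    ).sum().T
    pooled.columns.name = rank
    excluded = df.loc[:, labels.index[~assigned]]
    return pooled, excluded


def copies_to_cells(copies, operons_per_cell: float = 3.0):
    """Convert 16S gene copy densities to cell densities.

    Divides by the rRNA operon copy number per genome (default 3, the
    count in the complete reference genome of *Granulosicoccus
    antarcticus*).  Accepts scalars, arrays, Series or DataFrames.
    """
    if operons_per_cell <= 0:
        raise ValueError("operons_per_cell must be > 0")
    if isinstance(copies, (pd.Series, pd.DataFrame)):
        return copies / operons_per_cell
    out = np.asarray(copies, dtype=float) / operons_per_cell
    return float(out) if out.ndim == 0 else out
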