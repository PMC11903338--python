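"""Domain types, study-design vocabulary, and TSV readers/writers.

The study design this package targets is a year-round survey of the surface
microbiota of five intertidal macroalgae: the brown algae *Ascophyllum
nodosum* (Anod), *Fucus serratus* (Fser) and *Laminaria digitata* (Ldig,
swabbed on three blade regions: base LdigB, medium LdigM, old LdigO), the
red alga *Palmaria palmata* (Ppal) and the green alga *Ulva* sp. (Ulva).
Seven tissue types were swabbed monthly over ten months in triplicate,
giving 70 tissue x month conditions; two conditions yielded only two
replicates, for 208 samples in total.

All tabular inputs and outputs are tab-separated UTF-8 text with a header
row.  Matrices are oriented samples-in-rows, taxa-in-columns everywhere;
writers always emit this orientation.  Floats are serialised with 12
significant digits and a "." decimal separator regardless of locale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Study-design vocabulary
# ---------------------------------------------------------------------------

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

TISSUES: tuple[str, ...] = ("Anod", "Fser", "LdigB", "LdigM", "LdigO", "Ppal", "Ulva")

TISSUE_TO_HOST: Mapping[str, str] = {
    "Anod": "Anod",
    "Fser": "Fser",
    "LdigB": "Ldig",
    "LdigM": "Ldig",
    "LdigO": "Ldig",
    "Ppal": "Ppal",
    "Ulva": "Ulva",
}

HOSTS: tuple[str, ...] = ("Anod", "Fser", "Ldig", "Ppal", "Ulva")

#: Brown algae (class Phaeophyceae); Ppal is red, Ulva is green.
BROWN_HOSTS: frozenset[str] = frozenset({"Anod", "Fser", "Ldig"})

ALL_MONTHS: tuple[str, ...] = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: The ten months actually sampled (no Apr/May field campaign).
SAMPLED_MONTHS: tuple[str, ...] = (
    "Jan", "Feb", "Mar", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: Month-to-season assignment used for all season-level analyses.  The two
#: unsampled months (Apr, May) are deliberately unmapped and rejected.
SEASON_MAP: Mapping[str, str] = {
    "Jan": "winter", "Feb": "winter", "Mar": "winter",
    "Jun": "summer", "Jul": "summer", "Aug": "summer",
    "Sep": "autumn", "Oct": "autumn", "Nov": "autumn", "Dec": "autumn",
}

SEASONS: tuple[str, ...] = ("winter", "summer", "autumn")

#: Conditions with only two replicates instead of three.
DEFAULT_DEFICITS: tuple[tuple[str, str, int], ...] = (
    ("LdigB", "Feb", 2),
    ("Ulva", "Mar", 2),
)

#: The 15 environmental variables recorded at the monitoring station.
ENV_VARIABLES: tuple[str, ...] = (
    "T", "S", "O", "pH", "NH4", "NO3", "NO2", "PHO4", "SiOH4",
    "COP", "NOP", "MES", "DN15", "DC13", "CHLA",
)

_FLOAT_FORMAT = "%.12g"


def canonical_month(label: str) -> str:
    """Canonicalise a month label to its three-letter English abbreviation.

    Accepts any case and full month names ("february" -> "Feb").  Raises
    ``ValueError`` for unrecognisable labels.
    """
    if not isinstance(label, str) or len(label) < 3:
        raise ValueError(f"unrecognised month label: {label!r}")
    key = label.strip()[:3].title()
    if key not in ALL_MONTHS:
        raise ValueError(f"unrecognised month label: {label!r}")
    return key


def month_to_season(month: str) -> str:
    """Map a sampled month to its season (winter / summer / autumn).

    Raises ``ValueError`` with an "unmapped month" message for Apr/May
    (not sampled, no season assigned) and for unknown labels.
    """
    key = canonical_month(month)
    try:
        return SEASON_MAP[key]
    except KeyError:
        raise ValueError(f"unmapped month: {key!r} has no season assignment") from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AsvTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    ``counts`` is a DataFrame whose index holds opaque sample identifiers
    and whose columns hold opaque ASV identifiers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV identifiers: {dupes}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("read counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
        if values.size and (df.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        self.counts.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)].copy())

    def drop_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.drop(columns=list(asv_ids)))


@dataclasses.dataclass
class TaxonomyTable:
    """ASV -> seven-rank lineage (domain ... species).

    Missing ranks are encoded as empty strings, never "NA" text, so a genus
    literally named "NA" cannot collide with missingness.
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        if df.index.duplicated().any():
            raise ValueError("duplicate ASV identifiers in taxonomy")
        for rank in RANKS:
            if rank not in df.columns:
                df[rank] = ""
        df = df[list(RANKS)].fillna("").astype(str)
        df.index.name = "asv_id"
        object.__setattr__(self, "lineages", df)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        if asv_id not in self.lineages.index:
            raise KeyError(f"ASV {asv_id!r} missing from taxonomy")
        return tuple(self.lineages.loc[asv_id, list(RANKS)])

    def rank_labels(self, asv_ids: Sequence[str], rank: str) -> pd.Series:
        """Labels at ``rank`` for the given ASVs; raises if any ASV is absent."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        missing = [a for a in asv_ids if a not in self.lineages.index]
        if missing:
            raise KeyError(f"ASVs missing from taxonomy: {missing[:5]}")
        return self.lineages.loc[list(asv_ids), rank]


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample design variables.

    Columns: host, tissue, month, season (derived from month), replicate,
    dna_conc (ng/uL, original extract concentration C), is_negative_control.
    Negative controls carry empty tissue/host/month fields and are exempt
    from design checks.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in metadata")
        df.index.name = "sample_id"
        if "is_negative_control" not in df.columns:
            df["is_negative_control"] = False
        df["is_negative_control"] = df["is_negative_control"].astype(bool)
        real = ~df["is_negative_control"]

        if "tissue" not in df.columns:
            raise ValueError("metadata requires a 'tissue' column")
        bad_tissue = df.loc[real, "tissue"][~df.loc[real, "tissue"].isin(TISSUE_TO_HOST)]
        if len(bad_tissue):
            raise ValueError(f"unknown tissues: {sorted(bad_tissue.unique())}")
        derived_host = df.loc[real, "tissue"].map(TISSUE_TO_HOST)
        if "host" in df.columns:
            clash = df.loc[real, "host"].astype(str) != derived_host
            if clash.any():
                raise ValueError(
                    f"host/tissue mismatch for samples {df.index[real][clash].tolist()[:5]}"
                )
        df.loc[real, "host"] = derived_host
        df.loc[~real, "host"] = ""

        months = df.loc[real, "month"].map(canonical_month)
        df.loc[real, "month"] = months
        seasons = months.map(SEASON_MAP)
        if seasons.isna().any():
            raise ValueError(
                f"unmapped months in metadata: {sorted(months[seasons.isna()].unique())}"
            )
        if "season" in df.columns:
            given = df.loc[real, "season"].astype(str)
            clash = given.ne(seasons) & given.ne("")
            if clash.any():
                raise ValueError("season column inconsistent with month-season map")
        df.loc[real, "season"] = seasons
        df.loc[~real, "season"] = ""

        if "dna_conc" in df.columns:
            conc = pd.to_numeric(df.loc[real, "dna_conc"])
            if (conc <= 0).any():
                raise ValueError("dna_conc must be > 0 for non-control samples")
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def control_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_negative_control"]])

    @property
    def real_ids(self) -> list[str]:
        return list(self.table.index[~self.table["is_negative_control"]])

    def column(self, name: str) -> pd.Series:
        return self.table[name]


# ---------------------------------------------------------------------------
# Design enumeration
# ---------------------------------------------------------------------------


def enumerate_design(
    tissues: Sequence[str] = TISSUES,
    months: Sequence[str] = SAMPLED_MONTHS,
    replicates: int = 3,
    exceptions: Sequence[tuple[str, str, int]] = DEFAULT_DEFICITS,
) -> pd.DataFrame:
    """Enumerate every expected sample slot of the sampling design.

    ``exceptions`` are (tissue, month, replicate-count) overrides for
    conditions that deviate from the default replicate count.  Returns a
    DataFrame with columns sample_id, tissue, month, replicate; the number
    of conditions is ``len(tissues) * len(months)`` and the number of rows
    is the total expected sample count.
    """
    if not tissues or not months:
        raise ValueError("tissue and month vocabularies must be non-empty")
    months = [canonical_month(m) for m in months]
    overrides: dict[tuple[str, str], int] = {}
    for tissue, month, count in exceptions:
        month = canonical_month(month)
        if tissue not in tissues:
            raise ValueError(f"exception references unknown tissue {tissue!r}")
        if month not in months:
            raise ValueError(f"exception references unknown month {month!r}")
        overrides[(tissue, month)] = int(count)
    rows = []
    for tissue in tissues:
        for month in months:
            n_rep = overrides.get((tissue, month), replicates)
            for rep in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}-{month}-{rep}",
                        "tissue": tissue,
                        "month": month,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def design_counts(design: pd.DataFrame) -> tuple[int, int]:
    """(number of tissue x month conditions, number of samples)."""
    conditions = design.groupby(["tissue", "month"], sort=False).ngroups
    return conditions, len(design)


# ---------------------------------------------------------------------------
# Readers / writers (TSV; optional sparse-triplet dialect for counts)
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def read_asv_table(path: str | Path, dialect: str = "tsv") -> AsvTable:
    """Read an ASV count table.

    ``dialect="tsv"``: wide matrix, first column sample_id, remaining
    columns one per ASV.  ``dialect="triplets"``: BIOM-style sparse
    triplets with columns sample_id, asv_id, count; absent cells are zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] == 0:
            raise ValueError("no samples in ASV table")
        if df.isna().any().any():
            raise ValueError("ragged rows or missing counts in ASV table")
        return AsvTable(df.astype(np.int64))
    if dialect == "triplets":
        df = pd.read_csv(path, sep="\t")
        required = {"sample_id", "asv_id", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"triplet dialect requires columns {sorted(required)}")
        if df.shape[0] == 0:
            raise ValueError("no samples in ASV table")
        wide = (
            df.pivot_table(index="sample_id", columns="asv_id", values="count",
                           aggfunc="sum", fill_value=0)
            .astype(np.int64)
        )
        wide.columns.name = None
        return AsvTable(wide)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_asv_table(table: AsvTable, path: str | Path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_tsv(table.counts, path)
    elif dialect == "triplets":
        long = table.counts.stack().reset_index()
        long.columns = ["sample_id", "asv_id", "count"]
        long = long[long["count"] != 0]
        _write_tsv(long, path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    _write_tsv(taxonomy.lineages, path)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[], dtype={"month": str, "tissue": str})
    if "is_negative_control" in df.columns:
        df["is_negative_control"] = df["is_negative_control"].astype(str).str.lower().isin(
            {"true", "1", "yes"}
        )
    if "dna_conc" in df.columns:
        df["dna_conc"] = pd.to_numeric(df["dna_conc"], errors="coerce")
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    _write_tsv(metadata.table, path)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """qPCR measurements: sample_id plus either copies_in_reaction (n) or cq.

    Optional columns: C, V, c, v, S overriding assay defaults; a 'well'
    column marks technical qPCR replicates of one sample.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("qPCR table requires a sample_id column")
    if "copies_in_reaction" not in df.columns and "cq" not in df.columns:
        raise ValueError("qPCR table requires copies_in_reaction or cq")
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path, index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Month x environmental-variable table; missing values stay explicit NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [canonical_month(m) for m in df.index]
    df.index.name = "month"
    return df


def write_env_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path)
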