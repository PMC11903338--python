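"""Host-specificity set analysis: upset-style intersections and shared ASVs.

Two complementary views of taxon sharing across algal hosts:

* exclusive intersection counts — each detected taxon is assigned to the
  exact subset of hosts on which it occurs (>= 1 read in any sample of the
  host), giving the cell counts of an upset plot over the 2^H - 1 nonempty
  host subsets;
* pairwise shared-ASV counts — for every unordered sample pair, the number
  of ASVs with nonzero abundance in both, classified by host phylogeny:
  intra-species (two samples of the same brown alga), intra-phylum (two
  different brown algae) or inter-phylum (a brown alga versus the red or
  the green alga).  Classes are compared with a Kruskal-Wallis omnibus test
  followed by pairwise Wilcoxon rank-sum tests with Benjamini-Hochberg
  correction.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epiquant.io_model import BROWN_HOSTS, SampleMetadata
from epiquant.preprocess import AbsoluteAbundanceMatrix


@dataclasses.dataclass
class IntersectionCounts:
    """Exclusive host-subset counts for an upset plot.

    ``counts`` maps each nonempty host subset (a frozenset) to the number
    of taxa detected on exactly that subset; ``set_sizes`` gives per-host
    totals (taxa detected on the host, regardless of other hosts).
    """

    counts: dict[frozenset[str], int]
    set_sizes: dict[str, int]
    hosts: tuple[str, ...]

    @property
    def total_detected(self) -> int:
        return sum(self.counts.values())

    def count(self, subset: Sequence[str]) -> int:
        return self.counts.get(frozenset(subset), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.counts, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "hosts": "+".join(sorted(subset)),
                    "degree": len(subset),
                    "count": self.counts[subset],
                }
            )
        return pd.DataFrame(rows)


def host_membership(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    metadata: SampleMetadata,
) -> dict[str, frozenset[str]]:
    """Exact host set on which each taxon is detected (>= 1 read anywhere)."""
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    meta = metadata.table
    real = [s for s in df.index
            if s in meta.index and not meta.loc[s, "is_negative_control"]]
    hosts = tuple(dict.fromkeys(meta.loc[real, "host"]))
    detected = {
        host: (df.loc[[s for s in real if meta.loc[s, "host"] == host]] > 0).any(axis=0)
        for host in hosts
    }
    presence = pd.DataFrame(detected)
    return {
        taxon: frozenset(presence.columns[presence.loc[taxon].to_numpy()])
        for taxon in presence.index
        if presence.loc[taxon].any()
    }


def intersection_counts(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    metadata: SampleMetadata,
) -> IntersectionCounts:
    """Exclusive host-subset membership counts over all detected taxa.

    Detection is >= 1 read (or any positive abundance) aggregated across
    all non-control samples of the host; the three Ldig blade regions
    collapse into the single host "Ldig".  Taxa detected nowhere are not
    counted.
    """
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    meta = metadata.table
    real = meta.index[~meta["is_negative_control"]]
    real = [s for s in real if s in df.index]
    hosts = tuple(dict.fromkeys(meta.loc[real, "host"]))
    if len(hosts) < 2:
        raise ValueError("intersection counts require at least two hosts")
    detected = {}
    for host in hosts:
        samples = [s for s in real if meta.loc[s, "host"] == host]
        detected[host] = (df.loc[samples] > 0).any(axis=0)
    presence = pd.DataFrame(detected)  # taxa x hosts, bool
    anywhere = presence.any(axis=1)
    presence = presence.loc[anywhere]
    counts: dict[frozenset[str], int] = {}
    membership = presence.apply(lambda row: frozenset(presence.columns[row.to_numpy()]), axis=1)
    for subset, group in membership.groupby(membership):
        counts[subset] = len(group)
    set_sizes = {host: int(presence[host].sum()) for host in hosts}
    return IntersectionCounts(counts, set_sizes, hosts)


PAIR_CLASSES: tuple[str, ...] = ("intra-species", "intra-phylum", "inter-phylum")


def _pair_class(host_a: str, host_b: str) -> str | None:
    a_brown = host_a in BROWN_HOSTS
    b_brown = host_b in BROWN_HOSTS
    if a_brown and b_brown:
        return "intra-species" if host_a == host_b else "intra-phylum"
    if a_brown != b_brown:
        return "inter-phylum"
    return None  # red/green vs red/green: outside the three-way comparison


def pairwise_shared(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Shared-taxon counts for all unordered sample pairs, with pair class.

    ``shared`` counts taxa with nonzero abundance in both samples.  The
    class column follows the brown/red/green host grouping (the three Ldig
    blade regions are one species); pairs outside the three classes (e.g.,
    Ulva vs Ulva or Ulva vs Ppal) carry class ``None`` and are excluded
    from the group comparison.  Self-pairs and controls are excluded.
    """
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    meta = metadata.table
    samples = [s for s in df.index if s in meta.index and not meta.loc[s, "is_negative_control"]]
    if len(samples) < 2:
        raise ValueError("pairwise sharing requires at least two samples")
    presence = (df.loc[samples] > 0).to_numpy()
    shared = presence.astype(np.int64) @ presence.astype(np.int64).T
    hosts = meta.loc[samples, "host"].to_numpy()
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        rows.append(
            {
                "sample_a": samples[i],
                "sample_b": samples[j],
                "shared": int(shared[i, j]),
                "pair_class": _pair_class(hosts[i], hosts[j]),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class GroupComparison:
    """Omnibus and pairwise results of the shared-count comparison."""

    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # class_a, class_b, statistic, p, p_adjusted
    medians: pd.Series


def group_comparison(pair_table: pd.DataFrame) -> GroupComparison:
    """Kruskal-Wallis omnibus plus BH-adjusted pairwise Wilcoxon tests.

    Operates on the ``shared`` column grouped by ``pair_class``; classes
    with fewer than two observations are rejected.  The pairwise tests are
    two-sided Wilcoxon rank-sum (Mann-Whitney) tests; adjusted p-values use
    the Benjamini-Hochberg step-up rule.  Medians per class report the
    effect direction.
    """
    table = pair_table.dropna(subset=["pair_class"])
    groups = {k: g["shared"].to_numpy(float) for k, g in table.groupby("pair_class")}
    if len(groups) < 2:
        raise ValueError("group comparison requires at least two pair classes")
    for name, values in groups.items():
        if values.size < 2:
            raise ValueError(f"pair class {name!r} has fewer than two observations")
    names = sorted(groups)
    stat, p = stats.kruskal(*[groups[n] for n in names])
    rows = []
    for a, b in itertools.combinations(names, 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"class_a": a, "class_b": b, "statistic": float(res.statistic),
                     "p": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    medians = pd.Series({n: float(np.median(groups[n])) for n in names}, name="median_shared")
    return GroupComparison(float(stat), float(p), pairwise, medians)
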