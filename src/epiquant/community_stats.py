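"""Distance-based community statistics.

Bray-Curtis dissimilarities on the absolute-abundance table feed a
single-factor PERMANOVA: with pairwise distances d_ij over N samples in k
groups,

    SS_total   = (1/N) * sum_{i<j} d_ij^2
    SS_within  = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    F = (SS_between / (k - 1)) / (SS_within / (N - k))

The p-value permutes whole sample labels; with P permutations,
p = (1 + #{F_perm >= F_obs}) / (1 + P), so p is never zero and is
bit-reproducible given (seed, P).  Within-group dispersion embeds the
distance matrix by principal-coordinate analysis, retaining negative
eigenvalues with an imaginary-part correction (squared distance to a group
centroid = positive-axis part minus negative-axis part), and permutes the
resulting distances over groups for an ANOVA-type F test.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from epiquant.preprocess import AbsoluteAbundanceMatrix

DEFAULT_PERMUTATIONS = 999


def bray_curtis(matrix: AbsoluteAbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i); requires non-negative
    abundances and a positive total per sample.
    """
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    values = df.to_numpy(float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = df.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total abundance: {bad[:5]}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in df.index])


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    """Single-factor PERMANOVA outcome."""

    statistic: float        # pseudo-F
    p_value: float
    df_between: int         # k - 1
    df_within: int          # N - k
    r_squared: float        # SS_between / SS_total
    n_permutations: int
    seed: int | None

    def __repr__(self) -> str:  # compact, table-like
        return (
            f"PermanovaResult(F={self.statistic:.4g}, p={self.p_value:.4g}, "
            f"df=({self.df_between}, {self.df_within}), R2={self.r_squared:.4g})"
        )


def _align_groups(dist: DistanceMatrix, groups: pd.Series | Sequence[str]) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [i for i in dist.ids if i not in groups.index]
        if missing:
            raise KeyError(f"samples lacking a group label: {missing[:5]}")
        return groups.loc[list(dist.ids)].to_numpy()
    groups = np.asarray(groups)
    if groups.shape[0] != len(dist.ids):
        raise ValueError("group labels length does not match distance matrix")
    return groups


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # sum_g (1 / 2 n_g) * 1_g' D2 1_g  (factor 2: D2 counts each pair twice)
    quad = np.einsum("ig,ij,jg->g", onehot, d2, onehot)
    return float((quad / (2.0 * sizes)).sum())


def permanova(
    dist: DistanceMatrix,
    groups: pd.Series | Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    ``groups`` is a categorical label per sample (a Series indexed by
    sample id, or a sequence in matrix order).  Requires at least two
    groups and a positive within-group degree of freedom.  When all
    within-group distances are zero the pseudo-F is infinite (perfectly
    separated groups) and a warning is emitted.
    """
    labels = _align_groups(dist, groups)
    uniq, inverse = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = len(labels)
    if k < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if n - k <= 0:
        raise ValueError("no within-group degrees of freedom (N - k <= 0)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = np.asarray(dist.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    sizes = np.bincount(inverse).astype(float)

    def f_stat(inv: np.ndarray) -> float:
        onehot = np.eye(k)[inv]
        ssw = _ss_within(d2, onehot, sizes)
        ssb = ss_total - ssw
        if ssw == 0.0:
            return np.inf
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(inverse)
    if np.isinf(f_obs):
        warnings.warn("all within-group distances are zero; pseudo-F is infinite")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(inverse)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    onehot = np.eye(k)[inverse]
    ssw = _ss_within(d2, onehot, sizes)
    r2 = (ss_total - ssw) / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        statistic=float(f_obs),
        p_value=float(p),
        df_between=k - 1,
        df_within=n - k,
        r_squared=float(r2),
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: pd.Series | Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA on every group pair's submatrix, BH-adjusted across pairs."""
    labels = _align_groups(dist, groups)
    ids = np.asarray(dist.ids)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("pairwise PERMANOVA requires at least two groups")
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(uniq, 2)):
        mask = (labels == a) | (labels == b)
        sub = dist.filter(ids[mask])
        sub_groups = pd.Series(labels[mask], index=ids[mask])
        # seed + i keeps each pair's stream deterministic and makes the
        # two-group case reduce exactly to the omnibus test
        res = permanova(sub, sub_groups, n_perm=n_perm,
                        seed=None if seed is None else seed + i)
        rows.append({"group_a": a, "group_b": b, "statistic": res.statistic,
                     "p": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclasses.dataclass(frozen=True)
class DispersionResult:
    """Within-group dispersion (distance to centroid) with permutation test."""

    distances: pd.Series      # per-sample distance to its group centroid
    group_means: pd.Series
    statistic: float          # ANOVA F over distances
    p_value: float
    n_permutations: int
    seed: int | None


def _pcoa_coordinates(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary axes.

    Returns (pos, neg): coordinates on positive-eigenvalue axes and on
    negative-eigenvalue axes (the latter scaled by sqrt(|eigenvalue|));
    squared inter-point distances are ||dpos||^2 - ||dneg||^2.
    """
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    tol = np.abs(eigval).max() * 1e-12 if eigval.size else 0.0
    pos = eigvec[:, eigval > tol] * np.sqrt(eigval[eigval > tol])
    neg = eigvec[:, eigval < -tol] * np.sqrt(-eigval[eigval < -tol])
    return pos, neg


def dispersion(
    dist: DistanceMatrix,
    groups: pd.Series | Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> DispersionResult:
    """Per-group mean distance to centroid and a permutation F-test.

    Mirrors the classical multivariate-dispersion procedure: the distance
    matrix is embedded by principal coordinates keeping negative
    eigenvalues; the squared distance from a sample to its group centroid
    is the positive-part contribution minus the negative-part contribution
    (clipped at zero).  Homogeneity is tested by an ANOVA F over those
    distances, with a label-permutation null.
    """
    labels = _align_groups(dist, groups)
    uniq, inverse = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        small = [u for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"groups with fewer than two samples: {small}")
    d = np.asarray(dist.data, dtype=float)
    pos, neg = _pcoa_coordinates(d)

    z = np.empty(len(labels))
    for g in range(len(uniq)):
        members = inverse == g
        cpos = pos[members].mean(axis=0) if pos.size else np.zeros(0)
        cneg = neg[members].mean(axis=0) if neg.size else np.zeros(0)
        d2 = np.zeros(members.sum())
        if pos.size:
            d2 += ((pos[members] - cpos) ** 2).sum(axis=1)
        if neg.size:
            d2 -= ((neg[members] - cneg) ** 2).sum(axis=1)
        z[members] = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(values: np.ndarray) -> float:
        grand = values.mean()
        ssb = sum(sizes[g] * (values[inverse == g].mean() - grand) ** 2
                  for g in range(len(uniq)))
        ssw = sum(((values[inverse == g] - values[inverse == g].mean()) ** 2).sum()
                  for g in range(len(uniq)))
        if ssw == 0.0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (len(uniq) - 1)) / (ssw / (len(values) - len(uniq)))

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(rng.permutation(z)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    distances = pd.Series(z, index=list(dist.ids), name="distance_to_centroid")
    group_means = pd.Series(
        {u: float(z[inverse == g].mean()) for g, u in enumerate(uniq)},
        name="mean_dispersion",
    )
    return DispersionResult(distances, group_means, float(f_obs), float(p), n_perm, seed)


def observed_richness(
    matrix: AbsoluteAbundanceMatrix | pd.DataFrame,
    groupby: pd.Series | None = None,
    detection_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-sample count of taxa at or above the detection threshold.

    With ``groupby`` (a label per sample), a group column is attached so
    callers can summarise; the per-sample counts are always returned.
    """
    df = matrix.values if isinstance(matrix, AbsoluteAbundanceMatrix) else matrix
    richness = (df >= detection_threshold).sum(axis=1)
    out = pd.DataFrame({"richness": richness})
    if groupby is not None:
        out["group"] = groupby.loc[out.index]
    out.index.name = "sample_id"
    return out


@dataclasses.dataclass
class EnvPruneResult:
    """Outcome of collinearity pruning among environmental variables."""

    retained: list[str]
    removed: list[str]
    report: pd.DataFrame      # var_a, var_b, r, p, p_adjusted, constant flags


def env_prune(
    env_table: pd.DataFrame,
    alpha: float = 0.05,
    r_threshold: float = 0.8,
) -> EnvPruneResult:
    """Greedy removal of highly inter-correlated environmental variables.

    All pairwise Pearson correlations (complete-case per pair) are tested
    and BH-adjusted; while any retained pair has adjusted p < ``alpha``
    and |r| >= ``r_threshold``, the variable with the largest maximum |r|
    over such pairs is removed (ties broken alphabetically).  Constant
    variables have undefined correlations: they are flagged and treated as
    uncorrelated.  The full correlation report is returned for audit.
    """
    variables = list(env_table.columns)
    if len(variables) < 2:
        raise ValueError("pruning requires at least two variables")
    if len(env_table) < 3:
        raise ValueError("pruning requires at least three observations")
    rows = []
    for a, b in itertools.combinations(variables, 2):
        sub = env_table[[a, b]].dropna()
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        const = (np.ptp(xa) == 0) or (np.ptp(xb) == 0) or len(sub) < 3
        if const:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(xa, xb)
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p),
                     "constant_pair": bool(const)})
    report = pd.DataFrame(rows)
    report["p_adjusted"] = multipletests(report["p"], method="fdr_bh")[1]

    retained = set(variables)
    removed: list[str] = []
    while True:
        live = report[
            report["var_a"].isin(retained)
            & report["var_b"].isin(retained)
            & (report["p_adjusted"] < alpha)
            & (report["r"].abs() >= r_threshold)
        ]
        if live.empty:
            break
        worst: dict[str, float] = {}
        for _, row in live.iterrows():
            for var in (row["var_a"], row["var_b"]):
                worst[var] = max(worst.get(var, 0.0), abs(row["r"]))
        victim = sorted(worst.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        retained.discard(victim)
        removed.append(victim)
    return EnvPruneResult(
        retained=[v for v in variables if v in retained],
        removed=removed,
        report=report,
    )
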