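"""16S ASV community profiling downstream of ASV inference.

Relative abundance by taxonomic rank, rare-taxon lumping, Bray-Curtis
dissimilarity, principal-coordinate analysis (PCoA) and one-way PERMANOVA
on a distance matrix.

PCoA follows the classical Gower construction: double-centre -D**2/2,
eigendecompose, scale eigenvectors by sqrt(eigenvalue); axes with negative
eigenvalues are dropped and excluded from the explained-variance
denominator.  PERMANOVA partitions squared distances into among- and
within-group sums; the p-value uses the +1/+1 convention (the observed
statistic counts as one permutation), so 999 permutations give a minimum
p of 1/1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from perihg.taxonomy import RANKS, TaxonomyLineage

__all__ = [
    "AsvTable",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "relative_abundance",
    "lump_rare",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class AsvTable:
    """Sample x ASV counts with per-ASV lineages and sample metadata.

    ``counts``: integer DataFrame, samples as rows, ASVs as columns.
    ``lineages``: DataFrame indexed by ASV with the rank columns
    domain..family (blank = unassigned).
    ``metadata``: DataFrame indexed by sample with site / treatment /
    molecule columns.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing_lin = set(self.counts.columns) - set(self.lineages.index)
        if missing_lin:
            raise ValueError(f"ASVs without lineage: {sorted(missing_lin)[:5]}")
        missing_meta = set(self.counts.index) - set(self.metadata.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)[:5]}")

    def lineage_of(self, asv: str) -> TaxonomyLineage:
        row = self.lineages.loc[asv]
        return TaxonomyLineage.from_names([row.get(r) for r in RANKS])


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal sample dissimilarities in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("nonzero diagonal")
        self.values = v


@dataclass
class OrdinationResult:
    """PCoA coordinates with per-axis explained-variance fractions."""

    coordinates: pd.DataFrame
    explained_fraction: np.ndarray


@dataclass
class PermanovaResult:
    """One-way PERMANOVA pseudo-F, effect size and permutation p."""

    pseudo_F: float
    r2: float
    p: float
    n_perm: int


def relative_abundance(table: AsvTable, rank: str = "phylum") -> pd.DataFrame:
    """Aggregate counts by lineage at ``rank`` and normalise rows to 1.

    ASVs unassigned at the rank pool into an "unclassified" taxon.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    taxa = []
    for asv in table.counts.columns:
        name = table.lineage_of(asv).at(rank)
        taxa.append(name if name is not None else "unclassified")
    grouped = table.counts.T.groupby(pd.Index(taxa, name=rank)).sum().T
    return grouped.div(totals, axis=0)


def lump_rare(
    fractions: pd.DataFrame, threshold: float = 0.02, per_sample: bool = False
) -> pd.DataFrame:
    """Merge taxa below ``threshold`` into an "others" column.

    By default a taxon is rare when its *mean* fraction across the given
    samples is strictly below the threshold (exactly-at-threshold taxa are
    kept); ``per_sample`` instead requires it to be rare in every sample.
    Row sums are preserved.
    """
    if per_sample:
        rare = (fractions < threshold).all(axis=0)
    else:
        rare = fractions.mean(axis=0) < threshold
    kept = fractions.loc[:, ~rare].copy()
    if rare.any():
        kept["others"] = fractions.loc[:, rare].sum(axis=1)
    return kept


def bray_curtis(abundances: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    BC(i, j) = 1 - 2 sum_k min(x_ik, x_jk) / sum_k (x_ik + x_jk); defined
    only when no pair of samples is entirely zero.
    """
    x = abundances.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            f"all-zero samples make pairs undefined: "
            f"{[abundances.index[i] for i in zero_rows]}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(abundances.index), d)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix."""
    dv = d.values
    n = dv.shape[0]
    # Gower double-centering of -D^2/2
    a = -0.5 * dv**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)
    explained = eigvals / eigvals.sum() if eigvals.size else eigvals
    frame = pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, explained)


def _permanova_ss(d2: np.ndarray, group_codes: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared distances (each pair once, / group size)."""
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(group_codes == g)
        sub = d2[np.ix_(members, members)]
        ss_within += sub.sum() / (2.0 * members.size)
    return ss_within


def permanova(
    d: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor.

    Requires at least two groups with two samples each.  With a fixed seed
    the permutation stream, hence the p-value, is bit-reproducible.
    """
    labels = pd.Series(groups).reindex(d.labels)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    codes, uniques = pd.factorize(labels)
    sizes = np.bincount(codes)
    if len(uniques) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = len(d.labels)
    a = len(uniques)
    d2 = d.values**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _permanova_ss(d2, codes, a)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):
        # ss_within = 0 (perfect separation) gives an infinite pseudo-F
        f_obs = np.divide(ss_among / (a - 1), ss_within / (n - a))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exceed = 0
    with np.errstate(divide="ignore"):
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            ss_w = _permanova_ss(d2, perm, a)
            f_perm = np.divide((ss_total - ss_w) / (a - 1), ss_w / (n - a))
            if f_perm >= f_obs:
                exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(ss_among / ss_total), float(p), n_perm)
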