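"""Gene classification and set statistics.

k-means classes of occupancy profiles, threshold-defined change gene sets,
one-sided hypergeometric overlap tests, Pearson correlation summaries with
the |r| >= 0.4 "meaningful association" convention, and Tukey HSD pairwise
group comparisons.  Missing values are always removed pairwise/rowwise with
counts reported, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene_ids within an explicit universe.

    ``universe`` carries the actual background gene ids when known (needed
    to intersect universes across tests); ``universe_size`` alone survives a
    file round-trip.
    """

    name: str
    members: frozenset[str]
    universe: frozenset[str] | None = None
    _universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.universe is not None and not self.members <= self.universe:
            raise ValidationError(f"gene set {self.name!r}: members outside universe")
        if self.universe is None and self._universe_size is None:
            raise ValidationError(f"gene set {self.name!r}: no universe information")
        if self._universe_size is not None and self._universe_size < len(self.members):
            raise ValidationError(f"gene set {self.name!r}: universe smaller than members")

    @property
    def universe_size(self) -> int:
        if self.universe is not None:
            return len(self.universe)
        return int(self._universe_size)  # type: ignore[arg-type]

    def __len__(self) -> int:
        return len(self.members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """One gene per line with a header comment carrying name and universe size."""
    with open(path, "w") as fh:
        fh.write(f"# name: {gene_set.name}\n")
        fh.write(f"# universe_size: {gene_set.universe_size}\n")
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    name, universe_size = Path(path).stem, None
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# name:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("# universe_size:"):
                universe_size = int(line.split(":", 1)[1])
            elif line and not line.startswith("#"):
                members.append(line)
    return GeneSet(name=name, members=frozenset(members), _universe_size=universe_size)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """k-means partition of genes with reproducibility metadata."""

    labels: pd.Series           # gene_id -> cluster index
    k: int
    cluster_means: np.ndarray   # k x n_features
    seed: int
    n_init: int
    inertia: float
    degenerate: bool = False
    feature_space: str = "profile"

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_cluster(
    features: pd.DataFrame | pd.Series,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Lloyd k-means (Euclidean, best of ``n_init`` seeded inits by inertia).

    ``features`` may be a metagene matrix slice (profile clustering) or a
    single gene-level column (scalar clustering).  Missing values must be
    filtered beforehand.  Deterministic given ``seed``.
    """
    if isinstance(features, pd.Series):
        features = features.to_frame()
        space = "scalar"
    else:
        space = "profile" if features.shape[1] > 1 else "scalar"
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("kmeans_cluster: missing values present; pre-filter first")
    if k >= len(features):
        raise ValidationError(f"k={k} must be < number of genes ({len(features)})")
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=features.index, name="cluster")
    degenerate = labels.nunique() < k
    if degenerate:
        logger.warning("kmeans_cluster: only %d of %d clusters populated", labels.nunique(), k)
    return ClusterResult(
        labels=labels, k=k, cluster_means=km.cluster_centers_,
        seed=seed, n_init=n_init, inertia=float(km.inertia_),
        degenerate=degenerate, feature_space=space,
    )


def select_extreme_cluster(result: ClusterResult, direction: str) -> GeneSet:
    """Members of the cluster with maximal (``highest``) or minimal
    (``lowest``) mean feature value; ties go to the larger cluster."""
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    populated = np.array(sorted(result.labels.unique()))
    scores = result.cluster_means[populated].mean(axis=1)
    sizes = result.labels.value_counts().reindex(populated).to_numpy()
    target = scores.max() if direction == "highest" else scores.min()
    candidates = populated[scores == target]
    if len(candidates) > 1:
        logger.warning(
            "select_extreme_cluster: %d tied clusters; taking the largest", len(candidates)
        )
        candidates = candidates[np.argsort(-sizes[np.isin(populated, candidates)])]
    chosen = int(candidates[0])
    if result.degenerate:
        logger.warning("select_extreme_cluster: upstream clustering was degenerate")
    members = frozenset(result.labels.index[result.labels == chosen])
    return GeneSet(
        name=f"{direction}_cluster_{chosen}",
        members=members,
        universe=frozenset(result.labels.index),
    )


def threshold_gene_set(
    changes: pd.Series,
    cutoff: float,
    direction: str = "le",
    name: str | None = None,
) -> GeneSet:
    """Genes passing an inclusive threshold on a change column.

    Universe = genes with non-missing values in the column.
    """
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    values = changes.dropna()
    if values.empty:
        raise ValidationError("threshold_gene_set: all values missing")
    mask = values <= cutoff if direction == "le" else values >= cutoff
    return GeneSet(
        name=name or f"{changes.name or 'change'}_{direction}_{cutoff}",
        members=frozenset(values.index[mask]),
        universe=frozenset(values.index),
    )


# ---------------------------------------------------------------------------
# overlap and correlation statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric overlap between two gene sets."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_value: float


def hypergeometric_overlap(set_a: GeneSet, set_b: GeneSet) -> OverlapResult:
    """One-sided (enrichment) hypergeometric test of list overlap.

    p = P[X >= k] with X ~ Hypergeom(N, K, n): N the shared universe size,
    K = |A|, n = |B|, k = |A intersect B| (inclusive upper tail).
    """
    if set_a.universe is not None and set_b.universe is not None:
        universe = set_a.universe & set_b.universe
        if universe != set_a.universe or universe != set_b.universe:
            logger.info(
                "hypergeometric_overlap: universes differ; using intersection (%d genes)",
                len(universe),
            )
        a = set_a.members & universe
        b = set_b.members & universe
        n_universe = len(universe)
    else:
        if set_a.universe_size != set_b.universe_size:
            raise ValidationError(
                "hypergeometric_overlap: universe members unknown and sizes differ"
            )
        a, b, n_universe = set_a.members, set_b.members, set_a.universe_size
    k = len(a & b)
    if k > min(len(a), len(b)):
        raise ValidationError("overlap exceeds smaller set size")  # unreachable by set algebra
    p = float(stats.hypergeom.sf(k - 1, n_universe, len(a), len(b)))
    return OverlapResult(
        n_universe=n_universe, n_a=len(a), n_b=len(b), n_overlap=k,
        p_value=min(max(p, 0.0), 1.0),
    )


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n_used: int
    defined: bool = True


def pearson_r(x, y) -> PearsonResult:
    """Pearson product-moment correlation with pairwise missing-value removal.

    Returns ``defined=False`` (r = NaN) when either argument has zero
    variance; requires at least 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"pearson_r needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(r=float("nan"), n_used=n, defined=False)
    r = float(stats.pearsonr(x, y).statistic)
    return PearsonResult(r=r, n_used=n)


def dependence_summary(
    reference: pd.Series,
    response: pd.Series,
    threshold: float = 0.4,
    scatter_path: str | Path | None = None,
) -> dict:
    """Correlation summary with the |r| >= threshold 'meaningful' call.

    Optionally writes the paired values as a scatter-ready two-column TSV.
    """
    joined = pd.concat({"reference": reference, "response": response}, axis=1).dropna()
    res = pearson_r(joined["reference"], joined["response"])
    if scatter_path is not None:
        joined.rename_axis("gene_id").to_csv(scatter_path, sep="\t")
    return {
        "r": res.r,
        "n": res.n_used,
        "meaningful": bool(res.defined and abs(res.r) >= threshold),
        "threshold": threshold,
    }


def tukey_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD adjusted pairwise comparisons on the studentized range.

    Returns one row per unordered pair with the mean difference
    (group1 - group2) and the adjusted p-value.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("tukey_pairwise needs >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if len(a) < 2:
            raise ValidationError(f"group {n!r} needs >= 2 values")
        if np.isnan(a).any():
            raise ValidationError(f"group {n!r} contains missing values")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValidationError("zero pooled within-group variance")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group1": names[i],
                "group2": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)
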