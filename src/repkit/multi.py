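"""Group-level analyses.

Clonal space homeostasis with a chi-square comparison, longitudinal
clonotype tracking, repertoire similarity matrices with agglomerative
clustering, diversity indices with rarefaction, and a two-group rank test.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    EmptyRepertoireError,
    Repertoire,
    ValidationError,
    downsample,
)
from .single import d50 as _d50

# -------------------------------------------------------------------------
# clonal space homeostasis

DEFAULT_BIN_EDGES = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
DEFAULT_BIN_LABELS = ("rare", "small", "medium", "large", "expanded", "hyperexpanded")


@dataclass(slots=True)
class HomeostasisProfile:
    """Fraction of repertoire read mass per clonal-frequency bin.

    Bins are half-open on the left: a clone with frequency ``f`` belongs to
    the bin with ``lower < f <= upper``; the implicit lowest lower edge is 0.
    """

    sample_id: str
    bin_edges: tuple[float, ...]  # ascending upper edges, final edge 1
    bin_labels: tuple[str, ...]
    mass_per_bin: tuple[float, ...]
    reads_per_bin: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        lowers = (0.0,) + self.bin_edges[:-1]
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "lower": lowers,
                "upper": self.bin_edges,
                "mass": self.mass_per_bin,
                "reads": self.reads_per_bin,
            }
        )


def clonal_space_homeostasis(
    rep: Repertoire,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    bin_labels: Sequence[str] | None = None,
) -> HomeostasisProfile:
    """Partition repertoire read mass by clone-frequency class."""
    if not rep.records:
        raise EmptyRepertoireError(f"homeostasis: repertoire {rep.sample_id!r} empty")
    edges = tuple(float(e) for e in bin_edges)
    if list(edges) != sorted(set(edges)) or edges[0] <= 0 or edges[-1] != 1.0:
        raise ValidationError(
            f"bin edges must be strictly ascending in (0, 1] ending at 1, got {edges}"
        )
    if bin_labels is None:
        if edges == DEFAULT_BIN_EDGES:
            labels = DEFAULT_BIN_LABELS
        else:
            labels = tuple(f"bin{i}" for i in range(len(edges)))
    else:
        labels = tuple(bin_labels)
        if len(labels) != len(edges):
            raise ValidationError("bin_labels length must match bin_edges length")
    mass = [0.0] * len(edges)
    reads = [0] * len(edges)
    for rec in rep.records:
        idx = bisect_left(edges, rec.freq)
        if idx >= len(edges):
            raise RepkitInternalError(
                f"clone frequency {rec.freq} above final edge {edges[-1]}"
            )
        mass[idx] += rec.freq
        reads[idx] += rec.count
    return HomeostasisProfile(
        sample_id=rep.sample_id,
        bin_edges=edges,
        bin_labels=labels,
        mass_per_bin=tuple(mass),
        reads_per_bin=tuple(reads),
    )


class RepkitInternalError(RuntimeError):
    """Invariant violation inside the library (not a user error)."""


def compare_homeostasis(
    profile_a: HomeostasisProfile, profile_b: HomeostasisProfile
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2 x k table of reads per bin.

    No continuity correction.  Bins empty in both profiles are dropped and
    the degrees of freedom reduced accordingly.  Returns (chi2, df, p).
    """
    if profile_a.bin_edges != profile_b.bin_edges:
        raise ValidationError("homeostasis profiles have different bin edges")
    table = np.array([profile_a.reads_per_bin, profile_b.reads_per_bin], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValidationError(
            "chi-square undefined: fewer than 2 bins contain any reads"
        )
    if np.array_equal(table[0], table[1]):
        # identical profiles: chi2 exactly 0, avoid 0/0 edge cases downstream
        return 0.0, table.shape[1] - 1, 1.0
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# -------------------------------------------------------------------------
# clonotype tracking


@dataclass(slots=True)
class TrackingMatrix:
    """Per-sample frequencies of a tracked clonotype set (0 when absent)."""

    keys: list[tuple[str, ...]]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_keys, n_samples)
    selection_rule: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "key", ["|".join(k) for k in self.keys])
        return df


def clonotype_tracking(
    reps: Sequence[Repertoire],
    select: str = "top_n_overall",
    n: int = 10,
    anchor: str | None = None,
    key_mode: str = "nt+vj",
) -> TrackingMatrix:
    """Track clonotype frequencies across an ordered list of samples.

    ``top_n_overall`` tracks the ``n`` clones maximizing the maximum
    frequency attained in any sample; ``top_n_from_sample`` tracks the top
    ``n`` of the ``anchor`` sample.  Absent clones get frequency 0.
    Rows are ordered by descending selection statistic (key tie-break).
    """
    if len(reps) < 2:
        raise ValidationError("clonotype tracking needs at least 2 samples")
    if select not in ("top_n_overall", "top_n_from_sample"):
        raise ValidationError(f"unknown selection rule {select!r}")
    reps = [r.rekey(key_mode) for r in reps]
    sample_ids = [r.sample_id for r in reps]
    tables = [r.freq_by_key() for r in reps]

    if select == "top_n_from_sample":
        if anchor is None:
            raise ValidationError("anchor sample_id required for top_n_from_sample")
        if anchor not in sample_ids:
            raise ValidationError(
                f"anchor {anchor!r} not among samples {sample_ids}"
            )
        stat = dict(tables[sample_ids.index(anchor)])
    else:
        stat: dict[tuple[str, ...], float] = {}
        for t in tables:
            for k, v in t.items():
                if v > stat.get(k, 0.0):
                    stat[k] = v
    tracked = sorted(stat.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    keys = [k for k, _ in tracked]
    values = np.array([[t.get(k, 0.0) for t in tables] for k in keys], dtype=float)
    return TrackingMatrix(
        keys=keys,
        sample_ids=sample_ids,
        values=values,
        selection_rule=f"{select}(n={n}"
        + (f", anchor={anchor})" if anchor else ")"),
    )


# -------------------------------------------------------------------------
# similarity

SIMILARITY_INDICES = ("jaccard", "overlap_coefficient", "morisita_horn", "bhattacharyya")


@dataclass(slots=True)
class SimilarityMatrix:
    index_name: str
    sample_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def pair_similarity(rep_a: Repertoire, rep_b: Repertoire, index_name: str) -> float:
    """One similarity index between two repertoires (common key mode assumed).

    ``jaccard`` and ``overlap_coefficient`` act on clone *sets*;
    ``morisita_horn`` = 2 sum(p q) / (sum p^2 + sum q^2) and
    ``bhattacharyya`` = sum sqrt(p q) act on frequency vectors over the
    union key set, absent clones having frequency 0.
    """
    if index_name not in SIMILARITY_INDICES:
        raise ValidationError(
            f"unknown similarity index {index_name!r}; choose from {SIMILARITY_INDICES}"
        )
    fa = rep_a.freq_by_key()
    fb = rep_b.freq_by_key()
    set_a, set_b = set(fa), set(fb)
    if index_name == "jaccard":
        union = len(set_a | set_b)
        return len(set_a & set_b) / union if union else 0.0
    if index_name == "overlap_coefficient":
        m = min(len(set_a), len(set_b))
        return len(set_a & set_b) / m if m else 0.0
    union = set_a | set_b
    p = np.array([fa.get(k, 0.0) for k in union])
    q = np.array([fb.get(k, 0.0) for k in union])
    if index_name == "morisita_horn":
        denom = float(p @ p + q @ q)
        return float(2 * (p @ q) / denom) if denom else 0.0
    return float(np.sqrt(p * q).sum())  # bhattacharyya


def similarity_matrix(
    reps: Sequence[Repertoire], index_name: str = "morisita_horn",
    key_mode: str | None = None,
) -> SimilarityMatrix:
    """Pairwise similarity over a list of repertoires.

    If ``key_mode`` is given, every repertoire is re-keyed first; otherwise
    all repertoires must already share a key mode.
    """
    if len(reps) < 2:
        raise ValidationError("similarity matrix needs at least 2 samples")
    if key_mode is not None:
        reps = [r.rekey(key_mode) for r in reps]
    modes = {r.key_mode for r in reps}
    if len(modes) > 1:
        raise ValidationError(f"mixed key modes {sorted(modes)}; re-key first")
    n = len(reps)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pair_similarity(reps[i], reps[j], index_name)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(
        index_name=index_name,
        sample_ids=[r.sample_id for r in reps],
        values=values,
    )


# -------------------------------------------------------------------------
# hierarchical clustering on 1 - similarity


@dataclass(slots=True)
class Dendrogram:
    """Agglomerative clustering result; ``newick`` serializes the tree.

    ``merges`` lists (label_left, label_right, height) in merge order, where
    a cluster is labelled by its lexicographically smallest member.
    """

    newick: str
    merges: list[tuple[str, str, float]]


def cluster_samples(matrix: SimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of samples on distance 1 - similarity.

    Supports ``average`` (size-weighted), ``complete`` and ``single``
    linkage.  Merge ties are broken by cluster label so the tree is
    deterministic.  Branch lengths are merge-height differences.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    if not np.all(np.isfinite(matrix.values)):
        raise ValidationError("similarity matrix contains non-finite entries")
    labels = list(matrix.sample_ids)
    if len(labels) < 2:
        raise ValidationError("clustering needs at least 2 samples")

    dist = 1.0 - matrix.values
    # active clusters: label -> (member indices, newick fragment, height)
    clusters: dict[str, tuple[list[int], str, float]] = {
        lab: ([i], lab, 0.0) for i, lab in enumerate(labels)
    }

    def cluster_distance(mi: list[int], mj: list[int]) -> float:
        block = dist[np.ix_(mi, mj)]
        if linkage == "single":
            return float(block.min())
        if linkage == "complete":
            return float(block.max())
        return float(block.mean())

    merges: list[tuple[str, str, float]] = []
    while len(clusters) > 1:
        names = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dval = cluster_distance(clusters[a][0], clusters[b][0])
                cand = (dval, a, b)
                if best is None or cand < best:
                    best = cand
        dval, a, b = best
        mi, nwk_a, ha = clusters.pop(a)
        mj, nwk_b, hb = clusters.pop(b)
        nwk = f"({nwk_a}:{dval - ha:.10g},{nwk_b}:{dval - hb:.10g})"
        clusters[min(a, b)] = (mi + mj, nwk, dval)
        merges.append((a, b, dval))
    (_, newick, _), = clusters.values()
    return Dendrogram(newick=newick + ";", merges=merges)


# -------------------------------------------------------------------------
# diversity

DIVERSITY_INDICES = (
    "shannon",
    "normalized_shannon",
    "inverse_simpson",
    "gini_simpson",
    "clonality",
    "chao1",
    "d50",
)


@dataclass(slots=True)
class RarefactionBlock:
    depth: int
    n_resamples: int
    mean: float
    sd: float
    seed: int


@dataclass(slots=True)
class DiversityResult:
    sample_id: str
    index_name: str
    value: float
    rarefaction: RarefactionBlock | None = None


def _diversity_value(rep: Repertoire, index_name: str) -> float:
    p = rep.freqs()
    s = rep.n_clones
    if index_name == "shannon":
        return float(-(p * np.log(p)).sum())
    if index_name == "normalized_shannon":
        if s == 1:
            return 0.0
        return float(-(p * np.log(p)).sum() / math.log(s))
    if index_name == "clonality":
        if s == 1:
            return 1.0
        return float(1.0 + (p * np.log(p)).sum() / math.log(s))
    if index_name == "inverse_simpson":
        return float(1.0 / (p @ p))
    if index_name == "gini_simpson":
        return float(1.0 - p @ p)
    if index_name == "chao1":
        counts = rep.counts()
        f1 = int((counts == 1).sum())
        f2 = int((counts == 2).sum())
        if f2 > 0:
            return float(s + f1 * f1 / (2.0 * f2))
        return float(s + f1 * (f1 - 1) / 2.0)  # bias-corrected, f2 = 0
    if index_name == "d50":
        return float(_d50(rep))
    raise ValidationError(
        f"unknown diversity index {index_name!r}; choose from {DIVERSITY_INDICES}"
    )


def diversity(rep: Repertoire, index_name: str = "shannon") -> DiversityResult:
    """One diversity index of a repertoire.

    shannon: H = -sum p ln p (natural log); normalized_shannon = H / ln S
    (0 for a single clone); clonality = 1 - H / ln S (1 for a single clone);
    inverse_simpson = 1 / sum p^2; gini_simpson = 1 - sum p^2; chao1 =
    S + f1^2 / (2 f2), or the bias-corrected S + f1 (f1 - 1) / (2 (f2 + 1))
    when no doubletons exist (f1, f2 = clones with read count 1, 2); d50 =
    minimal top clones covering half the reads.
    """
    if not rep.records:
        raise EmptyRepertoireError(f"diversity: repertoire {rep.sample_id!r} empty")
    return DiversityResult(
        sample_id=rep.sample_id,
        index_name=index_name,
        value=_diversity_value(rep, index_name),
    )


def rarefied_diversity(
    rep: Repertoire,
    index_name: str,
    depth: int,
    n_resamples: int,
    seed: int,
) -> DiversityResult:
    """Mean and sd of a diversity index over repeated rarefaction draws.

    Each of the ``n_resamples`` draws downsamples independently to ``depth``
    reads; draw seeds derive deterministically from ``seed``.
    """
    if not rep.records:
        raise EmptyRepertoireError(f"diversity: repertoire {rep.sample_id!r} empty")
    if n_resamples < 1:
        raise ValidationError(f"n_resamples must be >= 1, got {n_resamples}")
    rng = np.random.default_rng(seed)
    draw_seeds = rng.integers(0, 2**63 - 1, size=n_resamples)
    values = np.array(
        [
            _diversity_value(downsample(rep, depth, int(s)), index_name)
            for s in draw_seeds
        ]
    )
    if np.all(values == values[0]):  # e.g. depth == total_reads: exhaustive draw
        mean, sd = float(values[0]), 0.0
    else:
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    return DiversityResult(
        sample_id=rep.sample_id,
        index_name=index_name,
        value=mean,
        rarefaction=RarefactionBlock(
            depth=depth,
            n_resamples=n_resamples,
            mean=mean,
            sd=sd,
            seed=seed,
        ),
    )


# -------------------------------------------------------------------------
# two-group comparison


def compare_groups(
    values: dict[str, Sequence[float]]
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U (unpaired rank-sum) between two groups.

    The exact null distribution is used when both groups have at most 8
    values and there are no ties; otherwise the normal approximation with
    tie correction (no continuity correction).  Returns
    (U statistic, p, method label).
    """
    if len(values) != 2:
        raise ValidationError(
            f"exactly 2 groups required, got {len(values)}; "
            "run pairwise invocations for more groups"
        )
    (la, xs), (lb, ys) = values.items()
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if len(xs) < 1 or len(ys) < 1:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([xs, ys])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(xs) <= 8 and len(ys) <= 8:
        res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "mann-whitney-exact"
    if np.ptp(pooled) == 0:
        # fully degenerate: identical constant groups, no evidence of shift
        return float(len(xs) * len(ys) / 2.0), 1.0, "mann-whitney-normal-degenerate"
    res = stats.mannwhitneyu(
        xs, ys, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue), "mann-whitney-normal-tie-corrected"


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()
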