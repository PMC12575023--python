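"""Community diversity: prevalence filtering, richness sets, Bray–Curtis,
PCoA and permutation tests for group separation.

PERMANOVA, ANOSIM and MRPP share one seeded permutation engine so p-values
are bit-reproducible; p = (1 + #{permuted statistic at least as extreme}) /
(1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from micronet.core import OtuTable, ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues and per-axis variance.

    Negative eigenvalues are reported but excluded from the variance
    denominator, so quoted axis percentages refer to the positive mass.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def filter_prevalence(table: OtuTable, min_samples: int = 2) -> OtuTable:
    """Drop OTUs detected (count > 0) in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = [o for o, p in zip(table.otu_ids, prevalence) if p >= min_samples]
    if not keep:
        raise ValidationError("prevalence filter removed every OTU")
    return table.subset_otus(keep)


def richness_and_sets(table: OtuTable) -> dict:
    """Observed richness and shared/unique OTU membership by group.

    Returns per-sample richness, per-group OTU counts, the core set present
    in every group, and each group's exclusive set (upset-plot style).
    """
    labels = table.group_labels()
    present = table.counts > 0
    per_sample = {
        s: int(present[i].sum()) for i, s in enumerate(table.sample_ids)
    }
    group_sets: dict[str, set[str]] = {}
    for g in table.groups:
        mask = labels == g
        member = present[mask].any(axis=0)
        group_sets[g] = {o for o, m in zip(table.otu_ids, member) if m}
    core = set.intersection(*group_sets.values()) if group_sets else set()
    unique = {
        g: s - set.union(*(group_sets[h] for h in group_sets if h != g))
        if len(group_sets) > 1
        else s
        for g, s in group_sets.items()
    }
    return {
        "richness_per_sample": per_sample,
        "group_otu_counts": {g: len(s) for g, s in group_sets.items()},
        "group_sets": group_sets,
        "core": core,
        "unique": unique,
    }


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness estimate for one sample's count vector."""
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def bray_curtis(table: OtuTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    Computed on per-sample relative abundances by default; set
    ``use_relative=False`` to use raw counts.
    """
    if (table.counts.sum(axis=1) == 0).any():
        raise ValidationError("all-zero sample; cannot compute Bray-Curtis")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    d = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal co-ordinate analysis by Gower double-centering.

    Eigendecomposition of -0.5 * J d^2 J with J the centering matrix; axes
    ordered by decreasing eigenvalue. Coordinates are produced for positive
    eigenvalues only.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 units")
    d2 = dist.matrix**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    denom = eigvals[pos].sum()
    proportions = np.where(pos, eigvals / denom, 0.0) if denom > 0 else eigvals * 0
    return OrdinationResult(dist.ids, coords, eigvals, proportions)


# ---------------------------------------------------------------------------
# permutation tests


def _permanova_stat(d2: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    groups, inverse = np.unique(labels, return_inverse=True)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(len(groups)):
        idx = np.flatnonzero(inverse == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    k = len(groups)
    ssa = sst - ssw
    return (ssa / (k - 1)) / (ssw / (n - k))


def _anosim_stat(rank_d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    r_within = rank_d[same].mean()
    r_between = rank_d[~same].mean()
    m = n * (n - 1) / 2.0
    return (r_between - r_within) / (m / 2.0)


def _mrpp_stat(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            delta += (len(idx) / n) * sub[np.triu_indices(len(idx), 1)].mean()
    return delta


def permutation_group_tests(
    dist: DistanceMatrix,
    labels: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """PERMANOVA, ANOSIM and MRPP with a shared label-permutation null.

    PERMANOVA and ANOSIM count permutations with statistic >= observed
    (separation increases the statistic); MRPP counts delta <= observed
    (separation shrinks the within-group mean distance).
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    if isinstance(labels, Mapping):
        lab = np.array([labels[s] for s in dist.ids])
    else:
        lab = np.asarray(list(labels))
    if len(np.unique(lab)) < 2:
        raise ValidationError("permutation tests need >= 2 groups")
    d = dist.matrix
    d2 = d**2
    iu = np.triu_indices(len(lab), 1)
    rank_d = stats.rankdata(d[iu])
    obs = {
        "permanova": _permanova_stat(d2, lab),
        "anosim": _anosim_stat(rank_d, lab),
        "mrpp": _mrpp_stat(d, lab),
    }
    rng = np.random.default_rng(seed)
    hits = {k: 0 for k in obs}
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if _permanova_stat(d2, perm) >= obs["permanova"]:
            hits["permanova"] += 1
        if _anosim_stat(rank_d, perm) >= obs["anosim"]:
            hits["anosim"] += 1
        if _mrpp_stat(d, perm) <= obs["mrpp"]:
            hits["mrpp"] += 1
    out = {}
    names = {"permanova": "pseudo_F", "anosim": "R", "mrpp": "delta"}
    for k, stat in obs.items():
        out[k] = {
            names[k]: float(stat),
            "p": (1 + hits[k]) / (1 + n_perm),
            "n_permutations": n_perm,
        }
    return out


def agglomerate(table: OtuTable, rank: str) -> "tuple[list[str], np.ndarray]":
    """Sum relative abundances of OTUs sharing a taxon at the given rank."""
    from micronet.core import TAXONOMIC_RANKS

    if table.taxonomy is None:
        raise ValidationError("table has no taxonomy")
    if rank not in TAXONOMIC_RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    level = TAXONOMIC_RANKS.index(rank)
    rel = table.relative_abundance()
    taxa: dict[str, np.ndarray] = {}
    for j, otu in enumerate(table.otu_ids):
        lineage = table.taxonomy.get(otu)
        name = lineage[level] if lineage else "unclassified"
        taxa.setdefault(name, np.zeros(table.n_samples))
        taxa[name] += rel[:, j]
    names = sorted(taxa)
    return names, np.column_stack([taxa[t] for t in names])


def taxon_group_tests(
    table: OtuTable, rank: str = "phylum", alpha: float = 0.05
) -> dict[str, dict[str, float | bool]]:
    """Per-taxon Kruskal–Wallis across groups on rank-agglomerated abundance."""
    names, matrix = agglomerate(table, rank)
    labels = table.group_labels()
    out: dict[str, dict[str, float | bool]] = {}
    for j, name in enumerate(names):
        col = matrix[:, j]
        by_group = [col[labels == g] for g in table.groups]
        if np.all(col == col[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*by_group)
        out[name] = {"H": float(h), "p": float(p), "significant": bool(p < alpha)}
    return out


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to a common depth."""
    totals = table.counts.sum(axis=1)
    if (totals < depth).any():
        raise ValidationError("some samples are shallower than the target depth")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for i in range(table.n_samples):
        reads = np.repeat(np.arange(table.n_otus), table.counts[i])
        picked = rng.choice(reads, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=table.n_otus)
    from dataclasses import replace

    return replace(table, counts=out)
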