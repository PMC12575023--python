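"""Module eigenvectors (MicroMEs) and their phenotype/dose associations.

A MicroME is the first principal-component profile of a module of co-varying
OTUs across samples (the microbial analogue of a WGCNA module eigengene);
kME is each member's correlation with that profile. Phenotype variables are
clustered into featured modules the same way, and MicroME-phenotype-dose
associations are scored with Spearman correlations and Mantel tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from micronet.core import PhenotypeTable, ValidationError


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def cluster_differential_otus(
    matrix: pd.DataFrame, target_modules: int
) -> dict[str, int]:
    """Cluster differential OTUs into modules on 1 - Spearman distance.

    ``matrix`` is samples x OTUs (log relative abundance). Average-linkage
    hierarchical clustering is cut at ``target_modules`` clusters; module
    ids are 0-based in order of first appearance.
    """
    otus = list(matrix.columns)
    if len(otus) < 2:
        raise ValidationError("need at least two differential OTUs")
    if target_modules > len(otus):
        raise ValidationError("more modules requested than OTUs")
    rho = matrix.corr(method="spearman")
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=target_modules, criterion="maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for otu, raw in zip(otus, labels):
        if raw not in remap:
            remap[raw] = len(remap)
        out[otu] = remap[raw]
    return out


@dataclass(frozen=True)
class MicroME:
    module_id: int | str
    members: tuple[str, ...]
    eigenvector: pd.Series  # per-sample profile, zero mean, unit variance
    variance_explained: float
    kme: dict[str, tuple[float, float]]  # member -> (Spearman r, p)


def module_eigenvector(
    submatrix: pd.DataFrame, module_id: int | str = 0
) -> MicroME:
    """First singular profile of a module's standardized abundance submatrix.

    Each member OTU is z-scored across samples, the first left singular
    vector of the samples x OTUs matrix is the eigenvector (scaled to unit
    variance), variance explained is lambda_1 / sum(lambda), and the sign is
    oriented so the mean kME is non-negative.
    """
    keep = [c for c in submatrix.columns if submatrix[c].nunique() > 1]
    dropped = set(submatrix.columns) - set(keep)
    if dropped:
        import warnings

        warnings.warn(f"zero-variance members dropped: {sorted(dropped)}",
                      stacklevel=2)
    if not keep:
        raise ValidationError("module has no member with variance")
    x = _zscore(submatrix[keep].to_numpy(dtype=float))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    profile = u[:, 0]
    profile = (profile - profile.mean()) / profile.std()
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    kme = {}
    for c in keep:
        r, p = stats.spearmanr(submatrix[c].to_numpy(), profile)
        kme[c] = (float(r), float(p))
    if np.mean([r for r, _ in kme.values()]) < 0:
        profile = -profile
        kme = {c: (-r, p) for c, (r, p) in kme.items()}
    return MicroME(
        module_id=module_id,
        members=tuple(keep),
        eigenvector=pd.Series(profile, index=submatrix.index),
        variance_explained=var_explained,
        kme=kme,
    )


def extract_micromes(
    matrix: pd.DataFrame, module_of: Mapping[str, int]
) -> dict[str, MicroME]:
    """One MicroME per module of a differential-OTU abundance matrix."""
    out: dict[str, MicroME] = {}
    for mid in sorted(set(module_of.values())):
        members = [o for o, m in module_of.items() if m == mid]
        name = f"MicroME{mid + 1}"
        out[name] = module_eigenvector(matrix[members], module_id=name)
    return out


@dataclass(frozen=True)
class PhenoModuleSet:
    module_of: dict[str, str]  # variable -> module label
    eigenvectors: pd.DataFrame  # units x modules, standardized


def phenotype_modules(
    phenotypes: PhenotypeTable, target_modules: int
) -> PhenoModuleSet:
    """Cluster phenotype variables into featured modules and extract profiles.

    Variables are clustered on 1 - |Spearman| (sign-blind, so a variable and
    its mirror land together); each module's eigenvector is extracted as for
    MicroMEs and labelled by its dominant category (growth1, growth2, ...).
    """
    variables = list(phenotypes.variables)
    if len(variables) < 2:
        raise ValidationError("need at least two phenotype variables")
    if target_modules > len(variables):
        raise ValidationError("more modules requested than variables")
    zero_var = phenotypes.zero_variance_variables()
    if zero_var:
        import warnings

        warnings.warn(f"zero-variance phenotype variables: {zero_var}",
                      stacklevel=2)
    values = phenotypes.values
    rho = values.corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(np.clip(dist, 0, 1), checks=False), method="average")
    labels = fcluster(z, t=target_modules, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for v, lab in zip(variables, labels):
        groups.setdefault(int(lab), []).append(v)
    counters: dict[str, int] = {}
    module_of: dict[str, str] = {}
    eig = {}
    for lab in sorted(groups):
        members = groups[lab]
        cats = [phenotypes.category_of[v] for v in members]
        dominant = max(set(cats), key=cats.count)
        counters[dominant] = counters.get(dominant, 0) + 1
        name = f"{dominant}{counters[dominant]}"
        for v in members:
            module_of[v] = name
        me = module_eigenvector(values[members], module_id=name)
        eig[name] = me.eigenvector
    return PhenoModuleSet(module_of=module_of, eigenvectors=pd.DataFrame(eig))


# ---------------------------------------------------------------------------
# association


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Mantel test between two square distance matrices (one-sided, greater).

    The statistic is the Spearman (or Pearson) correlation of the condensed
    upper triangles; the null permutes one matrix's units with a seeded RNG;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    n = d1.shape[0]
    if d1.shape != d2.shape or n < 3:
        raise ValidationError("Mantel needs two equal square matrices, n >= 3")
    iu = np.triu_indices(n, 1)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    r_obs = float(corr(d1[iu], d2[iu])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = float(corr(d1[iu], d2[np.ix_(perm, perm)][iu])[0])
        if r >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


@dataclass(frozen=True)
class AssociationResult:
    spearman_r: pd.DataFrame  # MicroMEs (+dose) x phenotype modules (+dose)
    spearman_p: pd.DataFrame
    mantel: dict[str, tuple[float, float]]  # MicroME -> (r, p) vs phenotype set


def associate(
    micromes: Mapping[str, MicroME],
    pheno: PhenoModuleSet,
    dose: pd.Series | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Spearman and Mantel associations between MicroMEs, phenotype modules
    and dose.

    Sample universes must match (MicroME profiles are aggregated to the
    phenotype units upstream when the trial measures phenotypes per cage).
    Each MicroME's Mantel test compares Euclidean distances of its profile
    with those of the full phenotype-module eigenvector matrix.
    """
    units = list(pheno.eigenvectors.index)
    rows: dict[str, pd.Series] = {
        name: me.eigenvector for name, me in micromes.items()
    }
    for name, profile in rows.items():
        if list(profile.index) != units:
            raise ValidationError(
                f"sample universe of {name} does not match phenotype units"
            )
    cols = pheno.eigenvectors.copy()
    if dose is not None:
        if list(dose.index) != units:
            raise ValidationError("dose vector units do not match")
        cols["dose"] = dose.astype(float)
        rows = dict(rows)
        rows["dose"] = dose.astype(float)
    r_mat = pd.DataFrame(index=list(rows), columns=list(cols.columns), dtype=float)
    p_mat = r_mat.copy()
    for rname, profile in rows.items():
        for cname in cols.columns:
            r, p = stats.spearmanr(profile.to_numpy(), cols[cname].to_numpy())
            r_mat.loc[rname, cname] = float(r)
            p_mat.loc[rname, cname] = float(p)
    pheno_dist = squareform(pdist(pheno.eigenvectors.to_numpy()))
    mantel: dict[str, tuple[float, float]] = {}
    for i, (name, me) in enumerate(micromes.items()):
        d_me = squareform(pdist(me.eigenvector.to_numpy()[:, None]))
        mantel[name] = mantel_test(d_me, pheno_dist, n_perm=n_perm, seed=seed + i)
    return AssociationResult(spearman_r=r_mat, spearman_p=p_mat, mantel=mantel)


def identify_biomarkers(
    microme: MicroME,
    abundance: pd.DataFrame,
    group_of: Mapping[str, str],
    taxonomy: Mapping[str, tuple[str, ...]] | None = None,
    alpha: float = 0.05,
    kme_r_min: float = 0.4,
) -> list[dict]:
    """Member OTUs that track the MicroME and differ across groups.

    Selection: kME r > kme_r_min with p < alpha, plus a significant
    Kruskal–Wallis test of the OTU's abundance across treatment groups.
    Returns one record per biomarker with taxonomy and per-group means.
    """
    labels = np.array([group_of[s] for s in abundance.index])
    groups = list(dict.fromkeys(labels))
    out = []
    for otu in microme.members:
        r, p = microme.kme[otu]
        if not (r > kme_r_min and p < alpha):
            continue
        col = abundance[otu].to_numpy(dtype=float)
        by_group = [col[labels == g] for g in groups]
        if np.all(col == col[0]):
            continue
        _, kw_p = stats.kruskal(*by_group)
        if kw_p >= alpha:
            continue
        out.append(
            {
                "otu": otu,
                "kme_r": r,
                "kme_p": p,
                "kruskal_p": float(kw_p),
                "taxonomy": taxonomy.get(otu) if taxonomy else None,
                "group_means": {
                    g: float(col[labels == g].mean()) for g in groups
                },
            }
        )
    out.sort(key=lambda rec: -rec["kme_r"])
    return out
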