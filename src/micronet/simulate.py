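"""Synthetic community and phenotype generators with known ground truth.

Every generator is a pure function of its parameters and seed.  They emulate
the feeding-trial design — five dose groups, six gut samples per group,
sparse overdispersed OTU counts, planted differential OTUs and correlated
modules, neutral- and niche-assembled communities, and cage-level phenotypes
with a quadratic dose response — so each analysis stage can be checked
against planted truth without the original sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from micronet.core import DoseDesign, OtuTable, PhenotypeTable, ValidationError


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a simulated OTU table.

    differential_otus maps each planted OTU id to its true log2 effect in
    treated groups; module_assignment maps module-member OTUs to module ids;
    latent_factors holds the unit-variance module factors (samples x modules).
    """

    differential_otus: dict[str, float]
    module_assignment: dict[str, int]
    latent_factors: np.ndarray
    neutral_m: float | None = None
    phenotype_coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    noise_sd: float = 0.0


def _lognormal_base(rng: np.random.Generator, n_otus: int, sigma: float) -> np.ndarray:
    base = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    return base / base.sum()


def simulate_otu_table(
    n_groups: int = 5,
    n_per_group: int = 6,
    n_otus: int = 300,
    n_diff: int = 30,
    n_modules: int = 3,
    effect_log2: float = 1.5,
    depth_mean: float = 20000.0,
    seed: int = 0,
    base_sigma: float = 1.5,
    module_size: int = 20,
    module_loading: float = 0.85,
    dispersion: float | None = None,
    dose_linked_modules: int = 0,
    groups: Sequence[str] | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Dose-group OTU table with planted differential OTUs and modules.

    Expected abundances start from a log-normal base profile
    (``base_sigma`` controls the long tail). Planted differential OTUs are
    shifted by ``effect_log2`` (alternating sign) in every treated group
    relative to the first (control) group; planting is restricted to the
    50th–85th abundance percentile band so planted signals are detectable
    at the default depth without dominating the compositional total. OTUs
    of a module share a unit-variance Gaussian latent factor injected on
    the log scale before compositional closure with loading
    ``module_loading``; module factors are centered within each group so
    that planted modules are co-varying but, by construction, not
    differential (use ``dose_linked_modules`` for treatment-associated
    modules). Counts are multinomial at a Poisson(``depth_mean``) depth;
    passing a Dirichlet concentration via ``dispersion`` adds taxon-level
    overdispersion on top.
    """
    if n_diff > n_otus:
        raise ValidationError("n_diff cannot exceed n_otus")
    if depth_mean <= 0:
        raise ValidationError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = [f"G{i}" for i in range(n_groups)]
    groups = list(groups)[:n_groups]
    n_samples = n_groups * n_per_group
    sample_ids = [f"{g}_s{j + 1}" for g in groups for j in range(n_per_group)]
    group_idx = np.repeat(np.arange(n_groups), n_per_group)
    otu_ids = [f"OTU{i + 1}" for i in range(n_otus)]

    base = _lognormal_base(rng, n_otus, base_sigma)
    log_mu = np.tile(np.log(base), (n_samples, 1))

    # planted differential OTUs: alternating-sign log2 shift in treated
    # groups, drawn from the mid-abundance band
    q_lo, q_hi = np.quantile(base, 0.5), np.quantile(base, 0.85)
    eligible = np.flatnonzero((base >= q_lo) & (base <= q_hi))
    need = n_diff + n_modules * module_size
    if len(eligible) < need:
        eligible = np.argsort(base)[n_otus // 2:]  # fall back to the top half
    if len(eligible) < need:
        raise ValidationError("not enough OTUs to plant signals; raise n_otus")
    diff_idx = rng.choice(eligible, size=n_diff, replace=False)
    signs = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
    effects = signs * effect_log2
    treated = group_idx > 0
    for j, e in zip(diff_idx, effects):
        log_mu[treated, j] += e * np.log(2.0)

    def _center_by_group(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        for g in range(n_groups):
            out[group_idx == g] -= out[group_idx == g].mean()
        sd = out.std()
        return out / sd if sd > 0 else out

    # planted modules share a latent factor before closure
    module_of: dict[str, int] = {}
    free = np.setdiff1d(eligible, diff_idx)
    rng.shuffle(free)
    latent = rng.standard_normal((n_samples, max(n_modules, 1)))
    n_linked = min(dose_linked_modules, n_modules)
    for m in range(max(n_modules, 1)):
        if m < n_linked:
            doses = group_idx.astype(float)
            z = (doses - doses.mean()) / doses.std()
            mixed = 0.8 * z + 0.6 * rng.standard_normal(n_samples)
            latent[:, m] = (mixed - mixed.mean()) / mixed.std()
        else:
            latent[:, m] = _center_by_group(latent[:, m])
    lam = module_loading
    for m in range(n_modules):
        members = free[m * module_size: (m + 1) * module_size]
        for j in members:
            noise = rng.standard_normal(n_samples)
            if m >= n_linked:
                noise = _center_by_group(noise)
            log_mu[:, j] += lam * latent[:, m] + np.sqrt(1 - lam**2) * noise
            module_of[otu_ids[j]] = m

    # compositional closure + multinomial realization
    mu = np.exp(log_mu)
    props = mu / mu.sum(axis=1, keepdims=True)
    depths = rng.poisson(depth_mean, size=n_samples)
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for s in range(n_samples):
        if dispersion is None:
            p = props[s]
        else:
            p = rng.dirichlet(np.maximum(props[s] * dispersion, 1e-8))
        counts[s] = rng.multinomial(max(int(depths[s]), 1), p)

    planted = {otu_ids[j]: float(e) for j, e in zip(diff_idx, effects)}
    observed = counts[:, diff_idx].sum(axis=0)
    if effect_log2 != 0 and np.mean(observed == 0) > 0.2:
        raise ValidationError(
            "more than 20% of planted differential OTUs are all-zero; "
            "increase depth_mean or reduce base_sigma"
        )
    group_of = {s: g for s, g in zip(sample_ids, np.repeat(groups, n_per_group))}
    table = OtuTable(tuple(sample_ids), tuple(otu_ids), counts, group_of)
    truth = SyntheticTruth(
        differential_otus=planted if effect_log2 != 0 else {k: 0.0 for k in planted},
        module_assignment=module_of,
        latent_factors=latent[:, :n_modules],
    )
    return table, truth


def simulate_neutral_community(
    n_samples: int = 30,
    n_taxa: int = 200,
    m: float = 0.1,
    depth: int = 1000,
    seed: int = 0,
    meta_sigma: float = 1.5,
) -> OtuTable:
    """Community assembled under the Sloan neutral model.

    Metacommunity relative abundances p_i are log-normal (normalized). Each
    sample's taxon proportions are drawn from the stationary beta
    distribution Beta(N m p_i, N m (1 - p_i)) with N = depth, renormalized,
    and realized as a multinomial of size ``depth``. Larger migration m pins
    local communities closer to the metacommunity.
    """
    if not 0 < m <= 1:
        raise ValidationError("migration rate m must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = _lognormal_base(rng, n_taxa, meta_sigma)
    nm = depth * m
    a = np.maximum(nm * p, 1e-12)
    b = np.maximum(nm * (1.0 - p), 1e-12)
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        x = rng.beta(a, b)
        total = x.sum()
        probs = x / total if total > 0 else np.full(n_taxa, 1.0 / n_taxa)
        counts[s] = rng.multinomial(depth, probs)
    sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    otu_ids = tuple(f"OTU{i + 1}" for i in range(n_taxa))
    return OtuTable(sample_ids, otu_ids, counts,
                    {s: "neutral" for s in sample_ids})


def simulate_niche_community(
    n_samples: int = 30,
    n_taxa: int = 200,
    filter_strength: float = 5.0,
    seed: int = 0,
    depth: int = 10000,
    base_sigma: float = 1.0,
) -> OtuTable:
    """Community shaped by environmental filtering along a 1-D gradient.

    Each taxon has an environmental optimum; its expected abundance in a
    sample follows a Gaussian response to the sample's environment value,
    sharpened by ``filter_strength``. Strength 0 reduces to uniform expected
    abundance (every taxon a generalist).
    """
    if filter_strength < 0:
        raise ValidationError("filter_strength must be >= 0")
    rng = np.random.default_rng(seed)
    env = rng.uniform(0.0, 1.0, size=n_samples)
    optima = rng.uniform(0.0, 1.0, size=n_taxa)
    base = _lognormal_base(rng, n_taxa, base_sigma)
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        response = np.exp(-filter_strength * (env[s] - optima) ** 2)
        w = base * response
        counts[s] = rng.multinomial(depth, w / w.sum())
    sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    otu_ids = tuple(f"OTU{i + 1}" for i in range(n_taxa))
    return OtuTable(sample_ids, otu_ids, counts,
                    {s: "niche" for s in sample_ids})


def simulate_phenotypes(
    design: DoseDesign,
    coefficients: Mapping[str, tuple[float, float, float]],
    noise_sd: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    category_of: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Cage-level phenotypes with a quadratic dose response.

    Each variable is y = b0 + b1 x + b2 x^2 + eps, x the group dose in
    mg/kg, eps ~ Normal(0, noise_sd), replicated at the cage level
    according to the design.
    """
    if len(design.groups) < 3:
        raise ValidationError("quadratic truth needs at least 3 dose levels")
    rng = np.random.default_rng(seed)
    import pandas as pd

    unit_ids: list[str] = []
    group_of: dict[str, str] = {}
    doses: list[float] = []
    for g in design.groups:
        for r in range(design.replicates[g]):
            uid = f"{g}_c{r + 1}"
            unit_ids.append(uid)
            group_of[uid] = g
            doses.append(design.dose_of[g])
    x = np.asarray(doses)
    data = {}
    for var, (b0, b1, b2) in coefficients.items():
        sd = noise_sd[var] if isinstance(noise_sd, Mapping) else float(noise_sd)
        y = b0 + b1 * x + b2 * x**2
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(x))
        data[var] = y
    values = pd.DataFrame(data, index=unit_ids)
    cats = dict(category_of) if category_of else {v: "growth" for v in coefficients}
    return PhenotypeTable(tuple(unit_ids), values, cats, group_of)


def sloan_expected_occupancy(p: np.ndarray, n_reads: float, m: float,
                             detection: float = 1.0) -> np.ndarray:
    """Expected occupancy under the Sloan neutral model.

    Probability that a taxon with metacommunity relative abundance p exceeds
    the detection limit (``detection`` reads out of ``n_reads``) in a sample:
    1 - BetaCDF(detection / n_reads; N m p, N m (1 - p)).
    """
    nm = n_reads * m
    d = detection / n_reads
    return 1.0 - stats.beta.cdf(d, np.maximum(nm * p, 1e-12),
                                np.maximum(nm * (1.0 - p), 1e-12))
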