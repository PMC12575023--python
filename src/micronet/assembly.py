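"""Community assembly diagnostics: Sloan neutral model and niche breadth.

The Sloan neutral community model predicts a taxon's occupancy (fraction of
samples in which it is detected) from its metacommunity relative abundance
through a beta distribution governed by the migration parameter m; a good
fit (high R^2) indicates drift-plus-dispersal assembly, a poor fit
deterministic (niche) processes. Levins niche breadth B = 1 / sum(q_j^2)
measures how evenly a taxon spreads over samples; permutation nulls separate
generalists (B above the null) from specialists (B below it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from micronet.core import OtuTable, ValidationError
from micronet.simulate import sloan_expected_occupancy


@dataclass(frozen=True)
class NeutralFit:
    m: float
    nm: float  # N * m with N the mean sample depth
    r_squared: float
    mean_depth: float
    otu_ids: tuple[str, ...]
    mean_relative_abundance: np.ndarray
    observed_occupancy: np.ndarray
    predicted_occupancy: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    partition: np.ndarray  # "above" | "within" | "below" per OTU


def _wilson_band(p: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score interval around a predicted binomial frequency."""
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def fit_neutral_model(table: OtuTable, detection: float = 1.0) -> NeutralFit:
    """Fit the Sloan neutral model to an OTU table's occupancy-abundance curve.

    m is estimated by bounded least squares on occupancy; R^2 = 1 - SSE/SST
    (it may be negative when the neutral expectation fits worse than the
    mean). OTUs outside the Wilson 95% band around the prediction are
    partitioned into "above" and "below".
    """
    if table.n_otus < 2:
        raise ValidationError("neutral fit needs more than one OTU")
    if table.n_samples < 10:
        raise ValidationError("neutral fit needs at least 10 samples")
    depths = table.counts.sum(axis=1)
    n_reads = float(depths.mean())
    p = table.relative_abundance().mean(axis=0)
    keep = p > 0
    occ = (table.counts >= detection).mean(axis=0)

    def sse(m: float) -> float:
        pred = sloan_expected_occupancy(p[keep], n_reads, m, detection)
        return float(((occ[keep] - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    m = float(res.x)
    pred = np.zeros_like(p)
    pred[keep] = sloan_expected_occupancy(p[keep], n_reads, m, detection)
    sst = float(((occ[keep] - occ[keep].mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lo, hi = _wilson_band(pred, table.n_samples)
    partition = np.where(occ > hi, "above", np.where(occ < lo, "below", "within"))
    partition[~keep] = "within"
    return NeutralFit(
        m=m,
        nm=m * n_reads,
        r_squared=float(r2),
        mean_depth=n_reads,
        otu_ids=table.otu_ids,
        mean_relative_abundance=p,
        observed_occupancy=occ,
        predicted_occupancy=pred,
        ci_lower=lo,
        ci_upper=hi,
        partition=partition,
    )


def levins_breadth(table: OtuTable) -> dict[str, float]:
    """Levins niche breadth per OTU: B = 1 / sum_j q_j^2.

    q_j is the OTU's share of its own total in sample j; B ranges from 1
    (single-sample specialist) to the number of samples (perfectly even).
    All-zero OTUs are returned as NaN.
    """
    totals = table.counts.sum(axis=0).astype(float)
    out: dict[str, float] = {}
    for j, otu in enumerate(table.otu_ids):
        if totals[j] == 0:
            out[otu] = float("nan")
            continue
        q = table.counts[:, j] / totals[j]
        out[otu] = float(1.0 / np.sum(q**2))
    return out


@dataclass(frozen=True)
class NicheResult:
    breadth: dict[str, float]
    classification: dict[str, str]  # generalist | specialist | non-significant
    null_lower: dict[str, float]
    null_upper: dict[str, float]
    counts: dict[str, int]


def classify_generalists(
    table: OtuTable,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> NicheResult:
    """Classify OTUs as generalists/specialists against a permutation null.

    The null reallocates each OTU's total reads across samples by a
    multinomial proportional to sample depths, preserving both margins in
    expectation. Observed B above the (1 - alpha/2) null quantile is a
    generalist, below the alpha/2 quantile a specialist.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    depths = table.counts.sum(axis=1).astype(float)
    probs = depths / depths.sum()
    observed = levins_breadth(table)
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    classification: dict[str, str] = {}
    null_lower: dict[str, float] = {}
    null_upper: dict[str, float] = {}
    totals = table.counts.sum(axis=0)
    for j, otu in enumerate(table.otu_ids):
        total = int(totals[j])
        if total == 0:
            classification[otu] = "non-significant"
            null_lower[otu] = null_upper[otu] = float("nan")
            continue
        draws = rng.multinomial(total, probs, size=n_perm).astype(float)
        q = draws / total
        b_null = 1.0 / np.sum(q**2, axis=1)
        lo = float(np.quantile(b_null, lo_q))
        hi = float(np.quantile(b_null, hi_q))
        null_lower[otu], null_upper[otu] = lo, hi
        b = observed[otu]
        if b > hi:
            classification[otu] = "generalist"
        elif b < lo:
            classification[otu] = "specialist"
        else:
            classification[otu] = "non-significant"
    counts = {
        "generalist": sum(1 for c in classification.values() if c == "generalist"),
        "specialist": sum(1 for c in classification.values() if c == "specialist"),
        "non-significant": sum(
            1 for c in classification.values() if c == "non-significant"
        ),
    }
    return NicheResult(
        breadth=observed,
        classification=classification,
        null_lower=null_lower,
        null_upper=null_upper,
        counts=counts,
    )


def classify_by_group(
    table: OtuTable, n_perm: int = 999, seed: int = 0, alpha: float = 0.05
) -> dict[str, NicheResult]:
    """Per-treatment-group generalist/specialist classification."""
    out = {}
    for i, g in enumerate(table.groups):
        sub = table.subset_group(g)
        present = [o for o, c in zip(sub.otu_ids, sub.counts.sum(axis=0)) if c > 0]
        sub = sub.subset_otus(present)
        out[g] = classify_generalists(sub, n_perm=n_perm, seed=seed + i, alpha=alpha)
    return out
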