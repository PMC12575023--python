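"""Moderated linear-model differential OTU analysis.

Per-OTU one-way linear models on log2 relative abundance, with residual
variances shrunk toward a common prior by empirical Bayes: the prior
(d0, s0^2) is estimated by matching the moments of log sample variances
(digamma/trigamma inversion), the posterior variance is the precision-
weighted blend (d0 s0^2 + d s^2) / (d0 + d), and the moderated t carries
d0 + d degrees of freedom. Flags follow the trial's thresholds: raw
p < 0.05 and |log2 fold change| >= 1 versus the control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from micronet.core import OtuTable, ValidationError


def transform_log_relative(table: OtuTable, pseudocount: float | None = None) -> pd.DataFrame:
    """log2(relative abundance + pseudocount), samples x OTUs.

    The default pseudocount is half the smallest nonzero relative abundance
    in the table, keeping the offset on the data's own scale.
    """
    rel = table.relative_abundance()
    if pseudocount is None:
        nonzero = rel[rel > 0]
        if nonzero.size == 0:
            raise ValidationError("table has no nonzero counts")
        pseudocount = float(nonzero.min()) / 2.0
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return pd.DataFrame(
        np.log2(rel + pseudocount),
        index=list(table.sample_ids),
        columns=list(table.otu_ids),
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene-wise variances.

    Matches the first two moments of e = log(s^2) - digamma(d/2) + log(d/2),
    whose theoretical mean and variance under the scaled inverse chi-square
    model are log(s0^2) - digamma(d0/2) + log(d0/2) and
    trigamma(d/2) + trigamma(d0/2). Returns d0 = inf when the observed
    spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need at least two positive variances")
    e = np.log(s2[ok]) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    if e_var < 1e-12:  # identical variances: the common value is the prior
        return float("inf"), float(np.mean(s2[ok]))
    excess = e_var - float(polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = float("inf")
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


@dataclass(frozen=True)
class DifferentialResult:
    otu_ids: tuple[str, ...]
    contrasts: tuple[str, ...]  # treated group vs reference
    reference: str
    logfc: pd.DataFrame  # OTUs x contrasts
    t: pd.DataFrame
    p: pd.DataFrame
    s2_posterior: np.ndarray
    d0: float
    s0_2: float
    df_residual: int


def moderated_fit(
    matrix: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    reference: str,
) -> DifferentialResult:
    """Fit per-OTU group-means models and moderate the t-statistics.

    ``matrix`` is samples x OTUs (log2 relative abundance); every treated
    group is contrasted against ``reference``.
    """
    labels = pd.Series(groups).reindex(matrix.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    if reference not in set(labels):
        raise ValidationError(f"reference group {reference!r} not present")
    group_names = [g for g in dict.fromkeys(labels) if g != reference]
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    n, k = len(labels), sizes.size
    d = n - k
    if d < 1:
        raise ValidationError("no residual degrees of freedom")
    means = {g: x[(labels == g).to_numpy()].mean(axis=0) for g in sizes.index}
    ss_res = np.zeros(x.shape[1])
    for g in sizes.index:
        sub = x[(labels == g).to_numpy()]
        ss_res += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    s2 = ss_res / d
    d0, s0_2 = estimate_variance_prior(s2[s2 > 0], d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = 1_000_000  # effectively a z-test against the prior scale
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    logfc = {}
    tstats = {}
    pvals = {}
    ref_n = sizes[reference]
    for g in group_names:
        v = 1.0 / sizes[g] + 1.0 / ref_n
        fc = means[g] - means[reference]
        t = fc / np.sqrt(s2_post * v)
        logfc[g] = fc
        tstats[g] = t
        pvals[g] = 2.0 * stats.t.sf(np.abs(t), df_total)
    otus = tuple(matrix.columns)
    return DifferentialResult(
        otu_ids=otus,
        contrasts=tuple(group_names),
        reference=reference,
        logfc=pd.DataFrame(logfc, index=list(otus)),
        t=pd.DataFrame(tstats, index=list(otus)),
        p=pd.DataFrame(pvals, index=list(otus)),
        s2_posterior=s2_post,
        d0=float(d0),
        s0_2=float(s0_2),
        df_residual=d,
    )


def call_differential(
    result: DifferentialResult,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    adjust: str = "none",
) -> dict:
    """Flag OTUs with p < alpha and |log2FC| >= lfc_min per contrast.

    Reports per-contrast up/down counts and the union of differential OTUs
    across contrasts. ``adjust="bh"`` applies Benjamini–Hochberg within each
    contrast before thresholding (the default matches the trial: raw p).
    """
    per_contrast: dict[str, dict] = {}
    union: set[str] = set()
    for g in result.contrasts:
        p = result.p[g].to_numpy()
        if adjust == "bh":
            p = _bh(p)
        fc = result.logfc[g].to_numpy()
        flag = (p < alpha) & (np.abs(fc) >= lfc_min)
        up = [o for o, f, c in zip(result.otu_ids, flag, fc) if f and c > 0]
        down = [o for o, f, c in zip(result.otu_ids, flag, fc) if f and c < 0]
        per_contrast[g] = {
            "up": up,
            "down": down,
            "n_up": len(up),
            "n_down": len(down),
        }
        union |= set(up) | set(down)
    return {
        "per_contrast": per_contrast,
        "union": sorted(union),
        "n_union": len(union),
    }


def _bh(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
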