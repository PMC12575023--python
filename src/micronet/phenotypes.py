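"""Growth indices, group comparisons, polynomial contrasts and the dose optimum.

Implements the phenotype-side statistics of the feeding trial: the standard
crustacean growth formulas (WGR, SGR, FCR, HSI, CF, SR), one-way ANOVA with
Tukey letters, ANOVA reconstructed from printed mean ± SEM summaries,
Kruskal–Wallis with Dunn's pairwise test, orthogonal polynomial contrasts for
linear/quadratic dose trends, the 2^-ddCt fold change, and the quadratic
dose–response fit whose vertex is the estimated optimal supplementation level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from micronet.core import ValidationError


@dataclass(frozen=True)
class GrowthRecord:
    """Cage-level raw measurements needed for the growth indices.

    Weights in grams, body length in cm, trial duration in days.
    """

    iaw: float
    faw: float
    days: float
    feed_intake: float = float("nan")
    hep_weight: float = float("nan")
    body_weight: float = float("nan")
    body_length: float = float("nan")
    survived: int = 0
    stocked: int = 0

    def __post_init__(self) -> None:
        if self.iaw <= 0 or self.days <= 0:
            raise ValidationError("initial weight and days must be positive")
        if self.faw <= 0:
            raise ValidationError("final weight must be positive")
        if self.stocked and self.survived > self.stocked:
            raise ValidationError("survived cannot exceed stocked")


def compute_growth_indices(record: GrowthRecord) -> dict[str, float]:
    """Growth performance indices from a cage record.

    WGR (%) = (FAW - IAW) / IAW x 100
    SGR (%/day) = (ln FAW - ln IAW) / days x 100
    FCR = total feed intake / total weight gain
    HSI (%) = hepatopancreas weight / body weight x 100
    CF (g/cm^3) = body weight / body length^3 x 100
    SR (%) = survived / stocked x 100
    """
    out: dict[str, float] = {}
    out["WGR"] = (record.faw - record.iaw) / record.iaw * 100.0
    out["SGR"] = (math.log(record.faw) - math.log(record.iaw)) / record.days * 100.0
    gain = record.faw - record.iaw
    if not math.isnan(record.feed_intake):
        out["FCR"] = record.feed_intake / gain if gain != 0 else float("inf")
    if not math.isnan(record.hep_weight) and not math.isnan(record.body_weight):
        out["HSI"] = record.hep_weight / record.body_weight * 100.0
    if not math.isnan(record.body_weight) and not math.isnan(record.body_length):
        out["CF"] = record.body_weight / record.body_length**3 * 100.0
    if record.stocked:
        out["SR"] = record.survived / record.stocked * 100.0
    return out


# ---------------------------------------------------------------------------
# group comparisons


def _compact_letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    nonsig_pairs: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed best-first (largest mean gets the letter 'a'),
    matching the convention of the trial's tables.
    """
    order = sorted(groups, key=lambda g: -means[g])
    letters: list[set[str]] = []  # each letter = set of groups sharing it
    for g in order:
        placed = False
        for column in letters:
            if all(frozenset((g, h)) in nonsig_pairs for h in column):
                column.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb columns fully contained in another
    kept = [
        c
        for i, c in enumerate(letters)
        if not any(c < other for j, other in enumerate(letters) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, column in zip(alphabet, kept):
        for g in column:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    letters: dict[str, str]
    pairwise_p: dict[frozenset, float]


def one_way_anova_tukey(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD letters (a = largest group mean)."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        raise ValidationError("all observations identical; ANOVA degenerate")
    f, p = stats.f_oneway(*arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    pair_index = tk._multicomp.pairindices
    pairs = list(
        zip(tk.groupsunique[pair_index[0]], tk.groupsunique[pair_index[1]])
    )
    pairwise: dict[frozenset, float] = {}
    nonsig: set[frozenset] = set()
    for (g1, g2), pv, rej in zip(pairs, tk.pvalues, tk.reject):
        key = frozenset((str(g1), str(g2)))
        pairwise[key] = float(pv)
        if not rej:
            nonsig.add(key)
    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    letters = _compact_letter_display(groups, means, nonsig)
    return AnovaResult(f=float(f), p=float(p), letters=letters, pairwise_p=pairwise)


def anova_from_summary(
    means: Sequence[float], sems: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA reconstructed from per-group mean, SEM and n.

    Within-group variance per group is recovered as n * sem^2; the pooled
    within mean square and between mean square give F with (k-1, N-k) df.
    Lets the printed mean ± SEM tables be re-analyzed without raw data.
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if np.any(ns < 2):
        raise ValidationError("summary ANOVA needs n >= 2 per group")
    if np.any(sems == 0) and np.any(sems > 0):
        import warnings

        warnings.warn("some groups report SEM 0; F may be inflated", stacklevel=2)
    k = len(means)
    n_total = int(ns.sum())
    variances = ns * sems**2  # s^2 = n * sem^2
    ssw = float(np.sum((ns - 1) * variances))
    grand = float(np.sum(ns * means) / n_total)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        return (0.0, 1.0) if msb == 0 else (float("inf"), 0.0)
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    p: float
    pairwise_p: dict[frozenset, float]


def kruskal_dunn(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> KruskalDunnResult:
    """Tie-corrected Kruskal–Wallis with Dunn's pairwise z-tests.

    Dunn z uses the pooled-rank variance N(N+1)/12 with the tie correction
    sum(t^3 - t) / (12 (N-1)); pairwise p-values are Bonferroni-adjusted by
    default (the number of pairs), capped at 1.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalDunnResult(
            h=0.0, p=1.0, pairwise_p={frozenset((a, b)): 1.0
                                      for i, a in enumerate(groups)
                                      for b in groups[i + 1:]}
        )
    h, p = stats.kruskal(*arrays)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # mean rank per group
    idx = 0
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for g, a in zip(groups, arrays):
        mean_rank[g] = float(np.mean(ranks[idx: idx + len(a)]))
        sizes[g] = len(a)
        idx += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise: dict[frozenset, float] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_rank[g1] - mean_rank[g2]) / se
            pv = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                pv = min(1.0, pv * n_pairs)
            pairwise[frozenset((g1, g2))] = float(pv)
    return KruskalDunnResult(h=float(h), p=float(p), pairwise_p=pairwise)


# ---------------------------------------------------------------------------
# polynomial contrasts and the quadratic optimum


def orthogonal_polynomial_coefficients(
    doses: Sequence[float], degree: int
) -> np.ndarray:
    """Contrast coefficients of the given degree via Gram–Schmidt on dose powers.

    For five equally spaced levels the degree-1 and degree-2 rows are
    proportional to the tabulated integers (-2,-1,0,1,2) and (2,-1,-2,-1,2).
    """
    x = np.asarray(doses, dtype=float)
    if degree >= len(x):
        raise ValidationError("degree must be below the number of dose levels")
    basis = np.vander(x, degree + 1, increasing=True).astype(float)
    q, _ = np.linalg.qr(basis)
    coef = q[:, degree]
    coef = coef - coef.mean() if degree == 0 else coef
    # fix sign so the leading trend is positive
    if coef[-1] < 0:
        coef = -coef
    return coef


def opc_contrasts(
    values_by_group: Mapping[str, Sequence[float]],
    doses: Sequence[float],
) -> dict[str, dict[str, float]]:
    """Linear and quadratic orthogonal polynomial contrasts on group data.

    Contrast estimates are tested with t = L / sqrt(MSW * sum(c_g^2 / n_g))
    against the pooled within-group mean square.
    """
    groups = list(values_by_group)
    if len(groups) < 3:
        raise ValidationError("quadratic contrast needs at least 3 dose levels")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays])
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_w = int(ns.sum()) - len(groups)
    msw = ssw / df_w if df_w > 0 else float("nan")
    out: dict[str, dict[str, float]] = {}
    for name, degree in (("linear", 1), ("quadratic", 2)):
        c = orthogonal_polynomial_coefficients(doses, degree)
        estimate = float(np.dot(c, means))
        se = math.sqrt(msw * float(np.sum(c**2 / ns)))
        if se == 0:
            t = float("inf") if estimate != 0 else 0.0
            p = 0.0 if estimate != 0 else 1.0
        else:
            t = estimate / se
            p = float(2.0 * stats.t.sf(abs(t), df_w))
        out[name] = {"estimate": estimate, "t": float(t), "p": p}
    return out


@dataclass(frozen=True)
class DoseFit:
    """Quadratic dose–response fit y = b0 + b1 x + b2 x^2 and its vertex."""

    response: str
    b0: float
    b1: float
    b2: float
    vertex_mg_per_kg: float | None
    curvature: str  # "concave" (max), "convex" (min), or "none"
    r_squared: float
    valid_optimum: bool


def fit_quadratic_optimum(
    doses: Sequence[float],
    responses: Sequence[float],
    objective: str = "max",
    response_name: str = "",
) -> DoseFit:
    """OLS quadratic fit with vertex -b1/(2 b2) as the candidate optimum.

    The vertex is flagged invalid when the curvature contradicts the
    objective (a convex fit cannot maximize) or falls outside the dose range.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need at least 3 distinct doses for a quadratic")
    b2, b1, b0 = np.polyfit(x, y, 2)
    yhat = b0 + b1 * x + b2 * x**2
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else float("nan")
    if abs(b2) < 1e-12:
        return DoseFit(response_name, float(b0), float(b1), float(b2),
                       None, "none", r2, False)
    vertex = -b1 / (2.0 * b2)
    curvature = "concave" if b2 < 0 else "convex"
    ok = (curvature == "concave") == (objective == "max")
    ok = ok and (x.min() <= vertex <= x.max())
    return DoseFit(response_name, float(b0), float(b1), float(b2),
                   float(vertex), curvature, r2, bool(ok))


def optimal_dose_range(
    doses: Sequence[float],
    responses_by_name: Mapping[str, Sequence[float]],
    objectives: Mapping[str, str],
) -> tuple[float, float, dict[str, DoseFit]]:
    """[min, max] of valid quadratic vertices over a set of responses.

    Mirrors how the trial reports its "optimal inclusion range": each growth
    or feed-utilization response is fitted against dose and the valid vertex
    locations bracket the recommendation.
    """
    fits = {
        name: fit_quadratic_optimum(doses, vals, objectives.get(name, "max"), name)
        for name, vals in responses_by_name.items()
    }
    vertices = [f.vertex_mg_per_kg for f in fits.values() if f.valid_optimum]
    if not vertices:
        raise ValidationError("no response yielded a valid interior optimum")
    return min(vertices), max(vertices), fits


def ddct_fold_change(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the comparative Ct method, 2^-ddCt."""
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
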