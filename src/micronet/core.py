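"""Shared domain types: OTU tables, dose designs, phenotype matrices, config.

All downstream modules accept and return these containers.  Validation is
eager: a malformed table fails at construction, not three stages later.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TAXONOMIC_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class ValidationError(ValueError):
    """Raised when a domain container violates its invariants."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OtuTable:
    """Integer count matrix (samples x OTUs) with group labels and taxonomy.

    Parameters
    ----------
    sample_ids, otu_ids
        Unique identifiers for rows and columns of ``counts``.
    counts
        Non-negative integer read counts, one row per sample.
    group_of
        Treatment group label for every sample.
    taxonomy
        Optional 7-rank lineage (kingdom..species) per OTU.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray
    group_of: Mapping[str, str]
    taxonomy: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(counts != np.round(counts))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        if self.taxonomy is not None:
            for otu, lineage in self.taxonomy.items():
                if len(lineage) != len(TAXONOMIC_RANKS):
                    raise ValidationError(
                        f"taxonomy for {otu!r} has {len(lineage)} ranks, "
                        f"expected {len(TAXONOMIC_RANKS)}"
                    )

    # -- convenience views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in order of first appearance across samples."""
        out: list[str] = []
        for s in self.sample_ids:
            g = self.group_of[s]
            if g not in out:
                out.append(g)
        return tuple(out)

    def group_labels(self) -> np.ndarray:
        return np.array([self.group_of[s] for s in self.sample_ids])

    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions; rows sum to 1 (all-zero rows stay zero)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.counts / totals, 0.0)
        return rel

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return replace(
            self,
            sample_ids=tuple(keep),
            counts=self.counts[idx],
            group_of={s: self.group_of[s] for s in keep},
        )

    def subset_group(self, group: str) -> "OtuTable":
        keep = [s for s in self.sample_ids if self.group_of[s] == group]
        if not keep:
            raise ValidationError(f"no samples in group {group!r}")
        return self.subset_samples(keep)

    def subset_otus(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in keep]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy}
        return replace(
            self, otu_ids=tuple(keep), counts=self.counts[:, idx], taxonomy=tax
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )


#: The feeding trial's five-arm design: a control and four supplementation
#: levels of kelp (Laminaria japonica) extract, three cages per group.
DEFAULT_GROUPS = ("CK", "LJP0.5", "LJP1.0", "LJP1.5", "LJP2.0")
DEFAULT_DOSES = (0.0, 500.0, 1000.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class DoseDesign:
    """Ordered treatment groups with their dose (mg/kg) and replication."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    dose_of: Mapping[str, float] = field(
        default_factory=lambda: dict(zip(DEFAULT_GROUPS, DEFAULT_DOSES))
    )
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {g: 3 for g in DEFAULT_GROUPS}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) < 2:
            raise ValidationError("a dose design needs at least two groups")
        doses = [self.dose_of[g] for g in self.groups]
        if any(d < 0 for d in doses):
            raise ValidationError("doses must be non-negative")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError("doses must strictly increase across groups")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(self.dose_of[g] for g in self.groups)


@dataclass(frozen=True)
class PhenotypeTable:
    """Numeric trait matrix over sample or cage units.

    ``category_of`` assigns each variable to a family such as ``growth``,
    ``hemolymph``, ``hepatopancreas_enzyme`` or ``gene_expression``; MicroME
    phenotype modules are labelled by their dominant category.
    """

    unit_ids: tuple[str, ...]
    values: pd.DataFrame
    category_of: Mapping[str, str]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))
        _check_unique(self.unit_ids, "unit")
        if list(self.values.index) != list(self.unit_ids):
            raise ValidationError("values index must equal unit_ids")
        missing = [u for u in self.unit_ids if u not in self.group_of]
        if missing:
            raise ValidationError(f"units without group label: {missing}")
        for v in self.values.columns:
            if v not in self.category_of:
                raise ValidationError(f"variable {v!r} has no category label")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def zero_variance_variables(self) -> list[str]:
        """Variables with no spread; callers must report, never drop silently."""
        return [v for v in self.values.columns if self.values[v].nunique() <= 1]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide thresholds and reproducibility settings.

    Defaults follow the study's stated analysis choices: Spearman similarity
    cutoff 0.93, prevalence floor of two samples, raw p < 0.05 with a
    minimum log2 fold change of 1, and kME cutoff r > 0.4 for biomarkers.
    """

    similarity_threshold: float = 0.93
    prevalence_min: int = 2
    alpha: float = 0.05
    lfc_min: float = 1.0
    n_permutations: int = 999
    n_random_networks: int = 100
    rng_seed: int = 0
    kme_r_min: float = 0.4
    rarefy: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.similarity_threshold <= 1:
            raise ValidationError("similarity_threshold must be in (0, 1]")
        if self.prevalence_min < 1:
            raise ValidationError("prevalence_min must be >= 1")
        if self.n_permutations < 1 or self.n_random_networks < 1:
            raise ValidationError("permutation counts must be positive")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
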