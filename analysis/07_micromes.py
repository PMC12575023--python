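#!/usr/bin/env python
"""MicroME extraction and phenotype/dose association on the synthetic study.

Clusters the differential OTUs into modules, extracts module eigenvectors
(MicroMEs), builds phenotype feature modules, associates both with each
other and with dose (Spearman + Mantel), and lists biomarker OTUs of the
dose-linked module.
"""

import json
from pathlib import Path

import pandas as pd

from micronet.differential import (
    call_differential,
    moderated_fit,
    transform_log_relative,
)
from micronet.diversity import filter_prevalence
from micronet.io import read_otu_table
from micronet.micromes import (
    associate,
    cluster_differential_otus,
    extract_micromes,
    identify_biomarkers,
    phenotype_modules,
)
from micronet.core import PhenotypeTable

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1
DOSE_OF = {"CK": 0.0, "LJP0.5": 500.0, "LJP1.0": 1000.0,
           "LJP1.5": 1500.0, "LJP2.0": 2000.0}


def main() -> None:
    meta = pd.read_csv(BASE / "synthetic" / "metadata.csv")
    groups = dict(zip(meta["sample"], meta["group"]))
    table = read_otu_table(BASE / "synthetic" / "otu_table.tsv", groups)
    table = filter_prevalence(table, 2)
    matrix = transform_log_relative(table)

    fit = moderated_fit(matrix, table.group_of, "CK")
    union = call_differential(fit)["union"]

    assignment = cluster_differential_otus(matrix[union], target_modules=4)
    micromes = extract_micromes(matrix[union], assignment)

    # per-sample phenotype emulation on the same sample universe
    pheno_values = pd.read_csv(BASE / "synthetic" / "phenotypes.csv",
                               index_col="unit")
    pheno_values.index = list(table.sample_ids)  # six units per group, in order
    pheno = PhenotypeTable(
        tuple(pheno_values.index),
        pheno_values,
        {v: "growth" for v in pheno_values.columns},
        {s: table.group_of[s] for s in pheno_values.index},
    )
    pheno_mods = phenotype_modules(pheno, target_modules=2)
    dose = pd.Series(
        [DOSE_OF[table.group_of[s]] for s in table.sample_ids],
        index=list(table.sample_ids),
    )
    assoc = associate(micromes, pheno_mods, dose=dose, n_perm=999, seed=SEED)

    dose_r = assoc.spearman_r["dose"].drop("dose")
    top = dose_r.abs().idxmax()
    biomarkers = identify_biomarkers(
        micromes[top], matrix[list(micromes[top].members)], table.group_of,
        alpha=0.05, kme_r_min=0.4,
    )
    payload = {
        "n_differential": len(union),
        "micromes": {
            name: {
                "n_members": len(me.members),
                "variance_explained": round(me.variance_explained, 3),
            }
            for name, me in micromes.items()
        },
        "spearman_r": assoc.spearman_r.round(3).to_dict(),
        "mantel": {k: [round(r, 3), p] for k, (r, p) in assoc.mantel.items()},
        "dose_module": top,
        "biomarkers": [
            {k: v for k, v in rec.items() if k != "group_means"}
            for rec in biomarkers
        ],
    }
    (BASE / "micromes.json").write_text(json.dumps(payload, indent=2))
    print(f"{len(union)} differential OTUs -> {len(micromes)} MicroMEs")
    print(f"dose-associated module: {top} "
          f"(Spearman r vs dose = {dose_r[top]:.2f})")
    print(f"biomarkers of {top}: {[b['otu'] for b in biomarkers]}")


if __name__ == "__main__":
    main()
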