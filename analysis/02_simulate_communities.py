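#!/usr/bin/env python
"""Generate the synthetic study: OTU tables, phenotypes and ground truth.

Emulates the trial's design — five dose groups x six gut samples, sparse
OTU counts with planted differential OTUs and co-varying modules (the first
module dose-linked), plus neutral- and niche-assembled communities and
cage-level phenotypes with a quadratic dose response. Everything downstream
(03-07) runs off these files; truth is stored for recovery checks.
"""

import json
from pathlib import Path

import pandas as pd

from micronet.core import DEFAULT_GROUPS, DoseDesign
from micronet.io import write_otu_table
from micronet.simulate import (
    simulate_neutral_community,
    simulate_niche_community,
    simulate_otu_table,
    simulate_phenotypes,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_otu_table(
        n_diff=30, effect_log2=2.0, dose_linked_modules=1, seed=SEED,
        groups=DEFAULT_GROUPS,
    )
    write_otu_table(table, OUT / "otu_table.tsv")
    meta = pd.DataFrame(
        {
            "sample": table.sample_ids,
            "group": [table.group_of[s] for s in table.sample_ids],
            "cage": [f"{table.group_of[s]}_c{i % 3 + 1}"
                     for i, s in enumerate(table.sample_ids)],
        }
    )
    meta.to_csv(OUT / "metadata.csv", index=False)

    design = DoseDesign(replicates={g: 6 for g in DEFAULT_GROUPS})
    coefficients = {
        "WGR": (147.0, 0.0232, -7.69e-6),
        "SGR": (2.16, 2.6e-4, -8.6e-8),
        "FCR": (1.68, -2.9e-4, 9.4e-8),
    }
    pheno = simulate_phenotypes(design, coefficients, noise_sd=1.0, seed=SEED)
    pheno.values.to_csv(OUT / "phenotypes.csv", index_label="unit")

    neutral = simulate_neutral_community(30, 200, m=0.1, depth=1000, seed=SEED)
    write_otu_table(neutral, OUT / "neutral_community.tsv")
    niche = simulate_niche_community(30, 200, filter_strength=30.0, seed=SEED)
    write_otu_table(niche, OUT / "niche_community.tsv")

    truth_payload = {
        "seed": SEED,
        "differential_otus": truth.differential_otus,
        "module_assignment": truth.module_assignment,
        "phenotype_coefficients": coefficients,
    }
    (OUT / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    print(f"wrote synthetic study to {OUT} "
          f"({table.n_samples} samples x {table.n_otus} OTUs, "
          f"{len(truth.differential_otus)} planted differential OTUs)")


if __name__ == "__main__":
    main()
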