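"""Optional benchmark against the public glioma cohort (Zenodo record
7228791: 384 HRMAS-NMR spectra with 37 quantified metabolite
concentrations, survival labels and malignancy annotations).

This script is NOT part of the test suite: it requires the user to download
the deposit and export (or obtain) the per-sample metabolite concentration
table and labels in the package's delimited-text layout, plus a KEGG-derived
metabolite-to-pathway mapping. It reports median time-dependent c-indices of
the pathway-informed model, the width-matched dense baseline and the
classical Cox fit under the repeated 5-fold protocol, for qualitative
comparison with published results. No numeric assertion is made: the exact
published numbers depend on hyperparameter tables not reproduced here.

Usage:
    python scripts/real_data_benchmark.py \
        --features cohort_features.csv --labels cohort_labels.csv \
        --mapping kegg_mapping.tsv --out results/real_data.tsv
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd

from pathsurv.data_model import read_dataset
from pathsurv.networks import RiskModelConfig
from pathsurv.pathway_matrix import load_mapping
from pathsurv.pipeline import run_cv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", required=True)
    parser.add_argument("--labels", required=True)
    parser.add_argument("--mapping", required=True)
    parser.add_argument("--out", required=True)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    ds = read_dataset(args.features, args.labels)
    pm = load_mapping(args.mapping, ds.metabolite_names)
    print(f"cohort: {ds.n_samples} samples, {ds.n_features} metabolites, "
          f"{pm.shape[1]} pathways ({pm.edge_count} edges)")

    frames = []
    for depth in (2, 3, 4):
        pi = RiskModelConfig(depth=depth, input_dim=ds.n_features,
                             pathway_informed=True, loss="cox", seed=0)
        dn = RiskModelConfig(depth=depth, input_dim=ds.n_features,
                             pathway_informed=False, first_width=pm.shape[1],
                             loss="cox", seed=0)
        for cfg, label in ((pi, "pathway_informed"), (dn, "dense")):
            res = run_cv(ds, cfg, pm if cfg.pathway_informed else None,
                         seed=args.seed, model_id=f"{label}_d{depth}")
            med = res.summary()["median"]
            print(f"{label} depth={depth}: median c-index {med:.3f}")
            frames.append(res.to_frame())
    res = run_cv(ds, "coxph", seed=args.seed)
    print(f"coxph: median c-index {res.summary()['median']:.3f}")
    frames.append(res.to_frame())
    pd.concat(frames).to_csv(args.out, sep="\t", index=False)
    print(f"per-iteration results written to {args.out}")


if __name__ == "__main__":
    main()
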