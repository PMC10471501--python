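#!/usr/bin/env python
"""Fit the hierarchical normative model on training controls, score every
held-out subject as a deviation z map, and run the model diagnostics
(5-fold cross-validated fit metrics; LSVM site-leakage check).

Reads results/data/; writes results/normative/{model.json,z_maps.tsv,
burden.tsv,cv_metrics.tsv,site_leakage.tsv}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import hetmap as h

DATA, OUT = Path("results/data"), Path("results/normative")
SEED = 3301


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = h.CohortTable.read(DATA / "cohort.tsv")
    train, test = h.split_train_test(cohort, seed=SEED)
    fit = h.fit_normative(train, min_batch=5)
    fit.to_json(OUT / "model.json")

    dmap = h.deviation_map(fit, test)
    dmap.write(OUT / "z_maps.tsv")
    burden = h.deviation_burden(dmap.pos_extreme, dmap.neg_extreme)
    burden.insert(0, "group", dmap.groups)
    burden.to_csv(OUT / "burden.tsv", sep="\t", index_label="subject_id")

    cv = h.crossval_evaluate(train, k=5, seed=SEED + 1, min_batch=2)
    cv_all = pd.concat(cv["metrics"], keys=range(5), names=["fold", "region"])
    cv_all.to_csv(OUT / "cv_metrics.tsv", sep="\t")

    hc_test = (dmap.groups == "HC_test").to_numpy()
    leak = h.site_leakage_score(dmap.z.to_numpy()[hc_test],
                                test.subjects["site"].to_numpy()[hc_test],
                                n_repeats=25, seed=SEED + 2)
    pd.Series(leak["per_site"]).rename("balanced_accuracy").to_csv(
        OUT / "site_leakage.tsv", sep="\t", header=True)

    z_hc = dmap.z.to_numpy()[hc_test]
    case_burden = burden.loc[~hc_test & dmap.groups.str.startswith("case:").to_numpy(),
                             "n_neg"]
    print(f"trained on {train.n_subjects} controls "
          f"({len(fit.batches)} site/sex batches), scored {test.n_subjects} subjects")
    print(f"held-out control z: mean {z_hc.mean():+.3f}, SD {z_hc.std():.3f} "
          f"(standard normal expected)")
    print(f"median cross-validated EV {cv_all['EV'].median():.3f}, "
          f"median MSLL {cv_all['MSLL'].median():.3f}")
    print(f"site-leakage balanced accuracy {100 * leak['mean']:.1f}% (chance = 50%)")
    print(f"mean negative-deviation burden in cases: {case_burden.mean():.2f} regions")


if __name__ == "__main__":
    main()
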