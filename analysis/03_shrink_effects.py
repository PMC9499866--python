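#!/usr/bin/env python
"""Classify each pair's log HR as null or non-null by spike-and-slab shrinkage.

Runs the collapsed Gibbs sampler (10,000 post burn-in sweeps, Beta(1,19)
inclusion prior, slab at +-0.3) one exposure at a time over the estimates
from 02_fit_associations.py, discards pairs whose posterior null
probability is over 10%, and compares the retained set with the simulated
truth.
"""

from pathlib import Path

import pandas as pd

from genedaly import io as gio
from genedaly.shrinkage import ShrinkagePrior, shrink_estimate_set

SEED = 2021
OUT = Path("results/analysis")


def main() -> None:
    est = gio.read_estimates(OUT / "estimates.tsv")
    ok = est[est["status"] == "ok"]
    prior = ShrinkagePrior()
    res = shrink_estimate_set(ok, prior, seed=SEED)
    retained = res.table["retained"]
    print(f"shrinkage: {int(retained.sum())}/{len(res.table)} pairs retained "
          f"(null probability <= {prior.null_threshold:.0%})")

    truth = pd.read_csv(OUT / "true_log_hr.csv", index_col=0)
    is_nonnull = [
        truth.loc[e, d] != 0.0
        for e, d in zip(res.table["exposure_id"], res.table["disease_id"])
    ]
    tab = pd.crosstab(pd.Series(is_nonnull, name="truly non-null"), retained)
    print("confusion table (rows: truth, cols: retained):")
    print(tab)

    gio.write_shrinkage(res, OUT / "shrinkage.tsv")
    print(f"wrote shrinkage.tsv -> {OUT}")


if __name__ == "__main__":
    main()
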