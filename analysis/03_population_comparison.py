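#!/usr/bin/env python
"""Compare the pre and post populations produced by 02_run_pipeline.py.

Reports the resting-state contrasts (rate, ISI CV, burstiness; rank-sum),
the response-type by state contingency with adjusted standardized
residuals, and the shift of the event-locking index distribution
(Kolmogorov-Smirnov).  Tables land under results/population/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from perispike.stats import contingency_with_residuals, group_comparisons

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "results" / "pipeline"
OUT = ROOT / "results" / "population"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    units = pd.concat([pd.read_csv(PIPE / s / "units.tsv", sep="\t")
                       for s in ("pre", "post")], ignore_index=True)
    responses = pd.concat([pd.read_csv(PIPE / s / "responses.tsv", sep="\t")
                           for s in ("pre", "post")], ignore_index=True)
    locking = pd.concat([pd.read_csv(PIPE / s / "locking.tsv", sep="\t")
                         for s in ("pre", "post")], ignore_index=True)

    # resting-state contrasts
    rest_rows = []
    for metric in ("mean_rate", "isi_cv", "burstiness"):
        a = units.loc[units.state == "pre", metric].dropna()
        b = units.loc[units.state == "post", metric].dropna()
        stat, p = sps.ranksums(a, b)
        rest_rows.append(dict(metric=metric, pre_mean=a.mean(),
                              post_mean=b.mean(), ranksum_p=p))
        print(f"{metric:12s} pre {a.mean():7.2f}  post {b.mean():7.2f}  "
              f"rank-sum p={p:.3g}")
    pd.DataFrame(rest_rows).to_csv(OUT / "rest_contrasts.tsv", sep="\t",
                                   index=False, lineterminator="\n")

    # response-type prevalence by state
    detected = responses[responses.rtype != "none"]
    table = pd.crosstab(detected.rtype, detected.state)
    table.to_csv(OUT / "rtype_by_state.tsv", sep="\t", lineterminator="\n")
    if table.shape[0] >= 2 and (table.values > 0).all():
        res = contingency_with_residuals(table.values)
        print(f"\nresponse type x state: chi2={res.chi2:.2f} "
              f"dof={res.dof} p={res.p:.3g}; flagged cells "
              f"{[ (table.index[i], table.columns[j]) for i, j in res.flagged_cells ]}")

    # event-locking shift
    eli_pre = locking.loc[locking.state == "pre", "eli"].dropna()
    eli_post = locking.loc[locking.state == "post", "eli"].dropna()
    if len(eli_pre) >= 3 and len(eli_post) >= 3:
        ks, p = sps.ks_2samp(eli_pre, eli_post)
        print(f"\nELI median pre {eli_pre.median():+.2f} "
              f"post {eli_post.median():+.2f}  KS p={p:.3g}")
        pd.DataFrame([dict(pre_median=eli_pre.median(),
                           post_median=eli_post.median(), ks_p=p)]).to_csv(
            OUT / "eli_shift.tsv", sep="\t", index=False,
            lineterminator="\n")
    print(f"\npopulation tables under {OUT}")


if __name__ == "__main__":
    main()
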