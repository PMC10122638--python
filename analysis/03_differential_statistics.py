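#!/usr/bin/env python
"""Global-shift, fold-change and coupling statistics on the landscape.

Tests whether circRNA expression rises globally from the first to the
last differentiation state (normality-gated signed-rank test on paired
per-candidate log2 RPM means), classifies candidates by the strict
>2-fold rule, and regresses linear-host fold changes on circRNA fold
changes to quantify circ-host coupling.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from circscape import circquant as cq
from circscape import diffstats as ds
from circscape import io as cio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inp", type=Path, default=Path("results/landscape"))
    ap.add_argument("--out", type=Path, default=Path("results/diff"))
    ap.add_argument("--fold", type=float, default=2.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    jcs = cio.read_counts(
        args.inp / "bsj_counts.tsv",
        args.inp / "linear_counts.tsv",
        args.inp / "samples.tsv",
    )
    kept = cq.filter_high_abundance(jcs)
    summary = cq.summarize_expression(kept)
    cond_a, cond_b = summary.mean_rpm.columns[0], summary.mean_rpm.columns[-1]

    # global shift on paired per-candidate log2(RPM + 1) state means
    log_rpm = np.log2(summary.rpm + 1.0)
    cond = kept.samples["condition"]
    a = log_rpm[cond[cond == cond_a].index].mean(axis=1).to_numpy()
    b = log_rpm[cond[cond == cond_b].index].mean(axis=1).to_numpy()
    shift = ds.global_shift_test(a, b)
    print(
        f"global shift {cond_a} -> {cond_b}: {shift.test_used}, "
        f"W={shift.statistic:.0f}, p={shift.p_value:.3g} "
        f"(n={shift.n_pairs_used} pairs)"
    )

    # per-candidate fold changes and strict >2-fold classification
    rows = []
    for cid in summary.rpm.index:
        fc, l2fc = ds.fold_change(
            summary.mean_rpm.loc[cid, cond_a],
            summary.mean_rpm.loc[cid, cond_b],
            pseudocount=1.0,
        )
        rows.append(
            {
                "candidate_id": cid,
                "mean_rpm_a": summary.mean_rpm.loc[cid, cond_a],
                "mean_rpm_b": summary.mean_rpm.loc[cid, cond_b],
                "log2fc": l2fc,
                "regulation": ds.classify_regulation(l2fc, args.fold),
            }
        )
    diff = pd.DataFrame(rows).set_index("candidate_id")
    diff.to_csv(args.out / "fold_changes.tsv", sep="\t")
    counts = diff["regulation"].value_counts()
    print(
        f"of {len(diff)} high-abundance candidates: "
        f"{counts.get('up', 0)} up, {counts.get('down', 0)} down, "
        f"{counts.get('unchanged', 0)} unchanged at >{args.fold}-fold"
    )

    # MA table for plotting
    ds.ma_table(
        diff[["mean_rpm_a", "mean_rpm_b"]].mean(axis=1).to_numpy(),
        diff["log2fc"].to_numpy(),
        threshold_fold=args.fold,
        ids=diff.index,
    ).to_csv(args.out / "ma_table.tsv", sep="\t", index=False)

    # circ-host coupling: linear fold changes vs circ fold changes
    lin = (kept.donor_linear + kept.acceptor_linear) / 2.0
    lin_rpm = lin.div(kept.samples["library_size"], axis=1) * 1e6
    lin_cond = lin_rpm.T.groupby(cond).mean().T
    lin_l2fc = np.log2((lin_cond[cond_b] + 1.0) / (lin_cond[cond_a] + 1.0))
    coupling = ds.coupling_regression(diff["log2fc"].to_numpy(), lin_l2fc.to_numpy())
    print(
        f"circ-host coupling: slope={coupling.slope:.3f}, "
        f"R^2={coupling.r_squared:.3f}, F={coupling.f_statistic:.1f}, "
        f"p={coupling.p_value:.3g}"
    )
    (args.out / "stats.json").write_text(
        json.dumps(
            {
                "contrast": [cond_a, cond_b],
                "global_shift": {
                    "test_used": shift.test_used,
                    "statistic": shift.statistic,
                    "p_value": shift.p_value,
                    "n_pairs_used": shift.n_pairs_used,
                },
                "regulation_counts": {k: int(v) for k, v in counts.items()},
                "coupling": {
                    "slope": coupling.slope,
                    "r_squared": coupling.r_squared,
                    "f_statistic": coupling.f_statistic,
                    "p_value": coupling.p_value,
                    "n": coupling.n,
                },
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
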