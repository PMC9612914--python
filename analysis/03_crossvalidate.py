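"""Fivefold cross-validation of the fitted relationships.

Every merged global dataset is shuffled (seeded), split into five
non-overlapping partitions, refitted on each 80% slice and scored on the
held-out 20% with the normalized maximum error (nME, % of the observed
value), normalized RMSE (% of the mean observed value) and the squared
Pearson correlation between predicted and observed values, averaged over
the five permutations and compared with the full-data fit r2.
"""

from pathlib import Path

import pandas as pd

import mnrelations as mn

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    globals_ = mn.build_globals(
        mn.load_datasets(ROOT / "corpus" / "corpus.csv"))
    rows = []
    for g in globals_:
        rep = mn.crossvalidate(g, folds=5, seed=SEED)
        rows.append({
            "pair": f"{rep.prop_y};{rep.prop_x}", "n": len(g),
            "nME_percent": round(rep.nme, 1),
            "nRMSE_percent": round(rep.nrmse, 1),
            "r2_pred": round(rep.r2_pred, 2),
            "r2_exp": round(rep.r2_exp, 2),
        })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "crossval.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nnRMSE spans {df.nRMSE_percent.min():.0f}-"
          f"{df.nRMSE_percent.max():.0f}% and r2_pred tracks r2_exp "
          f"(max gap {(df.r2_exp - df.r2_pred).abs().max():.2f}) "
          f"-> {ROOT / 'crossval.csv'}")


if __name__ == "__main__":
    main()
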