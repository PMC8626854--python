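"""Summary analyses over search records and observer tables.

Computes the accuracy-vs-human-likeness correlation per depth with its
quadratic trend and zero crossing, the depth composition of the most
human-like decile, and leave-one-out observer correlations on the
diagnostic set; writes tidy CSV report tables and a depth-trend figure.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from glossbench import analysis_metrics as am
from glossbench import observer_sim as osim
from glossbench.pipeline import run_diagnostic_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--records", type=str, default="results/search_records.csv")
    ap.add_argument("--out-dir", type=str, default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = pd.read_csv(args.records)
    trend = am.depth_trend(records)
    trend.per_depth_rho.rename("rho").to_csv(out / "depth_trend.csv")
    print("accuracy-vs-likeness correlation per depth:")
    print(trend.per_depth_rho.round(3).to_string())
    if trend.zero_crossing is not None:
        print(f"quadratic trend crosses zero near depth {trend.zero_crossing:.1f}")
    else:
        print("quadratic trend has no zero crossing in the observed depth range")

    top = am.top_decile_composition(records)
    top.to_csv(out / "top_decile_composition.csv")
    print("depth composition of the most human-like decile:")
    print(top.round(2).to_string())

    pipe = run_diagnostic_pipeline(seed=args.seed)
    raters = osim.ObserverPopulation().draw(64, seed=args.seed + 5)
    ratings = osim.respond_table(
        raters, pipe.evidence.loc[pipe.diagnostic["image_id"]], task="rating5", seed=args.seed + 6
    )
    loo = am.loo_human_correlations(ratings)
    loo.to_csv(out / "loo_observer_correlations.csv")
    print(f"leave-one-out observer correlation: mean {loo.mean():.2f} (range {loo.min():.2f}..{loo.max():.2f})")

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.axhline(0, color="gray", lw=0.5)
    ax.plot(trend.per_depth_rho.index, trend.per_depth_rho.values, "o-")
    ax.set_xlabel("network depth (conv layers)")
    ax.set_ylabel("corr(accuracy, human-likeness)")
    fig.tight_layout()
    fig.savefig(out / "depth_trend.png", dpi=150)
    print(f"report tables and figure written to {out}/")


if __name__ == "__main__":
    main()
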