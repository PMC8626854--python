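"""Bayesian search for human-like CNNs across depths.

For each requested depth, trains a budget of networks with TPE-sampled
architecture/training hyperparameters, scoring each by the Pearson
correlation between its diagnostic-set responses and mean simulated-human
ratings. Writes one JSON-lines trial log per depth and a combined summary
table consumed by the metrics report.
"""

import argparse
from pathlib import Path

import pandas as pd

from glossbench import cnn_zoo as cz
from glossbench import human_likeness_search as hls
from glossbench import stimulus_synth as ss
from glossbench.pipeline import diagnostic_images_and_means, run_diagnostic_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--depths", type=int, nargs="+", default=[1, 3, 5])
    ap.add_argument("--budget", type=int, default=20)
    ap.add_argument("--n-scenes", type=int, default=200)
    ap.add_argument("--sampler", choices=["tpe", "gp-ei", "random"], default="tpe")
    ap.add_argument("--out-dir", type=str, default="results")
    args = ap.parse_args()

    print("building corpus and diagnostic set ...")
    manifest = ss.build_corpus(args.n_scenes, seed=args.seed + 100, size=32)
    manifest = ss.split_corpus(manifest, set(), val_frac=0.1, seed=args.seed + 101)
    data = cz.train_data_from_split(manifest, size=32)
    pipe = run_diagnostic_pipeline(seed=args.seed)
    diag, means = diagnostic_images_and_means(pipe, size=32)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_hp = cz.TrainingHyperParams(
        learning_rate=0.01, momentum=0.9, l2=1e-4, batch_size=16, val_interval=25, patience=5, max_steps=150
    )
    frames = []
    for depth in args.depths:
        rec = hls.run_search(
            depth, args.budget, hls.SearchSpace(), sampler=args.sampler, seed=args.seed,
            data=data, diagnostic_images=diag, human_means=means, input_size=32, base_hp=base_hp,
        )
        (out / f"search_depth{depth}.jsonl").write_text(rec.to_jsonl() + "\n")
        frames.append(rec.to_frame())
        best = rec.best()
        dead = sum(t.dead for t in rec.trials)
        print(f"depth {depth}: best human-likeness r = {best.objective:.3f} "
              f"(val acc {best.val_accuracy:.2f}); {dead}/{len(rec.trials)} trials dead")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "search_records.csv", index=False)
    print(f"trial log written to {out / 'search_records.csv'}")


if __name__ == "__main__":
    main()
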