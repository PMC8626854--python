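"""Evaluate the two hand-engineered baselines by repeated twofold CV.

Max-margin classification on eight pixel summary statistics, and logistic
regression on PCA-reduced wavelet texture statistics, both with
scene-level twofold cross-validation repeated 10 times so each image gets
10 held-out predictions. Writes per-image prediction tables and prints
cross-validated accuracies.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glossbench import cnn_zoo as cz
from glossbench import linear_baselines as lb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--manifest", type=str, default="results/corpus/manifest.csv")
    ap.add_argument("--size", type=int, default=64)
    ap.add_argument("--repeats", type=int, default=10)
    ap.add_argument("--out-dir", type=str, default="results")
    args = ap.parse_args()

    manifest = pd.read_csv(args.manifest)
    X, y, ids = cz.images_from_manifest(manifest, size=args.size)
    scene_ids = manifest["scene_id"].to_numpy()
    imgs = [x.transpose(1, 2, 0).astype(np.float64) for x in X]

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pix = np.array([lb.pixel_stats(im) for im in imgs])
    pix_table = lb.twofold_cv(pix, y, scene_ids, model="max-margin", n_repeats=args.repeats, seed=args.seed)
    pix_acc = lb.cv_accuracy(pix_table, y)
    pix_table.assign(image_id=lambda t: ids[t["image_index"]]).to_csv(out / "pixel_stat_predictions.csv", index=False)

    cfg = lb.TextureConfig()
    tex = np.array([lb.texture_stats(im, cfg) for im in imgs])
    tex_table = lb.twofold_cv(
        tex, y, scene_ids, model="logistic", n_repeats=args.repeats, seed=args.seed, pca_threshold=0.99
    )
    tex_acc = lb.cv_accuracy(tex_table, y)
    tex_table.assign(image_id=lambda t: ids[t["image_index"]]).to_csv(out / "texture_stat_predictions.csv", index=False)

    print(f"{len(ids)} images; {args.repeats} CV repeats; texture vector length {cfg.vector_length()}")
    print(f"pixel-statistic max-margin accuracy:   {pix_acc:.3f}")
    print(f"texture-statistic logistic accuracy:   {tex_acc:.3f}")


if __name__ == "__main__":
    main()
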