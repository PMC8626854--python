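"""Derive the DCGAN family and run a tiny adversarial training demo.

Builds the five generator/discriminator pairs (start resolutions 4..64,
all reaching the full image size with a 100-dim latent), writes their
shape schedules, trains one small instance per material class for a few
steps at reduced resolution, and emits the 900-row triangular-rating
experiment manifest.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from glossbench import cnn_zoo as cz
from glossbench import gan_zoo as gz
from glossbench import stimulus_synth as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--steps", type=int, default=30)
    ap.add_argument("--train-size", type=int, default=16)
    ap.add_argument("--out-dir", type=str, default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = {}
    for depth in range(1, 6):
        spec = gz.build_dcgan(depth)
        specs[depth] = {
            "start_resolution": spec.start_resolution,
            "generator_resolutions": spec.generator_resolutions(),
            "discriminator_resolutions": spec.discriminator_resolutions(),
            "generator_filters": spec.generator_filters(),
            "discriminator_filters": spec.discriminator_filters(),
            "latent_dim": spec.latent_dim,
        }
        print(f"depth {depth}: start {spec.start_resolution:>2}x{spec.start_resolution:<2} -> "
              f"{spec.generator_resolutions()[-1]}x{spec.generator_resolutions()[-1]}, latent {spec.latent_dim}")
    (out / "dcgan_family.json").write_text(json.dumps(specs, indent=2) + "\n")

    manifest = ss.build_corpus(24, seed=args.seed, size=args.train_size)
    X, y, _ = cz.images_from_manifest(manifest, size=args.train_size)
    tiny = gz.build_dcgan(2, base_filters=4, image_size=args.train_size)
    for material, label in (("high", 1.0), ("low", 0.0)):
        imgs = np.clip(X[y == label], 0, 1)
        res = gz.train_dcgan(tiny, imgs, steps=args.steps, seed=args.seed)
        sample_var = float(gz.sample_images(res.generator, 8, seed=args.seed + 3).var())
        print(f"{material}-gloss instance: {args.steps} steps, final D loss {res.d_losses[-1]:.2f}, "
              f"G loss {res.g_losses[-1]:.2f}, sample variance {sample_var:.4f}"
              + (" [mode collapse]" if res.collapsed else ""))

    exp = gz.experiment_manifest()
    exp.to_csv(out / "dcgan_experiment_manifest.csv", index=False)
    print(f"triangular-rating experiment manifest: {len(exp)} stimuli "
          f"({(exp['source'] == 'dcgan').sum()} generated + {(exp['source'] == 'render').sum()} renderings)")


if __name__ == "__main__":
    main()
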