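"""Build a desk-scale stimulus corpus and report its bookkeeping.

Generates a coverage-filtered corpus of procedural scenes, composes the
high-gloss (w=0.98) and low-gloss (w=0.02) image of every scene, carves a
balanced 10% validation split, and writes the manifest. Pass --export-png
to also write gamma-encoded renderings and one example component stack.
"""

import argparse
from pathlib import Path

from glossbench import stimulus_synth as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-scenes", type=int, default=300)
    ap.add_argument("--size", type=int, default=64)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=str, default="results/corpus")
    ap.add_argument("--export-png", action="store_true")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = ss.build_corpus(args.n_scenes, seed=args.seed, size=args.size, out_dir=out if args.export_png else None)
    manifest = ss.split_corpus(manifest, set(), val_frac=0.1, seed=args.seed + 1)
    manifest.to_csv(out / "manifest.csv", index=False)
    if args.export_png:
        ss.save_components(ss.generate_scene_components(int(manifest["seed"].iloc[0]), size=args.size), out / "components")

    print(f"corpus: {len(manifest)} images from {args.n_scenes} scenes at {args.size} px")
    print(manifest.groupby(["split", "material"]).size().to_string())
    print(f"manifest written to {out / 'manifest.csv'}")


if __name__ == "__main__":
    main()
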