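#!/usr/bin/env python
"""Generate one synthetic study per scenario preset.

Writes exposure/outcome summary-statistic tables, the LD panel and the truth
sidecar for each preset under scratch/studies/<preset>/ (inputs for
02_run_atlas.py), and prints what was planted in each scenario.
"""

import argparse
import json
from pathlib import Path

from mratlas.simulate import PRESET_NAMES, preset_config, simulate_study

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "studies")
    args = parser.parse_args()

    for i, preset in enumerate(PRESET_NAMES):
        study = simulate_study(preset_config(preset, seed=args.seed + i))
        paths = study.write(args.outdir / preset)
        truth = study.truth
        print(f"[{preset}] -> {paths['exposure'].parent}")
        print(f"  true log-OR per SD: {truth['true_log_or']:+.4f}  "
              f"causal SNPs: {len(truth['causal_ids'])}  "
              f"pleiotropic: {len(truth['pleiotropic_ids'])}  "
              f"planted outliers: {truth['outlier_ids'] or 'none'}")
        flips = {c: len(v) for c, v in truth["flipped_ids"].items()}
        print(f"  palindromes: {len(truth['palindromic_ids'])}  coding flips: {flips}")
    manifest = {p: str(args.outdir / p) for p in PRESET_NAMES}
    (args.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


if __name__ == "__main__":
    main()
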