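#!/usr/bin/env python
"""Integration run on user-supplied IDX datasets (NOT a desk-scale check).

This script needs real image data (e.g. the MNIST or Fashion-MNIST IDX
files) in ``--data-dir``; nothing is downloaded.  It trains the
class-incremental five-task protocol at full scale and reports whether the
qualitative ordering of methods holds:

    sequential  <  SRC        (sleep recovers forgotten tasks)
    rehearsal  <=  rehearsal + SRC

Expected files under --data-dir (standard IDX names, uncompressed):
    train-images-idx3-ubyte  train-labels-idx1-ubyte
    t10k-images-idx3-ubyte   t10k-labels-idx1-ubyte

Example:
    python scripts/integration_real_data.py --data-dir ~/mnist --seed 0 \
        --out results/integration --epochs 10

Sleep hyperparameters are grid-searched on training data before each sleep
phase (there are no universal per-dataset values); expect a multi-hour run at full MNIST scale on one CPU.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from sleepreplay import (RehearsalConfig, SleepConfig, TrainingConfig,
                         build_task_stream, read_idx_dataset,
                         run_rehearsal_protocol, run_sequential,
                         run_src_protocol)

MNIST_GRID = {
    "thresholds": ((2.0, 1.0, 0.5), (3.0, 1.0, 0.5), (2.0, 0.5, 0.5),
                   (4.0, 2.0, 1.0)),
    ("inc", "dec"): ((0.0002, 0.0001), (0.001, 0.0005)),
}


def final_overall(table) -> float:
    return float(table[table["task_id"] == "overall"]["accuracy"].iloc[-1])


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--data-dir", required=True, type=Path,
                    help="directory with the four uncompressed IDX files")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/integration"))
    ap.add_argument("--epochs", type=int, default=10)
    ap.add_argument("--subsample", type=int, default=0,
                    help="optional cap on training images per class (0 = all)")
    ap.add_argument("--rehearsal-fraction", type=float, default=0.0075)
    args = ap.parse_args()

    train = read_idx_dataset(args.data_dir / "train-images-idx3-ubyte",
                             args.data_dir / "train-labels-idx1-ubyte")
    test = read_idx_dataset(args.data_dir / "t10k-images-idx3-ubyte",
                            args.data_dir / "t10k-labels-idx1-ubyte")
    if args.subsample:
        x, y = train
        keep = np.concatenate([
            np.flatnonzero(y == c)[:args.subsample] for c in np.unique(y)])
        train = (x[keep], y[keep])

    stream = build_task_stream(train, test, classes_per_task=2,
                               order_seed=args.seed)
    sizes = [train[0].shape[1], 1200, 1200, int(train[1].max()) + 1]
    tcfg = TrainingConfig(epochs_per_task=args.epochs, seed=args.seed)
    scfg = SleepConfig(duration=10_000, seed=args.seed)

    results = {}
    results["sequential"] = final_overall(
        run_sequential(stream, sizes, tcfg, seed=args.seed).table)
    print(f"sequential: {results['sequential']:.4f}")
    results["src"] = final_overall(
        run_src_protocol(stream, sizes, tcfg, scfg, seed=args.seed,
                         tune_grid=MNIST_GRID).table)
    print(f"src: {results['src']:.4f}")
    reh = RehearsalConfig(fraction_stored=args.rehearsal_fraction)
    results["rehearsal"] = final_overall(
        run_rehearsal_protocol(stream, sizes, tcfg, reh, seed=args.seed).table)
    print(f"rehearsal: {results['rehearsal']:.4f}")
    results["rehearsal_src"] = final_overall(
        run_rehearsal_protocol(stream, sizes, tcfg, reh, sleep_config=scfg,
                               with_src=True, seed=args.seed,
                               tune_grid=MNIST_GRID).table)
    print(f"rehearsal+src: {results['rehearsal_src']:.4f}")

    results["ordering_src_gt_sequential"] = results["src"] > results["sequential"]
    results["ordering_rehearsal_src_ge_rehearsal"] = (
        results["rehearsal_src"] >= results["rehearsal"])
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "integration.json").write_text(json.dumps(results, indent=2))
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
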