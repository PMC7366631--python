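"""Stratified Kennard-Stone 70/15/15 partition of the preprocessed samples.

Runs the deterministic max-min-distance ranking within each class and
writes the sample ids of the training, validation and test sets to JSON.

Usage:  python analysis/03_partition_samples.py [--in results/spectra_preprocessed.csv]
        [--out results/split.json]
"""

import argparse
import json
from pathlib import Path

import numpy as np

import fibrospec as fs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--in", dest="inp", type=Path, default=Path("results/spectra_preprocessed.csv")
    )
    parser.add_argument(
        "--fractions", type=float, nargs=3, default=(0.70, 0.15, 0.15), metavar="F"
    )
    parser.add_argument("--out", type=Path, default=Path("results/split.json"))
    args = parser.parse_args()

    spectra = fs.read_spectra_csv(args.inp)
    split = fs.stratified_split(spectra, tuple(args.fractions))

    payload = {"fractions": list(split.fractions)}
    for name, idx in (
        ("train", split.train_idx),
        ("validation", split.val_idx),
        ("test", split.test_idx),
    ):
        payload[name] = {
            "sample_ids": spectra.sample_id[idx].tolist(),
            "n_case": int(np.sum(spectra.label[idx] == fs.CASE)),
            "n_control": int(np.sum(spectra.label[idx] == fs.CONTROL)),
        }
        print(
            f"{name:>10}: {idx.size} samples "
            f"({payload[name]['n_case']} case / {payload[name]['n_control']} control)"
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"Wrote {args.out}")


if __name__ == "__main__":
    main()
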