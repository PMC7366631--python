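"""Average replicates and run the preprocessing chain.

Reads the raw spectra CSV, averages each subject's triplicate
measurements, then applies truncation to 900-1,800 cm^-1,
Savitzky-Golay smoothing, AWLS baseline correction and vector
normalisation, and writes the preprocessed per-subject spectra.

Usage:  python analysis/02_preprocess_spectra.py [--in results/spectra_raw.csv]
        [--out results/spectra_preprocessed.csv]
"""

import argparse
from pathlib import Path

import numpy as np

import fibrospec as fs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="inp", type=Path, default=Path("results/spectra_raw.csv"))
    parser.add_argument(
        "--out", type=Path, default=Path("results/spectra_preprocessed.csv")
    )
    args = parser.parse_args()

    raw = fs.read_spectra_csv(args.inp)
    averaged = fs.average_replicates(raw)
    print(f"Averaged {raw.n_rows} replicate spectra into {averaged.n_rows} per-subject spectra.")

    config = fs.PreprocessConfig()
    pre = fs.preprocess_pipeline(averaged, config)
    norms = np.linalg.norm(pre.absorbance, axis=1)
    print(
        f"Preprocessed: axis {pre.axis[0]:.0f}-{pre.axis[-1]:.0f} cm^-1 "
        f"({pre.n_points} points), SG window {config.sg_window}/order {config.sg_order}, "
        f"AWLS order {config.awls_order}; row norms all "
        f"{'1.000000' if np.allclose(norms, 1.0) else 'NOT UNIT -- check'}"
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fs.write_spectra_csv(pre, args.out)
    print(f"Wrote {args.out}")


if __name__ == "__main__":
    main()
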