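"""Benchmark the nine selector x classifier pairings and report figures of merit.

For each of PCA / SPA / GA crossed with LDA / QDA / SVM: fit the selector
on the training set (validation where its cost requires), fit the
classifier, tune on validation, score the test set once.  Writes the
figures-of-merit table, the GA-selected wavenumbers with their marker
assignments, and the per-sample GA-LDA discriminant scores.

Usage:  python analysis/04_benchmark_models.py [--seed N]
        [--in results/spectra_preprocessed.csv] [--out-dir results]
"""

import argparse
from pathlib import Path

import pandas as pd

import fibrospec as fs
from fibrospec.classify import fit_discriminant


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--in", dest="inp", type=Path, default=Path("results/spectra_preprocessed.csv")
    )
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    spectra = fs.read_spectra_csv(args.inp)
    split = fs.stratified_split(spectra)
    report, details = fs.run_benchmark(
        spectra, split, fs.BenchmarkConfig(seed=args.seed), return_details=True
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    report_path = args.out_dir / "figures_of_merit.csv"
    report.frame.to_csv(report_path, index=False)
    show = report.frame[["method", "accuracy", "sensitivity", "specificity", "n_features"]]
    print("Figures of merit on the external test set (%):")
    print(show.round(1).to_string(index=False))

    ga = details["GA"]
    assigned = fs.assign_markers(ga.selected_wavenumbers.tolist(), tolerance=4.0)
    marker_path = args.out_dir / "ga_selected_wavenumbers.csv"
    pd.DataFrame(
        [(w, a if a else "") for w, a in assigned],
        columns=["wavenumber_cm-1", "tentative_assignment"],
    ).to_csv(marker_path, index=False)
    n_hit = sum(a is not None for _, a in assigned)
    print(
        f"\nGA selected {ga.selected_indices.size} wavenumbers; "
        f"{n_hit} lie within 4 cm^-1 of a marker-table band."
    )

    # per-sample discriminant scores of the winning GA-LDA model
    train = spectra.take(split.train_idx)
    cols = ga.selected_indices
    model = fit_discriminant(train.absorbance[:, cols], train.label)
    reduced = spectra.with_absorbance(spectra.absorbance[:, cols], axis=spectra.axis[cols])
    scores = fs.export_discriminant_scores(model, reduced, split)
    scores_path = args.out_dir / "ga_lda_discriminant_scores.csv"
    scores.to_csv(scores_path, index=False)
    print(f"Wrote {report_path}, {marker_path} and {scores_path}")


if __name__ == "__main__":
    main()
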