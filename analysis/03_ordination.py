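"""Occurrence/distribution structure: prevalence order, PCA, correspondence analysis.

Writes results/ordination_variance.csv and results/ordination_coords.csv.
The prevalence (total-mass) ranking on the fixture is antimony > selenium >
arsenic; the standardized PCA of the 35 wells × 3 analytes matrix reports
the explained-variance split of its components.
"""

from pathlib import Path

from gwtrace import load_study_fixture, prevalence_order
from gwtrace.multivariate import correspondence_analysis, matrix_from_summaries, pca
from gwtrace.pipeline import RunConfig, run_full_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summaries = list(load_study_fixture().summaries)

    order, totals, tie = prevalence_order(summaries)
    print("prevalence (total mass) order:", " > ".join(order), "(tie)" if tie else "")
    for analyte in order:
        print(f"  {analyte:>9}: total {totals[analyte]:.1f} μg/L across 35 wells")

    X, wells, cols = matrix_from_summaries(summaries)
    res = pca(X, standardize=True, row_labels=wells, col_labels=cols)
    fracs = ", ".join(f"{100 * f:.1f}%" for f in res.explained_fraction)
    print(f"\nPCA (correlation matrix) explained variance: {fracs}")

    ca = correspondence_analysis(X, row_labels=wells, col_labels=cols)
    print(f"CA total inertia: {ca.total:.4f}; "
          f"dimension split: {', '.join(f'{100 * f:.1f}%' for f in ca.explained_fraction)}")

    tables = run_full_pipeline(RunConfig(use_fixture=True))
    OUT.mkdir(exist_ok=True)
    for name in ("ordination_variance", "ordination_coords"):
        tables[name].to_csv(OUT / f"{name}.csv", index=False, float_format="%.6g")
    print(f"\nwrote ordination tables under {OUT}")


if __name__ == "__main__":
    main()
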