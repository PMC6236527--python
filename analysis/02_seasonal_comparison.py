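"""Wet-vs-dry seasonal comparison: paired t tests, Pearson correlation, ANOVA.

Writes results/seasonal_tests.csv. Expected picture on the fixture: antimony
and selenium are markedly higher in the dry season (low precipitation
concentrates the groundwater); arsenic — detected in a handful of dry-season
wells only — shows no significant seasonal shift.
"""

from pathlib import Path

import pandas as pd

from gwtrace import ANALYTES, anova_oneway, load_study_fixture, paired_seasonal_ttest
from gwtrace.summary import seasonal_pairs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summaries = list(load_study_fixture().summaries)

    rows = []
    for analyte in ANALYTES:
        res = paired_seasonal_ttest(summaries, analyte)
        rows.append(
            {
                "analyte": analyte,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "significant": res.significant,
                "pearson_r": res.pearson_r,
            }
        )
        verdict = "significant" if res.significant else "not significant"
        print(
            f"{analyte:>9}: dry−wet paired t = {res.statistic:6.2f} (df={res.df}), "
            f"p = {res.p_value:.2e} → {verdict}; wet/dry Pearson r = {res.pearson_r:.4f}"
        )

    # one-way ANOVA of overall well means across land-use areas
    print("\nacross-area ANOVA of per-well overall means:")
    for analyte in ANALYTES:
        groups: dict[str, list[float]] = {}
        for s in summaries:
            if s.analyte == analyte and s.scope == "overall":
                groups.setdefault(s.area, []).append(s.mean)
        f, df1, df2, p, *_ = anova_oneway(groups)
        print(f"  {analyte:>9}: F({df1},{df2}) = {f:.2f}, p = {p:.3f}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "seasonal_tests.csv", index=False, float_format="%.6g")
    print(f"\nwrote {OUT / 'seasonal_tests.csv'}")


if __name__ == "__main__":
    main()
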