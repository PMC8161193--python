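#!/usr/bin/env python
"""Cohort statistics on the processed table.

Reads results/cohort.csv (from 02_process_cohort.py), computes the full
battery — Shapiro-Wilk-gated reference limits, Mann-Whitney sex
comparisons, Kruskal-Wallis across age bands, Spearman correlations with
age, ANCOVA with a sex:age interaction, and the normative models
%FF ~ age and ADC ~ sex + age — and writes results/statistics.json plus a
readable summary table (results/summary_tables.md) and a by-band box plot
figure (results/params_by_age_group.png).
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import marrowmap as mm
import marrowmap.cohortstats as cs

ROOT = Path(__file__).resolve().parents[1]

LABELS = {"median_ff": "%FF (%)", "median_nsi_b50": "nSI$_{b50}$",
          "median_nsi_b900": "nSI$_{b900}$", "median_adc": "ADC (um$^2$/s)"}


def summary_tables(table, bundle):
    lines = ["# Cohort summary", "",
             f"n = {bundle['n']} subjects with successful segmentation", "",
             "## Reference limits", "",
             "| parameter | mean (SD) | limits | method |",
             "|---|---|---|---|"]
    for p, rl in bundle["reference_limits"].items():
        lines.append(f"| {p} | {rl['mean']:.1f} ({rl['sd']:.1f}) "
                     f"| {rl['lower']:.1f} - {rl['upper']:.1f} | {rl['method']} |")
    lines += ["", "## Spearman correlation with age", "",
              "| parameter | all | men | women |", "|---|---|---|---|"]
    for p, d in bundle["age_correlation"].items():
        lines.append(f"| {p} | {d['all']['statistic']:.2f} "
                     f"| {d['M']['statistic']:.2f} | {d['F']['statistic']:.2f} |")
    ff = bundle["normative_models"]["ff_model"]["coefficients"]
    adc = bundle["normative_models"]["adc_model"]["coefficients"]
    lines += ["", "## Normative models", "",
              f"%FF = {ff['Intercept']['estimate']:.1f} "
              f"+ {ff['age']['estimate']:.3f} x Age",
              f"ADC = {adc['Intercept']['estimate']:.0f} "
              f"+ {adc['sex_code']['estimate']:.1f} x Sex "
              f"{adc['age']['estimate']:+.2f} x Age   (Sex: 0 = men, 1 = women)"]
    return "\n".join(lines) + "\n"


def box_figure(table, path):
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    bands = sorted(table.age_group.unique())
    for ax, (p, label) in zip(axes.ravel(), LABELS.items()):
        for i, sex in enumerate(("M", "F")):
            data = [table.loc[(table.sex == sex) & (table.age_group == b), p]
                    for b in bands]
            pos = [j + (i - 0.5) * 0.35 for j in range(len(bands))]
            bp = ax.boxplot(data, positions=pos, widths=0.3, patch_artist=True)
            for box in bp["boxes"]:
                box.set_facecolor("#6699cc" if sex == "M" else "#cc6677")
        ax.set_xticks(range(len(bands)), bands)
        ax.set_ylabel(label)
    fig.suptitle("Bone-marrow parameters by sex (blue = men) and age band")
    fig.tight_layout()
    fig.savefig(path, dpi=110)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort.csv")
    args = ap.parse_args()

    table = pd.read_csv(args.cohort)
    bundle = mm.cohort_statistics(table)
    out = args.cohort.parent
    (out / "statistics.json").write_text(json.dumps(bundle, indent=1))
    (out / "summary_tables.md").write_text(summary_tables(table, bundle))
    box_figure(table[table.segmentation_ok], out / "params_by_age_group.png")

    ff = bundle["normative_models"]["ff_model"]
    adc = bundle["normative_models"]["adc_model"]
    print(f"n = {bundle['n']}")
    print(f"%FF ~ age: slope {ff['coefficients']['age']['estimate']:.3f} %/yr, "
          f"adj R^2 {ff['adjusted_r2']:.2f}")
    print(f"ADC ~ sex + age: sex {adc['coefficients']['sex_code']['estimate']:+.1f}, "
          f"age {adc['coefficients']['age']['estimate']:+.2f}, "
          f"adj R^2 {adc['adjusted_r2']:.2f}")
    r = bundle["age_correlation"]["median_ff"]
    print(f"Spearman r(age, %FF): all {r['all']['statistic']:.2f} "
          f"(men {r['M']['statistic']:.2f}, women {r['F']['statistic']:.2f})")
    print(f"outputs -> {out}/statistics.json, summary_tables.md, "
          f"params_by_age_group.png")


if __name__ == "__main__":
    main()
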