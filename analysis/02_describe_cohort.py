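#!/usr/bin/env python
"""Per-sex descriptives of the simulated cohort with between-sex tests.

Reads results/cohort.csv (run 01_simulate_cohort.py first), reports each
covariate as mean +/- SD by sex with a Welch t-test p value and the
event rate with a chi-square p value, and writes
results/descriptives.csv.
"""

from pathlib import Path

from smecki import describe_cohort, read_cohort_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    table = describe_cohort(cohort)
    table.to_csv(OUT / "descriptives.csv", index=False)
    with_fmt = table.copy()
    for col in ("female_mean", "female_sd", "male_mean", "male_sd"):
        with_fmt[col] = with_fmt[col].map(lambda v: f"{v:.2f}")
    with_fmt["p_value"] = with_fmt["p_value"].map(lambda v: f"{v:.3g}")
    print(with_fmt.to_string(index=False))
    print(f"\nwrote {OUT / 'descriptives.csv'}")


if __name__ == "__main__":
    main()
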