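"""Apply the four diagnostic scores to the synthetic cohort.

Reads results/synthetic_cohort.csv (run 01 first), evaluates the
Wieneke criteria, modified Wieneke score and both reticulin-algorithm
variants on every case, and writes the per-case panel to
results/panel.csv with the class distribution printed per system.
"""

from pathlib import Path

from acnscore.cohort import read_cohort
from acnscore.scoring import panel_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "synthetic_cohort.csv")
    panel = panel_frame(cohort)
    path = RESULTS / "panel.csv"
    panel.to_csv(path, index=False)
    print(f"scored {len(cohort)} cases -> {path}")
    for column in ("wc_class", "mwc_class", "ara_class", "pra_class"):
        counts = panel[column].value_counts(dropna=False).to_dict()
        print(f"{column}: {counts}")


if __name__ == "__main__":
    main()
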