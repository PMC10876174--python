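"""Concordance between the four scoring systems.

Computes pairwise Cohen kappa (same-label pairs) and Cramér V for the
scored synthetic panel (results/panel.csv, run 02 first) and writes a
tidy table to results/agreement.csv.  The same statistics computed on
the published cross-tabulations live in the reproduction report (05).
"""

from pathlib import Path

import pandas as pd

from acnscore.agreement import (cohen_kappa, contingency, cramer_v,
                                interpret_kappa, interpret_v)

RESULTS = Path(__file__).resolve().parents[1] / "results"

PAIRS = [("pra_class", "ara_class"), ("mwc_class", "pra_class"),
         ("mwc_class", "ara_class"), ("wc_class", "ara_class"),
         ("wc_class", "pra_class"), ("wc_class", "mwc_class")]


def main() -> None:
    panel = pd.read_csv(RESULTS / "panel.csv")
    rows = []
    for col_a, col_b in PAIRS:
        a = [None if pd.isna(v) else v for v in panel[col_a]]
        b = [None if pd.isna(v) else v for v in panel[col_b]]
        table = contingency(a, b)
        v = cramer_v(table)
        row = {"pair": f"{col_a} vs {col_b}", "n": table.n,
               "dropped": table.dropped_pairs, "cramer_v": round(v, 3),
               "v_band": interpret_v(v)}
        if table.is_square():
            kappa = cohen_kappa(table)
            row.update(kappa=round(kappa.kappa, 3),
                       kappa_ci=f"{kappa.ci_low:.2f}-{kappa.ci_high:.2f}",
                       kappa_band=interpret_kappa(kappa.kappa))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "agreement.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
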