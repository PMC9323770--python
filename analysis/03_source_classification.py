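"""Classify the gas sources: Schoell fields and Bernard ratios.

All seven samples plot in the thermogenic Schoell field, but every
Bernard ratio exceeds 100 — thermogenic methane whose C2+ hydrocarbons
have been stripped after generation.  Writes results/classification.csv.
"""

import csv
from pathlib import Path

from mudgas import classify, datasets

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fields = classify.load_source_fields()
    rows = []
    for r in datasets.load_tokamachi():
        ratio = classify.bernard_ratio(r.composition)
        schoell = classify.classify_schoell(
            r.isotope_value("d13c_ch4"), r.isotope_value("dd_ch4"), fields
        )
        call = classify.classify_bernard(r.isotope_value("d13c_ch4"), ratio, fields)
        tag = " (altered)" if call.altered else ""
        print(f"  {r.id}: C1/(C2+C3) = {ratio:8.1f}; {schoell} / {call.name}{tag}")
        rows.append([r.id, ratio, schoell, call.name, call.altered])
    with open(OUT / "classification.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "bernard_ratio", "schoell", "bernard", "altered"])
        w.writerows(rows)
    print(f"wrote {OUT / 'classification.csv'}")


if __name__ == "__main__":
    main()
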