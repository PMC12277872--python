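#!/usr/bin/env python
"""Summarize the measured enzyme-inhibition activities.

Loads the packaged activity table (21 thiosemicarbazones x 4 enzymes, plus
the reference inhibitors), converts potencies to the log scale and writes
per-enzyme SAR summaries — how many compounds beat the standard, the IC50
range, and the potency ranking — to results/sar_summary.json.
"""

import json
from pathlib import Path

from thioqsar.activity import (
    load_activity_table,
    records_for_enzyme,
    sar_summary,
    to_negative_log_molar,
)

OUT = Path(__file__).resolve().parents[1] / "results"

STANDARD_FOR = {
    "AChE": "galantamine",
    "BChE": "galantamine",
    "MAO-A": "clorgyline",
    "MAO-B": "clorgyline",
}


def main() -> None:
    df = load_activity_table()
    summaries = {}
    for enzyme, std in STANDARD_FOR.items():
        s = sar_summary(df, enzyme, std)
        summaries[enzyme] = s
        print(
            f"{enzyme:6s}: {s['count_more_potent']:2d}/21 more potent than "
            f"{std} ({s['standard_ic50_nM']} nM); IC50 range "
            f"{s['ic50_min_nM']}-{s['ic50_max_nM']} nM; most potent {s['ranking'][0]}"
        )
    # log-scale potencies of the best compound per enzyme
    for enzyme in STANDARD_FOR:
        rec = records_for_enzyme(df, enzyme)
        best = rec.loc[rec.ic50_nM.idxmin()]
        p = to_negative_log_molar(best.ic50_nM)
        print(f"{enzyme:6s}: best {best.compound_id} pIC50 = {p:.2f}")
    OUT.mkdir(exist_ok=True)
    (OUT / "sar_summary.json").write_text(json.dumps(summaries, indent=1))
    print(f"wrote {OUT / 'sar_summary.json'}")


if __name__ == "__main__":
    main()
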