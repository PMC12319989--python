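"""Scalp dose table for the three study arms of the 4-pair HD montage."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS

from tdcsdose import dosimetry


def main() -> None:
    rows = []
    for label, per_pair in (("sham (1 mA total)", 0.25),
                            ("4 mA", 1.0), ("6 mA", 1.5)):
        m = dosimetry.MontageSpec(current_per_pair_ma=per_pair)
        d = dosimetry.skin_current_density(per_pair, m.gel_contact_area_cm2)
        rows.append({"arm": label, "per_pair_ma": per_pair,
                     "total_ma": dosimetry.total_current(m),
                     "density_ma_per_cm2": round(d.density_ma_per_cm2, 3),
                     "flag": d.flag})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "dosimetry.csv", index=False)
    print(df.to_string(index=False))
    print("tolerability bound: 0.5 mA/cm^2 per electrode")


if __name__ == "__main__":
    main()
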