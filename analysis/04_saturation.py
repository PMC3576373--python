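"""Substitution-saturation diagnostics.

Tabulates transition and transversion counts against K2P divergence for all
sites, first+second codon positions, and third positions, and compares
windowed slopes: transition accumulation flattening at high divergence
while transversions keep rising is the classic saturation signature.

Writes results/saturation/slopes.tsv (full point tables under scratch/; a
scatter figure under scratch/ as well).
"""

from pathlib import Path

from _data import load_dataset

import pandas as pd

from barcodeqc.saturation import (PARTITIONS, plot_saturation, saturation_frame,
                                  saturation_points, windowed_slope)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "saturation"
SCRATCH = ROOT / "scratch"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    ds, _ = load_dataset()
    rows = []
    for partition in PARTITIONS:
        frac = {"all": 1.0, "pos12": 2 / 3, "pos3": 1 / 3}[partition]
        points, omitted = saturation_points(ds, partition,
                                            min_overlap=max(1, int(300 * frac)))
        saturation_frame(points).to_csv(SCRATCH / f"saturation_{partition}.tsv",
                                        sep="\t", index=False)
        if partition == "all":
            plot_saturation(points, SCRATCH / "fig_saturation.png",
                            title="transitions/transversions vs K2P divergence")
        row = {"partition": partition, "n_pairs": len(points), "omitted": omitted}
        try:
            row["s_slope_low"] = windowed_slope(points, 0.0, 0.1, "s")
            row["s_slope_high"] = windowed_slope(points, 0.15, 0.3, "s")
            row["v_slope_high"] = windowed_slope(points, 0.15, 0.3, "v")
        except ValueError:
            pass  # a partition may lack points in a window
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "slopes.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    all_row = table[table.partition == "all"].iloc[0]
    if {"s_slope_low", "s_slope_high"} <= set(table.columns):
        print(f"\ntransition slope drops from {all_row.s_slope_low:.0f} to "
              f"{all_row.s_slope_high:.0f} counts per unit divergence at high d "
              "(saturation); transversions keep rising")


if __name__ == "__main__":
    main()
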