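"""Fit potential ammonium-oxidation rates and partition them among guilds.

Reads results/timeseries.csv (from 01_simulate.py), fits the NO2+NO3 slope
of each replicate (excluding the 0-12 h adaptation window for saline
incubations), partitions treatment-level rates into comammox (I-II),
AOB (II-III) and AOA (III), checks the treatment-IV nitrate control, and
writes the guild-level table to results/partition.csv.

Run from the repository root:  python analysis/02_partition_rates.py
"""

import argparse

import pandas as pd

from nitripartition.io import read_csv
from nitripartition.pipeline import RunConfig, run_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    parser.add_argument("--timeseries", default=None)
    args = parser.parse_args()

    run_experiment(
        RunConfig(stages=("partition",), out_dir=args.out,
                  timeseries_path=args.timeseries)
    )
    table = read_csv(f"{args.out}/partition.csv")
    with pd.option_context("display.width", 120):
        print(table.round(2).to_string(index=False))
    for _, row in table.iterrows():
        print(
            f"salinity {row['salinity']}%: comammox {row['par_cmx']:.2f} "
            f"({row['contrib_cmx_pct']:.0f}%), AOB {row['par_aob']:.2f} "
            f"({row['contrib_aob_pct']:.0f}%), AOA {row['par_aoa']:.2f} "
            f"({row['contrib_aoa_pct']:.0f}%) mg N/day/kg; "
            f"DNRA control ok: {row['dnra_control_ok']}"
        )


if __name__ == "__main__":
    main()
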