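#!/usr/bin/env python
"""Apply the two cleaning pipelines to the raw observation table.

Produces cleaned_site.csv (adults, complete records, active season, sites
with >= 15 records: the site torpor-index dataset) and
cleaned_individual.csv (additionally mass > 10 g, sites with >= 2 records:
the individual-model dataset), plus JSON cleaning reports.
"""

import argparse
import json
from pathlib import Path

from dormouse_torpor import data_model as dm


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/cleaned"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = dm.load_observations(args.data / "observations.csv")
    print(f"loaded {len(records)} records")

    for mode, cleaner in (("site", dm.clean_for_site_analysis),
                          ("individual", dm.clean_for_individual_analysis)):
        kept, report = cleaner(records)
        dm.observations_to_frame(kept).to_csv(args.out / f"cleaned_{mode}.csv", index=False)
        (args.out / f"report_{mode}.json").write_text(report.to_json())
        print(f"{mode} dataset: {report.n_input} -> {report.n_retained} "
              f"({json.dumps(report.removed)})")


if __name__ == "__main__":
    main()
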