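"""Opt-in full-scale runs of the registered study scenarios.

A full-scale quarter-domain acoustic solve (2 MHz, dx = dy = 0.152 mm,
dz = 76 um over a ~54 mm x 18 mm domain) holds ~1e7 cells and needs
>1e4 implicit steps to ring up -- hours per scenario on one CPU, with
several GB for the factorised operator.  This driver is therefore NOT
part of the default test or acceptance runs; invoke it explicitly, and
preferably start with --grid-scale > 1 (coarsened) or --column (the 1D
full-frequency layered column, which runs in under a minute and already
carries the configuration-ordering physics).

Examples:
    python analysis/04_full_scale.py --column
    python analysis/04_full_scale.py --scenario monolayer_dc15_p0433 --grid-scale 4
    python analysis/04_full_scale.py --scenario monolayer_dc15_p0433   # hours
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from sonodish.config import write_summary
from sonodish.fixtures import make_study_scenarios
from sonodish.scenarios import SCENARIO_TABLE, compare_to_experiment, run_scenario

sys.path.insert(0, str(Path(__file__).parent.parent / "scripts"))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scenario", choices=list(SCENARIO_TABLE), action="append")
    parser.add_argument("--grid-scale", type=float, default=1.0,
                        help="multiply all grid spacings (coarsen with > 1)")
    parser.add_argument("--column", action="store_true",
                        help="run the tractable 1D full-frequency columns instead")
    parser.add_argument("--thermal-coarsen", type=int, default=1)
    parser.add_argument("--out", type=Path,
                        default=Path(__file__).parent.parent / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.column:
        from acceptance import full_frequency_column

        rows = []
        for configuration in ("monolayer", "spheroid"):
            t_final, n = full_frequency_column(configuration)
            rows.append(dict(configuration=configuration, t_final_c=t_final, n=n))
            print(f"{configuration}: final cell-plane temperature {t_final:.3f} C")
        pd.DataFrame(rows).to_csv(args.out / "full_frequency_columns.csv", index=False)
        return

    labels = args.scenario or list(SCENARIO_TABLE)
    configs = make_study_scenarios()
    summaries = []
    for label in labels:
        cfg = configs[label]
        cfg.numerics.grid_scale = [args.grid_scale] * 2 + [args.grid_scale]
        cfg.numerics.thermal_xy_coarsen = args.thermal_coarsen
        print(f"running {label} at grid scale {args.grid_scale} ...", flush=True)
        summary = run_scenario(cfg)
        summaries.append(summary)
        print(f"  T_max = {summary.t_max_c:.2f} C, range "
              f"({summary.t_min_c:.2f}; {summary.t_max_c:.2f}) C")
    write_summary(summaries, args.out / "full_scale_summaries.csv")
    comparison = compare_to_experiment(summaries)
    comparison.to_csv(args.out / "full_scale_comparison.csv", index=False)
    print(comparison.to_string(index=False))


if __name__ == "__main__":
    main()
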