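"""Run the scaled desk-size variants of all registered study scenarios.

One acoustic -> Q_US -> thermal pipeline per operating point (both
culture configurations, duty cycles 15/30/55%, source pressures
0.433/0.661 MPa).  At desk scale the absolute temperature rises are
small; the informative outputs are the orderings and ratios between
operating points, which the full-size study also rests on.  Writes
results/scenarios_scaled.csv.
"""

from pathlib import Path

from sonodish.fixtures import make_scaled_scenario
from sonodish.scenarios import SCENARIO_TABLE, sweep


def main() -> None:
    configs = [make_scaled_scenario(label) for label in SCENARIO_TABLE]
    table = sweep(configs)
    table["rise_c"] = table["t_max_c"] - 25.0
    out = Path(__file__).parent.parent / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "scenarios_scaled.csv", index=False)
    print(table[["label", "t_max_c", "rise_c", "gradient_c", "cycles"]].to_string(index=False))

    by = table.set_index("label")
    r15 = by.loc["monolayer_dc15_p0433_scaled0.05", "rise_c"]
    r30 = by.loc["monolayer_dc30_p0433_scaled0.05", "rise_c"]
    rhp = by.loc["monolayer_dc15_p0661_scaled0.05", "rise_c"]
    print(f"\nDC 30/15 rise ratio:      {r30 / r15:.3f} (more ON time -> more heat)")
    print(f"0.661/0.433 rise ratio:   {rhp / r15:.3f} (heating scales as p0^2 = {(0.661/0.433)**2:.3f})")
    print(f"wrote {out / 'scenarios_scaled.csv'}")


if __name__ == "__main__":
    main()
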