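"""Validate the wave and heat solvers against closed-form references.

Four desk-scale checks, each against an independent oracle: a lossy 1D
plane wave vs exp(-alpha z); the focused source vs the Rayleigh integral;
the absorbing boundary vs a long-domain run; a point heat release vs the
free-space conduction kernel; plus the adiabatic heating-rate limit.
Writes results/solver_validation.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent.parent / "scripts"))
from acceptance import (  # noqa: E402
    adiabatic_rate_error,
    boundary_reflection,
    greens_kernel_error,
    lossy_decay_error,
    rayleigh_focus_error,
)

CHECKS = [
    ("lossy plane wave vs exp(-alpha z)", lossy_decay_error, 1.0),
    ("focused bowl vs Rayleigh integral (focal amplitude)", rayleigh_focus_error, 10.0),
    ("absorbing boundary reflection", boundary_reflection, 1.0),
    ("point release vs conduction kernel", greens_kernel_error, 2.0),
    ("adiabatic heating-rate limit", adiabatic_rate_error, 1.0),
]


def main() -> None:
    rows = []
    for name, fn, tol_pct in CHECKS:
        err_pct, n = fn()
        status = "ok" if err_pct < tol_pct else "EXCEEDS"
        rows.append(dict(check=name, error_pct=err_pct, tolerance_pct=tol_pct,
                         n=n, status=status))
        print(f"{name}: {err_pct:.3f}% (tolerance {tol_pct}%, n={n}) -> {status}")
    out = Path(__file__).parent.parent / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "solver_validation.csv", index=False)
    print(f"wrote {out / 'solver_validation.csv'}")


if __name__ == "__main__":
    main()
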