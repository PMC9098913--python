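"""Photobleach-corrected residence times from multi-interval dwell data.

Simulates single-molecule dwell observations at lapse intervals 0.125-2 s
(50 ms exposure) for slow- and fast-exchanging membrane binders, applies the
multi-interval regression, and tabulates true vs recovered unbinding rates.
"""

import csv
from pathlib import Path

from slbkit.kinetics import DwellDataset, bleach_corrected_lifetime
from slbkit.simgen import DwellSimConfig, simulate_dwell_tracks

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for k_off in (0.04, 0.05, 0.37):
        for bleach_number in (0.1, 0.2, 0.3):
            cfg = DwellSimConfig(
                k_off_true=k_off, bleach_rate=bleach_number / 0.05,
                integration_time=0.05, n_molecules_per_interval=10_000,
                seed=int(k_off * 1000) + int(bleach_number * 10))
            data = simulate_dwell_tracks(cfg)
            fit = bleach_corrected_lifetime(
                [DwellDataset(tau, d, 0.05) for tau, d in data.items()])
            rows.append({
                "k_off_true_per_s": k_off,
                "bleach_number_true": bleach_number,
                "k_off_fit_per_s": round(fit.params["k_off"], 5),
                "k_off_stderr": round(fit.stderr["k_off"], 5),
                "bleach_number_fit": round(fit.params["bleach_number"], 4),
                "lifetime_s": round(fit.params["lifetime"], 2)})
            print(f"k_off {k_off} /s, bleach number {bleach_number}: "
                  f"recovered {fit.params['k_off']:.4f} /s "
                  f"(lifetime {fit.params['lifetime']:.1f} s)")
    path = OUT / "lifetime_recovery.csv"
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]))
        w.writeheader()
        w.writerows(rows)
    print(f"table written to {path}")


if __name__ == "__main__":
    main()
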