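"""Decompose FRAP recovery into lateral diffusion and membrane exchange.

Simulates 1D recovery profiles (2% measurement noise) for a slow-exchange /
mobile binder (D = 0.14 um^2/s, k_off = 0.04 /s), a fast-exchange binder
(D = 0.01 um^2/s, k_off = 0.37 /s) and the two single-mode limits, fits the
reaction-diffusion model to each profile, and tabulates true vs fitted
parameters.
"""

import csv
from pathlib import Path

import numpy as np

from slbkit.frapfret import fit_frap
from slbkit.simgen import simulate_frap_profiles

OUT = Path(__file__).resolve().parent.parent / "results"

CASES = [
    ("slow_exchange_mobile", 0.14, 0.04, np.arange(0.0, 61.0, 2.0)),
    ("fast_exchange", 0.01, 0.37, np.arange(0.0, 16.0, 1.0)),
    ("pure_exchange", 0.0, 0.10, np.arange(0.0, 31.0, 1.0)),
    ("pure_diffusion", 0.20, 0.0, np.arange(0.0, 41.0, 2.0)),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, d, k, times in CASES:
        prof = simulate_frap_profiles(
            d_coeff=d, k_off=k, domain_length=20.0,
            bleach_window=(7.5, 12.5), bleach_depth=0.9, times=times,
            noise_sd=0.02, seed=1)
        fit = fit_frap(prof)
        rows.append({
            "case": name, "d_true_um2_s": d, "k_off_true_per_s": k,
            "d_fit_um2_s": round(fit.params["D_coeff"], 4),
            "d_stderr": round(fit.stderr["D_coeff"], 4),
            "k_off_fit_per_s": round(fit.params["k_off"], 4),
            "k_off_stderr": round(fit.stderr["k_off"], 4),
            "flag": fit.message})
        print(f"{name}: D {d} -> {fit.params['D_coeff']:.3g} um^2/s, "
              f"k_off {k} -> {fit.params['k_off']:.3g} /s"
              + (f"  [{fit.message}]" if fit.message else ""))
    path = OUT / "frap_fits.csv"
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]))
        w.writeheader()
        w.writerows(rows)
    print(f"table written to {path}")


if __name__ == "__main__":
    main()
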