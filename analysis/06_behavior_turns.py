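#!/usr/bin/env python
"""Behavioral turn sequences: threshold fitting and flip-rate recovery.

Generates bout sequences driven by hidden telegraph orientational
states at several switching rates, fits the forward/turn angle mixture
to find the classification threshold, builds the orientational signal,
and recovers each rate from the Lorentzian fit of ten-run averaged
spectra of densely sampled state signals.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from artr.activity import lorentzian_fit, power_spectrum
from artr.behavior import classify_bouts, fit_angle_mixture, orientational_signal
from artr.synth import generate_bouts, telegraph_signal

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "behavior"
RATES = (0.1, 0.3, 0.6)
SEED = 8


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    bouts, truth = generate_bouts(0.3, 1800.0, seed=SEED)
    mix = fit_angle_mixture(np.abs(bouts.dtheta), seed=SEED)
    print(
        f"Angle-mixture threshold: {mix.threshold_deg:.1f} deg "
        f"(forward sigma {mix.forward_sigma:.1f}, turn Gamma shape "
        f"{mix.gamma_shape:.2f}, scale {mix.gamma_scale:.1f})"
    )
    tern = classify_bouts(bouts, threshold_deg=mix.threshold_deg)
    sig = orientational_signal(tern, bouts)
    counts = pd.Series(tern.symbols).value_counts()
    print(f"Bout labels: {counts.to_dict()}; signal duration {sig.duration:.0f} s")

    rows = []
    for k in RATES:
        specs = []
        for rep in range(10):
            x = telegraph_signal(k, 1800.0, 0.04, seed=SEED + 100 * rep + int(1000 * k))
            f, p = power_spectrum(x, 0.04, method="periodogram")
            specs.append(p)
        fit = lorentzian_fit(f, np.mean(specs, axis=0))
        rows.append(
            {
                "true_kflip_hz": k,
                "fitted_kflip_hz": fit.kflip,
                "rel_error": abs(fit.kflip - k) / k,
                "dwell_time_s": 1.0 / fit.kflip,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "kflip_recovery.csv", index=False)
    print("\n" + df.to_string(index=False))
    print(
        "\nThe Lorentzian corner frequency tracks the hidden switching "
        "rate across the behaviorally observed range; 1/kflip is the "
        "mean time spent chaining same-direction turns."
    )


if __name__ == "__main__":
    main()
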