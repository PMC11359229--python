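"""From a concentration reduction to avoided deaths.

Log-linear concentration-response chain: RR = exp(beta * dc),
AF = 1 - exp(-beta * dc), avoided deaths = AF * daily deaths * days.
Baseline mortality here is illustrative, not real demographics.
"""

import deweather as dw

delta_c = 16.0   # ug/m3 reduction magnitude (the cohort mean)
n_days = 56      # lockdown length, 23 Jan - 18 Mar 2020

for cause, daily_deaths in [("non_accidental", 100.0),
                            ("cardiovascular", 45.0),
                            ("respiratory", 12.0)]:
    beta = dw.health.DEFAULT_BETA[cause]
    p = dw.CauseParams(cause, beta=beta, daily_deaths=daily_deaths)
    rr = dw.relative_risk(beta, delta_c)
    af = dw.attributable_fraction(beta, delta_c)
    deaths = dw.avoided_mortality(p, delta_c, n_days)
    print(f"{cause:>15}: beta={beta:.3f}  RR={rr:.3f}  AF={af:.3%}  "
          f"avoided deaths ~ {deaths:.0f}")

print("\nAF is the share of baseline deaths attributable to the pollution that")
print("the lockdown removed; multiplying by daily deaths and the 56 lockdown")
print("days gives the avoided count. beta is per ug/m3.")
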