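"""Identifiability of the metric-targeted rate calibration.

Perturbs each of the flipping and desensitization rates (delta, d, r,
d') of the leucine fixture by x0.3 and x3, then refits the perturbed
rate alone against the unperturbed scheme's summary metrics (peak, rise
time, FR10, FR500, deactivation tau_mean).  Single-rate fits recover the
truth to a few percent; a deliberately redundant two-rate fit against a
single target is flagged non-identifiable by the multi-start dispersion.

Writes results/rate_recovery.csv.
"""

from pathlib import Path

import pandas as pd

import gabakin as gk
from gabakin.ratefit import MetricTarget, ObjectiveSpec, fit_rates, summarize

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

scheme = gk.load_fixture("glig_leu")
protocol = gk.build_protocol("long_pulse", conc=0.1, pulse_s=0.6,
                             wash_pre_s=0.05, wash_post_s=0.5)
window = (0.05, 0.65)
report = summarize(scheme, [(protocol, window)], dt=2e-4)[0]
targets = [MetricTarget(m, protocol, window, getattr(report, m))
           for m in ("peak", "rt_10_90_ms", "fr10", "fr500", "tau_mean_ms")]

rows = []
for rate in ("delta", "d", "r", "dp"):
    truth = scheme.rate_values()[rate]
    for factor in (0.3, 3.0):
        perturbed = scheme.with_rates({rate: factor * truth})
        result = fit_rates(perturbed, ObjectiveSpec(
            {rate: (truth / 30.0, truth * 30.0)}, targets,
            n_starts=2, seed=11), dt=2e-4)
        rows.append({
            "rate": rate, "true_value": truth, "perturbation": factor,
            "recovered": result.rates[rate],
            "relative_error": result.rates[rate] / truth - 1.0,
            "objective": result.objective,
            "dispersion": result.dispersion,
        })

table = pd.DataFrame(rows)
table.to_csv(out_dir / "rate_recovery.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

# redundant parameterization: two free rates, one target
rates = scheme.rate_values()
redundant = fit_rates(
    scheme.with_rates({"delta": 2.0 * rates["delta"]}),
    ObjectiveSpec({"delta": (rates["delta"] / 10, rates["delta"] * 10),
                   "gamma": (rates["gamma"] / 10, rates["gamma"] * 10)},
                  [t for t in targets if t.metric == "peak"],
                  n_starts=4, seed=1),
    dt=2e-4)
print(f"\nredundant two-rate fit: dispersion {redundant.dispersion:.2f} "
      f"-> identifiable = {redundant.identifiable} (distinct rate sets "
      "reproduce the same trace, so the diagnostic must flag this).")
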