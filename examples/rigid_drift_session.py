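"""Full rigid-motion session: 10 mm cranial-caudal drift during delivery.

Reconstructs the delivered dose live from the machine stream and synced
motion, compares it with the planned dose at the virtual diode array,
and forecasts the end-of-fraction target coverage.  The deviation
between measurement and plan (sigma_P) grows with the drift while the
deviation between measurement and live calculation (sigma_C) stays at
the engine noise floor — the live reconstruction explains what the plan
cannot.
"""

import mrdose as m
from mrdose import phantoms as ph

phantom = ph.build_phantom("delta4_like")
plan = ph.make_plan(12, 7.0, 7.5, seed=3, total_mu=96.0)
model = m.calibrate_output(m.BeamModel(noise_rel_sd=0.05), plan,
                           phantom.density, phantom.masks["ctv"])
messages = ph.gen_stream(plan)
trace = ph.gen_motion("linear_drift", duration_s=messages[-1].t + 1.0,
                      amplitude_mm=10.0)
config = m.SessionConfig(mode="rigid", noise_on=True,
                         forecast_every_segments=20, seed=7)
report = m.run_session(plan, phantom, trace, model, config, messages=messages)

tab = report.deviation.table
print(f"segments reconstructed: {len(report.delivered.ledger)}")
print(f"band diodes (60-85% of max planned dose): "
      f"sigma/MAD evaluated at {len(tab)} MU points")
print("\n   MU    sigma_P [Gy]  sigma_C [Gy]")
for _, row in tab.iloc[:: len(tab) // 8].iterrows():
    print(f" {row.mu:6.1f}   {row.sigma_p:8.3f}     {row.sigma_c:8.3f}")
print(f"\nfinal sigma_P = {tab.sigma_p.iloc[-1]:.2f} Gy "
      f"({m.gy_to_percent(tab.sigma_p.iloc[-1], 7.5)}% of the 7.5 Gy fraction)"
      " -- the motion corrupts the plan's prediction")
print(f"max sigma_C  = {tab.sigma_c.max():.3f} Gy (engine noise floor "
      f"{report.noise_floor_gy:.3f} Gy) -- the live calculation tracks it")
print(f"\nplanned V95 = {report.planned_v95_pct:.1f}%  ->  "
      f"final forecast V95 = {report.forecasts[-1].v95_pct:.1f}%")
print("the forecast flags the coverage loss while the fraction still runs")
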