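"""Evoked and intrinsic currents: AHP tail, I_h sag, passive properties.

Builds analytic protocol traces and measures them back: the
afterhyperpolarization tail (peak = fast component, charge transfer = slow
component), the hyperpolarization-activated sag current of an 800 ms step,
and Rs/Rm/Cm from an ideal seal-test transient.
"""

from dopaphys import ahp_measures, ih_and_passive, simulate_step_response

tail, truth = simulate_step_response(
    "ahp", {"amplitude_pa": 662.0, "tau_ms": 16.3, "duration": 1.0}
)
r = ahp_measures(tail)
print(f"AHP: peak {r.peak_amplitude:.0f} pA, charge {r.charge_transfer:.0f} pA*ms "
      f"(analytic A*tau = {truth['charge_pa_ms']:.0f})")

ih_trace, truth = simulate_step_response("ih", {"sag_pa": 425.0, "duration": 2.0})
print(f"I_h: {ih_and_passive(ih_trace).i_h:.0f} pA (generator sag {truth['i_h_pa']:.0f})")

seal, _ = simulate_step_response(
    "seal_test",
    {"rs_mohm": 15.0, "rm_mohm": 366.0, "cm_pf": 122.0, "step_mv": 10.0,
     "duration": 0.6},
)
p = ih_and_passive(seal, step_mv=10.0)
print(f"passive: Rs {p.rs:.1f} MOhm, Rm {p.rm:.0f} MOhm, Cm {p.cm:.0f} pF "
      f"(truth 15 / 366 / 122)")

# All three measurements recover their construction-time truth: the charge
# equals A*tau, the sag fit extrapolates back to step onset, and the RC
# estimates follow the standard single-compartment formulas.
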