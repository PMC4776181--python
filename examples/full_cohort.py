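"""End-to-end synthetic cohort: generation -> analyses -> group report.

Runs the full pipeline at reduced sample sizes (for speed) and prints the
group comparison table. With the default regimes the treated group shows
higher SWB, smaller and sparser mIPSCs and a smaller GABA-evoked current,
while mean rate, I_h and AHP show no designed difference — the
disinhibition pattern.
"""

import json
import tempfile

from dopaphys import PipelineConfig, run_pipeline
from dopaphys.pipeline import default_regimes

control, treated = default_regimes()
for regime in (control, treated):
    regime.n_units_in_vivo = 12
    regime.n_muscimol = 6
    regime.n_mipsc_cells = 4
    regime.n_gaba_cells = 6
    regime.n_ahp_cells = 6
    regime.n_ih_cells = 4

config = PipelineConfig(
    seed=1, epoch_duration=60.0, slice_duration=30.0, mipsc_duration=40.0,
    pool_events_per_cell=40, regimes=(control, treated),
)

with tempfile.TemporaryDirectory() as tmp:
    out = run_pipeline(config, tmp)
    report = json.loads((out / "report.json").read_text())

print(f"{'measure':24s} {'control':>12s} {'treated':>12s}   p (MW)")
means = {(r["measure"], r["group"]): r["mean"] for r in report["summary"]}
pvals = {r["measure"]: r["p_value"] for r in report["comparisons"]}
for m in ("in_vivo_rate_hz", "swb_percent", "mipsc_amplitude_pa",
          "mipsc_frequency_hz", "gaba_peak_pa", "ih_pa", "ahp_peak_pa"):
    c = means.get((m, "control"), float("nan"))
    t = means.get((m, "eNRG1"), float("nan"))
    p = pvals.get(m, float("nan"))
    print(f"{m:24s} {c:12.2f} {t:12.2f}   {p:.3g}")
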