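"""Run the whole pipeline (simulate -> BP -> filter -> BrainAGE -> mixed
models -> report tables) from one configuration, reproducibly."""

import json
from pathlib import Path

import brainagebp as bab

cfg = bab.PipelineConfig(
    outdir="scratch/pipeline_demo",
    sim=bab.SimulationConfig(n_ma=30, n_oa=30, n_waves=3,
                             dropout_hazard=(0.0, 0.2), feature_dim=50,
                             n_latent=2),
    measures=("map",), models=("base",), seed=11)
manifest = bab.run_pipeline(cfg)

print("stage timings (s):", manifest["timings_s"])
print("brainage diagnostics:", {k: round(v, 3) for k, v in
                                manifest["brainage_diagnostics"].items()})
fits = json.loads((Path(cfg.outdir) / "fits.json").read_text())
coef = [c for c in fits[0]["coefficients"] if c["term"] == "centered_map"][0]
print(f"MAP coefficient from LOSO BrainAGE: {coef['estimate']:.4f} yr/mmHg")
# Every artifact (subjects/visits/features/estimates TSV, eligibility and
# fit JSON, demographic and coefficient tables) lands in the output
# directory; rerunning with the same config + seed regenerates the TSVs
# byte-identically, as recorded in manifest.json.
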