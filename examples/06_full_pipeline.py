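"""End-to-end pipeline: simulate, analyse, compare, report.

Runs the whole analysis on a small seeded cohort (4 vs 8 L/min) and prints
where the artifacts land plus a digest of the group contrasts. Re-running
with the same seed reproduces every output byte for byte.
"""

import ventwave as vw

scenario = vw.Scenario(groups={"F4": 4.0, "F8": 8.0}, duration=20.0,
                       n_per_group=4)
config = vw.PipelineConfig(scenario=scenario, seed=42,
                           out_dir="scratch/pipeline_demo",
                           eit_shape=(32, 32))
result = vw.run_pipeline(config)

print(f"artifacts in {result['out_dir']}/ "
      f"(config hash {result['metadata']['config_hash']})")
summary = result["summary"].set_index(["metric", "group"])
for metric in ("T_peak_pressure_s", "slope_max_insp_volume", "Flow_peak_lpm",
               "V_T_mlkg", "C_dyn_mlkg_cmH2O", "MP_tidal_J_min_kg", "VEI",
               "CoV_VD"):
    comp = result["comparisons"].get(metric)
    f4 = summary.loc[(metric, "F4"), "mean"]
    f8 = summary.loc[(metric, "F8"), "mean"]
    ptxt = f"p = {comp.p:.3g}" if comp is not None else ""
    print(f"  {metric:24s} F4 {f4:9.3f}   F8 {f8:9.3f}   {ptxt}")

print("\nMotion metrics (T_peak, Slope_max, Flow_peak) separate the flow "
      "groups; delivered V_T, compliance, power and regional distribution do "
      "not - the flow rate changes how fast the lung moves, not how much.")
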