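"""Run the whole pipeline and print the quadrant report.

Synthesize -> eye features -> band ratios -> 288-triple sync matrix ->
condition comparison -> quadrant report, all from one RunConfig, writing
the six artifacts plus a run log into ./scratch_run.
"""

from eyesync import CouplingSpec, RunConfig, SyntheticConfig, report, run_all

cfg = RunConfig(
    synthetic=SyntheticConfig(
        n_subjects=2, n_videos=8, duration_s=60.0, seed=9,
        couplings=(CouplingSpec("pupil_right", "F3", "delta", 0.95,
                                empathic=True),)),
    window_s=20.0,          # test profile; the fidelity profile uses 180 s
    split_mode="random",
    outdir="scratch_run",
    seed=9,
)

paths = run_all(cfg)
for name, path in paths.items():
    print(f"{name:16s} {path}")

print("\n--- quadrant report ---")
print(report(cfg.outdir))
# Re-running with the same config reproduces byte-identical CSVs; the
# config hash in each artifact ties outputs to their settings.
#
# Caveat for this miniature demo: with only two subjects per condition the
# +/-1 std exclusion intervals are weak, so many uncoupled triples survive
# alongside the planted pupil_right ~ F3 delta one; the significance marks
# (p < 0.01 / 0.05) separate them.  At study scale (see
# examples/05_condition_comparison.py with more subjects and 300 s
# sessions) false retention drops below 10%.
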