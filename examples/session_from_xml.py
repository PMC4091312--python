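"""A complete configuration-driven fitting session with artifacts.

Generates the synaptic voltage-clamp surrogate (target trace file +
XML configuration), shrinks the optimizer budget for a quick demo,
runs the session and lists the artifacts it writes: the best-fitting
trace, a comparison figure, an HTML report, a machine-readable result
summary, and a configuration that reproduces the run.  The same
session can be run from a shell with

    tracefit -c demo_session/uc2_synapse_vc_config.xml --generations 10
"""

from dataclasses import replace
from pathlib import Path

from tracefit import SurrogateCase, make_surrogate, run_session

workdir = Path("demo_session")
traces, config = make_surrogate(SurrogateCase("uc2_synapse_vc"), out_dir=workdir)
print(f"surrogate target: {len(traces)} {traces.kind} trace(s), "
      f"{traces[0].duration:.0f} ms at {traces.dt} ms")

config = replace(
    config, optimizer=replace(config.optimizer, pop_size=30, generations=10),
)
result = run_session(config, output_dir=workdir / "results")

print(f"best fitness: {result.best_fitness:.3e} "
      f"after {result.n_evaluations} evaluations")
for name, value in zip((p.name for p in config.parameters), result.best_params):
    print(f"  {name} = {value:.6g}")
print("artifacts:")
for f in sorted((workdir / "results").iterdir()):
    print(f"  {f}")
# report.html contains the settings, the fitted parameters and the
# per-feature error breakdown; config.xml re-runs this exact session.
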