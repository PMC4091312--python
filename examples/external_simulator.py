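"""Drive an external black-box simulator through the file contract.

Any executable can serve as a model backend: the tunable parameter
values are appended to its command line in declared order, it writes
the simulated trace(s) as a whitespace-separated text file, and the
file is read back for cost evaluation.  Here the "simulator" is a
five-line Python script that implements an RC membrane analytically.
"""

import sys
import tempfile
from pathlib import Path

import numpy as np

from tracefit import ExternalBackend, ProtocolSpec

workdir = Path(tempfile.mkdtemp(prefix="tracefit_ext_"))
out_file = workdir / "trace.txt"

# the black box: V(t) = EL + R*I*(1 - exp(-t/tau)), parameters R (MOhm), tau (ms)
sim_script = workdir / "rc_membrane.py"
sim_script.write_text(
    "import sys, numpy as np\n"
    "R, tau = float(sys.argv[1]), float(sys.argv[2])\n"
    "t = np.arange(0, 200.0001, 0.1)\n"
    "v = -70 + R * 0.1 * (1 - np.exp(-t / tau))\n"
    f"np.savetxt({str(out_file)!r}, v)\n"
)

backend = ExternalBackend(
    command=[sys.executable, str(sim_script)],
    output_path=out_file,
    parameter_names=("R", "tau"),
    kind="voltage",
)
protocol = ProtocolSpec(amplitudes=[0.1], delay=0.0, duration=200.0,
                        tstop=200.0, dt=0.1, v_init=-70.0)

traces = backend.simulate([120.0, 15.0], protocol)
v = traces[0].values
print(f"external simulator returned {traces[0].n} samples")
print(f"steady-state depolarization: {v[-1] - v[0]:.2f} mV "
      f"(expected R*I = {120.0 * 0.1:.1f} mV)")
k = int(np.searchsorted(v - v[0], (v[-1] - v[0]) * (1 - np.exp(-1))))
print(f"63% rise reached at ~{traces[0].times[k]:.1f} ms (tau = 15 ms)")
# The same backend object plugs into optimize()/run_session() exactly
# like the built-in models, so any simulator that can read argv and
# write a text file can be fitted.
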