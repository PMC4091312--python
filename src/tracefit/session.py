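"""End-to-end fitting sessions driven by an XML configuration.

The configuration file follows a one-tag-per-option schema under a
versioned ``<settings version="1">`` root.  ``read_config`` validates
strictly: missing required tags and unknown tags are reported by name,
so a typo fails at load time rather than mid-run.  ``run_session``
loads the target data, aligns sampling, builds the objective
(cost of simulated vs target traces over normalized parameters), runs
the configured optimizer and writes the result artifacts:

* the best-fitting trace(s) as a text file,
* a target-vs-best comparison figure (PNG; EPS on request),
* an HTML report with the settings, the final parameter values and
  the per-feature error breakdown,
* a machine-readable ``result.txt`` (key=value lines), and
* a configuration XML that reproduces the run.
"""

from __future__ import annotations

import html
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

from .costs import FEATURE_IDS, CostSpec, combine_features
from .optimizers import (
    ALGORITHMS,
    FitResult,
    OptimizerSettings,
    optimize,
)
from .simulators import (
    AdExpBackend,
    ExternalBackend,
    HHStepBackend,
    ParameterSpec,
    ProtocolSpec,
    SynapticVCBackend,
)
from .traces import align_sampling, read_traces, write_traces

__all__ = [
    "DataConfig",
    "BackendConfig",
    "SessionConfig",
    "read_config",
    "write_config",
    "build_backend",
    "run_session",
]

BACKEND_IDS = ("hh_step", "synaptic_vc", "adexp", "external")
CONFIG_VERSION = "1"


@dataclass
class DataConfig:
    path: str
    kind: str
    unit: str
    dt: float
    n_traces: int


@dataclass
class BackendConfig:
    id: str
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id not in BACKEND_IDS:
            raise ValueError(
                f"unknown backend {self.id!r}; valid: {', '.join(BACKEND_IDS)}"
            )


@dataclass
class SessionConfig:
    """Everything needed to reproduce one optimization run."""

    data: DataConfig
    backend: BackendConfig
    parameters: list
    protocol: ProtocolSpec
    cost: CostSpec
    optimizer: OptimizerSettings
    output_dir: str = "results"

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if len(self.optimizer.bounds) != len(self.parameters):
            raise ValueError("optimizer bounds must match the parameter list")


# ------------------------------------------------------------------
# XML round trip

def _text(parent, tag, value):
    el = ET.SubElement(parent, tag)
    el.text = str(value)
    return el


def write_config(config: SessionConfig, path) -> None:
    """Serialize a session configuration to the XML schema."""
    root = ET.Element("settings", version=CONFIG_VERSION)

    data = ET.SubElement(root, "data")
    _text(data, "path", config.data.path)
    _text(data, "kind", config.data.kind)
    _text(data, "unit", config.data.unit)
    _text(data, "dt", repr(config.data.dt))
    _text(data, "n_traces", config.data.n_traces)

    backend = ET.SubElement(root, "backend", id=config.backend.id)
    for key, val in sorted(config.backend.settings.items()):
        if isinstance(val, (list, tuple)):
            _text(backend, key, " ".join(repr(float(v)) for v in val))
        else:
            _text(backend, key, repr(val) if isinstance(val, float) else val)

    params = ET.SubElement(root, "parameters")
    for p in config.parameters:
        pe = ET.SubElement(params, "parameter")
        _text(pe, "name", p.name)
        _text(pe, "lower", repr(p.lower))
        _text(pe, "upper", repr(p.upper))
        if p.initial is not None:
            _text(pe, "initial", repr(p.initial))

    proto = ET.SubElement(root, "protocol")
    _text(proto, "mode", config.protocol.mode)
    _text(proto, "stim_kind", config.protocol.stim_kind)
    _text(proto, "amplitudes", " ".join(repr(float(a)) for a in config.protocol.amplitudes))
    _text(proto, "delay", repr(config.protocol.delay))
    _text(proto, "duration", repr(config.protocol.duration))
    _text(proto, "tstop", repr(config.protocol.tstop))
    _text(proto, "dt", repr(config.protocol.dt))
    _text(proto, "v_init", repr(config.protocol.v_init))
    _text(proto, "record", config.protocol.record)

    cost = ET.SubElement(
        root, "cost", normalize_weights=str(config.cost.normalize_weights).lower()
    )
    for fid, w in config.cost.terms:
        ET.SubElement(cost, "term", feature=fid, weight=repr(float(w)))
    _text(cost, "spike_threshold", repr(config.cost.spike_threshold))
    _text(cost, "exclusion_halfwidth", repr(config.cost.exclusion_halfwidth))
    if config.cost.stim_window is not None:
        _text(
            cost, "stim_window",
            f"{config.cost.stim_window[0]!r} {config.cost.stim_window[1]!r}",
        )
    _text(cost, "pptd_bins", config.cost.pptd_bins)

    opt = ET.SubElement(root, "optimizer")
    _text(opt, "algorithm", config.optimizer.algorithm)
    _text(opt, "seed", config.optimizer.seed)
    _text(opt, "pop_size", config.optimizer.pop_size)
    _text(opt, "generations", config.optimizer.generations)
    _text(opt, "mutation_rate", repr(config.optimizer.mutation_rate))
    _text(opt, "mutation_sigma", repr(config.optimizer.mutation_sigma))
    _text(opt, "mutation_sigma_final", repr(config.optimizer.mutation_sigma_final))
    _text(opt, "blend_alpha", repr(config.optimizer.blend_alpha))
    _text(opt, "tournament_size", config.optimizer.tournament_size)
    if config.optimizer.start is not None:
        _text(opt, "start", " ".join(repr(float(v)) for v in config.optimizer.start))

    _text(root, "output_dir", config.output_dir)

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _require(el, tag):
    child = el.find(tag)
    if child is None or child.text is None:
        raise ValueError(f"configuration is missing the <{tag}> tag under <{el.tag}>")
    return child.text.strip()


def _check_known(el, known):
    for child in el:
        if child.tag not in known:
            raise ValueError(f"unknown tag <{child.tag}> under <{el.tag}>")


def read_config(path) -> SessionConfig:
    """Parse and strictly validate a session configuration file."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    if root.tag != "settings":
        raise ValueError(f"expected <settings> root, found <{root.tag}>")
    if root.get("version") != CONFIG_VERSION:
        raise ValueError(
            f"unsupported configuration version {root.get('version')!r}"
        )
    _check_known(
        root, {"data", "backend", "parameters", "protocol", "cost",
               "optimizer", "output_dir"}
    )
    for tag in ("data", "backend", "parameters", "protocol", "cost", "optimizer"):
        if root.find(tag) is None:
            raise ValueError(f"configuration is missing the <{tag}> section")

    d = root.find("data")
    _check_known(d, {"path", "kind", "unit", "dt", "n_traces"})
    data = DataConfig(
        path=_require(d, "path"), kind=_require(d, "kind"),
        unit=_require(d, "unit"), dt=float(_require(d, "dt")),
        n_traces=int(_require(d, "n_traces")),
    )

    b = root.find("backend")
    backend_id = b.get("id")
    if backend_id not in BACKEND_IDS:
        raise ValueError(
            f"unknown backend id {backend_id!r}; valid: {', '.join(BACKEND_IDS)}"
        )
    settings = {}
    for child in b:
        text = (child.text or "").strip()
        if child.tag in ("spike_times", "command"):
            settings[child.tag] = (
                [float(x) for x in text.split()]
                if child.tag == "spike_times" else text
            )
        else:
            try:
                settings[child.tag] = float(text)
            except ValueError:
                settings[child.tag] = text
    backend = BackendConfig(id=backend_id, settings=settings)

    params = []
    pe = root.find("parameters")
    _check_known(pe, {"parameter"})
    for p in pe.findall("parameter"):
        _check_known(p, {"name", "lower", "upper", "initial"})
        initial = p.find("initial")
        params.append(
            ParameterSpec(
                name=_require(p, "name"),
                lower=float(_require(p, "lower")),
                upper=float(_require(p, "upper")),
                initial=float(initial.text) if initial is not None else None,
            )
        )
    if not params:
        raise ValueError("configuration declares no <parameter> entries")

    pr = root.find("protocol")
    _check_known(
        pr, {"mode", "stim_kind", "amplitudes", "delay", "duration", "tstop",
             "dt", "v_init", "record"}
    )
    protocol = ProtocolSpec(
        mode=_require(pr, "mode"),
        stim_kind=_require(pr, "stim_kind"),
        amplitudes=[float(x) for x in _require(pr, "amplitudes").split()],
        delay=float(_require(pr, "delay")),
        duration=float(_require(pr, "duration")),
        tstop=float(_require(pr, "tstop")),
        dt=float(_require(pr, "dt")),
        v_init=float(_require(pr, "v_init")),
        record=_require(pr, "record"),
    )

    c = root.find("cost")
    _check_known(
        c, {"term", "spike_threshold", "exclusion_halfwidth", "stim_window",
            "pptd_bins"}
    )
    terms = []
    for term in c.findall("term"):
        fid = term.get("feature")
        if fid not in FEATURE_IDS:
            raise ValueError(
                f"unknown cost feature {fid!r}; valid: {', '.join(FEATURE_IDS)}"
            )
        terms.append((fid, float(term.get("weight", "1.0"))))
    if not terms:
        raise ValueError("configuration declares no cost <term> entries")
    sw = c.find("stim_window")
    cost = CostSpec(
        terms=terms,
        spike_threshold=float(_require(c, "spike_threshold")),
        exclusion_halfwidth=float(_require(c, "exclusion_halfwidth")),
        stim_window=tuple(float(x) for x in sw.text.split()) if sw is not None else None,
        pptd_bins=int(_require(c, "pptd_bins")),
        normalize_weights=c.get("normalize_weights", "false") == "true",
    )

    o = root.find("optimizer")
    _check_known(
        o, {"algorithm", "seed", "pop_size", "generations", "mutation_rate",
            "mutation_sigma", "mutation_sigma_final", "blend_alpha",
            "tournament_size", "start"}
    )
    algorithm = _require(o, "algorithm")
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid: {', '.join(ALGORITHMS)}"
        )
    start_el = o.find("start")
    optimizer = OptimizerSettings(
        algorithm=algorithm,
        bounds=[(p.lower, p.upper) for p in params],
        seed=int(_require(o, "seed")),
        pop_size=int(_require(o, "pop_size")),
        generations=int(_require(o, "generations")),
        mutation_rate=float(_require(o, "mutation_rate")),
        mutation_sigma=float(_require(o, "mutation_sigma")),
        mutation_sigma_final=float(_require(o, "mutation_sigma_final")),
        blend_alpha=float(_require(o, "blend_alpha")),
        tournament_size=int(_require(o, "tournament_size")),
        start=[float(x) for x in start_el.text.split()] if start_el is not None else None,
    )

    out_el = root.find("output_dir")
    output_dir = out_el.text.strip() if out_el is not None and out_el.text else "results"
    return SessionConfig(
        data=data, backend=backend, parameters=params, protocol=protocol,
        cost=cost, optimizer=optimizer, output_dir=output_dir,
    )


# ------------------------------------------------------------------
# session execution

def build_backend(config: SessionConfig):
    """Instantiate the simulator backend described by a configuration."""
    s = config.backend.settings
    if config.backend.id == "hh_step":
        return HHStepBackend(
            diam_um=float(s.get("diam", 10.0)), length_um=float(s.get("L", 100.0))
        )
    if config.backend.id == "synaptic_vc":
        return SynapticVCBackend(
            spike_times=s.get("spike_times", (10.0, 110.0, 210.0, 310.0)),
            e_rev=float(s.get("e_rev", 0.0)),
            diam_um=float(s.get("diam", 10.0)),
            length_um=float(s.get("L", 100.0)),
        )
    if config.backend.id == "adexp":
        return AdExpBackend()
    # external
    if "command" not in s or "output_path" not in s:
        raise ValueError(
            "the external backend needs <command> and <output_path> settings"
        )
    return ExternalBackend(
        command=str(s["command"]).split(),
        output_path=s["output_path"],
        parameter_names=[p.name for p in config.parameters],
        kind=config.data.kind,
        unit=config.data.unit,
    )


def _load_target(config: SessionConfig):
    target = read_traces(
        config.data.path, config.data.kind, config.data.unit,
        config.data.dt, config.data.n_traces,
    )
    target, effective_dt = align_sampling(target, config.protocol.dt)
    protocol = replace(config.protocol, dt=effective_dt)
    return target, protocol


def build_objective(config: SessionConfig, user_mapping=None):
    """Return ``(objective, target, protocol, backend)`` for a config.

    The objective maps a physical parameter vector to the combined
    weighted cost of the simulated traces against the target.
    """
    target, protocol = _load_target(config)
    backend = build_backend(config)
    if user_mapping is not None:
        backend.user_mapping = user_mapping
    cost = config.cost

    def objective(x):
        sim = backend.simulate(x, protocol)
        total, _ = combine_features(cost, sim, target)
        return total

    return objective, target, protocol, backend


def _write_report(path, config, result, per_feature, weighted_total, figure_name):
    rows = "".join(
        f"<tr><td>{html.escape(p.name)}</td><td>{v:.6g}</td>"
        f"<td>[{p.lower:g}, {p.upper:g}]</td></tr>"
        for p, v in zip(config.parameters, result.best_params)
    )
    feat_rows = "".join(
        f"<tr><td>{html.escape(fid)}</td><td>{val:.6g}</td></tr>"
        for fid, val in per_feature.items()
    )
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>tracefit report</title></head>
<body>
<h1>Model fitting report</h1>
<p>Backend: <b>{config.backend.id}</b> &middot; algorithm:
<b>{config.optimizer.algorithm}</b> &middot; seed: {result.seed} &middot;
evaluations: {result.n_evaluations}</p>
<h2>Best parameters</h2>
<table border="1"><tr><th>parameter</th><th>value</th><th>bounds</th></tr>
{rows}</table>
<h2>Fitness</h2>
<p>Total (weighted) cost: <b>{result.best_fitness:.9g}</b></p>
<table border="1"><tr><th>feature</th><th>accumulated value</th></tr>
{feat_rows}</table>
<h2>Target vs best trace</h2>
<img src="{figure_name}" alt="target vs best trace" style="max-width:100%">
</body></html>
"""
    Path(path).write_text(doc)


def _write_figure(out_dir, target, best, eps=False):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(target)
    fig, axes = plt.subplots(n, 1, figsize=(9, 2.6 * n), squeeze=False, sharex=True)
    unit = "mV" if target.kind == "voltage" else "nA"
    for i, (ax, tr, sim) in enumerate(zip(axes[:, 0], target, best)):
        ax.plot(tr.times, tr.values, lw=0.8, label="target")
        ax.plot(sim.times, sim.values, lw=0.8, label="best fit")
        ax.set_ylabel(f"trace {i} ({unit})")
    axes[0, 0].legend(loc="upper right")
    axes[-1, 0].set_xlabel("time (ms)")
    fig.tight_layout()
    png = Path(out_dir) / "fit.png"
    fig.savefig(png, dpi=110)
    if eps:
        fig.savefig(Path(out_dir) / "fit.eps")
    plt.close(fig)
    return png.name


def run_session(
    config: SessionConfig,
    seed: int | None = None,
    generations: int | None = None,
    output_dir=None,
    user_mapping=None,
    eps: bool = False,
    verbose: bool = False,
) -> FitResult:
    """Run one complete fitting session and write its artifacts.

    ``seed``, ``generations`` and ``output_dir`` override the
    corresponding configuration entries (useful for scaled-down or
    repeated runs without editing the XML).
    """
    opt_settings = config.optimizer
    if seed is not None:
        opt_settings = replace(opt_settings, seed=seed)
    if generations is not None:
        opt_settings = replace(opt_settings, generations=generations)
    config = replace(config, optimizer=opt_settings)

    objective, target, protocol, backend = build_objective(config, user_mapping)
    result = optimize(objective, config.optimizer)
    if verbose:
        for g, (b, m) in enumerate(zip(result.history.best, result.history.mean)):
            print(f"generation {g}: best {b:.6g} mean {m:.6g}")

    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    best = backend.simulate(result.best_params, protocol)
    write_traces(best, out / "best_trace.txt")
    figure_name = _write_figure(out, target, best, eps=eps)
    weighted_total, per_feature = combine_features(config.cost, best, target)
    _write_report(
        out / "report.html", config, result, per_feature, weighted_total,
        figure_name,
    )
    write_config(config, out / "config.xml")

    lines = [
        f"algorithm={config.optimizer.algorithm}",
        f"seed={result.seed}",
        f"n_evaluations={result.n_evaluations}",
        f"best_fitness={result.best_fitness:.12g}",
    ]
    for p, v in zip(config.parameters, result.best_params):
        lines.append(f"param.{p.name}={v:.12g}")
    for fid, val in per_feature.items():
        lines.append(f"feature.{fid}={val:.12g}")
    (out / "result.txt").write_text("\n".join(lines) + "\n")
    return result
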