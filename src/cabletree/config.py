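"""Run configuration: schema-validated YAML/mapping -> resolved run objects.

A run is described by a nested key-value document with sections

* ``geometry``  — builder name + parameters, or an SWC path + options
* ``params``    — electrical parameter preset name and/or explicit fields
* ``solver``    — scheme, eta, dt, duration, tolerances, decimation
* ``stimulus``  — list of current injections (element or axial position)
* ``probes``    — element indices, or axial positions (m) resolved to the
                  nearest element (ties -> lower index)
* ``mechanics`` — optional strain loading + channel alteration hook
* ``output``    — output directory
* ``seed``      — governs only the random tree builder

Unknown keys anywhere are rejected, and every offending key is listed in a
single :class:`ConfigError`.  The fully-resolved configuration (defaults
expanded) is echoed into each run's JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import inspect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import mechanics, morphology, presets, solvers
from .membrane import ElectricalParams
from .morphology import NeuriteTree
from .presets import probe_near

__all__ = ["RunConfig", "ConfigError", "parse_config"]


class ConfigError(ValueError):
    """Schema violation; message lists every offending key."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


_BUILDERS = {
    "myelinated_axon": morphology.build_myelinated_axon,
    "symmetric_tree": morphology.build_symmetric_tree,
    "swc": morphology.load_swc,
}

_ALTERATIONS = {
    "identity": lambda **kw: mechanics.ChannelAlteration(),
    "scale": lambda **kw: mechanics.ChannelAlteration(**kw),
}

_SOLVER_KEYS = {f.name for f in dataclasses.fields(solvers.SolverConfig)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ElectricalParams)}
_TOP_KEYS = {"geometry", "params", "solver", "stimulus", "probes",
             "mechanics", "output", "seed"}


@dataclass
class RunConfig:
    """A fully-resolved, validated run description."""

    tree: NeuriteTree
    params: ElectricalParams
    solver: solvers.SolverConfig
    stimulus: solvers.StimulusProtocol
    probes: list[int]
    mech: mechanics.MechanicalLoading | None
    output_dir: Path
    seed: int
    resolved: dict = field(default_factory=dict)


def _builder_kwargs(fn, section: dict, skip: set[str], problems: list[str],
                    where: str) -> dict:
    sig = inspect.signature(fn)
    allowed = set(sig.parameters)
    kwargs = {}
    for k, v in section.items():
        if k in skip:
            continue
        if k not in allowed:
            problems.append(f"{where}: unknown key {k!r} (allowed: {sorted(allowed)})")
        else:
            kwargs[k] = v
    return kwargs


def parse_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a run configuration (YAML path or mapping)."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        base_dir = Path(source).parent
    else:
        raw = dict(source)
        base_dir = Path(".")
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])

    problems: list[str] = []
    for k in raw:
        if k not in _TOP_KEYS:
            problems.append(f"unknown top-level key {k!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed: must be an integer")
        seed = 0

    # geometry ---------------------------------------------------------
    tree = None
    geo = raw.get("geometry")
    if not isinstance(geo, dict):
        problems.append("geometry: section is required and must be a mapping")
    else:
        name = geo.get("builder")
        if name not in _BUILDERS:
            problems.append(f"geometry.builder: unknown builder {name!r} "
                            f"(available: {sorted(_BUILDERS)})")
        else:
            fn = _BUILDERS[name]
            kwargs = _builder_kwargs(fn, geo, {"builder"}, problems, "geometry")
            if name == "symmetric_tree":
                kwargs.setdefault("seed", seed)
            if name == "swc" and "path" in kwargs:
                p = Path(kwargs["path"])
                kwargs["path"] = p if p.is_absolute() else base_dir / p
            if name == "swc" and "include_types" in kwargs:
                kwargs["include_types"] = set(kwargs["include_types"])
            if not problems:
                try:
                    tree = fn(**kwargs)
                except (TypeError, morphology.MorphologyError, OSError) as exc:
                    problems.append(f"geometry: {exc}")

    # params -----------------------------------------------------------
    params = None
    psec = dict(raw.get("params") or {"preset": "classic_squid"})
    preset = psec.pop("preset", None)
    bad = [k for k in psec if k not in _PARAM_KEYS]
    for k in bad:
        problems.append(f"params: unknown key {k!r}")
    if not bad:
        try:
            if preset is not None:
                if preset not in presets.PARAM_PRESETS:
                    problems.append(f"params.preset: unknown preset {preset!r} "
                                    f"(available: {sorted(presets.PARAM_PRESETS)})")
                else:
                    params = presets.PARAM_PRESETS[preset]()
                    if psec:
                        params = dataclasses.replace(params, **psec)
            else:
                params = ElectricalParams(**psec)
        except (TypeError, ValueError) as exc:
            problems.append(f"params: {exc}")

    # solver -----------------------------------------------------------
    ssec = dict(raw.get("solver") or {})
    for k in ssec:
        if k not in _SOLVER_KEYS:
            problems.append(f"solver: unknown key {k!r} (allowed: {sorted(_SOLVER_KEYS)})")
    solver_cfg = None
    if not problems or all(not p.startswith("solver") for p in problems):
        try:
            solver_cfg = solvers.SolverConfig(
                **{k: v for k, v in ssec.items() if k in _SOLVER_KEYS})
        except ValueError as exc:
            problems.append(f"solver: {exc}")

    # stimulus ---------------------------------------------------------
    stim_items = []
    for j, item in enumerate(raw.get("stimulus") or []):
        if not isinstance(item, dict):
            problems.append(f"stimulus[{j}]: must be a mapping")
            continue
        it = dict(item)
        kind = it.pop("type", "pulse")
        where = None
        if "element" in it:
            where = int(it.pop("element"))
        elif "position" in it and tree is not None:
            where = probe_near(tree, float(it.pop("position")))
        else:
            problems.append(f"stimulus[{j}]: needs 'element' or 'position'")
        try:
            if kind == "pulse":
                wave = solvers.RectPulse(
                    start=float(it.pop("start", 0.0)),
                    duration=float(it.pop("duration")),
                    amplitude=float(it.pop("amplitude")))
            elif kind == "train":
                wave = solvers.PulseTrain(
                    start=float(it.pop("start", 0.0)),
                    period=float(it.pop("period")),
                    count=int(it.pop("count")),
                    pulse_duration=float(it.pop("pulse_duration")),
                    amplitude=float(it.pop("amplitude")))
            else:
                problems.append(f"stimulus[{j}].type: unknown type {kind!r}")
                wave = None
        except KeyError as exc:
            problems.append(f"stimulus[{j}]: missing key {exc}")
            wave = None
        for k in it:
            problems.append(f"stimulus[{j}]: unknown key {k!r}")
        if wave is not None and where is not None:
            stim_items.append((where, wave))

    # probes -----------------------------------------------------------
    probe_idx: list[int] = []
    for j, p in enumerate(raw.get("probes") or []):
        if isinstance(p, bool):
            problems.append(f"probes[{j}]: must be an index or a position")
        elif isinstance(p, int):
            probe_idx.append(p)
        elif isinstance(p, float):
            if tree is not None:
                probe_idx.append(probe_near(tree, p))
        elif isinstance(p, dict) and set(p) == {"position"}:
            if tree is not None:
                probe_idx.append(probe_near(tree, float(p["position"])))
        else:
            problems.append(f"probes[{j}]: must be an index or a position")

    # mechanics --------------------------------------------------------
    mech = None
    msec = raw.get("mechanics")
    if msec is not None:
        if not isinstance(msec, dict):
            problems.append("mechanics: must be a mapping")
        else:
            mk = dict(msec)
            alt_spec = mk.pop("channel_alteration", None)
            allowed = {"strain", "strain_rate", "strain_transfer"}
            for k in mk:
                if k not in allowed:
                    problems.append(f"mechanics: unknown key {k!r}")
            overlay = None
            if alt_spec is not None and tree is not None:
                a = dict(alt_spec)
                name = a.pop("type", "identity")
                elements = a.pop("elements", "all_hh")
                if name not in _ALTERATIONS:
                    problems.append(f"mechanics.channel_alteration.type: "
                                    f"unknown alteration {name!r}")
                else:
                    try:
                        alt = _ALTERATIONS[name](**a)
                        el = None if elements == "all_hh" else list(elements)
                        overlay = mechanics.apply_channel_alteration(tree, alt, el)
                    except (TypeError, ValueError) as exc:
                        problems.append(f"mechanics.channel_alteration: {exc}")
            if not problems or all(not p.startswith("mechanics") for p in problems):
                try:
                    mech = mechanics.MechanicalLoading(
                        macro_strain=float(mk.get("strain", 0.0)),
                        strain_rate=float(mk.get("strain_rate", 0.0)),
                        transfer=mk.get("strain_transfer", "identity"),
                        channel_alteration=overlay)
                except ValueError as exc:
                    problems.append(f"mechanics: {exc}")

    # output -----------------------------------------------------------
    osec = dict(raw.get("output") or {})
    out_dir = Path(osec.pop("dir", "cabletree_out"))
    for k in osec:
        problems.append(f"output: unknown key {k!r}")

    if problems:
        raise ConfigError(problems)

    stimulus = solvers.StimulusProtocol(stim_items)
    stimulus.validate(len(tree))
    for p in probe_idx:
        if not (0 <= p < len(tree)):
            raise ConfigError([f"probes: element index {p} out of range"])
    if not probe_idx:
        probe_idx = [len(tree) - 1]

    resolved = {
        "geometry": dict(raw.get("geometry") or {}),
        "params": dataclasses.asdict(params),
        "solver": dataclasses.asdict(solver_cfg),
        "stimulus": [
            {"element": i, **dataclasses.asdict(w),
             "type": "pulse" if isinstance(w, solvers.RectPulse) else "train"}
            for i, w in stimulus.items],
        "probes": list(probe_idx),
        "mechanics": None if mech is None else {
            "strain": mech.macro_strain, "strain_rate": mech.strain_rate,
            "strain_transfer": mech.transfer,
            "channel_alteration": None if not mech.channel_alteration else {
                str(k): dataclasses.asdict(v)
                for k, v in mech.channel_alteration.items()}},
        "output": {"dir": str(out_dir)},
        "seed": seed,
    }
    return RunConfig(tree=tree, params=params, solver=solver_cfg,
                     stimulus=stimulus, probes=probe_idx, mech=mech,
                     output_dir=out_dir, seed=seed, resolved=resolved)
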