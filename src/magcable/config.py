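"""Run configuration: YAML schema, explicit units, object construction.

Every dimensional entry in a config file is a string with an explicit unit
suffix ("2cm", "13uH", "200uF", "36V") or a bare number in the block's SI /
engine-native unit.  A single parsing layer converts to internal units; the
rest of the package never re-parses units.  Unknown keys are rejected with
the schema path of the violation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .coil import Coil
from .engine import SimConfig
from .membrane import MechanismSpec, default_mechanisms
from .morphology import Neuron, build_toy, load_swc
from .pulse import RLCParams

__all__ = ["ConfigError", "RunConfig", "parse_quantity"]

# multiplier to SI for each recognised suffix
_UNITS = {
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "H": 1.0, "mH": 1e-3, "uH": 1e-6, "nH": 1e-9,
    "F": 1.0, "mF": 1e-3, "uF": 1e-6, "nF": 1e-9,
    "ohm": 1.0, "mohm": 1e-3, "kohm": 1e3,
    "V": 1.0, "mV": 1e-3, "kV": 1e3,
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9,
    "deg": 1.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z]*)\s*$")


class ConfigError(ValueError):
    """A config violation; the message names the offending schema path."""


def parse_quantity(text, target_si_scale: float = 1.0, path: str = "") -> float:
    """Parse '13uH' / '2cm' / 0.02 into a float in the caller's unit.

    ``target_si_scale`` is the SI size of the caller's unit (1.0 for an SI
    target, 1e-6 if the caller works in um, ...).  Bare numbers are taken to
    be already in the caller's unit.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _QTY_RE.match(str(text))
    if not m:
        raise ConfigError(f"{path}: cannot parse quantity {text!r}")
    value, unit = m.groups()
    try:
        v = float(value)
    except ValueError as exc:
        raise ConfigError(f"{path}: bad number in {text!r}") from exc
    if not unit:
        return v
    if unit not in _UNITS:
        raise ConfigError(f"{path}: unknown unit {unit!r} in {text!r}")
    return v * _UNITS[unit] / target_si_scale


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown key")


@dataclass
class RunConfig:
    """A fully resolved run: coil, pulse, neuron, mechanisms, sim, protocol."""

    coil: Coil
    pulse: RLCParams
    neuron: Neuron
    mechanisms: dict[str, MechanismSpec]
    sim: SimConfig
    protocol: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, text_or_path) -> "RunConfig":
        text = str(text_or_path)
        if "\n" not in text and text.endswith((".yml", ".yaml", ".json")):
            with open(text) as fh:
                text = fh.read()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(
            data,
            {"coil", "pulse", "morphology", "mechanisms", "sim", "protocol"},
            "config",
        )

        cblock = data.get("coil", {})
        _check_keys(
            cblock, {"radius", "turns", "standoff", "center_offset", "permeability"},
            "coil",
        )
        try:
            coil = Coil(
                radius=parse_quantity(cblock.get("radius", "2cm"), 1.0, "coil.radius"),
                turns=int(cblock.get("turns", 30)),
                standoff=parse_quantity(
                    cblock.get("standoff", "1cm"), 1.0, "coil.standoff"
                ),
                center_offset=tuple(
                    parse_quantity(v, 1.0, "coil.center_offset")
                    for v in cblock.get("center_offset", (0.0, 0.0))
                ),
                permeability=float(cblock.get("permeability", 4e-7 * 3.141592653589793)),
            )
        except ValueError as exc:
            raise ConfigError(f"coil: {exc}") from exc

        pblock = data.get("pulse", {})
        _check_keys(pblock, {"V0", "R", "L", "C"}, "pulse")
        try:
            pulse = RLCParams(
                V0=parse_quantity(pblock.get("V0", "1V"), 1.0, "pulse.V0"),
                R=parse_quantity(pblock.get("R", 0.09), 1.0, "pulse.R"),
                L=parse_quantity(pblock.get("L", "13uH"), 1.0, "pulse.L"),
                C=parse_quantity(pblock.get("C", "200uF"), 1.0, "pulse.C"),
            )
        except ValueError as exc:
            raise ConfigError(f"pulse.{_rlc_culprit(pblock)}: {exc}") from exc

        mblock = data.get("morphology", {})
        _check_keys(mblock, {"swc", "toy"}, "morphology")
        if "swc" in mblock and "toy" in mblock:
            raise ConfigError("morphology: give either 'swc' or 'toy', not both")
        if "swc" in mblock:
            neuron = load_swc(mblock["swc"])
        elif "toy" in mblock:
            try:
                neuron = build_toy(mblock["toy"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"morphology.toy: {exc}") from exc
        else:
            raise ConfigError("morphology: missing 'swc' or 'toy'")

        mechs = dict(default_mechanisms())
        for tag, over in (data.get("mechanisms") or {}).items():
            base = mechs.get(tag) or mechs.get(over.get("kind", ""), None)
            if base is None:
                raise ConfigError(f"mechanisms.{tag}: unknown mechanism tag")
            try:
                mechs[tag] = base.replace(
                    **{k: v for k, v in over.items() if k != "kind"}
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"mechanisms.{tag}: {exc}") from exc

        sblock = data.get("sim", {})
        _check_keys(
            sblock,
            {"dt", "t_stop", "record", "pulse_delay", "settle_ms", "theta",
             "d_lambda", "max_seg_um"},
            "sim",
        )
        try:
            sim = SimConfig(
                dt=parse_quantity(sblock.get("dt", 0.001), 1e-3, "sim.dt"),
                t_stop=parse_quantity(sblock.get("t_stop", 5.0), 1e-3, "sim.t_stop"),
                record=[tuple(r) for r in sblock.get("record", [])],
                pulse_delay=parse_quantity(
                    sblock.get("pulse_delay", 0.0), 1e-3, "sim.pulse_delay"
                ),
                settle_ms=parse_quantity(
                    sblock.get("settle_ms", 5.0), 1e-3, "sim.settle_ms"
                ),
                theta=float(sblock.get("theta", 1.0)),
                d_lambda=float(sblock.get("d_lambda", 0.1)),
                max_seg_um=sblock.get("max_seg_um"),
            )
        except ValueError as exc:
            raise ConfigError(f"sim: {exc}") from exc

        protocol = data.get("protocol", {}) or {}
        _check_keys(
            protocol,
            {"kind", "experiment", "overrides", "bounds", "resolution", "site",
             "output"},
            "protocol",
        )
        return cls(coil, pulse, neuron, mechs, sim, protocol, raw=data)


def _rlc_culprit(block: dict) -> str:
    # find which RLC entry is invalid, for the error path
    for key, default in (("V0", 1.0), ("R", 0.09), ("L", 13e-6), ("C", 200e-6)):
        try:
            v = parse_quantity(block.get(key, default), 1.0, f"pulse.{key}")
            if key != "V0" and v <= 0:
                return key
            if key == "V0" and v < 0:
                return key
        except ConfigError:
            return key
    return "?"
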