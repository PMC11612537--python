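"""Flat key–value configuration files and reproducible run manifests.

The config dialect is one ``key = value`` pair per line (``#`` comments),
with keys mirroring the published parameter symbols.  An empty or missing
file reproduces the default parameter table exactly; unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .params import ConfigurationError, ModelParameters, ThermalNiche

#: config key -> ModelParameters field
_SCALAR_KEYS = {
    "K": "K",
    "rho": "rho",
    "omega": "omega",
    "lb": "lb",
    "lv": "lv",
    "lmat": "lmat",
    "linf": "linf",
    "I_Topt": "I_topt",
    "Rh": "Rh",
    "G_Topt": "G_topt",
    "B_Topt": "B_topt",
    "a": "attack",
    "h": "handling",
    "f_Topt": "f_topt",
    "eps": "eps",
    "mu0": "mu0",
    "E_act": "E_act",
    "beta": "beta",
    "T0": "T0",
    "k_boltz": "k_boltz",
    "tsr_ref": "tsr_ref",
}
_NICHE_KEYS = {
    "Tmin": "tmin",
    "Topt": "topt",
    "Tmax": "tmax",
    "consumer_Tmin": ("consumer", "tmin"),
    "consumer_Topt": ("consumer", "topt"),
    "consumer_Tmax": ("consumer", "tmax"),
    "predator_Tmin": ("predator", "tmin"),
    "predator_Topt": ("predator", "topt"),
    "predator_Tmax": ("predator", "tmax"),
}


def load_config(path: str | Path | None = None) -> ModelParameters:
    """Load model parameters from a flat config file.

    ``None`` or an empty file yields the default parameter set.  Shared
    niche keys (``Tmin``/``Topt``/``Tmax``) set both species; the
    ``consumer_``/``predator_``-prefixed variants override one species.
    """
    values: dict[str, float] = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (part.strip() for part in line.partition("="))
            if key not in _SCALAR_KEYS and key not in _NICHE_KEYS:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            if key in values:
                raise ConfigurationError(f"{path}:{lineno}: duplicate key {key!r}")
            try:
                values[key] = float(val)
            except ValueError as err:
                raise ConfigurationError(
                    f"{path}:{lineno}: non-numeric value for {key!r}: {val!r}"
                ) from err
    return _build(values)


def _build(values: dict[str, float]) -> ModelParameters:
    kwargs = {
        field_name: values[key]
        for key, field_name in _SCALAR_KEYS.items()
        if key in values
    }
    niche_fields: dict[str, dict[str, float]] = {"consumer": {}, "predator": {}}
    for key, spec in _NICHE_KEYS.items():
        if key not in values:
            continue
        if isinstance(spec, str):  # shared key
            niche_fields["consumer"][spec] = values[key]
            niche_fields["predator"][spec] = values[key]
        else:
            species, attr = spec
            niche_fields[species][attr] = values[key]
    for species in ("consumer", "predator"):
        if niche_fields[species]:
            base = ThermalNiche()
            merged = {
                "tmin": base.tmin,
                "topt": base.topt,
                "tmax": base.tmax,
                **niche_fields[species],
            }
            kwargs[f"{species}_niche"] = ThermalNiche(**merged)
    return ModelParameters(**kwargs)


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set in the flat config dialect."""
    lines = [f"# tritherm parameter file (all values explicit)"]
    for key, field_name in _SCALAR_KEYS.items():
        lines.append(f"{key} = {getattr(params, field_name)!r}")
    for species in ("consumer", "predator"):
        niche: ThermalNiche = getattr(params, f"{species}_niche")
        for attr in ("tmin", "topt", "tmax"):
            lines.append(f"{species}_T{attr[1:]} = {getattr(niche, attr)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(params: ModelParameters) -> str:
    """Deterministic hash of a parameter set (stable across runs)."""
    payload = json.dumps(asdict(params), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output.

    Identical manifests (ignoring the timestamp) imply bit-identical
    outputs: every algorithm in the toolkit is deterministic.
    """

    config_hash: str
    scenario: int | str
    grids: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def content_hash(self) -> str:
        """Hash over everything except the timestamp."""
        payload = {k: v for k, v in asdict(self).items() if k != "timestamp"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        record = asdict(self)
        record["content_hash"] = self.content_hash()
        Path(path).write_text(json.dumps(record, indent=2) + "\n")
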