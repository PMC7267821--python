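"""Read/write simulation-parameter files (YAML, or flat key=value text)."""

from __future__ import annotations

import dataclasses

import yaml

from .engine import SimulationParameters

_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationParameters)}
_INT_FIELDS = {"c_max", "N0", "t_max", "N_cap", "seed"}


def load_params(path) -> SimulationParameters:
    """Parse a parameter file; keys mirror SimulationParameters exactly.

    YAML is the primary format; a flat ``key = value`` text file (one pair
    per line, ``#`` comments) is accepted as a fallback.
    """
    text = open(path).read()
    try:
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError
    except Exception:
        data = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: cannot parse line {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            data[key] = value
    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        kwargs[key] = int(value) if key in _INT_FIELDS else float(value)
    return SimulationParameters(**kwargs)


def write_params(params: SimulationParameters, path) -> None:
    data = dataclasses.asdict(params)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
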