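"""Key-value configuration files for simulation parameters."""

from __future__ import annotations

import os
from dataclasses import fields
from typing import Union

from .params import DomainBoundary, SimParams

__all__ = ["load_config", "save_config"]

_SCALARS = {"b", "k", "D", "v", "alpha", "k_p", "k_u", "dt", "d_t1", "d_close"}


def load_config(path: Union[str, os.PathLike]) -> SimParams:
    """Load simulation parameters from a ``key = value`` text file.

    Unknown keys are rejected; omitted keys take the documented defaults
    (b=0.02 µm/s, k=0.005 µm⁻¹s⁻¹, D=1e-5 µm²/s, v=1 µm/s, no catastrophe or
    pinning, circular domain of radius 15 µm).
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in kv:
                raise ValueError(f"{path}:{ln}: duplicate key {key!r}")
            kv[key] = val

    kwargs: dict = {}
    domain_kind = kv.pop("domain", "circle")
    radius = kv.pop("radius", None)
    extents = kv.pop("extents", None)
    for key, val in kv.items():
        if key in _SCALARS:
            try:
                kwargs[key] = float(val)
            except ValueError as exc:
                raise ValueError(f"invalid value for {key!r}: {val!r}") from exc
        elif key == "seed":
            kwargs[key] = int(val)
        elif key == "growth_mode":
            kwargs[key] = val
        else:
            valid = sorted(_SCALARS | {"seed", "growth_mode", "domain",
                                       "radius", "extents"})
            raise ValueError(f"unknown configuration key {key!r} "
                             f"(valid: {', '.join(valid)})")
    dom_kwargs: dict = {}
    if radius is not None:
        dom_kwargs["radius"] = float(radius)
    if extents is not None:
        parts = [float(x) for x in extents.replace(",", " ").split()]
        if len(parts) == 1:
            parts = parts * 2
        dom_kwargs["extents"] = tuple(parts[:2])
    kwargs["domain"] = DomainBoundary(domain_kind, **dom_kwargs)
    params = SimParams(**kwargs)
    params.validate()
    return params


def save_config(params: SimParams, path: Union[str, os.PathLike]) -> None:
    """Write parameters in the format accepted by :func:`load_config`."""
    with open(path, "w") as fh:
        fh.write("# liquidnet configuration\n")
        for f in fields(params):
            if f.name == "domain":
                d = params.domain
                fh.write(f"domain = {d.kind}\n")
                if d.kind == "circle":
                    fh.write(f"radius = {d.radius!r}\n")
                elif d.kind == "periodic":
                    fh.write(f"extents = {d.extents[0]!r} {d.extents[1]!r}\n")
                continue
            val = getattr(params, f.name)
            if val is None:
                continue
            text = val if isinstance(val, str) else repr(val)
            fh.write(f"{f.name} = {text}\n")
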