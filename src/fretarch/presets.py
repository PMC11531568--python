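"""Access to bundled presets: dye pairs, AV geometries, vdW radii."""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .photophysics import DonorPhotophysics, FluorophorePair

__all__ = ["load_presets", "fluorophore_pair", "dye_av_params", "vdw_radius_table"]


@functools.cache
def load_presets() -> dict:
    """The raw preset dictionary bundled with the package."""
    text = resources.files("fretarch.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def fluorophore_pair(name: str) -> FluorophorePair:
    """Build a :class:`FluorophorePair` from a named preset (e.g. ``cy3b_T``)."""
    try:
        p = load_presets()["fluorophore_pairs"][name]
    except KeyError as exc:
        raise KeyError(f"unknown fluorophore pair preset {name!r}") from exc
    return FluorophorePair(
        donor=DonorPhotophysics(k_F=p["k_F"], tau_L=p["tau_L"]),
        kappa2=p["kappa2"],
        n_refr=p["n_refr"],
        J=float(p["J"]),
    )


def dye_av_params(name: str) -> dict:
    """Linker/dye geometry preset for the AV engine (lengths in Å)."""
    try:
        return dict(load_presets()["dyes"][name])
    except KeyError as exc:
        raise KeyError(f"unknown dye preset {name!r}") from exc


@functools.cache
def vdw_radius_table() -> dict:
    """Element symbol (upper case) -> vdW radius in Å, plus ``default``."""
    text = resources.files("fretarch.data").joinpath("vdw_radii.yaml").read_text()
    data = yaml.safe_load(text)
    table = {k.upper(): float(v) for k, v in data["radii"].items()}
    table["default"] = float(data["default"])
    return table
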