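"""Editable table of illustrative permittivity surrogates and stack builders.

The bundled values are fixtures with plausible band positions (SiN phonon in
the 800-1150 cm^-1 window, flat-lossy heavy water, lipid oscillators at
1466/1496/1603/1740 cm^-1), not literature fits. Users can point
``load_material_table`` at their own CSV with the same columns.
"""
from __future__ import annotations

import csv
import dataclasses
from importlib import resources
from pathlib import Path

from .errors import ParseError
from .forward_model import Layer, LayerStack, PermittivitySpectrum, _lorentz_eps

__all__ = ["Material", "load_material_table", "membrane_stack", "two_layer_stack"]


@dataclasses.dataclass(frozen=True)
class Material:
    """Lorentz-oscillator description of one medium."""

    name: str
    eps_infinity: float
    oscillators: tuple[tuple[float, float, float], ...] = ()

    def eps_at(self, wavenumber: float | None) -> complex:
        if not self.oscillators:
            return complex(self.eps_infinity)
        if wavenumber is None:
            raise ParseError(f"material {self.name!r} needs a wavenumber")
        return _lorentz_eps(self.oscillators, self.eps_infinity, wavenumber)

    def spectrum(self, grid) -> PermittivitySpectrum:
        from .forward_model import make_permittivity

        return make_permittivity(self.oscillators, self.eps_infinity, grid)


def load_material_table(path: str | Path | None = None) -> dict[str, Material]:
    """Read a material CSV (columns material,eps_inf,center_cm1,strength,damping_cm1).

    Multiple rows with the same material name accumulate oscillators; blank
    oscillator fields declare a constant permittivity.
    """
    if path is None:
        source = resources.files("nanoswitch.data").joinpath("materials.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    by_name: dict[str, dict] = {}
    for i, row in enumerate(rows, start=2):
        try:
            name = row["material"].strip()
            eps_inf = float(row["eps_inf"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"materials CSV line {i}: {exc}") from exc
        entry = by_name.setdefault(name, {"eps_inf": eps_inf, "oscillators": []})
        if row.get("center_cm1") and row["center_cm1"].strip():
            try:
                osc = (
                    float(row["center_cm1"]),
                    float(row["strength"]),
                    float(row["damping_cm1"]),
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"materials CSV line {i}: {exc}") from exc
            entry["oscillators"].append(osc)
    return {
        name: Material(name, entry["eps_inf"], tuple(entry["oscillators"]))
        for name, entry in by_name.items()
    }


def _as_layer_eps(material: Material):
    if not material.oscillators:
        return complex(material.eps_infinity)
    # Layer accepts PermittivitySpectrum; build one lazily over a wide grid so
    # oscillator-backed materials evaluate exactly at any wavenumber.
    import numpy as np

    grid = np.linspace(400.0, 4000.0, 19)
    return material.spectrum(grid)


def two_layer_stack(substrate: str = "si", table=None) -> LayerStack:
    """Ambient air over a semi-infinite substrate (default: silicon reference)."""
    table = table or load_material_table()
    return LayerStack(
        [Layer(1.0 + 0j, None), Layer(_as_layer_eps(table[substrate]), None)]
    )


def membrane_stack(
    sample: str | None = None,
    sample_thickness: float = 4.0,
    membrane_thickness: float = 10.0,
    subphase: str = "d2o",
    table=None,
) -> LayerStack:
    """Air | SiN membrane | optional adhered sample layer | aqueous half-space."""
    table = table or load_material_table()
    layers = [
        Layer(1.0 + 0j, None),
        Layer(_as_layer_eps(table["sin_membrane"]), membrane_thickness),
    ]
    if sample is not None:
        layers.append(Layer(_as_layer_eps(table[sample]), sample_thickness))
    layers.append(Layer(_as_layer_eps(table[subphase]), None))
    return LayerStack(layers)
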