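"""Material attenuation tables and polyenergetic x-ray tube spectra.

Embedded NIST-grid elemental mass attenuation coefficients (total, with
coherent scattering) are combined with elemental mass fractions through the
mixture rule to give each material a ``mu/rho`` table; linear attenuation is
obtained by log-log interpolation times bulk density.

Tube spectra are modelled analytically: a Kramers bremsstrahlung continuum
plus tungsten K characteristic lines, hardened by an Al-equivalent filtration
thickness.  Spectra are relative (unit-sum) photon fluences per 1 keV bin;
absolute scaling enters later through mAs and a configurable fluence scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    LookupErrorDecbct,
    RangeError,
    ValidationError,
)

#: default energy axis: 1 keV bins covering 20..150 keV
DEFAULT_ENERGIES = np.arange(20.0, 151.0)

#: tungsten K fluorescence lines (keV) and relative intensities (Ka2, Ka1, Kb1, Kb2)
_W_K_LINES = ((57.98, 0.28), (59.32, 0.50), (67.24, 0.15), (69.07, 0.07))
_W_K_EDGE = 69.525
#: fraction of the (filtered) continuum fluence emitted in K lines above the edge
_K_LINE_FRACTION = 0.07


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform 1 keV energy axis used by spectra and VMI synthesis."""

    energies: np.ndarray = field(default_factory=lambda: DEFAULT_ENERGIES.copy())

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValidationError("energy grid must be a 1-D array with >= 2 bins")
        d = np.diff(e)
        if not np.all(d > 0):
            raise ValidationError("energy grid must be strictly increasing")
        if not np.allclose(d, 1.0):
            raise ValidationError("energy grid spacing must be exactly 1 keV")
        if e[0] > 40 or e[-1] < 150:
            raise ValidationError("energy grid must cover at least [40, 150] keV")
        object.__setattr__(self, "energies", e)


@dataclass(frozen=True)
class MaterialRecord:
    """A material: bulk density plus its tabulated mass attenuation curve."""

    name: str
    density: float  # g/cm^3
    energies: np.ndarray  # keV, strictly increasing
    mu_rho: np.ndarray  # cm^2/g, strictly positive

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValidationError(f"{self.name}: density must be positive")
        e = np.asarray(self.energies, float)
        m = np.asarray(self.mu_rho, float)
        if np.any(np.diff(e) <= 0):
            raise ValidationError(f"{self.name}: table energies must increase")
        if np.any(m <= 0):
            raise ValidationError(f"{self.name}: mass attenuation must be positive")
        if e[0] > 20 or e[-1] < 150:
            raise ValidationError(f"{self.name}: table must cover [20, 150] keV")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_rho", m)


def _read_resource(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("decbct.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=1)
def material_table() -> dict[str, MaterialRecord]:
    """All embedded materials, keyed by name (mixture rule over elements)."""
    elements = _read_resource("elements_mu_rho.csv")
    comps = _read_resource("materials.csv")
    energies = elements["energy_keV"].to_numpy(float)
    symbols = [c for c in elements.columns if c != "energy_keV"]
    table: dict[str, MaterialRecord] = {}
    for _, row in comps.iterrows():
        fractions = np.array([float(row[s]) for s in symbols])
        if not np.isclose(fractions.sum(), 1.0, atol=5e-3):
            raise ValidationError(f"{row['name']}: mass fractions must sum to 1")
        mu_rho = elements[symbols].to_numpy(float) @ fractions
        table[row["name"]] = MaterialRecord(
            name=row["name"],
            density=float(row["density_g_cc"]),
            energies=energies,
            mu_rho=mu_rho,
        )
    return table


def get_material(name: str) -> MaterialRecord:
    try:
        return material_table()[name]
    except KeyError:
        raise LookupErrorDecbct(f"unknown material {name!r}") from None


def mass_attenuation(material: MaterialRecord | str, energy) -> np.ndarray | float:
    """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
    if isinstance(material, str):
        material = get_material(material)
    e = np.asarray(energy, dtype=float)
    if np.any(e < material.energies[0]) or np.any(e > material.energies[-1]):
        raise RangeError(
            f"energy outside tabulated range "
            f"[{material.energies[0]}, {material.energies[-1]}] keV"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(material.energies), np.log(material.mu_rho))
    )
    return float(out) if np.isscalar(energy) else out


def linear_attenuation(material: MaterialRecord | str, energy) -> np.ndarray | float:
    """Linear attenuation coefficient mu (cm^-1) at the given energy (keV)."""
    if isinstance(material, str):
        material = get_material(material)
    return material.density * mass_attenuation(material, energy)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per 1 keV bin for one tube potential."""

    kvp: float
    energies: np.ndarray
    fluence: np.ndarray
    filtration_mm_al: float = 0.0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, float)
        f = np.asarray(self.fluence, float)
        if e.shape != f.shape:
            raise ValidationError("energies and fluence must have the same shape")
        if np.any(f < 0):
            raise ValidationError("fluence must be non-negative")
        if np.any(f[e > self.kvp] > 0):
            raise ValidationError("fluence must vanish above the tube potential")
        if not np.any(f > 0):
            raise DegenerateInputError("spectrum has no positive fluence bin")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    def to_csv(self, path) -> None:
        pd.DataFrame({"energy_keV": self.energies, "value": self.fluence}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, kvp: float, filtration_mm_al: float = 0.0) -> "Spectrum":
        df = pd.read_csv(path, comment="#")
        return cls(
            kvp=kvp,
            energies=df["energy_keV"].to_numpy(float),
            fluence=df["value"].to_numpy(float),
            filtration_mm_al=filtration_mm_al,
        )


def generate_spectrum(
    kvp: float,
    filtration_mm_al: float = 2.5,
    grid: EnergyGrid | None = None,
    characteristic_lines: bool = True,
) -> Spectrum:
    """Analytic tungsten-anode spectrum at ``kvp`` with Al filtration (mm).

    Kramers continuum ``(kvp - E)/E`` attenuated through ``filtration_mm_al``
    of aluminium; for potentials above the W K-edge a fixed fraction of the
    fluence is emitted in the four K lines.  Deterministic and unit-sum.
    """
    if not (50.0 <= kvp <= 150.0):
        raise ConfigurationError(f"unsupported tube potential {kvp} kVp")
    if filtration_mm_al < 0:
        raise ConfigurationError("filtration must be non-negative")
    grid = grid or EnergyGrid()
    e = grid.energies
    al = get_material("aluminum")

    continuum = np.clip(kvp - e, 0.0, None) / e
    transmission = np.exp(-linear_attenuation(al, e) * filtration_mm_al / 10.0)
    fluence = continuum * transmission

    if characteristic_lines and kvp > _W_K_EDGE:
        line_total = _K_LINE_FRACTION * fluence.sum()
        for line_e, weight in _W_K_LINES:
            idx = int(round(line_e - e[0]))
            if 0 <= idx < e.size and e[idx] <= kvp:
                t = np.exp(
                    -linear_attenuation(al, line_e) * filtration_mm_al / 10.0
                )
                fluence[idx] += line_total * weight * t

    fluence /= fluence.sum()
    return Spectrum(
        kvp=float(kvp),
        energies=e,
        fluence=fluence,
        filtration_mm_al=float(filtration_mm_al),
    )


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean photon energy (keV)."""
    total = spectrum.fluence.sum()
    if total <= 0:
        raise DegenerateInputError("cannot average an all-zero spectrum")
    return float((spectrum.energies * spectrum.fluence).sum() / total)


def detector_weights(energies: np.ndarray, detector: str = "ei") -> np.ndarray:
    """Per-bin detector response: energy-integrating (w=E) or photon-counting."""
    if detector == "ei":
        return np.asarray(energies, float)
    if detector == "pc":
        return np.ones_like(np.asarray(energies, float))
    raise ConfigurationError(f"unknown detector response {detector!r}")
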