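"""Nanoparticle dosimetry arithmetic.

Deterministic unit conversions linking three descriptions of a
nanoparticle exposure: composition (atoms per particle, atomic mass),
administered dose (particles per cell at a given cell density, or the
equivalent metal mass concentration), and measured uptake (total metal
mass by ICP-MS, converted to particles and mass per cell and the
fraction of cell volume occupied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # mol^-1 (CODATA)
PT_ATOMIC_MASS = 195.084  # g/mol (IUPAC)


@dataclass(frozen=True)
class ParticleSpec:
    """Composition and geometry of one nanoparticle species.

    Defaults describe a 2-nm platinum particle of 1000 Pt atoms with a
    volume of ~4.2 nm^3.
    """

    atoms_per_particle: int = 1000
    atomic_mass: float = PT_ATOMIC_MASS  # g/mol
    diameter: float = 2.0  # nm
    particle_volume: float | None = None  # nm^3; sphere from diameter if None

    def __post_init__(self) -> None:
        if self.atoms_per_particle <= 0:
            raise ValueError("atoms_per_particle must be > 0")
        if self.atomic_mass <= 0:
            raise ValueError("atomic_mass must be > 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.particle_volume is None:
            object.__setattr__(
                self, "particle_volume", math.pi / 6.0 * self.diameter**3
            )
        if self.particle_volume <= 0:
            raise ValueError("particle_volume must be > 0")


@dataclass(frozen=True)
class ExposureSpec:
    """Administered dose context: particles per cell at a cell density."""

    particles_per_cell: float
    cell_density: float  # cells per mL

    def __post_init__(self) -> None:
        if not (self.particles_per_cell >= 0 and math.isfinite(self.particles_per_cell)):
            raise ValueError("particles_per_cell must be finite and >= 0")
        if not (self.cell_density > 0 and math.isfinite(self.cell_density)):
            raise ValueError("cell_density must be finite and > 0")


@dataclass(frozen=True)
class UptakeReport:
    """Per-cell uptake summary derived from a total-mass measurement."""

    total_particles: float
    particles_per_cell: float
    mass_per_cell_pg: float
    cell_volume_fraction_percent: float
    uptake_percent: float | None = None

    def rounded(self) -> dict[str, float]:
        """Headline values at presentation precision (2 s.f.; 1 s.f. for
        the volume fraction); full precision stays on the attributes."""
        return {
            "total_particles": _sig_round(self.total_particles, 2),
            "particles_per_cell": _sig_round(self.particles_per_cell, 2),
            "mass_per_cell_pg": _sig_round(self.mass_per_cell_pg, 2),
            "cell_volume_fraction_percent": _sig_round(self.cell_volume_fraction_percent, 1),
            **(
                {"uptake_percent": _sig_round(self.uptake_percent, 2)}
                if self.uptake_percent is not None
                else {}
            ),
        }


def _sig_round(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def particle_mass(spec: ParticleSpec) -> float:
    """Mass of one particle in micrograms: atoms x atomic mass / N_A."""
    grams = spec.atoms_per_particle * spec.atomic_mass / AVOGADRO
    return grams * 1e6


def exposure_concentration(exposure: ExposureSpec, spec: ParticleSpec) -> float:
    """Metal mass concentration (mg/L) of an administered exposure.

    particles/cell x cells/mL gives particles per mL; x1000 per litre;
    x particle mass gives metal mass per litre.
    """
    particles_per_litre = exposure.particles_per_cell * exposure.cell_density * 1e3
    micrograms_per_litre = particles_per_litre * particle_mass(spec)
    return micrograms_per_litre * 1e-3  # ug -> mg


def particles_per_cell_from_concentration(
    concentration: float, cell_density: float, spec: ParticleSpec
) -> float:
    """Exact inverse of :func:`exposure_concentration`."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    micrograms_per_litre = concentration * 1e3
    particles_per_litre = micrograms_per_litre / particle_mass(spec)
    return particles_per_litre / (cell_density * 1e3)


def uptake_report(
    total_metal_mass: float,
    n_cells: float,
    spec: ParticleSpec,
    cell_volume: float,
    administered_mass: float | None = None,
) -> UptakeReport:
    """Convert an ICP-MS total metal mass into a per-cell uptake report.

    Parameters
    ----------
    total_metal_mass : float
        Total metal mass in the cell pellet, micrograms.
    n_cells : float
        Number of cells in the measured population.
    cell_volume : float
        Volume of one cell, nm^3.
    administered_mass : float, optional
        Total metal mass administered, micrograms; enables the uptake
        percentage.
    """
    if total_metal_mass < 0:
        raise ValueError("total_metal_mass must be >= 0")
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    total_particles = total_metal_mass / particle_mass(spec)
    per_cell = total_particles / n_cells
    mass_per_cell_pg = total_metal_mass / n_cells * 1e6  # ug -> pg
    vol_frac = per_cell * spec.particle_volume / cell_volume * 100.0
    uptake = (
        100.0 * total_metal_mass / administered_mass
        if administered_mass is not None
        else None
    )
    if administered_mass is not None and administered_mass <= 0:
        raise ValueError("administered_mass must be > 0")
    return UptakeReport(
        total_particles=total_particles,
        particles_per_cell=per_cell,
        mass_per_cell_pg=mass_per_cell_pg,
        cell_volume_fraction_percent=vol_frac,
        uptake_percent=uptake,
    )
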