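"""Simulation state containers.

The population is stored as flat numpy arrays (one row per cell) for speed;
:class:`Cell` is a lightweight per-cell view used by the single-cell force
API and by tests.  Genealogy is a growing ``parent_of`` array shared between
all snapshots of a run (``parent_of[id] = parent id``, -1 for cells created
at initialization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..well_geometry import WellSpec

STRAINS = ("neutralA", "neutralB", "sensitive", "resistant")
STRAIN_CODE = {name: i for i, name in enumerate(STRAINS)}


@dataclass
class PhysicsParams:
    """Mechanical and growth parameters.

    The reference stiffness constants (wall 1e7 pN/um, adhesion 1e6 pN/um)
    make explicit integration extremely stiff; the default "desk" profile
    uses a uniformly rescaled set that preserves the wall:adhesion ratio
    (10:1) and the quasi-static limit.  ``reference_profile`` keeps the
    reference values with a correspondingly tiny time step.
    """

    k_cell: float = 1.6e6          # pN / um^1.5, Hertzian-like prefactor
    k_wall: float = 8.0e6          # pN / um, linear wall repulsion
    k_adhesion: float = 8.0e5      # pN / um, 10:1 wall:adhesion ratio
    epsilon_max: float = 0.05      # spring breaks beyond this relative extension
    adhesion_enabled: bool = False
    gamma: float = 20.0            # pN h / um^2, Stokes friction per unit length
    gamma_rot: float = 20.0 / 12.0  # pN h / um^2 (slender-rod L^3 scaling)
    n_wall_samples: int = 7        # wall-contact sample points per centreline
    dt: float = 4.0e-4             # h
    elongation_rate: float = 0.3   # 1/h, exponential centreline elongation
    l_div: float = 3.0             # um, centreline length at division
    l_min: float = 0.9             # um, smallest allowed centreline length
    radius: float = 0.5            # um
    division_angle_noise: float = 0.05  # rad
    division_length_noise: float = 0.15  # fractional spread of the division length
    cap_fraction: Optional[float] = 0.04   # per-step displacement cap, x radius
    abort_fraction: float = 0.05   # uncapped runs abort beyond this, x radius

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.l_min >= self.l_div:
            raise ValueError("l_min must be smaller than l_div")
        if self.epsilon_max < 0:
            raise ValueError("epsilon_max must be >= 0")

    @property
    def birth_length(self) -> float:
        # extent-conserving division: daughters' caps touch at the split point
        return 0.5 * (self.l_div - 2.0 * self.radius)


def desk_profile(**overrides) -> PhysicsParams:
    """Default rescaled-stiffness parameter set used for desk-scale runs."""
    return PhysicsParams(**overrides)


def reference_profile(**overrides) -> PhysicsParams:
    """Reference stiffnesses (wall 1e7, adhesion 1e6 pN/um) with a tiny dt."""
    base = dict(k_cell=2.0e6, k_wall=1.0e7, k_adhesion=1.0e6, dt=5.0e-5, gamma=25.0,
                gamma_rot=25.0 / 12.0)
    base.update(overrides)
    return PhysicsParams(**base)


@dataclass
class AdhesionSpring:
    wall_anchor: tuple
    rest_length: float
    stiffness: float
    epsilon_max: float
    attach_abscissa: float  # fraction of the half-length, in [-1, 1]


@dataclass
class Cell:
    """Read-only view of one spherocylinder agent."""

    id: int
    founder_id: int
    genotype: int
    strain: str
    center: np.ndarray
    angle: float
    length: float
    radius: float
    growth_multiplier: float = 1.0
    springs: list = field(default_factory=list)

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])

    @property
    def extent(self) -> float:
        return self.length + 2.0 * self.radius


class SimState:
    """Population arrays plus bookkeeping for one simulated well."""

    def __init__(self, spec: WellSpec, params: PhysicsParams, rng: np.random.Generator):
        self.spec = spec
        self.params = params
        self.rng = rng
        self.time = 0.0
        self.removed_count = 0
        self.removed_area = 0.0
        self.next_id = 0
        self.elastic_energy = 0.0
        self.max_wall_penetration = 0.0
        self.strain_multipliers: dict[str, float] = {}
        self.parent_of: list[int] = []  # genealogy, shared across snapshots
        n0 = 0
        self.ids = np.zeros(n0, dtype=np.int64)
        self.founder = np.zeros(n0, dtype=np.int64)
        self.genotype = np.zeros(n0, dtype=np.int64)
        self.strain = np.zeros(n0, dtype=np.int8)
        self.x = np.zeros(n0)
        self.y = np.zeros(n0)
        self.angle = np.zeros(n0)
        self.length = np.zeros(n0)
        self.radius = np.zeros(n0)
        self.lth = np.zeros(n0)  # per-cell division threshold
        from .mechanics import NWALLS

        self.sp_active = np.zeros((n0, NWALLS), dtype=np.bool_)
        self.sp_ax = np.zeros((n0, NWALLS))
        self.sp_ay = np.zeros((n0, NWALLS))
        self.sp_rest = np.zeros((n0, NWALLS))
        self.sp_frac = np.zeros((n0, NWALLS))

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def total_area(self) -> float:
        """2D footprint area of the population (rectangles + caps)."""
        return float(np.sum(2.0 * self.radius * self.length + math.pi * self.radius**2))

    def heights_above_bottom(self) -> np.ndarray:
        from ..well_geometry import bottom_height

        h = bottom_height(self.spec, np.clip(self.x, 0.0, self.spec.width))
        return self.y - h

    def multiplier_array(self) -> np.ndarray:
        mult = np.ones(len(STRAINS))
        for name, value in self.strain_multipliers.items():
            mult[STRAIN_CODE[name]] = value
        return mult[self.strain]

    def cells(self) -> list[Cell]:
        mult = self.multiplier_array()
        out = []
        for i in range(self.n):
            springs = []
            for w in range(self.sp_active.shape[1]):
                if self.sp_active[i, w]:
                    springs.append(
                        AdhesionSpring(
                            wall_anchor=(self.sp_ax[i, w], self.sp_ay[i, w]),
                            rest_length=self.sp_rest[i, w],
                            stiffness=self.params.k_adhesion,
                            epsilon_max=self.params.epsilon_max,
                            attach_abscissa=self.sp_frac[i, w],
                        )
                    )
            out.append(
                Cell(
                    id=int(self.ids[i]),
                    founder_id=int(self.founder[i]),
                    genotype=int(self.genotype[i]),
                    strain=STRAINS[self.strain[i]],
                    center=np.array([self.x[i], self.y[i]]),
                    angle=float(self.angle[i]),
                    length=float(self.length[i]),
                    radius=float(self.radius[i]),
                    growth_multiplier=float(mult[i]),
                    springs=springs,
                )
            )
        return out

    def copy(self) -> "SimState":
        new = SimState.__new__(SimState)
        new.spec = self.spec
        new.params = self.params
        new.rng = self.rng  # snapshots share the live rng; use deepcopy to fork
        new.time = self.time
        new.removed_count = self.removed_count
        new.removed_area = self.removed_area
        new.next_id = self.next_id
        new.elastic_energy = self.elastic_energy
        new.max_wall_penetration = self.max_wall_penetration
        new.strain_multipliers = dict(self.strain_multipliers)
        new.parent_of = self.parent_of  # shared genealogy
        for name in ("ids", "founder", "genotype", "strain", "x", "y", "angle",
                     "length", "radius", "lth", "sp_active", "sp_ax", "sp_ay",
                     "sp_rest", "sp_frac"):
            setattr(new, name, getattr(self, name).copy())
        return new

    def genotypes_present(self) -> set:
        return set(np.unique(self.genotype).tolist())
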