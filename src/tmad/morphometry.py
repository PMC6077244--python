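"""Rescaled Weibel trumpet geometry for the one-dimensional lung model.

The respiratory tract is represented as a rigid "trumpet": a 1-D structure
whose airway cross-sectional area grows from the mouth (z = 0) toward the
distal alveolar end (z = L).  The conducting airways (generations 0-17) follow
a power law in axial position; the alveolar region occupies the final ``z1``
centimetres (generations 17-23), where a distributed alveolar compartment with
cross-section proportional to the local alveolar density is superimposed on
the airway duct area.  The whole geometry is rescaled so the total airspace
volume matches a target (default 3,700 ml).

The discrete geometry (:class:`TrumpetGrid`) carries, per axial node, the
airway and alveolar cross-sections plus the normalized per-length source
weights used by the gas-exchange solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AnatomicalConstants",
    "GenerationTable",
    "TrumpetGrid",
    "airway_cross_section",
    "conducting_airway_volume",
    "alveolar_region_profile",
    "build_grid",
]


class MorphometryError(ValueError):
    """Invalid anatomical configuration."""


@dataclass(frozen=True)
class AnatomicalConstants:
    """Constants defining the trumpet geometry.

    Parameters
    ----------
    L : float
        Total trumpet length from mouth to distal alveolar end (cm).
    z1 : float
        Axial length of the alveolar region (cm).
    A_c1 : float
        Airway cross-sectional area at generation 17, i.e. at z = L - z1 (cm^2).
    m : float
        Power-law exponent of the conducting-airway area profile.
    A_cA : float
        Total cross-sectional area of the alveolar compartment (cm^2).  The
        storage term of the exchange equation applies it per unit axial
        distance, ``A_alv(z) = (N_alv(z)/N_t) * A_cA``, so the total alveolar
        gas capacity on the grid is ``A_cA`` millilitres.
    N_t : float
        Total number of alveoli.
    N_max : float
        Reported maximum alveolar count at any axial position.  Metadata only:
        the solver uses the grid maximum of the alveolar density (per cm),
        which is what makes the ratio N_alv(z)/N_max dimensionless.
    V_total : float
        Reported rescale target for the airway cross-sections (ml); retained
        as metadata.
    """

    L: float = 27.2
    z1: float = 0.6
    A_c1: float = 217.0
    m: float = 2.0
    A_cA: float = 39444.0
    N_t: float = 480e6
    N_max: float = 263.3e6
    V_total: float = 3700.0

    def __post_init__(self) -> None:
        for name in ("L", "z1", "A_c1", "m", "A_cA", "N_t", "N_max", "V_total"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise MorphometryError(f"{name} must be strictly positive")
        if self.z1 >= self.L:
            raise MorphometryError("alveolar-region length z1 must be < total length L")


@dataclass(frozen=True)
class GenerationTable:
    """Per-generation morphometry (generations 0-23).

    Wraps a table with columns ``generation``, ``position_cm`` (cumulative
    axial position of the generation end, strictly increasing, ending at L),
    ``area_cm2`` (airway duct cross-section) and ``alveoli_fraction``
    (fraction of the total alveoli housed in the generation; non-zero only
    for generations 17-23 and summing to 1).
    """

    data: pd.DataFrame

    REQUIRED_COLUMNS = ("generation", "position_cm", "area_cm2", "alveoli_fraction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise MorphometryError(f"generation table missing columns: {missing}")
        pos = self.data["position_cm"].to_numpy(float)
        if not np.all(np.diff(pos) > 0):
            raise MorphometryError("generation positions must be strictly increasing")
        if np.any(self.data["area_cm2"].to_numpy(float) <= 0):
            raise MorphometryError("generation areas must be positive")
        frac = self.data["alveoli_fraction"].to_numpy(float)
        if np.any(frac < 0):
            raise MorphometryError("alveoli fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-6:
            raise MorphometryError(
                f"alveoli fractions must sum to 1 (got {frac.sum():.6f})"
            )

    @classmethod
    def default(cls) -> "GenerationTable":
        """Load the bundled rescaled-Weibel table."""
        with resources.files("tmad.data").joinpath("generation_table.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "GenerationTable":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def alveolar(self) -> pd.DataFrame:
        """Rows of generations that carry alveoli."""
        return self.data[self.data["alveoli_fraction"] > 0]


def airway_cross_section(z, constants: AnatomicalConstants | None = None):
    """Airway cross-sectional area of the conducting airways (cm^2).

    Power law ``A(z) = A_c1 * ((L - z)/z1)**(-m)``, valid for
    ``0 <= z <= L - z1`` (mouth to generation 17).  Accepts scalars or arrays.
    """
    constants = constants or AnatomicalConstants()
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > constants.L - constants.z1 + 1e-12):
        raise MorphometryError(
            f"z must lie in [0, {constants.L - constants.z1}] cm (conducting airways)"
        )
    area = constants.A_c1 * ((constants.L - z) / constants.z1) ** (-constants.m)
    return float(area) if area.ndim == 0 else area


def conducting_airway_volume(constants: AnatomicalConstants | None = None) -> float:
    """Closed-form conducting-airway (anatomic dead-space) volume, ml.

    Integral of the power-law area over [0, L - z1]; for m = 2 this is
    ``A_c1 * z1 * (1 - z1/L)``.
    """
    constants = constants or AnatomicalConstants()
    if constants.m == 2.0:
        return constants.A_c1 * constants.z1 * (1.0 - constants.z1 / constants.L)
    # general m != 1: A_c1 * z1/(m-1) * (1 - (z1/L)**(m-1))
    m, z1, L = constants.m, constants.z1, constants.L
    if m == 1.0:
        return constants.A_c1 * z1 * np.log(L / z1)
    return constants.A_c1 * z1 / (m - 1.0) * (1.0 - (z1 / L) ** (m - 1.0))


def alveolar_region_profile(
    z: np.ndarray,
    constants: AnatomicalConstants,
    table: GenerationTable,
    dz: float,
) -> tuple[np.ndarray, float]:
    """Alveolar density sampled on grid nodes, normalized to the total count.

    The per-generation alveoli fractions are anchored at the generation end
    positions and linearly interpolated across the alveolar region
    ``[L - z1, L]``; outside the region the density is zero.  The sampled
    density is renormalized so that ``sum(N_alv) * dz == N_t`` exactly.

    Returns
    -------
    N_alv : ndarray
        Alveoli per unit axial distance at each node (1/cm).
    N_max_effective : float
        Maximum of ``N_alv`` over the grid, used for the airway-attenuation
        ratio ``N_alv/N_max`` in the exchange equation.
    """
    alv = table.alveolar
    frac = alv["alveoli_fraction"].to_numpy(float)
    pos = alv["position_cm"].to_numpy(float)
    z = np.asarray(z, dtype=float)
    shape = np.interp(z, pos, frac)  # flat extension below first anchor
    shape[z < constants.L - constants.z1 - 1e-12] = 0.0
    total = shape.sum() * dz
    if total <= 0:
        raise MorphometryError("alveolar region contains no grid nodes")
    N_alv = shape * (constants.N_t / total)
    return N_alv, float(N_alv.max())


@dataclass(frozen=True)
class TrumpetGrid:
    """Discretized trumpet geometry on a uniform axial grid.

    Attributes
    ----------
    dz : float
        Grid spacing (cm).
    z : ndarray
        Node positions, ``z[0] = 0`` (mouth) to ``z[-1] = L`` (distal end).
    A_aw, A_alv : ndarray
        Airway and alveolar cross-sections per node (cm^2).
    N_alv : ndarray
        Alveolar density per node (1/cm); integrates to ``N_t``.
    w_aw, w_alv : ndarray
        Normalized per-length source weights (1/cm); each integrates to 1 so
        that the *total* maximum fluxes and diffusing capacities can be applied
        directly in the exchange equation.
    """

    dz: float
    z: np.ndarray
    A_aw: np.ndarray
    A_alv: np.ndarray
    N_alv: np.ndarray
    w_aw: np.ndarray
    w_alv: np.ndarray
    constants: AnatomicalConstants = field(default_factory=AnatomicalConstants)
    N_max_effective: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.z.size

    @property
    def capacity(self) -> np.ndarray:
        """Storage coefficient A_aw + A_alv per node (cm^2)."""
        return self.A_aw + self.A_alv

    @property
    def total_volume(self) -> float:
        """Total airspace volume on the grid, ml (node-centered sum)."""
        return float(self.capacity.sum() * self.dz)

    @property
    def conducting_volume(self) -> float:
        """Airway volume of the conducting region (z <= L - z1), ml
        (trapezoidal quadrature over the grid)."""
        mask = self.z <= self.constants.L - self.constants.z1 + 1e-12
        return float(np.trapezoid(self.A_aw[mask], self.z[mask]))

    def cumulative_volume(self) -> np.ndarray:
        """Cumulative airspace volume from the mouth to each node, ml."""
        return np.cumsum(self.capacity) * self.dz


def effective_capacity(grid: TrumpetGrid, node: int) -> float:
    """Storage coefficient ``A_aw + A_alv`` at one node (cm^2)."""
    return float(grid.A_aw[node] + grid.A_alv[node])


def build_grid(
    constants: AnatomicalConstants | None = None,
    table: GenerationTable | None = None,
    dz: float = 0.1,
) -> TrumpetGrid:
    """Discretize the trumpet geometry onto a uniform axial grid.

    Airway areas follow the power law up to generation 17 (z = L - z1) and the
    tabulated generation areas, linearly interpolated, beyond.  The alveolar
    cross-section follows the alveolar density, applied per unit axial
    distance: ``A_alv(z) = (N_alv(z)/N_t) * A_cA``, so the alveolar gas
    capacity integrates to exactly ``A_cA`` millilitres.  This large
    distributed capacity (~39.4 l for the default constants) is what gives the
    alveolar reservoir its several-second fill time constant ``A_cA / D_A``
    and makes end-tidal concentrations fall below the alveolar equilibrium.

    Raises
    ------
    MorphometryError
        If ``dz`` does not divide ``L`` to within one node, or ``dz > z1``.
    """
    constants = constants or AnatomicalConstants()
    table = table or GenerationTable.default()
    if dz <= 0:
        raise MorphometryError("dz must be positive")
    if dz > constants.z1:
        raise MorphometryError(
            f"dz = {dz} cm exceeds the alveolar-region length z1 = {constants.z1} cm"
        )
    n = round(constants.L / dz)
    if abs(n * dz - constants.L) > 1e-9 * max(1.0, constants.L):
        raise MorphometryError(f"dz = {dz} does not divide L = {constants.L}")

    z = np.linspace(0.0, constants.L, n + 1)
    z_cond_end = constants.L - constants.z1

    A_aw = np.empty_like(z)
    cond = z <= z_cond_end + 1e-12
    A_aw[cond] = constants.A_c1 * ((constants.L - z[cond]) / constants.z1) ** (
        -constants.m
    )
    # alveolar region: interpolate tabulated generation areas, anchored at the
    # power-law value at the region entrance for continuity
    alv_rows = table.data[table.data["position_cm"] > z_cond_end + 1e-12]
    anchor_pos = np.concatenate(([z_cond_end], alv_rows["position_cm"].to_numpy(float)))
    anchor_area = np.concatenate(([constants.A_c1], alv_rows["area_cm2"].to_numpy(float)))
    A_aw[~cond] = np.interp(z[~cond], anchor_pos, anchor_area)

    N_alv, N_max_eff = alveolar_region_profile(z, constants, table, dz)

    w_alv = N_alv / constants.N_t  # 1/cm, integrates to 1
    A_alv = w_alv * constants.A_cA  # sum(A_alv)*dz == A_cA exactly
    w_aw_raw = A_aw * (1.0 - N_alv / N_max_eff)
    w_aw = w_aw_raw / (w_aw_raw.sum() * dz)

    return TrumpetGrid(
        dz=dz,
        z=z,
        A_aw=A_aw,
        A_alv=A_alv,
        N_alv=N_alv,
        w_aw=w_aw,
        w_alv=w_alv,
        constants=constants,
        N_max_effective=N_max_eff,
    )
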