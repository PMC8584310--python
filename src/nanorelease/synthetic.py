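"""Ground-truth-labelled synthetic inputs for both analysis arms.

Release curves are drawn from any registered kinetic model at the
standard sampling grid (1, 3, 5, 10, 20, 30 min) with seeded additive
Gaussian noise, so parameter recovery and model selection can be scored
against known truth.  Boxed configurations emulate the simulated
adsorption setup — a zigzag carbon nanotube (multi-wall by default,
diameters near 6.42/7.12/7.83 nm, length 20 nm) centred in a
20 x 80 x 20 nm periodic box — with controlled populations of free
molecules, isolated aggregates, surface-adsorbed molecules and
molecules adsorbed inside the tube.  Separation margins of twice the
contact cutoff guarantee that the intended partition is the unique
single-linkage clustering, so the generator's truth record is exact,
not approximate.

Ligand molecules are rigid bead chains (3 beads, 0.2 nm spacing, unit
mass by default): the configuration statistics depend on coordinates
only, so chemical detail adds nothing to the ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .kinetics import (
    DomainError,
    InputError,
    MODELS,
    KineticModelSpec,
    ReleaseCurve,
    FRACTION_OVERSHOOT,
    predict,
)
from .trajectory import Configuration, Molecule, NanotubeModel

__all__ = [
    "PackingError",
    "SyntheticCurveSpec",
    "SyntheticConfigSpec",
    "SyntheticTruth",
    "DEFAULT_TIMES_MIN",
    "DEFAULT_BOX_NM",
    "MWCNT_WALL_DIAMETERS_NM",
    "CC_BOND_NM",
    "RING_SPACING_NM",
    "generate_release_curve",
    "generate_nanotube",
    "generate_configuration",
]

# Sampling grid of the shaken-release experiment, minutes.
DEFAULT_TIMES_MIN = (1.0, 3.0, 5.0, 10.0, 20.0, 30.0)
# Simulation-box edges, nm (tube axis along y).
DEFAULT_BOX_NM = (20.0, 80.0, 20.0)
# Wall diameters of the three-wall tube, nm (innermost first).
MWCNT_WALL_DIAMETERS_NM = (6.42, 7.12, 7.83)

CC_BOND_NM = 0.142  # graphene C-C bond
LATTICE_NM = math.sqrt(3) * CC_BOND_NM  # 0.246, zigzag circumference step
RING_SPACING_NM = 1.5 * CC_BOND_NM  # 0.213, axial zigzag-ring spacing


class PackingError(RuntimeError):
    """Placement could not satisfy the separation margins."""


# ---------------------------------------------------------------------------
# Release curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one noisy release curve with known parameters."""

    model: str | KineticModelSpec = "power_law"
    params: Mapping[str, float] = field(
        default_factory=lambda: {"K": 0.7379, "n": 0.088}
    )
    times: Sequence[float] = DEFAULT_TIMES_MIN
    noise_sd: float = 0.0
    seed: int = 0
    value_kind: str = "fraction"
    heteroscedastic: bool = False  # noise sd proportional to the value

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


def generate_release_curve(
    spec: SyntheticCurveSpec,
) -> tuple[ReleaseCurve, dict[str, float]]:
    """Model curve plus seeded Gaussian noise, clipped at zero.

    Returns the curve and the true parameters.  Reproducible per seed.
    When the noiseless model values themselves exceed the tolerated
    fraction ceiling (possible for steep parameter draws at late times)
    the curve is emitted as an amount with ``c_inf = 1`` — numerically
    the same scale, so fits are unaffected.
    """
    t = np.asarray(spec.times, dtype=float)
    clean = predict(spec.model, spec.params, t)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        sd = spec.noise_sd * clean if spec.heteroscedastic else spec.noise_sd
        values = clean + rng.normal(0.0, 1.0, t.shape) * sd
    else:
        values = clean.copy()
    values = np.clip(values, 0.0, None)
    kind, c_inf = spec.value_kind, None
    if kind == "fraction" and np.any(values > FRACTION_OVERSHOOT):
        kind, c_inf = "amount", 1.0
    curve = ReleaseCurve(t, values, kind, c_inf)
    return curve, dict(spec.params)


# ---------------------------------------------------------------------------
# Nanotube construction
# ---------------------------------------------------------------------------

def _orthonormal_frame(axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, e)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    u = np.cross(e, helper)
    u /= np.linalg.norm(u)
    w = np.cross(e, u)
    return e, u, w


def generate_nanotube(
    diameter: float = MWCNT_WALL_DIAMETERS_NM[0],
    length: float = 20.0,
    walls: int = 1,
    diameters: Sequence[float] | None = None,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    axis: Sequence[float] = (0.0, 1.0, 0.0),
    bend_amplitude: float = 0.0,
    bend_wavelength: float | None = None,
) -> tuple[NanotubeModel, np.ndarray]:
    """Build a zigzag-lattice nanotube and its ring partition.

    Each wall is a zigzag (m, 0) cylinder with C-C bond 0.142 nm: the
    requested diameter is rounded to the nearest realizable value
    d = 0.246 m / pi, so the achieved diameter differs by at most half
    an index step (~0.04 nm).  Zigzag rings repeat every 0.213 nm along
    the axis; all walls share the ring count, and the ring partition
    groups atoms of every wall by axial ring.  ``walls=3`` with the
    default diameter uses walls near 6.42 / 7.12 / 7.83 nm; other
    multi-wall requests space walls 0.7 nm apart in diameter.

    ``bend_amplitude`` adds a transverse sinusoidal displacement
    A * sin(2 pi z / wavelength) to model a flexing tube: the reported
    model keeps the nominal straight axis, so ring centres and the
    straight-cylinder idealisation disagree — the counting artifact a
    flexible tube produces.

    Returns (model, atoms); ``model.diameter`` is the innermost
    achieved wall diameter (the bore that matters for inside counting)
    and ``model.axis_point`` anchors the tube at the end, so axial
    coordinates run over [0, length].
    """
    if diameter <= 0 or length <= 0 or walls < 1:
        raise DomainError("tube dimensions must be positive")
    if diameters is None:
        if walls == 3 and abs(diameter - MWCNT_WALL_DIAMETERS_NM[0]) < 1e-9:
            diameters = MWCNT_WALL_DIAMETERS_NM
        else:
            diameters = [diameter + 0.7 * k for k in range(walls)]
    if len(diameters) != walls:
        raise InputError("need one wall diameter per wall")

    n_rings = max(2, int(round(length / RING_SPACING_NM)) + 1)
    achieved_length = (n_rings - 1) * RING_SPACING_NM
    e, u, w = _orthonormal_frame(axis)
    origin = np.asarray(center, dtype=float) - e * achieved_length / 2.0

    all_pos, all_ring = [], []
    achieved = []
    for d in diameters:
        m = int(round(math.pi * d / LATTICE_NM))
        if m < 3:
            raise DomainError(f"diameter {d} nm too small for a zigzag wall")
        r = LATTICE_NM * m / (2.0 * math.pi)
        achieved.append(2.0 * r)
        ridx = np.arange(n_rings)[:, None]
        k = np.arange(2 * m)[None, :]
        theta = (math.pi / m) * (k + 0.5 * (ridx % 2))
        z = ridx * RING_SPACING_NM + np.where(k % 2 == 0,
                                              CC_BOND_NM / 4.0,
                                              -CC_BOND_NM / 4.0)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        if bend_amplitude:
            lam = bend_wavelength or achieved_length
            x = x + bend_amplitude * np.sin(2.0 * math.pi * z / lam)
        pos = (origin[None, :]
               + z.ravel()[:, None] * e[None, :]
               + x.ravel()[:, None] * u[None, :]
               + y.ravel()[:, None] * w[None, :])
        all_pos.append(pos)
        all_ring.append(np.broadcast_to(ridx, theta.shape).ravel())
    atoms = np.concatenate(all_pos)
    rings = np.concatenate(all_ring)
    partition = tuple(np.flatnonzero(rings == i) for i in range(n_rings))
    model = NanotubeModel(
        axis_point=origin, axis_dir=e,
        diameter=min(achieved), length=achieved_length,
        walls=walls, ring_partition=partition,
    )
    return model, atoms


# ---------------------------------------------------------------------------
# Configurations with exact truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfigSpec:
    """Recipe for one boxed configuration with known labels.

    Counts are molecules; ``aggregate_sizes`` lists the size of each
    isolated ligand-only aggregate.  The defaults reproduce the
    simulated geometry: 20 x 80 x 20 nm periodic box, three-wall tube
    with walls near 6.42/7.12/7.83 nm, length 20 nm, axis along y.
    """

    box: Sequence[float] = DEFAULT_BOX_NM
    tube_diameter: float = MWCNT_WALL_DIAMETERS_NM[0]
    tube_length: float = 20.0
    walls: int = 3
    n_free: int = 10
    aggregate_sizes: Sequence[int] = ()
    n_surface_adsorbed: int = 0
    n_inside: int = 0
    beads_per_molecule: int = 3
    bead_spacing: float = 0.2
    cutoff: float = 0.35
    seed: int = 0
    bend_amplitude: float = 0.0
    bend_wavelength: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_free, self.n_surface_adsorbed, self.n_inside) < 0:
            raise InputError("molecule counts must be non-negative")
        if any(s < 1 for s in self.aggregate_sizes):
            raise InputError("aggregate sizes must be >= 1")
        if self.beads_per_molecule < 1 or self.bead_spacing <= 0:
            raise InputError("invalid bead geometry")
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive")
        if self.bead_spacing >= self.cutoff:
            raise InputError("bead spacing must stay below the cutoff")

    @property
    def n_molecules(self) -> int:
        return (self.n_free + sum(self.aggregate_sizes)
                + self.n_surface_adsorbed + self.n_inside)


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact generator-side labels and intended statistics."""

    labels: tuple[str, ...]  # free / aggregate_k / surface / inside
    partition: tuple[tuple[int, ...], ...]  # intended clusters of molecules
    n_clusters: int
    n_aggregates: int  # nanotube-containing cluster included when non-empty
    mean_aggregate_size: float
    pct_adsorbed: float
    pct_inside: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    q = np.mod(points, box)
    return np.where(q >= box, q - box, q)


class _Placer:
    """Rejection-sampling placement honouring the separation margins."""

    def __init__(self, spec: SyntheticConfigSpec, tube: NanotubeModel,
                 cnt_atoms: np.ndarray, rng: np.random.Generator):
        self.spec = spec
        self.box = np.asarray(spec.box, dtype=float)
        self.tube = tube
        self.rng = rng
        self.cnt_tree = cKDTree(_wrap(cnt_atoms, self.box),
                                boxsize=self.box)
        centers = np.array([
            cnt_atoms[idx].mean(axis=0) for idx in tube.ring_partition
        ])
        self.ring_tree = cKDTree(_wrap(centers, self.box), boxsize=self.box)
        self.bore_radius = tube.diameter / 2.0
        self.placed: list[np.ndarray] = []
        # index of the nearest outer-wall / inner-wall atoms for anchoring
        rel = cnt_atoms - tube.axis_point
        axial = rel @ tube.axis_dir
        radial_vec = rel - axial[:, None] * tube.axis_dir[None, :]
        radial = np.linalg.norm(radial_vec, axis=1)
        self.cnt_atoms = cnt_atoms
        self.radial = radial
        self.radial_dir = radial_vec / radial[:, None]
        self.outer_idx = np.flatnonzero(radial > radial.max() - 0.05)
        self.inner_idx = np.flatnonzero(radial < radial.min() + 0.05)

    def _min_dist_to_placed(self, beads: np.ndarray) -> float:
        if not self.placed:
            return math.inf
        tree = cKDTree(_wrap(np.concatenate(self.placed), self.box),
                       boxsize=self.box)
        d, _ = tree.query(_wrap(beads, self.box), k=1)
        return float(np.min(d))

    def _clear_of_others(self, beads: np.ndarray, margin: float) -> bool:
        return self._min_dist_to_placed(beads) > margin

    def _clear_of_cnt(self, beads: np.ndarray, margin: float) -> bool:
        d, _ = self.cnt_tree.query(_wrap(beads, self.box), k=1)
        return float(np.min(d)) > margin

    def _outside_bore(self, beads: np.ndarray, margin: float) -> bool:
        d, _ = self.ring_tree.query(_wrap(beads, self.box), k=1)
        return float(np.min(d)) > self.bore_radius + margin

    def _chain(self, start: np.ndarray, direction: np.ndarray,
               n_beads: int) -> np.ndarray:
        steps = np.arange(n_beads)[:, None] * self.spec.bead_spacing
        return start[None, :] + steps * direction[None, :]

    def _random_dir(self) -> np.ndarray:
        v = self.rng.normal(size=3)
        return v / np.linalg.norm(v)

    def place_surface(self) -> np.ndarray:
        c = self.spec.cutoff
        for _ in range(500):
            i = self.rng.choice(self.outer_idx)
            out = self.radial_dir[i]
            start = self.cnt_atoms[i] + 0.9 * c * out
            beads = self._chain(start, out, self.spec.beads_per_molecule)
            if self._clear_of_others(beads, 2 * c):
                self.placed.append(beads)
                return beads
        raise PackingError("could not place a surface-adsorbed molecule")

    def place_inside(self) -> np.ndarray:
        c = self.spec.cutoff
        for _ in range(500):
            i = self.rng.choice(self.inner_idx)
            inward = -self.radial_dir[i]
            start = self.cnt_atoms[i] + 0.9 * c * inward
            beads = self._chain(start, self.tube.axis_dir,
                                self.spec.beads_per_molecule)
            if self._clear_of_others(beads, 2 * c):
                self.placed.append(beads)
                return beads
        raise PackingError("could not place an inside-adsorbed molecule")

    def place_blob(self, n_molecules: int) -> list[np.ndarray]:
        """An isolated straight chain of mutually linked molecules."""
        c = self.spec.cutoff
        k = self.spec.beads_per_molecule
        link_gap = 0.85 * c  # inter-molecule bead gap, below the cutoff
        stride = (k - 1) * self.spec.bead_spacing + link_gap
        for _ in range(500):
            start = self.rng.uniform(0.0, 1.0, 3) * self.box
            direction = self._random_dir()
            beads = np.concatenate([
                self._chain(start + j * stride * direction, direction, k)
                for j in range(n_molecules)
            ])
            if (self._clear_of_cnt(beads, 2 * c)
                    and self._outside_bore(beads, 2 * c)
                    and self._clear_of_others(beads, 2 * c)):
                mols = [beads[j * k:(j + 1) * k] for j in range(n_molecules)]
                self.placed.extend(mols)
                return mols
        raise PackingError(
            f"could not place an aggregate of {n_molecules} molecules"
        )

    def place_free(self) -> np.ndarray:
        return self.place_blob(1)[0]


def generate_configuration(
    spec: SyntheticConfigSpec,
) -> tuple[Configuration, SyntheticTruth]:
    """Place the requested populations and return exact truth.

    Placement order (which fixes molecule indices and therefore the
    intended cluster labels): surface-adsorbed, inside-adsorbed,
    aggregates in the given order, free molecules.  Surface and inside
    molecules anchor 0.9 x cutoff away from a wall atom (guaranteed
    contact); aggregates and free molecules keep more than 2 x cutoff
    from everything else, which makes the intended partition the unique
    single-linkage solution at the generation cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    tube, cnt_atoms = generate_nanotube(
        spec.tube_diameter, spec.tube_length, spec.walls,
        center=np.asarray(spec.box, dtype=float) / 2.0,
        axis=(0.0, 1.0, 0.0),
        bend_amplitude=spec.bend_amplitude,
        bend_wavelength=spec.bend_wavelength,
    )
    placer = _Placer(spec, tube, cnt_atoms, rng)

    molecules: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(spec.n_surface_adsorbed):
        molecules.append(placer.place_surface())
        labels.append("surface")
    for _ in range(spec.n_inside):
        molecules.append(placer.place_inside())
        labels.append("inside")
    agg_groups: list[list[int]] = []
    for a, size in enumerate(spec.aggregate_sizes):
        start = len(molecules)
        for beads in placer.place_blob(size):
            molecules.append(beads)
            labels.append(f"aggregate_{a}")
        agg_groups.append(list(range(start, start + size)))
    for _ in range(spec.n_free):
        molecules.append(placer.place_free())
        labels.append("free")

    config = Configuration(
        box=np.asarray(spec.box, dtype=float),
        cnt_atoms=cnt_atoms,
        ligand_molecules=[
            Molecule(m, np.ones(m.shape[0])) for m in molecules
        ],
        periodic=True,
        cnt_masses=np.full(cnt_atoms.shape[0], 12.011),
    )

    n_ads = spec.n_surface_adsorbed + spec.n_inside
    n_mol = len(molecules)
    partition: list[tuple[int, ...]] = []
    if n_ads:
        partition.append(tuple(range(n_ads)))
    partition.extend(tuple(g) for g in agg_groups)
    partition.extend((i,) for i in range(n_mol - spec.n_free, n_mol))
    n_clusters = len(partition)
    mean_size = n_mol / n_clusters if n_clusters else 0.0
    truth = SyntheticTruth(
        labels=tuple(labels),
        partition=tuple(partition),
        n_clusters=n_clusters,
        n_aggregates=n_clusters,
        mean_aggregate_size=mean_size,
        pct_adsorbed=100.0 * n_ads / n_mol if n_mol else 0.0,
        pct_inside=100.0 * spec.n_inside / n_mol if n_mol else 0.0,
    )
    return config, truth
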