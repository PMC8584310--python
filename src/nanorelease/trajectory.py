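"""Configuration statistics for nanotube + ligand systems.

Operates on static boxed configurations (orthorhombic, optionally
periodic): detects molecular aggregates by single-linkage contact
clustering, reports aggregate counts and mean sizes, the percentage of
ligand molecules adsorbed by the nanotube (membership of the
nanotube-containing cluster), and the percentage adsorbed *inside* the
nanotube via the ring / virtual-sphere algorithm: the tube is divided
into single carbon rings along its axis, a sphere is centred on each
ring's centre of mass, ligand molecules whose centre of mass falls in
any sphere are collected, and duplicates are removed.  For a perfectly
straight tube with ring spacing at most the sphere radius this reduces
to membership of a finite cylinder with spherical end caps; for a bent
tube the two differ, which is exactly the counting artifact the ring
method exhibits on flexible nanotubes.

Distances use the minimum-image convention on the orthorhombic box when
``periodic`` is set.  Centres of mass of molecules that straddle a
periodic boundary are computed after unwrapping relative to the first
atom, so wrapped and unwrapped inputs give identical statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .kinetics import InputError

__all__ = [
    "Molecule",
    "Configuration",
    "NanotubeModel",
    "ClusterAssignment",
    "AdsorptionSummary",
    "DEFAULT_CUTOFF_NM",
    "read_configuration",
    "write_configuration",
    "cluster_molecules",
    "aggregate_stats",
    "percent_adsorbed",
    "inside_molecules",
    "percent_inside_ring_method",
    "summarize",
]

# Standard heavy-atom contact criterion for aggregate detection.
DEFAULT_CUTOFF_NM = 0.35


@dataclass(frozen=True)
class Molecule:
    """A ligand molecule: atom coordinates (nm) and masses."""

    coords: np.ndarray  # (k, 3)
    masses: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        m = np.atleast_1d(np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "masses", m)
        if c.shape[0] == 0 or c.shape[1] != 3 or m.shape[0] != c.shape[0]:
            raise InputError("molecule needs non-empty (k,3) coords, (k,) masses")
        if np.any(m <= 0):
            raise InputError("atom masses must be positive")


@dataclass(frozen=True)
class Configuration:
    """Boxed coordinates of a nanotube plus ligand molecules."""

    box: np.ndarray  # three orthorhombic edge lengths, nm
    cnt_atoms: np.ndarray  # (N, 3) nm; empty allowed
    ligand_molecules: tuple[Molecule, ...]
    periodic: bool = True
    cnt_masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        cnt = np.asarray(self.cnt_atoms, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "cnt_atoms", cnt)
        object.__setattr__(self, "ligand_molecules",
                           tuple(self.ligand_molecules))
        if box.shape != (3,) or np.any(box <= 0):
            raise InputError("box must be three positive edge lengths")
        if self.cnt_masses is None:
            object.__setattr__(self, "cnt_masses",
                               np.full(cnt.shape[0], 12.011))
        else:
            m = np.asarray(self.cnt_masses, dtype=float)
            if m.shape[0] != cnt.shape[0]:
                raise InputError("cnt_masses length mismatch")
            object.__setattr__(self, "cnt_masses", m)

    @property
    def n_molecules(self) -> int:
        return len(self.ligand_molecules)

    def molecule_com(self, i: int) -> np.ndarray:
        mol = self.ligand_molecules[i]
        return _com(mol.coords, mol.masses, self.box, self.periodic)

    def molecule_coms(self) -> np.ndarray:
        if not self.ligand_molecules:
            return np.empty((0, 3))
        return np.array([self.molecule_com(i)
                         for i in range(self.n_molecules)])


@dataclass(frozen=True)
class NanotubeModel:
    """Geometric tube model: axis, nominal dimensions, ring partition."""

    axis_point: np.ndarray  # anchor on the axis (one tube end), nm
    axis_dir: np.ndarray  # unit vector along the axis
    diameter: float  # nm (outermost wall for multi-wall tubes)
    length: float  # nm
    walls: int
    # ordered groups of cnt_atoms indices, one per axial carbon ring
    ring_partition: tuple[np.ndarray, ...] = field(default=())

    def __post_init__(self) -> None:
        p = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise InputError("axis direction must be non-zero")
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_dir", d / norm)
        object.__setattr__(
            self, "ring_partition",
            tuple(np.asarray(g, dtype=int) for g in self.ring_partition),
        )
        if self.diameter <= 0 or self.length <= 0 or self.walls < 1:
            raise InputError("tube dimensions must be positive")


@dataclass(frozen=True)
class ClusterAssignment:
    """Single-linkage partition of ligand molecules (plus the nanotube)."""

    labels: np.ndarray  # molecule index -> cluster id
    includes_cnt: int | None  # cluster id containing the nanotube
    n_clusters: int
    sizes: np.ndarray  # cluster id -> molecule count


@dataclass(frozen=True)
class AdsorptionSummary:
    """Headline statistics of one configuration."""

    pct_adsorbed: float
    pct_inside: float
    n_aggregates: int
    mean_aggregate_size: float


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _com(coords: np.ndarray, masses: np.ndarray, box: np.ndarray,
         periodic: bool) -> np.ndarray:
    """Mass-weighted centre of mass, unwrapping across the boundary."""
    if not periodic:
        return np.average(coords, axis=0, weights=masses)
    rel = _min_image(coords - coords[0], box)
    return coords[0] + np.average(rel, axis=0, weights=masses)


# ---------------------------------------------------------------------------
# Aggregate detection
# ---------------------------------------------------------------------------

def cluster_molecules(config: Configuration,
                      cutoff: float = DEFAULT_CUTOFF_NM) -> ClusterAssignment:
    """Single-linkage contact clustering of molecules and the nanotube.

    Two molecules (or a molecule and the nanotube) are linked iff any
    inter-atomic distance is strictly below ``cutoff``, with
    minimum-image distances when the configuration is periodic.  Cluster
    ids are assigned in order of each cluster's lowest molecule index,
    so the labelling is deterministic.  Cluster sizes count ligand
    molecules only; ``includes_cnt`` is None when no molecule touches
    the nanotube.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    n_mol = config.n_molecules
    if n_mol == 0:
        return ClusterAssignment(np.empty(0, dtype=int), None, 0,
                                 np.empty(0, dtype=int))
    box = config.box
    if config.periodic and cutoff > box.min() / 2:
        raise InputError("cutoff exceeds half the smallest box edge")

    coords = [m.coords for m in config.ligand_molecules]
    owner = np.concatenate(
        [np.full(c.shape[0], i) for i, c in enumerate(coords)]
    )
    has_cnt = config.cnt_atoms.shape[0] > 0
    cnt_node = n_mol  # pseudo-molecule node for the nanotube
    if has_cnt:
        coords.append(config.cnt_atoms)
        owner = np.concatenate(
            [owner, np.full(config.cnt_atoms.shape[0], cnt_node)]
        )
    pts = np.concatenate(coords)

    if config.periodic:
        wrapped = np.mod(pts, box)
        # np.mod can land exactly on the upper face for tiny negatives
        wrapped = np.where(wrapped >= box, wrapped - box, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        wrapped = pts
        tree = cKDTree(wrapped)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        # query_pairs uses <=; the contact criterion is strict
        d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
        if config.periodic:
            d = _min_image(d, box)
        keep = np.einsum("ij,ij->i", d, d) < cutoff**2
        pairs = pairs[keep]

    n_nodes = n_mol + (1 if has_cnt else 0)
    if pairs.size:
        i, j = owner[pairs[:, 0]], owner[pairs[:, 1]]
        mask = i != j
        graph = coo_matrix(
            (np.ones(mask.sum()), (i[mask], j[mask])),
            shape=(n_nodes, n_nodes),
        )
    else:
        graph = coo_matrix((n_nodes, n_nodes))
    _, comp = connected_components(graph, directed=False)

    mol_comp = comp[:n_mol]
    cnt_comp = comp[cnt_node] if has_cnt else None
    # order clusters by their lowest molecule index; drop a CNT-only one
    order: dict[int, int] = {}
    for m in range(n_mol):
        order.setdefault(mol_comp[m], len(order))
    labels = np.array([order[c] for c in mol_comp], dtype=int)
    n_clusters = len(order)
    sizes = np.bincount(labels, minlength=n_clusters)
    includes = None
    if cnt_comp is not None and cnt_comp in order:
        includes = order[cnt_comp]
    return ClusterAssignment(labels, includes, n_clusters, sizes)


def aggregate_stats(assignment: ClusterAssignment,
                    count_cnt_cluster: bool = True) -> tuple[int, float]:
    """Number of aggregates and mean molecules per aggregate.

    With ``count_cnt_cluster`` (default, matching the convention of
    counting the nanotube + ligand complex as one aggregate) the
    nanotube-containing cluster enters both statistics; otherwise it is
    excluded from both.
    """
    sizes = assignment.sizes
    if not count_cnt_cluster and assignment.includes_cnt is not None:
        sizes = np.delete(sizes, assignment.includes_cnt)
    n = int(sizes.size)
    return n, float(sizes.mean()) if n else 0.0


def percent_adsorbed(config: Configuration,
                     assignment: ClusterAssignment) -> float:
    """Percentage of ligand molecules in the nanotube-containing cluster."""
    n = config.n_molecules
    if n == 0 or assignment.includes_cnt is None:
        return 0.0
    return 100.0 * float(assignment.sizes[assignment.includes_cnt]) / n


# ---------------------------------------------------------------------------
# Inside-tube counting (ring / virtual-sphere method)
# ---------------------------------------------------------------------------

def ring_centers(config: Configuration, tube: NanotubeModel) -> np.ndarray:
    """Centre of mass of each axial carbon ring; empty rings are skipped."""
    centers = []
    for k, idx in enumerate(tube.ring_partition):
        if idx.size == 0:
            warnings.warn(f"ring {k} has no atoms; skipped", stacklevel=2)
            continue
        centers.append(_com(config.cnt_atoms[idx], config.cnt_masses[idx],
                            config.box, config.periodic))
    if not centers:
        raise InputError("tube has no non-empty rings")
    return np.array(centers)


def inside_molecules(config: Configuration, tube: NanotubeModel,
                     sphere_radius: float | None = None) -> np.ndarray:
    """Boolean mask over molecules counted inside the tube.

    A molecule is inside when its centre of mass lies strictly within
    ``sphere_radius`` of the centre of mass of any axial carbon ring
    (duplicates across rings collapse in the mask).  The default radius
    is half the tube diameter, i.e. the tube's own radius.
    """
    if sphere_radius is None:
        sphere_radius = tube.diameter / 2.0
    if sphere_radius <= 0:
        raise InputError("sphere radius must be positive")
    n = config.n_molecules
    if n == 0:
        return np.zeros(0, dtype=bool)
    centers = ring_centers(config, tube)
    coms = config.molecule_coms()
    if config.periodic:
        box = config.box
        c = np.mod(centers, box)
        c = np.where(c >= box, c - box, c)
        q = np.mod(coms, box)
        q = np.where(q >= box, q - box, q)
        tree = cKDTree(c, boxsize=box)
    else:
        tree = cKDTree(centers)
        q = coms
    dist, _ = tree.query(q, k=1)
    return dist < sphere_radius


def percent_inside_ring_method(config: Configuration, tube: NanotubeModel,
                               sphere_radius: float | None = None) -> float:
    """Percentage of all ligand molecules inside the tube (ring method)."""
    n = config.n_molecules
    if n == 0:
        return 0.0
    return 100.0 * float(inside_molecules(config, tube,
                                          sphere_radius).sum()) / n


def summarize(config: Configuration, cutoff: float = DEFAULT_CUTOFF_NM,
              tube: NanotubeModel | None = None,
              sphere_radius: float | None = None,
              count_cnt_cluster: bool = True) -> AdsorptionSummary:
    """Compose the four headline statistics of a configuration.

    ``pct_inside`` counts molecules that are both adsorbed (member of
    the nanotube-containing cluster) and geometrically inside the tube,
    as a percentage of all ligand molecules, so that
    ``pct_inside <= pct_adsorbed`` always holds.
    """
    assignment = cluster_molecules(config, cutoff)
    n_agg, mean_size = aggregate_stats(assignment, count_cnt_cluster)
    pct_ads = percent_adsorbed(config, assignment)
    pct_in = 0.0
    n = config.n_molecules
    if tube is not None and n > 0 and assignment.includes_cnt is not None:
        inside = inside_molecules(config, tube, sphere_radius)
        adsorbed = assignment.labels == assignment.includes_cnt
        pct_in = 100.0 * float(np.sum(inside & adsorbed)) / n
    return AdsorptionSummary(pct_ads, pct_in, n_agg, mean_size)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _molecule_map_from(obj) -> dict:
    if obj is None:
        raise InputError("XYZ configurations need a molecule map")
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            return json.load(fh)
    return dict(obj)


def read_configuration(path, format: str | None = None,
                       molecule_map=None, periodic: bool = True,
                       default_mass: float = 1.0) -> Configuration:
    """Read a boxed configuration from an XYZ or GRO file.

    XYZ: coordinates in nm; the comment line carries the box as
    ``box=Lx,Ly,Lz``; atom-to-molecule grouping comes from a JSON
    sidecar/dict with keys ``cnt`` (atom indices of the nanotube) and
    ``molecules`` (list of atom-index lists), optionally ``masses``
    (per-atom).  GRO (read through MDAnalysis, native nm): the residue
    named ``CNT`` is the nanotube and every other residue is one ligand
    molecule.  Ligand atoms default to unit mass — the statistics here
    depend on coordinates, not chemistry — unless masses are supplied
    in the sidecar.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "xyz":
        return _read_xyz(path, molecule_map, periodic, default_mass)
    if format == "gro":
        return _read_gro(path, periodic, default_mass)
    raise InputError(f"unknown configuration format {format!r}")


def _read_xyz(path: Path, molecule_map, periodic: bool,
              default_mass: float) -> Configuration:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise InputError(f"{path}: truncated XYZ (line 1)")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise InputError(f"{path}: bad atom count (line 1)") from None
    comment = lines[1]
    box = None
    for token in comment.replace(";", " ").split():
        if token.startswith("box="):
            try:
                box = [float(x) for x in
                       token[4:].rstrip("nm").rstrip(",").split(",")]
            except ValueError:
                raise InputError(f"{path}: bad box tag (line 2)") from None
    if box is None or len(box) != 3:
        raise InputError(f"{path}: comment line must carry box=Lx,Ly,Lz")
    if len(lines) < 2 + n_atoms:
        raise InputError(f"{path}: expected {n_atoms} atom lines")
    coords = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise InputError(f"{path}: malformed atom record (line {i + 3})")
        try:
            coords[i] = [float(x) for x in parts[1:4]]
        except ValueError:
            raise InputError(
                f"{path}: non-numeric coordinate (line {i + 3})"
            ) from None
    mm = _molecule_map_from(molecule_map)
    cnt_idx = np.asarray(mm.get("cnt", []), dtype=int)
    mol_groups = [np.asarray(g, dtype=int) for g in mm.get("molecules", [])]
    masses = np.asarray(mm["masses"], dtype=float) if "masses" in mm \
        else np.full(n_atoms, default_mass)
    claimed = np.concatenate([cnt_idx] + mol_groups) if (
        cnt_idx.size or mol_groups) else np.empty(0, dtype=int)
    if np.unique(claimed).size != claimed.size:
        raise InputError("molecule map assigns an atom twice")
    if claimed.size != n_atoms:
        missing = sorted(set(range(n_atoms)) - set(claimed.tolist()))
        raise InputError(f"unmapped atom indices: {missing[:5]}...")
    mols = [Molecule(coords[g], masses[g]) for g in mol_groups]
    return Configuration(np.array(box), coords[cnt_idx], mols, periodic,
                         cnt_masses=masses[cnt_idx] if cnt_idx.size else None)


def _read_gro(path: Path, periodic: bool,
              default_mass: float) -> Configuration:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path), to_guess=())
    box = u.dimensions[:3] / 10.0  # MDAnalysis uses Angstrom
    coords = u.atoms.positions / 10.0
    cnt_idx: list[int] = []
    mols: list[Molecule] = []
    for res in u.residues:
        idx = res.atoms.ix
        if res.resname.strip().upper() == "CNT":
            cnt_idx.extend(idx.tolist())
        else:
            mols.append(Molecule(coords[idx],
                                 np.full(len(idx), default_mass)))
    return Configuration(np.array(box), coords[np.array(cnt_idx, dtype=int)],
                         mols, periodic)


def write_configuration(config: Configuration, path,
                        format: str | None = None) -> None:
    """Write a configuration to XYZ (+ JSON molecule-map sidecar) or GRO."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "xyz":
        _write_xyz(config, path)
    elif format == "gro":
        _write_gro(config, path)
    else:
        raise InputError(f"unknown configuration format {format!r}")


def _write_xyz(config: Configuration, path: Path) -> None:
    n_cnt = config.cnt_atoms.shape[0]
    total = n_cnt + sum(m.coords.shape[0] for m in config.ligand_molecules)
    bx, by, bz = config.box
    lines = [str(total), f"box={bx},{by},{bz} nm"]
    for xyz in config.cnt_atoms:
        lines.append("C {:.6f} {:.6f} {:.6f}".format(*xyz))
    masses = list(config.cnt_masses)
    for m in config.ligand_molecules:
        for xyz in m.coords:
            lines.append("L {:.6f} {:.6f} {:.6f}".format(*xyz))
        masses.extend(m.masses.tolist())
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "cnt": list(range(n_cnt)),
        "molecules": [],
        "masses": masses,
    }
    start = n_cnt
    for m in config.ligand_molecules:
        k = m.coords.shape[0]
        sidecar["molecules"].append(list(range(start, start + k)))
        start += k
    Path(str(path) + ".molmap.json").write_text(json.dumps(sidecar))


def _write_gro(config: Configuration, path: Path) -> None:
    import MDAnalysis as mda

    n_cnt = config.cnt_atoms.shape[0]
    n_res = (1 if n_cnt else 0) + len(config.ligand_molecules)
    counts = ([n_cnt] if n_cnt else []) + \
        [m.coords.shape[0] for m in config.ligand_molecules]
    total = sum(counts)
    resindices = np.repeat(np.arange(n_res), counts)
    u = mda.Universe.empty(total, n_residues=n_res,
                           atom_resindex=resindices, trajectory=True)
    names = ["C"] * n_cnt + ["L"] * (total - n_cnt)
    resnames = (["CNT"] if n_cnt else []) + \
        ["LIG"] * len(config.ligand_molecules)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
    parts = ([config.cnt_atoms] if n_cnt else []) + \
        [m.coords for m in config.ligand_molecules]
    u.atoms.positions = np.concatenate(parts) * 10.0  # nm -> Angstrom
    u.dimensions = [*(config.box * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def infer_tube(config: Configuration,
               ring_spacing: float = 0.213) -> NanotubeModel:
    """Recover a tube model from the nanotube atoms of a configuration.

    The axis is the principal component of the atom cloud, the length
    the axial extent, the diameter twice the smallest radial distance
    (the innermost wall, whose bore governs inside counting), and the
    ring partition bins atoms along the axis with the zigzag ring
    spacing (0.213 nm = 3/2 the C-C bond by default).
    """
    atoms = config.cnt_atoms
    if atoms.shape[0] < 2:
        raise InputError("configuration has no nanotube atoms")
    centroid = atoms.mean(axis=0)
    rel = atoms - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    e = vt[0]
    if e[np.argmax(np.abs(e))] < 0:  # SVD sign is arbitrary; canonicalize
        e = -e
    tau = rel @ e
    lo, hi = float(tau.min()), float(tau.max())
    radial = np.linalg.norm(rel - tau[:, None] * e[None, :], axis=1)
    bins = np.round((tau - lo) / ring_spacing).astype(int)
    partition = tuple(np.flatnonzero(bins == b)
                      for b in range(bins.max() + 1))
    return NanotubeModel(
        axis_point=centroid + lo * e, axis_dir=e,
        diameter=2.0 * float(radial.min()), length=hi - lo,
        walls=1, ring_partition=partition,
    )


def analyze_frames(configs: Sequence[Configuration],
                   cutoff: float = DEFAULT_CUTOFF_NM,
                   tube: NanotubeModel | None = None,
                   sphere_radius: float | None = None,
                   count_cnt_cluster: bool = True):
    """Per-frame summary table: one row per configuration.

    Returns a pandas DataFrame with columns frame, n_aggregates,
    mean_size, pct_adsorbed, pct_inside.
    """
    import pandas as pd

    rows = []
    for i, cfg in enumerate(configs):
        s = summarize(cfg, cutoff, tube, sphere_radius, count_cnt_cluster)
        rows.append((i, s.n_aggregates, s.mean_aggregate_size,
                     s.pct_adsorbed, s.pct_inside))
    return pd.DataFrame(rows, columns=["frame", "n_aggregates", "mean_size",
                                       "pct_adsorbed", "pct_inside"])
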