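import numpy as np
import pytest

from nanorelease import Configuration, Molecule

STANDARD_TIMES = np.array([1.0, 3.0, 5.0, 10.0, 20.0, 30.0])


@pytest.fixture
def times():
    """The shaken-release sampling grid, minutes."""
    return STANDARD_TIMES.copy()


def random_configuration(rng, n_molecules, box=(12.0, 12.0, 12.0),
                         beads=3, spacing=0.25, cnt_atoms=None):
    """Uniformly scattered bead-chain molecules in a periodic box."""
    box = np.asarray(box, dtype=float)
    mols = []
    for _ in range(n_molecules):
        start = rng.uniform(0, 1, 3) * box
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        coords = start + np.arange(beads)[:, None] * spacing * d
        mols.append(Molecule(coords, np.ones(beads)))
    cnt = np.empty((0, 3)) if cnt_atoms is None else cnt_atoms
    return Configuration(box, cnt, mols, periodic=True)


def brute_force_partition(config, cutoff):
    """O(N^2) union-find single-linkage oracle over molecules + nanotube.

    Returns (labels, cnt_cluster) with the same deterministic labelling
    convention as cluster_molecules: ids ordered by lowest molecule
    index, nanotube-only components dropped.
    """
    box = config.box
    n_mol = config.n_molecules
    groups = [m.coords for m in config.ligand_molecules]
    has_cnt = config.cnt_atoms.shape[0] > 0
    if has_cnt:
        groups.append(config.cnt_atoms)
    n = len(groups)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # dense all-pairs atom distances over ligand atoms -> molecule
    # adjacency -> union-find; molecule-vs-nanotube contacts separately
    # (the tube can carry tens of thousands of atoms)
    def mi(d):
        if config.periodic:
            d = d - box * np.round(d / box)
        return d

    pts = np.concatenate(groups[:n_mol])
    owner = np.concatenate([np.full(g.shape[0], i)
                            for i, g in enumerate(groups[:n_mol])])
    contact = np.sum(mi(pts[:, None, :] - pts[None, :, :]) ** 2,
                     axis=-1) < cutoff**2
    ii, jj = np.nonzero(contact)
    mol_pairs = np.unique(
        np.sort(np.stack([owner[ii], owner[jj]], axis=1), axis=1), axis=0)
    for i, j in mol_pairs:
        if i != j:
            union(int(i), int(j))
    if has_cnt:
        cnt = groups[-1]
        for m in range(n_mol):
            d2 = np.sum(mi(groups[m][:, None, :] - cnt[None, :, :]) ** 2,
                        axis=-1)
            if np.any(d2 < cutoff**2):  # strict, as in the implementation
                union(m, n - 1)

    order = {}
    for m in range(n_mol):
        order.setdefault(find(m), len(order))
    labels = np.array([order[find(m)] for m in range(n_mol)], dtype=int)
    cnt_cluster = None
    if has_cnt and find(n - 1) in order:
        cnt_cluster = order[find(n - 1)]
    return labels, cnt_cluster


def capsule_oracle(config, tube, radius=None):
    """Analytic inside-tube membership against the *nominal* straight
    axis: molecule COM within ``radius`` of the axis segment (finite
    cylinder with spherical end caps).  For an ideal straight tube the
    ring centres lie exactly on this segment; for a bent tube they do
    not, which is the ring method's counting artifact."""
    if radius is None:
        radius = tube.diameter / 2.0
    a = tube.axis_point
    ab = tube.axis_dir * tube.length
    denom = float(ab @ ab)
    out = np.zeros(config.n_molecules, dtype=bool)
    for i in range(config.n_molecules):
        p = config.molecule_com(i)
        t = float((p - a) @ ab) / denom
        t = min(max(t, 0.0), 1.0)
        out[i] = np.linalg.norm(p - (a + t * ab)) < radius
    return out
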