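"""Periodic crystal model, torsion geometry, H-bond motifs and disorder models.

The central object is :class:`Crystal`: a P1 periodic cell with fractional
coordinates and a partition of sites into molecular units.  Molecules are
inferred from a covalent-radius bond graph unless supplied.  All distance
work happens in Cartesian space via the cell matrix with the minimum-image
convention; coordinates are stored fractionally and wrapped into [0, 1).

Torsions follow the IUPAC sign convention (right-hand rule, cis = 0°) and
are reported in (−180°, 180°].  ``set_torsion`` rotates only the atoms on
the distal side of the B–C bond, leaving every other internal coordinate
untouched, which is what a constrained-dihedral scan or a disorder-model
build requires.

The disorder generator reproduces the dispersed-disorder protocol used for
thiol-disordered amino-acid crystals: a random half (or any fraction) of
the C–C–S–H torsions is set to one hydrogen-bond-motif angle and the rest
to the other.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .elements import BOND_TOLERANCE, COVALENT_RADIUS, KNOWN_ELEMENTS, mass_of
from .errors import (
    ConfigurationError,
    ElementError,
    InvalidDonorError,
    TopologyError,
    UndefinedDihedralError,
)

__all__ = [
    "Crystal",
    "TorsionSpec",
    "ConformerLabel",
    "DisorderPlan",
    "lattice_from_parameters",
    "lattice_parameters",
    "cell_volume",
    "measure_torsion",
    "set_torsion",
    "build_supercell",
    "classify_sh_motif",
    "generate_disorder_model",
    "backbone_label",
]


# --------------------------------------------------------------------------
# lattice helpers

def lattice_from_parameters(a, b, c, alpha, beta, gamma):
    """Cell matrix (rows = lattice vectors, Å) from lengths and angles (°).

    Standard crystallographic construction: **a** along x, **b** in the
    x–y plane.
    """
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise ValueError("inconsistent lattice parameters (negative c_z²)")
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * math.cos(ga), b * math.sin(ga), 0.0],
            [cx, cy, math.sqrt(cz2)],
        ]
    )


def lattice_parameters(matrix):
    """(a, b, c, α, β, γ) in Å and degrees from a cell matrix."""
    m = np.asarray(matrix, dtype=float)
    a, b, c = (np.linalg.norm(v) for v in m)
    alpha = math.degrees(math.acos(np.dot(m[1], m[2]) / (b * c)))
    beta = math.degrees(math.acos(np.dot(m[0], m[2]) / (a * c)))
    gamma = math.degrees(math.acos(np.dot(m[0], m[1]) / (a * b)))
    return a, b, c, alpha, beta, gamma


def cell_volume(a, b, c, alpha, beta, gamma):
    """Unit-cell volume (Å³) from lattice parameters, closed form.

    V = abc √(1 − cos²α − cos²β − cos²γ + 2 cosα cosβ cosγ)
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    return a * b * c * math.sqrt(
        1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    )


def wrap_angle(angle):
    """Wrap an angle in degrees into (−180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class TorsionSpec:
    """Four ordered site ids A–B–C–D defining a dihedral; B–C is the axis."""

    a: int
    b: int
    c: int
    d: int
    minimum_image: bool = True

    def __post_init__(self):
        if len({self.a, self.b, self.c, self.d}) != 4:
            raise ConfigurationError("torsion sites must be four distinct ids")

    @property
    def ids(self):
        return (self.a, self.b, self.c, self.d)


BACKBONE_LABELS = ("g+", "g-", "t")
MOTIF_SS = "SH...S"
MOTIF_SO = "SH...O"
MOTIF_NONE = "none"
MOTIF_LABELS = (MOTIF_SS, MOTIF_SO, MOTIF_NONE)


@dataclass(frozen=True)
class ConformerLabel:
    """Backbone conformer (N–C–C–S) and thiol hydrogen-bond motif."""

    backbone: str
    motif: str

    def __post_init__(self):
        if self.backbone not in BACKBONE_LABELS:
            raise ConfigurationError(f"backbone label {self.backbone!r}")
        if self.motif not in MOTIF_LABELS:
            raise ConfigurationError(f"motif label {self.motif!r}")


def backbone_label(angle):
    """g+/g−/t label of a backbone torsion: ±gauche near ±60°, trans near 180°."""
    a = wrap_angle(angle)
    if abs(a) > 120.0:
        return "t"
    return "g+" if a > 0 else "g-"


@dataclass(frozen=True)
class DisorderPlan:
    """Record of a dispersed-disorder build: which torsion got which angle."""

    assignments: tuple  # of (TorsionSpec, angle °)
    seed: int
    fraction: float

    @property
    def n_at(self):
        """Counts per assigned angle value."""
        counts: dict[float, int] = {}
        for _, ang in self.assignments:
            counts[ang] = counts.get(ang, 0) + 1
        return counts


@dataclass
class Crystal:
    """A P1 periodic crystal: cell matrix, sites, molecular partition.

    Parameters
    ----------
    lattice : (3, 3) array
        Rows are the lattice vectors in Å.
    symbols : list of str
        Element symbol per site.
    frac_coords : (N, 3) array
        Fractional coordinates; wrapped into [0, 1) on construction.
    molecules : list of list of int, optional
        Partition of site indices into molecular units.  Inferred from the
        covalent bond graph when omitted.
    pressure_tag : float, optional
        External pressure (GPa) this geometry corresponds to.
    """

    lattice: np.ndarray
    symbols: list
    frac_coords: np.ndarray
    molecules: list | None = None
    pressure_tag: float | None = None
    provenance: str = ""

    def __post_init__(self):
        self.lattice = np.array(self.lattice, dtype=float)
        if self.lattice.shape != (3, 3):
            raise ConfigurationError("lattice must be a 3×3 matrix")
        if self.volume <= 0:
            raise ConfigurationError("cell volume must be positive")
        self.symbols = list(self.symbols)
        for s in self.symbols:
            if s not in KNOWN_ELEMENTS:
                raise ElementError(f"unknown element symbol {s!r}")
        self.frac_coords = np.array(self.frac_coords, dtype=float) % 1.0
        self.frac_coords[self.frac_coords >= 1.0] = 0.0  # guard 0.9999…%1
        if self.frac_coords.shape != (len(self.symbols), 3):
            raise ConfigurationError("frac_coords must be N×3")
        if self.molecules is not None:
            self.molecules = [list(m) for m in self.molecules]
            seen = sorted(i for m in self.molecules for i in m)
            if seen != list(range(len(self.symbols))):
                raise ConfigurationError(
                    "molecular partition must cover every site exactly once"
                )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_sites(self):
        return len(self.symbols)

    @property
    def volume(self):
        return float(abs(np.linalg.det(self.lattice)))

    @property
    def masses(self):
        return np.array([mass_of(s) for s in self.symbols])

    def cart_coords(self):
        """Cartesian coordinates (Å), wrapped images."""
        return self.frac_coords @ self.lattice

    def mic_vector(self, i, j):
        """Minimum-image Cartesian vector from site i to site j (Å)."""
        df = self.frac_coords[j] - self.frac_coords[i]
        df -= np.round(df)
        return df @ self.lattice

    def distance(self, i, j):
        return float(np.linalg.norm(self.mic_vector(i, j)))

    # -- bond graph and molecules -------------------------------------------

    def bond_graph(self):
        """Adjacency sets from covalent radii (minimum image)."""
        n = self.n_sites
        radii = np.array([COVALENT_RADIUS[s] for s in self.symbols])
        adj = [set() for _ in range(n)]
        # minimum-image pair scan; cells here are small enough for O(N²)
        frac = self.frac_coords
        for i in range(n):
            df = frac[i + 1 :] - frac[i]
            df -= np.round(df)
            d = np.linalg.norm(df @ self.lattice, axis=1)
            cut = BOND_TOLERANCE * (radii[i] + radii[i + 1 :])
            for k in np.nonzero(d < cut)[0]:
                j = i + 1 + int(k)
                adj[i].add(j)
                adj[j].add(i)
        return adj

    def infer_molecules(self):
        """Connected components of the bond graph, as sorted index lists."""
        adj = self.bond_graph()
        seen = [False] * self.n_sites
        mols = []
        for start in range(self.n_sites):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in adj[i]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
            mols.append(sorted(comp))
        return mols

    def get_molecules(self):
        if self.molecules is None:
            self.molecules = self.infer_molecules()
        return self.molecules

    def molecule_of(self, i):
        for k, mol in enumerate(self.get_molecules()):
            if i in mol:
                return k
        raise ConfigurationError(f"site {i} not in any molecule")

    def unwrapped_molecule_coords(self, mol_index):
        """Cartesian coordinates of one molecule made whole across boundaries.

        BFS from the first site, placing each neighbour at its minimum-image
        position relative to the already-placed atom.
        """
        mol = self.get_molecules()[mol_index]
        adj = self.bond_graph()
        pos = {mol[0]: self.frac_coords[mol[0]] @ self.lattice}
        queue = [mol[0]]
        while queue:
            i = queue.pop(0)
            for j in adj[i]:
                if j in pos or j not in mol:
                    continue
                pos[j] = pos[i] + self.mic_vector(i, j)
                queue.append(j)
        for j in mol:  # isolated sites (no bonds) fall back to wrapped position
            pos.setdefault(j, self.frac_coords[j] @ self.lattice)
        return pos

    def copy(self):
        return copy.deepcopy(self)


# --------------------------------------------------------------------------
# torsion geometry

def _dihedral_from_points(p0, p1, p2, p3):
    """Signed dihedral (°) of four Cartesian points, IUPAC convention, cis = 0."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise UndefinedDihedralError("zero-length central bond")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise UndefinedDihedralError("collinear atoms make the dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def _torsion_points(crystal: Crystal, spec: TorsionSpec):
    """Unwrapped Cartesian positions of the four torsion atoms."""
    ids = spec.ids
    for i in ids:
        if not (0 <= i < crystal.n_sites):
            raise ConfigurationError(f"torsion site {i} out of range")
    p = [crystal.frac_coords[ids[0]] @ crystal.lattice]
    if spec.minimum_image:
        for prev, cur in zip(ids[:-1], ids[1:]):
            p.append(p[-1] + crystal.mic_vector(prev, cur))
    else:
        p = [crystal.frac_coords[i] @ crystal.lattice for i in ids]
    return [np.asarray(q, dtype=float) for q in p]


def measure_torsion(crystal: Crystal, spec: TorsionSpec) -> float:
    """Signed dihedral angle A–B–C–D in degrees, in (−180, 180]."""
    return _dihedral_from_points(*_torsion_points(crystal, spec))


def _distal_set(crystal: Crystal, spec: TorsionSpec):
    """Sites that rotate when the B–C torsion changes: the C-side component
    of the bond graph with the B–C edge removed (C itself lies on the axis
    and is formally invariant, but is included for bookkeeping)."""
    adj = [set(s) for s in crystal.bond_graph()]
    b, c = spec.b, spec.c
    adj[b].discard(c)
    adj[c].discard(b)
    seen = {c}
    stack = [c]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if b in seen:
        raise TopologyError(
            "B–C bond lies in a ring; rotating the torsion would split it"
        )
    return seen


def set_torsion(crystal: Crystal, spec: TorsionSpec, target: float) -> Crystal:
    """Return a copy with the A–B–C–D dihedral set to *target* degrees.

    Only atoms distal to the B–C bond (the D side) move; they are rotated
    rigidly about the B→C axis, so bond lengths and angles not involving
    the rotation are preserved exactly.
    """
    target = wrap_angle(target)
    current = measure_torsion(crystal, spec)
    delta = wrap_angle(target - current)
    if delta == 0.0:
        return crystal.copy()
    moving = _distal_set(crystal, spec)

    # unwrapped Cartesian frame anchored at B
    mol_idx = crystal.molecule_of(spec.b)
    pos = crystal.unwrapped_molecule_coords(mol_idx)
    if spec.c not in pos:
        raise TopologyError("torsion axis atoms are not in one molecule")
    axis = pos[spec.c] - pos[spec.b]
    axis = axis / np.linalg.norm(axis)
    # Right-hand rotation of the D side about B→C by +delta increases the
    # IUPAC dihedral by +delta.
    rot = Rotation.from_rotvec(np.radians(delta) * axis)

    out = crystal.copy()
    origin = pos[spec.b]
    inv = np.linalg.inv(crystal.lattice)
    for i in moving:
        if i not in pos:
            continue
        new_cart = rot.apply(pos[i] - origin) + origin
        out.frac_coords[i] = (new_cart @ inv) % 1.0
    out.molecules = None if crystal.molecules is None else [
        list(m) for m in crystal.get_molecules()
    ]
    achieved = measure_torsion(out, spec)
    if abs(wrap_angle(achieved - target)) > 1e-6:
        raise TopologyError(
            f"torsion rotation failed to reach target ({achieved} vs {target})"
        )
    return out


# --------------------------------------------------------------------------
# supercell

def build_supercell(crystal: Crystal, multipliers) -> Crystal:
    """Replicate the cell by integer multipliers (n1, n2, n3).

    The molecular partition is replicated image by image; volume and site
    count scale exactly by n1·n2·n3.
    """
    n1, n2, n3 = (int(m) for m in multipliers)
    if min(n1, n2, n3) < 1:
        raise ConfigurationError("supercell multipliers must be ≥ 1")
    if (n1, n2, n3) == (1, 1, 1):
        return crystal.copy()
    mols = crystal.get_molecules()
    n = crystal.n_sites
    new_lattice = crystal.lattice * np.array([[n1], [n2], [n3]], dtype=float)
    symbols, fracs, new_mols = [], [], []
    image = 0
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                shift = np.array([i, j, k], dtype=float)
                scale = np.array([n1, n2, n3], dtype=float)
                fracs.append((crystal.frac_coords + shift) / scale)
                symbols.extend(crystal.symbols)
                for mol in mols:
                    new_mols.append([image * n + s for s in mol])
                image += 1
    return Crystal(
        lattice=new_lattice,
        symbols=symbols,
        frac_coords=np.vstack(fracs),
        molecules=new_mols,
        pressure_tag=crystal.pressure_tag,
        provenance=f"{crystal.provenance} supercell {n1}x{n2}x{n3}".strip(),
    )


# --------------------------------------------------------------------------
# hydrogen-bond motif classification

@dataclass(frozen=True)
class MotifResult:
    motif: str
    acceptor: int | None
    distance: float | None


def _image_range(lattice, cutoff):
    """Per-axis image count needed to cover a Cartesian cutoff sphere."""
    inv = np.linalg.inv(lattice)
    heights = 1.0 / np.linalg.norm(inv, axis=0)  # perpendicular cell heights
    return [int(math.ceil(cutoff / h)) + 1 for h in heights]


def classify_sh_motif(
    crystal: Crystal,
    donor_h: int,
    cutoff: float = 3.0,
    acceptors=("S", "O"),
) -> MotifResult:
    """Classify the thiol hydrogen bond of a donor H by its nearest acceptor.

    The motif is the element class (S or O) of the closest eligible acceptor
    within *cutoff* Å of the donor hydrogen, searched over all periodic
    images.  The hydrogen's own covalently bonded sulfur (the specific
    bonded image) is not an eligible acceptor.  Ties at exactly equal
    distance resolve to sulfur.

    Returns ``MotifResult(motif='none', ...)`` when no acceptor is in range.
    """
    if crystal.symbols[donor_h] != "H":
        raise InvalidDonorError(f"site {donor_h} is not a hydrogen")
    adj = crystal.bond_graph()
    bonded_s = [j for j in adj[donor_h] if crystal.symbols[j] == "S"]
    if not bonded_s:
        raise InvalidDonorError(f"H site {donor_h} is not bonded to a sulfur")
    partner = min(bonded_s, key=lambda j: crystal.distance(donor_h, j))

    nmax = _image_range(crystal.lattice, cutoff)
    h_cart = crystal.frac_coords[donor_h] @ crystal.lattice
    best = (math.inf, None, None)  # distance, site, element
    for j, sym in enumerate(crystal.symbols):
        if sym not in acceptors:
            continue
        excluded = math.inf
        if j == partner:
            excluded = crystal.distance(donor_h, j)  # skip the covalent image
        for na in range(-nmax[0], nmax[0] + 1):
            for nb in range(-nmax[1], nmax[1] + 1):
                for nc in range(-nmax[2], nmax[2] + 1):
                    fr = crystal.frac_coords[j] + np.array([na, nb, nc], float)
                    d = float(np.linalg.norm(fr @ crystal.lattice - h_cart))
                    if d > cutoff or (j == donor_h):
                        continue
                    if j == partner and abs(d - excluded) < 1e-9:
                        continue
                    better = d < best[0] - 1e-12 or (
                        abs(d - best[0]) <= 1e-12 and sym == "S" and best[2] == "O"
                    )
                    if better:
                        best = (d, j, sym)
    if best[1] is None:
        return MotifResult(MOTIF_NONE, None, None)
    motif = MOTIF_SS if best[2] == "S" else MOTIF_SO
    return MotifResult(motif, best[1], best[0])


# --------------------------------------------------------------------------
# dispersed-disorder generator

def generate_disorder_model(
    crystal: Crystal,
    torsions,
    angles=(-78.4, 87.0),
    fraction: float = 0.5,
    seed: int = 0,
):
    """Assign one of two motif angles to every listed torsion, at random.

    Exactly ``floor(fraction·N + 0.5)`` torsions (rounded half-up) are set
    to ``angles[0]`` — the "flipped" motif — and the remainder to
    ``angles[1]``.  Which torsions flip is drawn uniformly without
    replacement from ``numpy.random.default_rng(seed)``.

    Returns ``(new_crystal, DisorderPlan)``.
    """
    torsions = list(torsions)
    if len({t.ids for t in torsions}) != len(torsions):
        raise ConfigurationError("duplicate torsion specs in disorder request")
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    n = len(torsions)
    n_flip = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    flipped = set(rng.choice(n, size=n_flip, replace=False).tolist()) if n_flip else set()

    out = crystal.copy()
    assignments = []
    for k, spec in enumerate(torsions):
        ang = angles[0] if k in flipped else angles[1]
        out = set_torsion(out, spec, ang)
        assignments.append((spec, float(ang)))
    plan = DisorderPlan(tuple(assignments), seed=seed, fraction=fraction)
    return out, plan
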