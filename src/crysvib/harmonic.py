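"""Γ-point phonons, mode decomposition, quasi-harmonic stability, torsion profiles.

The dynamical matrix is built from a Cartesian force-constant matrix K
(eV Å⁻², 3N×3N) as D = M^{-1/2} K M^{-1/2}; eigenvalues λ give wavenumbers
ν̃ = 521.47·√λ cm⁻¹ (λ in eV Å⁻² amu⁻¹).  Negative eigenvalues are
reported as imaginary-flagged modes with ν̃ = −521.47·√|λ| and are never
dropped silently.

Vibrational free energies use the harmonic closed form

    F_vib(T) = Σ_k [ ħω_k/2 + k_B T ln(1 − e^{−ħω_k/k_B T}) ]

summed over real, non-acoustic modes.  Relative polymorph stability on a
pressure grid is the per-molecule Gibbs difference
ΔG(P) = Δ[E + P·V(P) + F_vib(T)], with caller-supplied per-pressure
volumes (no equation-of-state fitting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CM1_TO_EV,
    EV_TO_KJMOL,
    GPA_A3_TO_EV,
    KB_EV,
    SQRT_EV_A2_AMU_TO_CM1,
)
from .errors import ConfigurationError
from .structures import Crystal, wrap_angle

__all__ = [
    "PhononModes",
    "FreeEnergyCurve",
    "TorsionProfile",
    "gamma_phonons",
    "enforce_acoustic_sum_rule",
    "decompose_modes",
    "vibrational_free_energy",
    "relative_stability_curves",
    "analyze_torsion_profile",
]

log = logging.getLogger(__name__)

DEFAULT_ACOUSTIC_TOL_CM1 = 0.5


@dataclass
class PhononModes:
    """Γ-point normal modes of one cell.

    frequencies : (3N,) wavenumbers in cm⁻¹, ascending; imaginary modes
        carry negative values and are flagged in ``imaginary``.
    eigenvectors : (3N, 3N) mass-weighted orthonormal displacement patterns,
        one row per mode, reshaped on demand to (N, 3).
    masses : (N,) amu.
    born_charges : (N, 3, 3) Born effective charge tensors (e), optional.
    eps_inf : (3, 3) high-frequency dielectric tensor, optional.
    """

    frequencies: np.ndarray
    eigenvectors: np.ndarray
    masses: np.ndarray
    born_charges: np.ndarray | None = None
    eps_inf: np.ndarray | None = None
    acoustic_tol: float = DEFAULT_ACOUSTIC_TOL_CM1

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n3 = 3 * len(self.masses)
        if self.frequencies.shape != (n3,) or self.eigenvectors.shape != (n3, n3):
            raise ConfigurationError("need 3N frequencies and 3N×3N eigenvectors")
        if self.born_charges is not None:
            self.born_charges = np.asarray(self.born_charges, dtype=float)
        if self.eps_inf is not None:
            self.eps_inf = np.asarray(self.eps_inf, dtype=float)

    @property
    def n_sites(self):
        return len(self.masses)

    @property
    def imaginary(self):
        return self.frequencies < -self.acoustic_tol

    @property
    def acoustic(self):
        return np.abs(self.frequencies) <= self.acoustic_tol

    @property
    def optical(self):
        return ~(self.imaginary | self.acoustic)

    def mode_displacements(self, k):
        """(N, 3) real-space displacement of mode k (eigenvector / √m)."""
        return self.eigenvectors[k].reshape(-1, 3) / np.sqrt(self.masses)[:, None]


def enforce_acoustic_sum_rule(force_constants: np.ndarray) -> np.ndarray:
    """Return a copy with self-terms replaced so rows of 3×3 blocks sum to zero.

    Only the diagonal (self) blocks change:  K_ii ← −Σ_{j≠i} K_ij.  This is
    the translational-invariance condition that guarantees three zero-
    frequency acoustic modes.
    """
    k = np.array(force_constants, dtype=float)
    n3 = k.shape[0]
    n = n3 // 3
    for i in range(n):
        block_sum = np.zeros((3, 3))
        for j in range(n):
            if j != i:
                block_sum += k[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
        k[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = -block_sum
    return k


def gamma_phonons(
    force_constants,
    masses,
    born_charges=None,
    eps_inf=None,
    enforce_sum_rule: bool = True,
    acoustic_tol: float = DEFAULT_ACOUSTIC_TOL_CM1,
    symmetry_tol: float = 1e-8,
) -> PhononModes:
    """Diagonalize the mass-weighted dynamical matrix at Γ.

    Parameters
    ----------
    force_constants : (3N, 3N) array, eV Å⁻², Cartesian, symmetric.
    masses : (N,) amu.
    enforce_sum_rule : replace self-blocks so uniform translation costs
        nothing (default True).

    Returns sorted modes; negative-eigenvalue (imaginary) modes get
    negative wavenumbers and are flagged, never discarded.
    """
    k = np.asarray(force_constants, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n3 = 3 * len(masses)
    if k.shape != (n3, n3):
        raise ConfigurationError("force-constant matrix must be 3N×3N")
    scale = max(1.0, float(np.abs(k).max()))
    if np.abs(k - k.T).max() > symmetry_tol * scale:
        raise ConfigurationError("force-constant matrix is not symmetric")
    k = 0.5 * (k + k.T)
    if enforce_sum_rule:
        k = enforce_acoustic_sum_rule(k)
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    dyn = k / np.outer(sqrt_m, sqrt_m)
    evals, evecs = np.linalg.eigh(dyn)
    freqs = np.sign(evals) * SQRT_EV_A2_AMU_TO_CM1 * np.sqrt(np.abs(evals))
    order = np.argsort(freqs)
    modes = PhononModes(
        frequencies=freqs[order],
        eigenvectors=evecs[:, order].T,
        masses=masses,
        born_charges=None if born_charges is None else born_charges,
        eps_inf=None if eps_inf is None else eps_inf,
        acoustic_tol=acoustic_tol,
    )
    n_im = int(modes.imaginary.sum())
    if n_im:
        log.warning("gamma_phonons: %d imaginary mode(s) flagged", n_im)
    return modes


# --------------------------------------------------------------------------
# rigid-body mode decomposition

def _rigid_body_basis(crystal: Crystal, masses: np.ndarray) -> tuple:
    """Mass-weighted orthonormal rigid-body vectors (translations, rotations).

    Per molecule: 3 centre-of-mass translations and up to 3 rotations about
    the centre of mass (2 for linear molecules, 0 for single atoms), built
    in the mass-weighted coordinate space and orthonormalized.
    """
    n = crystal.n_sites
    trans, rots = [], []
    for mi, mol in enumerate(crystal.get_molecules()):
        pos = crystal.unwrapped_molecule_coords(mi)
        m = masses[mol]
        com = np.sum([masses[i] * pos[i] for i in mol], axis=0) / m.sum()
        for axis in range(3):
            v = np.zeros((n, 3))
            for i in mol:
                v[i, axis] = math.sqrt(masses[i])
            trans.append(v.ravel())
        if len(mol) > 1:
            cand = []
            for axis in np.eye(3):
                v = np.zeros((n, 3))
                for i in mol:
                    v[i] = math.sqrt(masses[i]) * np.cross(axis, pos[i] - com)
                cand.append(v.ravel())
            # drop null/linearly dependent rotations (linear molecules)
            q, r = np.linalg.qr(np.array(cand).T)
            keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
            for col in np.nonzero(keep)[0]:
                rots.append(q[:, col])
    basis = np.array(trans + rots)
    # orthonormalize the whole set (translations of different molecules are
    # already orthogonal; rotations may overlap translations slightly when
    # numerically degenerate)
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10
    q = q[:, keep]
    n_trans = len(trans)
    return q[:, :n_trans], q[:, n_trans:]


def decompose_modes(modes: PhononModes, crystal: Crystal) -> np.ndarray:
    """Translational/rotational/internal character of every mode.

    Returns an array of shape (3N, 3): percentages in [0, 100] summing to
    100, from squared projections onto the per-molecule mass-weighted
    rigid-body subspaces.
    """
    t_basis, r_basis = _rigid_body_basis(crystal, modes.masses)
    out = np.empty((len(modes.frequencies), 3))
    for k, vec in enumerate(modes.eigenvectors):
        pt = float(np.sum((t_basis.T @ vec) ** 2))
        pr = float(np.sum((r_basis.T @ vec) ** 2)) if r_basis.size else 0.0
        norm = float(vec @ vec)
        pi = max(norm - pt - pr, 0.0)
        out[k] = 100.0 * np.array([pt, pr, pi]) / norm
    return out


# --------------------------------------------------------------------------
# free energies

def vibrational_free_energy(
    frequencies_cm1, temperature: float, return_zpe: bool = False
):
    """Harmonic vibrational free energy (eV) of a set of real modes.

    F_vib(T) = Σ_k [ ħω_k/2 + k_B T ln(1 − e^{−ħω_k/k_B T}) ];
    at T = 0 this is exactly the zero-point energy.  The caller is
    responsible for excluding acoustic and imaginary modes (see
    :meth:`PhononModes.optical`); passing any ν̃ ≤ 0 raises.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    freqs = np.asarray(frequencies_cm1, dtype=float)
    if freqs.size and freqs.min() <= 0:
        raise ConfigurationError(
            "free energy needs strictly positive wavenumbers; "
            "filter acoustic/imaginary modes first"
        )
    e = freqs * CM1_TO_EV
    zpe = float(0.5 * e.sum())
    if temperature == 0 or freqs.size == 0:
        f = zpe
    else:
        kt = KB_EV * temperature
        f = zpe + float(kt * np.log1p(-np.exp(-e / kt)).sum())
    return (f, zpe) if return_zpe else f


@dataclass
class PolymorphRecord:
    """Inputs for one polymorph in a stability comparison.

    energy : static lattice energy, eV per cell (per-pressure array or scalar)
    volumes : Å³ per cell on the pressure grid
    modes : PhononModes or plain positive wavenumber array (cm⁻¹); optional
    n_molecules : molecules per cell, for per-molecule normalization
    """

    name: str
    energy: np.ndarray | float
    volumes: np.ndarray | float
    modes: object = None
    n_molecules: int = 1


@dataclass
class FreeEnergyCurve:
    """Relative Gibbs energies on a pressure grid, kJ/mol per molecule."""

    pressures: np.ndarray
    temperature: float
    reference: str
    delta_g: dict  # name -> (nP,) array
    crossovers: list = field(default_factory=list)  # (name_a, name_b, P*)


def _mode_wavenumbers(modes) -> np.ndarray:
    if modes is None:
        return np.array([])
    if isinstance(modes, PhononModes):
        return modes.frequencies[modes.optical]
    return np.asarray(modes, dtype=float)


def relative_stability_curves(
    records,
    reference: str,
    pressures,
    temperature: float,
    include_pv: bool = True,
    include_phonons: bool = True,
) -> FreeEnergyCurve:
    """Per-molecule relative Gibbs energy ΔG(P) of polymorphs vs a reference.

    G(P) = E + P·V(P) + F_vib(T) per cell, normalized per molecule and
    converted to kJ/mol; ``include_pv=False`` gives the Helmholtz-style
    comparison at fixed optimized volumes.  Crossovers between every pair
    of curves are located by sign change with linear interpolation.
    """
    pressures = np.asarray(pressures, dtype=float)
    by_name = {r.name: r for r in records}
    if reference not in by_name:
        raise ConfigurationError(f"reference polymorph {reference!r} not supplied")

    g = {}
    for rec in records:
        e = np.broadcast_to(np.asarray(rec.energy, dtype=float), pressures.shape)
        v = np.broadcast_to(np.asarray(rec.volumes, dtype=float), pressures.shape)
        total = e.copy()
        if include_pv:
            total = total + pressures * v * GPA_A3_TO_EV
        if include_phonons:
            total = total + vibrational_free_energy(
                _mode_wavenumbers(rec.modes), temperature
            )
        g[rec.name] = total * EV_TO_KJMOL / rec.n_molecules

    ref = g[reference]
    delta = {name: gi - ref for name, gi in g.items()}

    crossovers = []
    names = [r.name for r in records]
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            diff = delta[names[ai]] - delta[names[bi]]
            for k in range(len(pressures) - 1):
                if diff[k] == 0.0:
                    crossovers.append((names[ai], names[bi], float(pressures[k])))
                elif diff[k] * diff[k + 1] < 0:
                    frac = diff[k] / (diff[k] - diff[k + 1])
                    p_star = pressures[k] + frac * (pressures[k + 1] - pressures[k])
                    crossovers.append((names[ai], names[bi], float(p_star)))
    return FreeEnergyCurve(pressures, temperature, reference, delta, crossovers)


# --------------------------------------------------------------------------
# torsion-profile analysis

@dataclass
class TorsionProfile:
    """Periodic torsion energy profile on a uniform angular grid.

    angles : degrees, uniform spacing, covering one period (the +180°
        endpoint, when present, must duplicate −180° within ``tol``
        and is dropped internally).
    energies : kJ/mol, shifted so the global minimum is zero.
    """

    angles: np.ndarray
    energies: np.ndarray
    tol: float = 1e-6

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.shape != self.energies.shape or self.angles.ndim != 1:
            raise ConfigurationError("angles and energies must be equal 1-D arrays")
        steps = np.diff(self.angles)
        if steps.size and np.abs(steps - steps[0]).max() > 1e-9 * abs(steps[0]):
            raise ConfigurationError("angular grid must be uniform")
        span = self.angles[-1] - self.angles[0]
        if abs(span - 360.0) < 1e-9:  # closed grid: check closure, drop endpoint
            if abs(self.energies[0] - self.energies[-1]) > max(
                self.tol, 1e-8 * max(1.0, np.abs(self.energies).max())
            ):
                raise ConfigurationError(
                    "profile endpoints at ±180° disagree beyond tolerance"
                )
            self.angles = self.angles[:-1]
            self.energies = self.energies[:-1]
        self.energies = self.energies - self.energies.min()


@dataclass(frozen=True)
class TorsionMinimum:
    angle: float
    energy: float


@dataclass(frozen=True)
class TorsionBarrier:
    from_angle: float
    to_angle: float
    height: float        # energy above the departing minimum
    at_angle: float      # grid angle of the path maximum


def analyze_torsion_profile(profile: TorsionProfile):
    """Locate all periodic-grid local minima and adjacent-pair path barriers.

    A grid point is a minimum if it is ≤ both periodic neighbours (strict
    on at least one side).  For each ordered pair of angularly adjacent
    minima, the barrier is the maximum energy along the grid path from one
    to the next (going in the direction of increasing angle from the
    departing minimum), reported relative to the departing minimum.

    These are along-the-path barriers on the scanned coordinate, not
    transition-state heights.

    Returns ``(minima, barriers)`` lists of :class:`TorsionMinimum` /
    :class:`TorsionBarrier`.  A flat profile yields no minima (warned).
    """
    e = profile.energies
    a = profile.angles
    n = len(e)
    if np.ptp(e) < 1e-12:
        log.warning("analyze_torsion_profile: flat profile, no minima reported")
        return [], []
    minima_idx = []
    for i in range(n):
        left, right = e[(i - 1) % n], e[(i + 1) % n]
        if e[i] <= left and e[i] <= right and (e[i] < left or e[i] < right):
            minima_idx.append(i)
    # collapse flat minimum plateaus to their first grid point
    collapsed = []
    for i in minima_idx:
        if collapsed and (i - collapsed[-1]) % n == 1 and e[i] == e[collapsed[-1]]:
            continue
        collapsed.append(i)
    minima = [TorsionMinimum(wrap_angle(a[i]), float(e[i])) for i in collapsed]

    barriers = []
    m = len(collapsed)
    for k in range(m):
        i0, i1 = collapsed[k], collapsed[(k + 1) % m]
        path = [(i0 + s) % n for s in range((i1 - i0) % n + 1)] if m > 1 else list(
            range(i0, i0 + n + 1)
        )
        path_e = e[[p % n for p in path]]
        top = int(np.argmax(path_e))
        for a_idx, b_idx in ((i0, i1), (i1, i0)):
            barriers.append(
                TorsionBarrier(
                    from_angle=wrap_angle(a[a_idx]),
                    to_angle=wrap_angle(a[b_idx]),
                    height=float(path_e[top] - e[a_idx]),
                    at_angle=wrap_angle(a[path[top] % n]),
                )
            )
        if m == 1:
            barriers = barriers[:1]  # self-barrier over the full period, once
    return minima, barriers
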