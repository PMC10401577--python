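"""Synthetic inputs for every pipeline stage: toy polar molecular crystals
with harmonic force fields and Born charges, Langevin dynamics with cell-
dipole output, two-well torsion dynamics, and Ornstein–Uhlenbeck dipole
processes with known spectra.

The toy "molecules" are generic four-site polar bead chains (a C–C–S–H-like
backbone) — chemical realism is a non-goal.  What is emulated is the
statistical and spectral structure of a thiol-disordered molecular crystal:
two torsion basins near +87° and −78°, well offsets of order 1–3 kJ/mol,
and along-the-path barriers of order 4–6 kJ/mol.

Every generator takes an explicit integer seed and is deterministic under
it; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.constants as _c

from .constants import KB_EV, KB_KJMOL, SQRT_EV_A2_AMU_TO_CM1
from .errors import ConfigurationError, IntegrationError
from .dynamic_spectra import DipoleTrajectory
from .harmonic import enforce_acoustic_sum_rule, gamma_phonons
from .structures import Crystal, TorsionSpec, measure_torsion

__all__ = [
    "ToySystem",
    "make_toy_molecular_crystal",
    "simulate_harmonic_md",
    "simulate_torsion_langevin",
    "two_well_coefficients",
    "cosine_series",
    "cosine_series_deriv",
    "make_ou_dipole",
]

#: Å/fs² per (eV/Å/amu): (e/1e-10 m)/amu gives m/s²; ×1e10 Å/m ×(1e-15 s/fs)²
_ACC = (_c.elementary_charge / 1e-10 / _c.atomic_mass) * 1e-20
#: eV per amu·Å²/fs² (kinetic-energy conversion), exactly 1/_ACC
_EV_PER_AMU_A2_FS2 = 1.0 / _ACC

#: speed of light in cm/fs
_C_CM_PER_FS = _c.c * 100.0 * 1e-15


@dataclass
class ToySystem:
    """A toy molecular crystal with everything the analysis stages consume."""

    crystal: Crystal
    force_constants: np.ndarray     # (3N, 3N) eV/Å², symmetric, sum-rule-obeying
    born_charges: np.ndarray        # (N, 3, 3), summing to zero
    eps_inf: np.ndarray             # (3, 3)
    torsion_potentials: list = field(default_factory=list)  # (TorsionSpec, coeffs)

    def __post_init__(self):
        k = self.force_constants
        if np.abs(k - k.T).max() > 1e-10 * max(1.0, np.abs(k).max()):
            raise ConfigurationError("toy force constants must be symmetric")
        if np.abs(self.born_charges.sum(axis=0)).max() > 1e-10:
            raise ConfigurationError("toy Born charges must sum to zero")

    def phonons(self, **kw):
        return gamma_phonons(
            self.force_constants,
            self.crystal.masses,
            born_charges=self.born_charges,
            eps_inf=self.eps_inf,
            **kw,
        )


# one molecule: a bent C–C–S–H-like chain (Å, molecule-local frame)
_MOL_SYMBOLS = ["C", "C", "S", "H"]
_MOL_CHARGE_PATTERN = np.array([0.35, 0.15, -0.70, 0.20])  # sums to zero


def _molecule_template(tau_deg: float) -> np.ndarray:
    """Cartesian template with the C–C–S–H dihedral set to tau_deg."""
    r_cc, r_cs, r_sh = 1.53, 1.82, 1.34
    ang_ccs, ang_csh = math.radians(114.0), math.radians(96.0)
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([r_cc, 0.0, 0.0])
    p2 = p1 + r_cs * np.array([math.cos(math.pi - ang_ccs), math.sin(math.pi - ang_ccs), 0.0])
    # place H by dihedral construction about the C1→S axis
    b1 = p2 - p1
    b1u = b1 / np.linalg.norm(b1)
    # reference direction: component of (p0 − p1) ⊥ b1
    ref = (p0 - p1) - np.dot(p0 - p1, b1u) * b1u
    ref /= np.linalg.norm(ref)
    perp = np.cross(b1u, ref)
    tau = math.radians(tau_deg)
    theta = math.pi - ang_csh
    d = (
        math.cos(theta) * b1u
        + math.sin(theta) * (math.cos(tau) * ref + math.sin(tau) * perp)
    )
    p3 = p2 + r_sh * d
    return np.array([p0, p1, p2, p3])


def make_toy_molecular_crystal(
    n_molecules: int = 2,
    springs: tuple = (12.0, 1.5),
    charge: float = 0.6,
    seed: int = 0,
    tau_deg: float = 87.0,
    jitter: float = 0.04,
) -> ToySystem:
    """A periodic cell of polar four-site bead molecules with harmonic couplings.

    Parameters
    ----------
    n_molecules : molecules stacked along the c axis (≥ 1).
    springs : (intra, inter) longitudinal spring constants, eV/Å², > 0.
    charge : scale of the per-site Born charges (e); each molecule is
        charge-neutral.
    tau_deg : C–C–S–H-like dihedral every molecule starts at.
    jitter : seeded positional noise (Å) breaking accidental symmetry.

    The force-constant matrix is built from pair springs — longitudinal
    constant k along the pair axis plus 0.3k transverse — over bonded
    intra-molecular pairs, nearest inter-molecular contacts and a weak
    all-pair floor, then acoustic-sum-rule enforced.  Γ phonons therefore
    show exactly three acoustic modes plus distinct optical modes, at
    least one of them IR-active.
    """
    if n_molecules < 1:
        raise ConfigurationError("need at least one molecule")
    k_intra, k_inter = springs
    if k_intra <= 0 or k_inter <= 0:
        raise ConfigurationError("spring constants must be > 0")
    rng = np.random.default_rng(seed)

    template = _molecule_template(tau_deg)
    spacing = 4.6
    lattice = np.diag([9.0, 9.0, spacing * n_molecules])
    symbols, cart, molecules = [], [], []
    for m in range(n_molecules):
        offset = np.array([3.2, 3.6, spacing * (m + 0.25)])
        pos = template + offset + jitter * rng.standard_normal(template.shape)
        cart.append(pos)
        symbols.extend(_MOL_SYMBOLS)
        molecules.append(list(range(4 * m, 4 * m + 4)))
    cart = np.vstack(cart)
    frac = cart @ np.linalg.inv(lattice)
    crystal = Crystal(
        lattice, symbols, frac, molecules=molecules,
        provenance=f"toy crystal n={n_molecules} seed={seed}",
    )

    n = crystal.n_sites
    k = np.zeros((3 * n, 3 * n))

    def add_spring(i, j, kl):
        v = crystal.mic_vector(i, j)
        d = np.linalg.norm(v)
        nhat = v / d
        block = kl * np.outer(nhat, nhat) + 0.3 * kl * (np.eye(3) - np.outer(nhat, nhat))
        k[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        k[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block

    # per-bond scale factors spread the optical modes apart so spectra show
    # well-separated lines rather than near-degenerate clusters
    bonded = [(0, 1, 1.0), (1, 2, 0.55), (2, 3, 0.30)]
    bends = [(0, 2, 0.22), (1, 3, 0.12), (0, 3, 0.06)]
    for m in range(n_molecules):
        base = 4 * m
        for i, j, s in bonded + bends:
            add_spring(base + i, base + j, s * k_intra)
    # nearest inter-molecular contacts (periodic): couple molecule m to m+1
    for m in range(n_molecules) if n_molecules > 1 else []:
        a, b = m, (m + 1) % n_molecules
        pairs = sorted(
            ((crystal.distance(4 * a + i, 4 * b + j), i, j)
             for i in range(4) for j in range(4))
        )[:3]
        for _, i, j in pairs:
            add_spring(4 * a + i, 4 * b + j, k_inter)
    # weak all-pair floor removes accidental zero modes of sparse networks
    for i in range(n):
        for j in range(i + 1, n):
            add_spring(i, j, 0.02)
    k = enforce_acoustic_sum_rule(k)

    born = np.zeros((n, 3, 3))
    for m in range(n_molecules):
        for a in range(4):
            born[4 * m + a] = charge * _MOL_CHARGE_PATTERN[a] * np.eye(3)
    eps_inf = 2.5 * np.eye(3)

    coeffs = two_well_coefficients()
    torsions = [
        (TorsionSpec(4 * m, 4 * m + 1, 4 * m + 2, 4 * m + 3), coeffs)
        for m in range(n_molecules)
    ]
    return ToySystem(crystal, k, born, eps_inf, torsions)


# --------------------------------------------------------------------------
# harmonic Langevin MD

@dataclass
class MDResult:
    """Output of a harmonic Langevin run."""

    dipole: DipoleTrajectory
    displacements: np.ndarray | None     # (n_samples, N, 3) Å, if requested
    temperature_estimate: float          # K, from mean kinetic energy
    times_fs: np.ndarray


def simulate_harmonic_md(
    system: ToySystem,
    temperature: float = 300.0,
    dt: float = 0.5,
    n_steps: int = 20000,
    friction: float = 5e-4,
    seed: int = 0,
    sample_every: int = 1,
    n_equil: int = 0,
    return_displacements: bool = False,
) -> MDResult:
    """Langevin (BAOAB) dynamics on the toy harmonic force field.

    Integrates 3N Cartesian displacements with force −K·u; the per-frame
    cell dipole is M = Σ_a Z*_a·u_a (e·Å).  Long runs satisfy equipartition
    (mean kinetic energy per degree of freedom = k_B T/2 within a few %).

    The initial condition is drawn from the exact canonical distribution in
    normal-mode coordinates (acoustic modes at rest), so no equilibration
    is needed; the default friction is weak (5×10⁻⁴ fs⁻¹ ≈ 2.7 cm⁻¹ of
    Lorentzian broadening) to keep spectral lines near their harmonic
    positions while staying ergodic.

    dt is in fs and must resolve the stiffest mode (≥ 20 steps per period);
    friction is in fs⁻¹.
    """
    kmat = system.force_constants
    masses = np.repeat(system.crystal.masses, 3)  # (3N,)
    modes = system.phonons()
    numax = float(modes.frequencies.max())
    if numax > 0:
        period_fs = 1.0 / (numax * _C_CM_PER_FS)
        if dt > period_fs / 20.0:
            raise IntegrationError(
                f"dt={dt} fs too large for the stiffest mode "
                f"(period {period_fs:.2f} fs; need ≥ 20 steps/period)"
            )
    rng = np.random.default_rng(seed)
    n3 = len(masses)
    kt = KB_EV * temperature
    if temperature > 0:
        # canonical draw: mass-weighted mode amplitude c_k ~ N(0, √(kT/λ_k))
        sqrt_m = np.sqrt(masses)
        dyn = kmat / np.outer(sqrt_m, sqrt_m)
        lam, vecs = np.linalg.eigh(dyn)
        lam_min = (modes.acoustic_tol / SQRT_EV_A2_AMU_TO_CM1) ** 2
        amp = np.where(lam > lam_min, np.sqrt(kt / np.maximum(lam, lam_min)), 0.0)
        u = (vecs @ (amp * rng.standard_normal(n3))) / sqrt_m
        v = rng.standard_normal(n3) * np.sqrt(kt / (masses * _EV_PER_AMU_A2_FS2))
    else:
        u = np.zeros(n3)
        v = np.zeros(n3)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kt / (masses * _EV_PER_AMU_A2_FS2)) if temperature > 0 else 0.0

    z_flat = system.born_charges  # (N,3,3)
    n_samples = n_steps // sample_every
    dipoles = np.empty((n_samples, 3))
    disp = np.empty((n_samples, n3 // 3, 3)) if return_displacements else None
    ke_acc = 0.0
    ke_count = 0

    force = -(kmat @ u)
    half = 0.5 * dt
    for step in range(n_equil + n_steps):
        v += half * force / masses * _ACC
        u += half * v
        if temperature > 0:
            v = c1 * v + c2 * sigma_v * rng.standard_normal(n3)
        else:
            v = c1 * v
        u += half * v
        force = -(kmat @ u)
        v += half * force / masses * _ACC
        if step >= n_equil:
            i = step - n_equil
            if i % sample_every == 0:
                s = i // sample_every
                ua = u.reshape(-1, 3)
                dipoles[s] = np.einsum("aij,aj->i", z_flat, ua)
                if disp is not None:
                    disp[s] = ua
            ke = 0.5 * float(masses @ (v * v)) * _EV_PER_AMU_A2_FS2
            ke_acc += ke
            ke_count += 1
    if not np.isfinite(dipoles).all():
        raise IntegrationError("trajectory diverged (non-finite dipole)")

    t_est = 2.0 * (ke_acc / max(ke_count, 1)) / (n3 * KB_EV)
    times = np.arange(n_samples) * dt * sample_every
    traj = DipoleTrajectory(
        times=times,
        dipoles=dipoles,
        volume=system.crystal.volume,
        temperature=temperature if temperature > 0 else 1.0,
    )
    return MDResult(traj, disp, t_est, times)


# --------------------------------------------------------------------------
# torsion potentials and overdamped Langevin dynamics

def cosine_series(coeffs: np.ndarray, tau_rad):
    """V(τ) = Σ_n a_n cos(nτ) + b_n sin(nτ), coeffs shape (K, 2) in kJ/mol."""
    coeffs = np.asarray(coeffs, dtype=float)
    tau = np.asarray(tau_rad, dtype=float)
    out = np.zeros_like(tau, dtype=float)
    for n, (a, b) in enumerate(coeffs, start=1):
        out = out + a * np.cos(n * tau) + b * np.sin(n * tau)
    return out


def cosine_series_deriv(coeffs: np.ndarray, tau_rad):
    """dV/dτ in kJ/mol/rad."""
    coeffs = np.asarray(coeffs, dtype=float)
    tau = np.asarray(tau_rad, dtype=float)
    out = np.zeros_like(tau, dtype=float)
    for n, (a, b) in enumerate(coeffs, start=1):
        out = out + n * (-a * np.sin(n * tau) + b * np.cos(n * tau))
    return out


def two_well_coefficients(
    min_a: float = 87.0,
    min_b: float = -78.4,
    offset: float = 1.0,
    barrier: float = 6.3,
    barrier_angle: float = -20.0,
) -> np.ndarray:
    """Two-term cosine-series coefficients for a periodic double well.

    Solves the linear system pinning stationary points at *min_a* and
    *min_b* (degrees), an energy offset V(min_b) − V(min_a) (kJ/mol), and
    the profile height V(barrier_angle) − V(min_a).  Defaults place the
    wells near the two thiol hydrogen-bond motif angles with a ~1 kJ/mol
    offset and a ~6.3 kJ/mol saddle near −20°.
    """
    ta, tb, ts = (math.radians(x) for x in (min_a, min_b, barrier_angle))

    def vrow(t):
        return [math.cos(t), math.sin(t), math.cos(2 * t), math.sin(2 * t)]

    def drow(t):
        return [-math.sin(t), math.cos(t), -2 * math.sin(2 * t), 2 * math.cos(2 * t)]

    mat = np.array(
        [
            drow(ta),
            drow(tb),
            np.subtract(vrow(tb), vrow(ta)),
            np.subtract(vrow(ts), vrow(ta)),
        ]
    )
    rhs = np.array([0.0, 0.0, offset, barrier])
    a1, b1, a2, b2 = np.linalg.solve(mat, rhs)
    return np.array([[a1, b1], [a2, b2]])


def simulate_torsion_langevin(
    coeffs: np.ndarray,
    temperature: float = 300.0,
    friction: float = 10.0,
    dt: float = 0.01,
    n_steps: int = 100000,
    seed: int = 0,
    tau0_deg: float | None = None,
) -> tuple:
    """Overdamped Langevin dynamics of one torsion in a periodic potential.

    dτ = −V′(τ)/γ · dt + √(2 k_B T dt/γ) ξ, with τ in radians internally,
    V in kJ/mol, γ in kJ·mol⁻¹·ps·rad⁻², dt in ps.  The stationary
    distribution is the Boltzmann weight e^{−V/k_BT} on the circle.

    Returns ``(times_ps, tau_deg)`` with the angle series continuous
    (unwrapped).  Starting angle defaults to the global minimum.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    rng = np.random.default_rng(seed)
    kt = KB_KJMOL * temperature
    if tau0_deg is None:
        grid = np.linspace(-math.pi, math.pi, 721)
        tau = float(grid[np.argmin(cosine_series(coeffs, grid))])
    else:
        tau = math.radians(tau0_deg)
    noise = rng.standard_normal(n_steps) * math.sqrt(2.0 * kt * dt / friction)
    inv_g_dt = dt / friction
    out = np.empty(n_steps + 1)
    out[0] = tau
    # scalar loop: the K≤4 harmonic force is cheap enough in pure Python
    k_orders = [(n, a, b) for n, (a, b) in enumerate(coeffs, start=1)]
    for i in range(n_steps):
        dv = 0.0
        for n, a, b in k_orders:
            nt = n * tau
            dv += n * (-a * math.sin(nt) + b * math.cos(nt))
        tau = tau - dv * inv_g_dt + noise[i]
        out[i + 1] = tau
    times = np.arange(n_steps + 1) * dt
    return times, np.degrees(out)


# --------------------------------------------------------------------------
# Ornstein–Uhlenbeck dipole

def make_ou_dipole(
    tau_c: float = 100.0,
    amplitude: float = 1.0,
    dt: float = 1.0,
    n: int = 10000,
    seed: int = 0,
    volume: float = 1000.0,
    temperature: float = 300.0,
) -> DipoleTrajectory:
    """Exact-discretization Ornstein–Uhlenbeck dipole process, per component.

    tau_c and dt are in fs; the stationary per-component standard deviation
    is *amplitude* (e·Å) and the sample ACF decays as e^{−t/τc}.  Requires
    dt < τc/5 so the correlation is actually resolved.
    """
    if dt >= tau_c / 5.0:
        raise ConfigurationError("dt must be < tau_c/5 to resolve the correlation")
    rng = np.random.default_rng(seed)
    decay = math.exp(-dt / tau_c)
    kick = amplitude * math.sqrt(1.0 - decay * decay)
    x = np.empty((n, 3))
    x[0] = amplitude * rng.standard_normal(3)
    if amplitude == 0.0:
        x[:] = 0.0
    else:
        xi = rng.standard_normal((n - 1, 3))
        for i in range(1, n):
            x[i] = decay * x[i - 1] + kick * xi[i - 1]
    times = np.arange(n) * dt
    return DipoleTrajectory(times, x, volume, temperature)
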