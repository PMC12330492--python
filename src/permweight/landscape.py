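"""Desk-scale synthetic permeant model: proton-coupled 1-D Brownian dynamics.

This module is the stand-in for the all-atom constant-pH segments of the
weighted-ensemble protocol.  A permeant is reduced to a single coordinate
z (Å from the bilayer center, positive on the extracellular side) moving
by overdamped Euler–Maruyama dynamics on a state-dependent free-energy
landscape, coupled to a two-state protonation coordinate that hops with
rates obeying detailed balance against a z-dependent pKa.

The landscape for the neutral (deprotonated) species is a Gaussian
central barrier plus Gaussian interface wells at ±membrane_half_width;
the charged (protonated) species pays an additional penalty inside the
membrane, encoding the pH-partition picture that only the neutral form
crosses.  The z-dependent pKa drops toward the bilayer core following a
normalized logistic switch, so the permeant deprotonates before reaching
the core.  When ``charged_penalty = ln10·kT·pKa_shift_scale`` (the preset
default) the hop kinetics and the state-dependent landscape share one
thermodynamics and the stationary distribution of the joint process is
exactly the titration-marginalized Boltzmann density, which serves as an
analytic oracle in the tests.

Auxiliary per-walker observables (hydration count, H-bond count,
hydrophobic contacts, local-thickness change, orientation angle) are
drawn from z- and state-conditional generators; no atoms exist at this
scale, so these channels emulate the qualitative z-dependence seen in
all-atom simulations rather than computing geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import units
from .errors import StabilityWarning
from .titration import TitrationCurve, neutral_fraction

__all__ = [
    "ObservableParams",
    "ToyLandscape",
    "Walker",
    "OBSERVABLE_CHANNELS",
    "free_energy",
    "local_pKa",
    "effective_free_energy",
    "boltzmann_density",
    "propagate",
    "sample_observables",
    "titration_trajectory",
    "simulate_titration_curve",
    "make_opioid_presets",
    "make_scaled_presets",
]

OBSERVABLE_CHANNELS = (
    "hydration",
    "hbond_count",
    "hydrophobic_contacts",
    "delta_thickness",
    "orientation_angle",
)


@dataclass
class ObservableParams:
    """Parameters of the synthetic per-walker observable generators.

    The means are smooth functions of |z| chosen to mimic the qualitative
    behavior of permeants in a lipid bilayer: desolvation on entry
    (fast-desolvating permeants lose all first-shell waters by |z|≈5,
    slow ones retain 1–2 until near the core), interface-peaked H-bonding,
    hydrophobic contacts that grow inside the membrane, charged-state
    membrane thinning, and an orientation angle that is bimodal
    (vertical insertion, ~30°/160°) at the interface but uniform in bulk
    and in the membrane core.
    """

    hydration_bulk: float = 25.0  # first-shell waters in bulk solution
    desolvation_z: float = 9.0  # |z| where hydration has dropped to half
    desolvation_width: float = 1.2
    retained_waters: float = 0.0  # waters kept inside until |z| ~ retained_z
    retained_z: float = 3.0
    hbond_max: float = 1.0  # peak permeant-lipid H-bond count
    contact_max: float = 30.0  # hydrophobic contacts deep in the membrane
    contact_bulk: float = 0.0
    thinning_max: float = 1.0  # Å of charged-state local membrane thinning
    orientation_modes: tuple[float, float] = (30.0, 160.0)
    orientation_spread: float = 12.0
    interface_band: tuple[float, float] = (16.0, 24.0)  # |z| range of bimodality


@dataclass
class ToyLandscape:
    """State-dependent free-energy landscape and kinetic constants.

    Parameters
    ----------
    barrier_height
        Free-energy maximum of the neutral species at z = 0, kcal/mol.
    interface_well_depth
        Depth of the interface wells at |z| ≈ membrane_half_width, kcal/mol.
    charged_penalty
        Extra free energy of the charged species inside the membrane,
        kcal/mol.  ``None`` (default) derives the thermodynamically
        consistent value ln10·kT·pKa_shift_scale.
    membrane_half_width
        Half-width of the bilayer, Å.
    solution_pKa
        pKa of the titratable amine in bulk solution.
    pKa_shift_scale
        Magnitude of the pKa drop from bulk to the bilayer core.
    diffusion_coeff
        Å²/ps; the default 0.002 is a membrane-like diffusivity chosen so
        a 100 ps WE segment displaces walkers by about one membrane bin
        (the regime in which the WE bin ladder is effective).
    temperature
        K.
    attempt_rate
        Attempt frequency of protonation-state moves, 1/ps.
    """

    barrier_height: float = 7.8
    interface_well_depth: float = 2.0
    charged_penalty: float | None = None
    membrane_half_width: float = 20.0
    solution_pKa: float = 8.4
    pKa_shift_scale: float = 6.0
    diffusion_coeff: float = 0.002
    temperature: float = 300.0
    attempt_rate: float = 0.1
    barrier_width: float = 6.0  # σ of the central Gaussian, Å
    well_width: float = 3.0  # σ of the interface wells, Å
    pka_midpoint: float = 12.0  # |z| of the half-shift of the pKa switch, Å
    pka_width: float = 1.5  # logistic width of the pKa switch, Å
    barrier_calibration_pH: float | None = None  # see barrier_amplitude
    observables: ObservableParams = field(default_factory=ObservableParams)
    name: str = "toy"

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.diffusion_coeff <= 0 or self.temperature <= 0 or self.attempt_rate <= 0:
            raise ValueError(
                "diffusion_coeff, temperature and attempt_rate must be positive"
            )
        if self.charged_penalty is None:
            self.charged_penalty = units.LN10 * self.kT * self.pKa_shift_scale

    @property
    def kT(self) -> float:
        return units.kT(self.temperature)

    # -- pKa switch ---------------------------------------------------------

    @property
    def bulk_onset(self) -> float:
        """|z| beyond which the landscape reports bulk values exactly."""
        return self.membrane_half_width + 5.0

    def _switch(self, z):
        """Normalized logistic switch S(z): 1 at z=0, exactly 0 for |z| >= bulk."""
        u = np.abs(np.asarray(z, dtype=float))
        L = 1.0 / (1.0 + np.exp((u - self.pka_midpoint) / self.pka_width))
        L0 = 1.0 / (1.0 + math.exp(-self.pka_midpoint / self.pka_width))
        Lb = 1.0 / (1.0 + math.exp((self.bulk_onset - self.pka_midpoint) / self.pka_width))
        s = np.clip((L - Lb) / (L0 - Lb), 0.0, 1.0)
        return np.where(u >= self.bulk_onset, 0.0, s)

    def _switch_grad(self, z):
        z = np.asarray(z, dtype=float)
        u = np.abs(z)
        L = 1.0 / (1.0 + np.exp((u - self.pka_midpoint) / self.pka_width))
        L0 = 1.0 / (1.0 + math.exp(-self.pka_midpoint / self.pka_width))
        Lb = 1.0 / (1.0 + math.exp((self.bulk_onset - self.pka_midpoint) / self.pka_width))
        dLdu = -L * (1.0 - L) / self.pka_width
        ds = dLdu / (L0 - Lb) * np.sign(z)
        return np.where(u >= self.bulk_onset, 0.0, ds)

    # -- energies -----------------------------------------------------------

    @property
    def barrier_amplitude(self) -> float:
        """Amplitude of the neutral-state central Gaussian, kcal/mol.

        By default this is ``barrier_height`` directly.  When
        ``barrier_calibration_pH`` is set, the amplitude is reduced so that
        the *titration-marginalized* free-energy barrier at that pH equals
        ``barrier_height`` — matching how observed permeant free-energy
        profiles are reported (the profile marginalizes over protonation
        states, which raises the apparent barrier of a mostly-charged
        solution population by kT·ln(1 + 10^{pKa − pH})).
        """
        if self.barrier_calibration_pH is None:
            return self.barrier_height
        kT = self.kT
        w = 10.0 ** (self.barrier_calibration_pH - self.solution_pKa)
        corr = kT * math.log((1.0 + w) / (math.exp(-self.charged_penalty / kT) + w))
        return self.barrier_height - corr

    def base_energy(self, z):
        """Neutral-species free energy, kcal/mol (vectorized in z)."""
        z = np.asarray(z, dtype=float)
        m, sb, sw = self.membrane_half_width, self.barrier_width, self.well_width
        g = self.barrier_amplitude * np.exp(-(z**2) / (2 * sb**2))
        g -= self.interface_well_depth * (
            np.exp(-((z - m) ** 2) / (2 * sw**2)) + np.exp(-((z + m) ** 2) / (2 * sw**2))
        )
        return g

    def base_energy_grad(self, z):
        z = np.asarray(z, dtype=float)
        m, sb, sw = self.membrane_half_width, self.barrier_width, self.well_width
        g = self.barrier_amplitude * np.exp(-(z**2) / (2 * sb**2)) * (-z / sb**2)
        g -= self.interface_well_depth * (
            np.exp(-((z - m) ** 2) / (2 * sw**2)) * (-(z - m) / sw**2)
            + np.exp(-((z + m) ** 2) / (2 * sw**2)) * (-(z + m) / sw**2)
        )
        return g

    def energy(self, z, deprotonated):
        """State-dependent free energy; ``deprotonated`` is boolean (array)."""
        g = self.base_energy(z)
        pen = self.charged_penalty * self._switch(z)
        return np.where(np.asarray(deprotonated, dtype=bool), g, g + pen)

    def energy_grad(self, z, deprotonated):
        g = self.base_energy_grad(z)
        pen = self.charged_penalty * self._switch_grad(z)
        return np.where(np.asarray(deprotonated, dtype=bool), g, g + pen)

    def local_pKa(self, z):
        out = self.solution_pKa - self.pKa_shift_scale * self._switch(z)
        return float(out) if np.ndim(z) == 0 else out


@dataclass
class Walker:
    """One weighted trajectory snapshot."""

    z: float
    lam: float
    weight: float
    observables: dict = field(default_factory=dict)
    lineage: str = "none"  # last macrostate visited
    rng_stream_id: int = 0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("walker weight must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.lineage not in ("none", "extracellular", "intracellular"):
            raise ValueError(f"invalid lineage label {self.lineage!r}")


# -- module-level functional surface ---------------------------------------


def free_energy(landscape: ToyLandscape, z, state: str):
    """Free energy (kcal/mol) of the permeant at z in a protonation state.

    ``state`` is 'protonated' or 'deprotonated'.  The neutral profile is an
    even function of z with maximum ``barrier_height`` at z = 0 and wells at
    ±membrane_half_width; the charged profile adds ``charged_penalty`` inside
    the membrane.  Both tend to 0 in bulk.
    """
    if state not in ("protonated", "deprotonated"):
        raise ValueError(f"state must be 'protonated' or 'deprotonated', got {state!r}")
    out = landscape.energy(z, deprotonated=(state == "deprotonated"))
    return float(out) if np.ndim(z) == 0 else out


def local_pKa(landscape: ToyLandscape, z):
    """z-dependent pKa: equals solution_pKa in bulk, drops toward the core."""
    return landscape.local_pKa(z)


def effective_free_energy(landscape: ToyLandscape, z, pH: float):
    """Titration-marginalized free energy −kT ln[p_prot + p_deprot], bulk = 0.

    Exact stationary profile of the joint (z, protonation) dynamics when
    ``charged_penalty`` is thermodynamically consistent with the pKa shift.
    """
    kT = landscape.kT
    gp = landscape.energy(z, deprotonated=False)
    gd = landscape.energy(z, deprotonated=True)
    w_d = 10.0 ** (pH - landscape.solution_pKa)
    g = -kT * np.logaddexp(-gp / kT, math.log(w_d) - gd / kT)
    g0 = -kT * np.logaddexp(0.0, math.log(w_d))  # bulk reference
    out = g - g0
    return float(out) if np.ndim(z) == 0 else out


def boltzmann_density(landscape: ToyLandscape, z_edges: np.ndarray, pH: float):
    """Bin probabilities of the equilibrium z-density by direct quadrature.

    Integrates exp(−G_eff/kT) over each [z_i, z_{i+1}) using a fine
    trapezoidal grid and normalizes over the supplied range.  Serves as the
    independent oracle for sink-free weighted-ensemble runs.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    probs = np.empty(z_edges.size - 1)
    for i in range(z_edges.size - 1):
        zz = np.linspace(z_edges[i], z_edges[i + 1], 33)
        dens = np.exp(-effective_free_energy(landscape, zz, pH) / landscape.kT)
        probs[i] = np.trapezoid(dens, zz)
    return probs / probs.sum()


# -- propagation ------------------------------------------------------------


def check_time_step(landscape: ToyLandscape, dt: float, bin_width: float = 0.5) -> None:
    """Warn if one Euler–Maruyama step can exceed the membrane bin width."""
    zz = np.linspace(-landscape.bulk_onset - 5, landscape.bulk_onset + 5, 2001)
    gmax = float(
        np.max(
            np.maximum(
                np.abs(landscape.energy_grad(zz, True)),
                np.abs(landscape.energy_grad(zz, False)),
            )
        )
    )
    drift = landscape.diffusion_coeff / landscape.kT * gmax * dt
    step = drift + math.sqrt(2.0 * landscape.diffusion_coeff * dt)
    if step > bin_width:
        warnings.warn(
            f"time step dt={dt} ps allows displacements of ~{step:.2f} Å per step, "
            f"exceeding the bin width {bin_width} Å; reduce dt",
            StabilityWarning,
            stacklevel=2,
        )


try:  # optional JIT of the hot stepping kernel; the numpy path is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn

        return deco


@_njit(cache=False)
def _step_kernel(
    z, lam, normals, hop_u, hop_stride,
    grad_p, grad_d, f_tab, tab_lo, tab_inv_h,
    mob_dt, sig, p_attempt, z_min, z_max,
):  # pragma: no cover - exercised via _step_batch
    n_steps = normals.shape[0]
    n = z.shape[0]
    n_tab = grad_p.shape[0]
    for i in range(n_steps):
        for j in range(n):
            pos = (z[j] - tab_lo) * tab_inv_h
            if pos < 0.0:
                pos = 0.0
            elif pos > n_tab - 2:
                pos = float(n_tab - 2)
            k = int(pos)
            frac = pos - k
            if lam[j] > 0.5:
                g = grad_d[k] + (grad_d[k + 1] - grad_d[k]) * frac
            else:
                g = grad_p[k] + (grad_p[k + 1] - grad_p[k]) * frac
            zz = z[j] - mob_dt * g + sig * normals[i, j]
            if zz < z_min:
                zz = 2.0 * z_min - zz
            elif zz > z_max:
                zz = 2.0 * z_max - zz
            z[j] = zz
        if (i + 1) % hop_stride == 0:
            h = (i + 1) // hop_stride - 1
            for j in range(n):
                pos = (z[j] - tab_lo) * tab_inv_h
                if pos < 0.0:
                    pos = 0.0
                elif pos > n_tab - 2:
                    pos = float(n_tab - 2)
                k = int(pos)
                frac = pos - k
                f = f_tab[k] + (f_tab[k + 1] - f_tab[k]) * frac
                p = p_attempt * (1.0 - f) if lam[j] > 0.5 else p_attempt * f
                if hop_u[h, j] < p:
                    lam[j] = 1.0 - lam[j]


def _step_kernel_numpy(
    z, lam, normals, hop_u, hop_stride,
    grad_p, grad_d, f_tab, tab_lo, tab_inv_h,
    mob_dt, sig, p_attempt, z_min, z_max,
):
    """Vectorized twin of :func:`_step_kernel` (consumes the same draws)."""
    n_steps = normals.shape[0]
    n_tab = grad_p.shape[0]
    for i in range(n_steps):
        pos = np.clip((z - tab_lo) * tab_inv_h, 0.0, float(n_tab - 2))
        k = pos.astype(np.int64)
        frac = pos - k
        deprot = lam > 0.5
        gp = grad_p[k] + (grad_p[k + 1] - grad_p[k]) * frac
        gd = grad_d[k] + (grad_d[k + 1] - grad_d[k]) * frac
        g = np.where(deprot, gd, gp)
        z += -mob_dt * g + sig * normals[i]
        z[:] = np.where(z < z_min, 2.0 * z_min - z, z)
        z[:] = np.where(z > z_max, 2.0 * z_max - z, z)
        if (i + 1) % hop_stride == 0:
            h = (i + 1) // hop_stride - 1
            pos = np.clip((z - tab_lo) * tab_inv_h, 0.0, float(n_tab - 2))
            k = pos.astype(np.int64)
            frac = pos - k
            f = f_tab[k] + (f_tab[k + 1] - f_tab[k]) * frac
            deprot = lam > 0.5
            p = p_attempt * np.where(deprot, 1.0 - f, f)
            flip = hop_u[h] < p
            lam[:] = np.where(flip, 1.0 - lam, lam)


_TABLE_CACHE: dict = {}


def _step_tables(landscape: ToyLandscape, pH: float):
    """Dense lookup tables of the state gradients and the neutral fraction.

    Gradients are tabulated on a 0.01 Å grid over the landscape's support
    (both states are exactly bulk beyond it; the kernel clamps to the edge
    values outside) and linearly interpolated in the stepping kernel; the
    interpolation error is far below the thermal noise at this resolution.
    """
    key = (
        landscape.barrier_amplitude, landscape.interface_well_depth,
        landscape.charged_penalty, landscape.membrane_half_width,
        landscape.barrier_width, landscape.well_width,
        landscape.solution_pKa, landscape.pKa_shift_scale,
        landscape.pka_midpoint, landscape.pka_width,
        pH,
    )
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    h = 0.01
    lo = -(landscape.bulk_onset + 15.0)
    hi = landscape.bulk_onset + 15.0
    n = int(math.ceil((hi - lo) / h)) + 2
    grid = lo + h * np.arange(n)
    tables = (
        np.ascontiguousarray(landscape.energy_grad(grid, False)),
        np.ascontiguousarray(landscape.energy_grad(grid, True)),
        np.ascontiguousarray(neutral_fraction(landscape.local_pKa(grid), pH)),
        lo,
        1.0 / h,
    )
    if len(_TABLE_CACHE) > 32:
        _TABLE_CACHE.clear()
    _TABLE_CACHE[key] = tables
    return tables


def _step_batch(
    z: np.ndarray,
    lam: np.ndarray,
    landscape: ToyLandscape,
    pH: float,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    z_min: float,
    z_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a batch of walkers by n_steps of coupled diffusion/titration.

    λ is treated as two-state (0/1) at this scale; hops are attempted at
    ``attempt_rate`` with acceptance f (deprotonation) or 1−f (protonation),
    where f = neutral_fraction(local_pKa(z), pH), so the flip-rate ratio is
    k_deprot/k_prot = 10^{pH − pKa(z)} (detailed balance).  Hops are
    evaluated on a ~1 ps sub-schedule (waiting times at the default attempt
    rate are ~10 ps, so the coarser hop clock is inconsequential).
    Reflecting walls at z_min/z_max keep walkers in the simulated slab.
    All randomness is pre-drawn from ``rng``; repeat calls with the same
    inputs are bitwise identical, and the JIT-compiled and numpy kernels
    consume identical draws (they agree to floating-point rounding).
    """
    mob_dt = landscape.diffusion_coeff / landscape.kT * dt
    sig = math.sqrt(2.0 * landscape.diffusion_coeff * dt)
    hop_stride = max(1, int(round(1.0 / dt)))
    p_attempt = -math.expm1(-landscape.attempt_rate * dt * hop_stride)
    grad_p, grad_d, f_tab, tab_lo, tab_inv_h = _step_tables(landscape, pH)
    z = np.ascontiguousarray(z, dtype=float).copy()
    lam = np.ascontiguousarray(lam, dtype=float).copy()
    n = z.size
    done = 0
    chunk = max(1, min(n_steps, int(4e5) // max(n, 1)))  # bound draw memory
    kernel = _step_kernel if _HAVE_NUMBA else _step_kernel_numpy
    while done < n_steps:
        m = min(chunk, n_steps - done)
        m -= m % hop_stride if m > hop_stride else 0
        m = max(m, min(hop_stride, n_steps - done))
        normals = rng.standard_normal((m, n))
        hop_u = rng.random((m // hop_stride + 1, n))
        kernel(
            z, lam, normals, hop_u, hop_stride,
            grad_p, grad_d, f_tab, tab_lo, tab_inv_h,
            mob_dt, sig, p_attempt, z_min, z_max,
        )
        done += m
    return z, lam


def sample_observables(
    z: np.ndarray,
    lam: np.ndarray,
    params: ObservableParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw the auxiliary observable channels conditional on (z, state)."""
    z = np.asarray(z, dtype=float)
    u = np.abs(z)
    n = z.size
    p = params

    mu_hyd = observable_mean(z, "hydration", p)
    hydration = rng.poisson(np.maximum(mu_hyd, 0.0)).astype(float)

    hbond = rng.poisson(np.maximum(observable_mean(z, "hbond_count", p), 0.0)).astype(float)

    contacts = rng.poisson(
        np.maximum(observable_mean(z, "hydrophobic_contacts", p), 0.0)
    ).astype(float)

    charged = lam <= 0.5
    mu_thick = observable_mean(z, "delta_thickness", p) * np.where(charged, 1.0, 0.15)
    delta_thickness = mu_thick + 0.3 * rng.standard_normal(n)

    lo, hi = p.interface_band
    at_interface = (u >= lo) & (u <= hi)
    modes = np.asarray(p.orientation_modes)
    pick = rng.integers(0, 2, size=n)
    bimodal = np.clip(modes[pick] + p.orientation_spread * rng.standard_normal(n), 0.0, 180.0)
    uniform = rng.uniform(0.0, 180.0, size=n)
    orientation = np.where(at_interface, bimodal, uniform)

    return {
        "hydration": hydration,
        "hbond_count": hbond,
        "hydrophobic_contacts": contacts,
        "delta_thickness": delta_thickness,
        "orientation_angle": orientation,
    }


def observable_mean(z, channel: str, params: ObservableParams):
    """Configured conditional mean of an observable channel versus z.

    Exposed so profile estimators can be checked against the generating
    means (orientation_angle has no z-dependent scalar mean and is not
    covered here).
    """
    p = params
    u = np.abs(np.asarray(z, dtype=float))
    if channel == "hydration":
        s1 = 1.0 / (1.0 + np.exp(-(u - p.desolvation_z) / p.desolvation_width))
        s2 = 1.0 / (1.0 + np.exp(-(u - p.retained_z) / 1.0))
        return p.hydration_bulk * s1 + p.retained_waters * (1.0 - s1) * s2
    if channel == "hbond_count":
        inner = 1.0 / (1.0 + np.exp(-(u - 6.0) / 2.0))
        outer = 1.0 / (1.0 + np.exp((u - 25.0) / 2.0))
        return p.hbond_max * inner * outer
    if channel == "hydrophobic_contacts":
        inside = 1.0 / (1.0 + np.exp((u - 15.0) / 3.0))
        return p.contact_bulk + (p.contact_max - p.contact_bulk) * inside
    if channel == "delta_thickness":
        return -p.thinning_max * np.exp(-(u**2) / (2 * 8.0**2))
    raise KeyError(f"unknown observable channel {channel!r}")


def propagate(
    walker: Walker,
    landscape: ToyLandscape,
    tau: float,
    dt: float,
    pH: float,
    seed: int,
    z_min: float = -60.0,
    z_max: float = 60.0,
) -> Walker:
    """Advance a single walker by one WE segment of length tau (ps).

    The weight is untouched; observables are resampled at segment end.
    Identical (walker, seed) inputs yield an identical output walker.
    """
    if not (tau >= dt > 0):
        raise ValueError("need tau >= dt > 0")
    check_time_step(landscape, dt)
    n_steps = int(round(tau / dt))
    rng = np.random.default_rng(seed)
    z, lam = _step_batch(
        np.array([walker.z], dtype=float),
        np.array([walker.lam], dtype=float),
        landscape,
        pH,
        dt,
        n_steps,
        rng,
        z_min,
        z_max,
    )
    obs = sample_observables(z, lam, landscape.observables, rng)
    return Walker(
        z=float(z[0]),
        lam=float(lam[0]),
        weight=walker.weight,
        observables={k: float(v[0]) for k, v in obs.items()},
        lineage=walker.lineage,
        rng_stream_id=walker.rng_stream_id,
    )


# -- solution titration -----------------------------------------------------


def titration_trajectory(
    pKa: float, pH: float, n_attempts: int, seed: int, lam0: float = 0.0
) -> np.ndarray:
    """Two-state protonation chain of a walker pinned at a bulk position.

    Each attempted move deprotonates with probability f (if protonated) or
    protonates with probability 1−f (if deprotonated), where f is the
    Henderson–Hasselbalch neutral fraction; the stationary deprotonated
    fraction is exactly f.  Returns the λ state (0/1) after each attempt.
    """
    f = neutral_fraction(pKa, pH)
    u = np.random.default_rng(seed).random(n_attempts)
    states = np.empty(n_attempts)
    s = 1.0 if lam0 > 0.5 else 0.0
    for i in range(n_attempts):
        if s < 0.5:
            if u[i] < f:
                s = 1.0
        elif u[i] < 1.0 - f:
            s = 0.0
        states[i] = s
    return states


def simulate_titration_curve(
    pKa: float,
    ph_values: Iterable[float] = (7.0, 7.5, 8.0, 8.5, 9.0, 9.5),
    n_attempts: int = 100_000,
    seed: int = 0,
) -> TitrationCurve:
    """Synthetic solution-titration experiment at a series of pH values.

    One seeded chain per pH; the deprotonated fraction is averaged over the
    second half of each chain (the first half is discarded as equilibration).
    """
    ph_values = np.asarray(sorted(ph_values), dtype=float)
    fracs = []
    for i, ph in enumerate(ph_values):
        states = titration_trajectory(pKa, float(ph), n_attempts, seed=seed + i)
        fracs.append(float(states[n_attempts // 2 :].mean()))
    return TitrationCurve(ph_values, np.array(fracs))


# -- presets -----------------------------------------------------------------


def _presets(barriers: dict[str, float], tag: str) -> dict[str, ToyLandscape]:
    pkas = {"fentanyl": 8.4, "morphine": 8.2, "isotonitazene": 8.7, "naloxone": 7.9}
    obs = {
        # fast desolvation, few lipid H-bonds, many hydrophobic contacts
        "fentanyl": ObservableParams(
            desolvation_z=9.0, retained_waters=0.0, hbond_max=0.5,
            contact_max=40.0, thinning_max=0.5,
        ),
        "morphine": ObservableParams(
            desolvation_z=8.0, retained_waters=0.0, hbond_max=2.0,
            contact_max=25.0, thinning_max=1.0,
        ),
        # slow desolvation: retain 1–2 waters until near the core; thinning
        "isotonitazene": ObservableParams(
            desolvation_z=12.0, retained_waters=1.5, hbond_max=1.0,
            contact_max=30.0, thinning_max=5.0,
        ),
        "naloxone": ObservableParams(
            desolvation_z=12.0, retained_waters=2.0, hbond_max=2.0,
            contact_max=25.0, thinning_max=6.0,
        ),
    }
    return {
        name: ToyLandscape(
            barrier_height=b,
            solution_pKa=pkas[name],
            observables=obs[name],
            barrier_calibration_pH=7.5,
            name=f"{name}{tag}",
        )
        for name, b in barriers.items()
    }


def make_opioid_presets() -> dict[str, ToyLandscape]:
    """Four named landscapes with the characterized free-energy barriers.

    Barrier heights 7.8 / 14.2 / 24.8 / 33.4 kcal/mol and solution pKa's
    8.4 / 8.2 / 8.7 / 7.9 for fentanyl, morphine, isotonitazene and
    naloxone respectively.
    """
    return _presets(
        {"fentanyl": 7.8, "morphine": 14.2, "isotonitazene": 24.8, "naloxone": 33.4},
        tag="",
    )


def make_scaled_presets() -> dict[str, ToyLandscape]:
    """Scaled-down preset family (barriers 3/5/7/9 kcal/mol).

    The full barriers make sink arrival unobservably rare at desk-scale run
    lengths; this family preserves the barrier ordering while keeping
    permeation events observable, and is the family used by the worked
    examples and statistical checks.
    """
    return _presets(
        {"fentanyl": 3.0, "morphine": 5.0, "isotonitazene": 7.0, "naloxone": 9.0},
        tag="-scaled",
    )
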