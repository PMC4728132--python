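"""Linear stability analysis of the polarity model.

The homogeneous steady state is linearized and the growth rate of each
spatial mode is read off the resulting eigenvalue problem.  Because the
cytoplasm is well mixed, zero-mean spatial modes do not perturb the
cytosolic pools: for wavenumber q > 0 on the torus the relevant operator is
the 4x4 membrane reaction Jacobian ``J4`` shifted by ``-Dm q^2``, while the
q = 0 (uniform) mode couples membrane and cytosol through the full
six-variable Jacobian with the eta/A volume weighting.

A generic spherical scaffold is also provided for membrane/cytosol systems
with *finite* cytosolic diffusion: perturbations are expanded in spherical
harmonics Y_lm, cytosolic radial profiles are modified spherical Bessel
functions of the first kind i_l (regular at the origin), and eigenvalues
are roots of the characteristic equation obtained by matching the membrane
equations to the cytosolic boundary flux.  The kinetics are pluggable so
other reaction schemes can be analysed with the same machinery; the
concrete instance shipped is this package's own model, for which the
well-mixed (Dc -> infinity) limit applies.

At base abundances the model's homogeneous state is linearly stable for
every spatial mode (polarization is excitable, triggered by finite
perturbations); a band of linearly unstable modes opens once molecular
abundances are scaled up, notably at the 5.86-fold volume correction that
maps model-cell concentrations onto a real haploid cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_in, spherical_jn

from polarcomp.model import (
    FullState,
    ModelParameters,
    default_parameters,
    homogeneous_steady_state,
)

__all__ = [
    "DispersionSpectrum",
    "membrane_jacobian",
    "full_jacobian",
    "dispersion_relation_torus",
    "torus_mode_lattice",
    "unstable_mode_count",
    "abundance_volume_correction",
    "SphereKinetics",
    "sphere_mode_growth",
    "sweep_unstable_modes",
]


@dataclass
class DispersionSpectrum:
    """Leading growth rates per spatial mode."""

    modes: np.ndarray        # wavenumber q (1/um) on the torus, or l index
    growth_rates: np.ndarray  # leading eigenvalue real part (1/s)
    domain: str = "torus"    # "torus" | "sphere"
    params: ModelParameters | None = None
    abundance_scale: float = 1.0
    Dm: float | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.modes)
        self.modes = np.asarray(self.modes, dtype=float)[order]
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)[order]

    def leading(self) -> float:
        return float(np.max(self.growth_rates))


def membrane_jacobian(params: ModelParameters, state: FullState | None = None
                      ) -> np.ndarray:
    """4x4 Jacobian of the membrane reactions at a uniform state, with the
    cytosolic pools held fixed.  Species order (Cdc42T, Cdc42Dm, BemGEF42,
    BemGEFm)."""
    if state is None:
        state = homogeneous_steady_state(params)
    T = float(state.membrane.Cdc42T.flat[0])
    D = float(state.membrane.Cdc42Dm.flat[0])
    B42 = float(state.membrane.BemGEF42.flat[0])
    Bm = float(state.membrane.BemGEFm.flat[0])
    Bc = state.cytosol.BemGEFc
    p = params
    return np.array([
        [-p.k2b - p.k4a * Bm - p.k7 * Bc, p.k2a * Bm + p.k3 * B42,
         p.k3 * D + p.k4b, p.k2a * D - p.k4a * T],
        [p.k2b, -(p.k2a * Bm + p.k3 * B42) - p.k5b, -p.k3 * D, -p.k2a * D],
        [p.k4a * Bm + p.k7 * Bc, 0.0, -p.k4b, p.k4a * T],
        [-p.k4a * Bm, 0.0, p.k4b, -p.k1b - p.k4a * T],
    ])


def full_jacobian(params: ModelParameters, state: FullState | None = None
                  ) -> np.ndarray:
    """6x6 Jacobian of the uniform (q = 0) dynamics including the
    eta-weighted cytosolic pools.  Species order (Cdc42T, Cdc42Dm, BemGEF42,
    BemGEFm, Cdc42Dc, BemGEFc)."""
    if state is None:
        state = homogeneous_steady_state(params)
    p = params
    T = float(state.membrane.Cdc42T.flat[0])
    Bc = state.cytosol.BemGEFc
    J = np.zeros((6, 6))
    J[:4, :4] = membrane_jacobian(params, state)
    # membrane equations' dependence on the cytosolic pools
    J[1, 4] = p.k5a                       # Cdc42Dm <- k5a Cdc42Dc
    J[0, 5] = -p.k7 * T                   # Cdc42T loses k7 BemGEFc Cdc42T
    J[2, 5] = p.k7 * T                    # BemGEF42 gains the same
    J[3, 5] = p.k1a                       # BemGEFm <- k1a BemGEFc
    # cytosolic equations (uniform mode: spatial mean = value)
    J[4, 1] = p.eta * p.k5b
    J[4, 4] = -p.eta * p.k5a
    J[5, 3] = p.eta * p.k1b
    J[5, 5] = -p.eta * (p.k1a + p.k7 * T)
    J[5, 0] = -p.eta * p.k7 * Bc
    return J


def torus_mode_lattice(L: float, max_index: int = 12) -> np.ndarray:
    """Admissible nonzero wavenumbers q = 2 pi |(m, n)| / L on the torus.

    One entry per independent integer pair: m = 0..max_index with
    n = 1..max_index for m = 0 and n = -max_index..max_index otherwise
    (conjugate modes excluded, symmetry-degenerate modes kept individually).
    """
    pairs = [(0, n) for n in range(1, max_index + 1)]
    pairs += [(m, n) for m in range(1, max_index + 1)
              for n in range(-max_index, max_index + 1)]
    return 2.0 * np.pi * np.array([np.hypot(m, n) for m, n in pairs]) / L


def dispersion_relation_torus(params: ModelParameters, q_list,
                              state: FullState | None = None
                              ) -> DispersionSpectrum:
    """Leading eigenvalue versus wavenumber for the torus model.

    For q > 0 the leading eigenvalue of ``J4 - Dm q^2 I`` is returned; for
    q = 0 the leading *non-trivial* eigenvalue of the six-variable uniform
    Jacobian (which carries two exact zero eigenvalues from the conserved
    totals; these are excluded).
    """
    if state is None:
        state = homogeneous_steady_state(params)
    J4 = membrane_jacobian(params, state)
    q_arr = np.asarray(list(q_list), dtype=float)
    lead = np.empty_like(q_arr)
    for i, q in enumerate(q_arr):
        if q < 0:
            raise ValueError("wavenumbers must be >= 0")
        if q == 0:
            ev = np.linalg.eigvals(full_jacobian(params, state))
            # drop the two conservation zero-modes
            ev = sorted(ev, key=lambda z: abs(z))[2:]
            lead[i] = max(z.real for z in ev) if ev else 0.0
        else:
            ev = np.linalg.eigvals(J4 - params.Dm * q * q * np.eye(4))
            lead[i] = float(ev.real.max())
    return DispersionSpectrum(modes=q_arr, growth_rates=lead, domain="torus",
                              params=params, Dm=params.Dm)


def leading_eigenpair(params: ModelParameters, q: float,
                      state: FullState | None = None
                      ) -> tuple[float, np.ndarray]:
    """Leading eigenvalue and (real) eigenvector of the 4x4 operator at
    wavenumber q > 0; used to seed single-mode growth experiments."""
    if state is None:
        state = homogeneous_steady_state(params)
    A = membrane_jacobian(params, state) - params.Dm * q * q * np.eye(4)
    w, V = np.linalg.eig(A)
    k = int(np.argmax(w.real))
    if abs(w[k].imag) > 1e-10 * max(1.0, abs(w[k].real)):
        raise ValueError("leading eigenvalue is complex; no steady mode growth")
    v = V[:, k].real
    return float(w[k].real), v / np.max(np.abs(v))


def unstable_mode_count(spectrum: DispersionSpectrum,
                        tol: float = 0.0) -> int:
    """Number of admissible modes with positive leading growth rate.

    More than one positive growth rate is the necessary condition for
    competition between simultaneously emerging peaks.
    """
    return int(np.sum(spectrum.growth_rates > tol))


def abundance_volume_correction(molecule_numbers,
                                v_model_fL: float = 258.0,
                                v_cell_fL: float = 44.0):
    """Scale molecular abundances by the model-cell/real-cell volume ratio.

    Returns ``(scaled_numbers, factor)`` with ``factor = v_model / v_cell``
    (5.86 for the default 258 fL model sphere versus a 44 fL haploid cell).
    """
    if v_model_fL <= 0 or v_cell_fL <= 0:
        raise ValueError("volumes must be positive")
    factor = v_model_fL / v_cell_fL
    scaled = np.asarray(molecule_numbers, dtype=float) * factor
    if np.isscalar(molecule_numbers) or np.ndim(molecule_numbers) == 0:
        scaled = float(scaled)
    return scaled, factor


# ---------------------------------------------------------------------------
# spherical scaffold with finite cytosolic diffusion
# ---------------------------------------------------------------------------

@dataclass
class SphereKinetics:
    """Linearized kinetics of a membrane/cytosol system on a sphere.

    ``A_mm``: membrane reaction Jacobian (n_m x n_m), including attachment
    terms evaluated at the cytosolic surface concentrations.
    ``A_mc``: membrane equations' dependence on cytosolic surface values
    (n_m x n_c).
    ``B_cm``/``B_cc``: outward boundary flux of each cytosolic species,
    ``Dc_j dc_j/dr |_R = (B_cm u + B_cc c(R))_j`` — detachment from the
    membrane enters ``B_cm`` positively, attachment of cytosolic material
    enters ``B_cc`` negatively.
    ``Dc``: cytosolic diffusion coefficients (length n_c) — required,
    the model's own torus treatment covers the well-mixed limit.
    ``bulk_decay``: optional linear decay of cytosolic species in the bulk.
    """

    A_mm: np.ndarray
    A_mc: np.ndarray
    B_cm: np.ndarray
    B_cc: np.ndarray
    Dc: np.ndarray
    bulk_decay: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A_mm = np.atleast_2d(np.asarray(self.A_mm, dtype=float))
        self.A_mc = np.atleast_2d(np.asarray(self.A_mc, dtype=float))
        self.B_cm = np.atleast_2d(np.asarray(self.B_cm, dtype=float))
        self.B_cc = np.atleast_2d(np.asarray(self.B_cc, dtype=float))
        self.Dc = np.atleast_1d(np.asarray(self.Dc, dtype=float))
        if self.bulk_decay is None:
            self.bulk_decay = np.zeros_like(self.Dc)
        self.bulk_decay = np.atleast_1d(np.asarray(self.bulk_decay, dtype=float))

    @property
    def n_membrane(self) -> int:
        return self.A_mm.shape[0]

    @property
    def n_cytosol(self) -> int:
        return self.Dc.shape[0]


def _bessel_ratio(l: int, lam: float, Dc: float, gamma: float, R: float) -> float:
    """i_l(kR) / (Dc k i_l'(kR)) with k = sqrt((lam + gamma)/Dc).

    For lam + gamma < 0 the modified Bessel function continues to the
    ordinary spherical Bessel j_l and the ratio stays real:
    j_l(kR)/(Dc k j_l'(kR)).
    """
    mu = lam + gamma
    if mu > 0:
        k = np.sqrt(mu / Dc)
        num = spherical_in(l, k * R)
        den = Dc * k * spherical_in(l, k * R, derivative=True)
    elif mu == 0:
        if l == 0:
            return np.inf       # harmonic l=0 profile is constant: no flux
        return R / (Dc * l)     # c ~ r^l
    else:
        k = np.sqrt(-mu / Dc)
        num = spherical_jn(l, k * R)
        den = Dc * k * spherical_jn(l, k * R, derivative=True)
    if den == 0:
        return np.inf
    return num / den


def _sphere_char(l: int, lam: float, kin: SphereKinetics, R: float,
                 Dm: float) -> float:
    """det of the characteristic matrix; zero at an eigenvalue."""
    g = np.array([_bessel_ratio(l, lam, kin.Dc[j], kin.bulk_decay[j], R)
                  for j in range(kin.n_cytosol)])
    if np.any(~np.isfinite(g)):
        # no-flux cytosolic profile: surface value decouples unless B_cc acts
        G = np.diag(np.where(np.isfinite(g), g, 0.0))
        # treat infinite ratio as flux condition 0 = (B u + B_cc c) -> solve
        finite = np.isfinite(g)
        if not np.all(finite):
            # fall back: require boundary flux zero for those species
            Gf = np.diag(np.where(finite, g, 1e12))
            G = Gf
    else:
        G = np.diag(g)
    M = np.eye(kin.n_cytosol) - G @ kin.B_cc
    try:
        c_of_u = np.linalg.solve(M, G @ kin.B_cm)
    except np.linalg.LinAlgError:
        return np.nan
    eff = kin.A_mm + kin.A_mc @ c_of_u
    shift = lam + l * (l + 1) * Dm / (R * R)
    return float(np.linalg.det(eff - shift * np.eye(kin.n_membrane)))


def sphere_mode_growth(kinetics: SphereKinetics, R: float, Dm: float,
                       l_max: int = 8,
                       lam_range: tuple = None,
                       n_scan: int = 400) -> DispersionSpectrum:
    """Leading real eigenvalue per spherical-harmonic degree l.

    For each l = 0..l_max the characteristic function is scanned downward
    on a two-sided logarithmic eigenvalue grid (which resolves roots close
    to zero even when the reaction rates span decades) and the largest
    sign-change root is refined by bisection.  Brackets that straddle a pole
    of the characteristic function (possible on the oscillatory branch) are
    rejected by checking that the refined value is an actual zero.  Modes
    with no real root in the scanned range are reported as NaN.
    """
    if lam_range is None:
        scale = max(1.0, float(np.max(np.abs(kinetics.A_mm))))
        lam_range = (-3.0 * scale, 2.0 * scale)
    lo, hi = lam_range
    half = max(n_scan // 2, 50)
    pos = np.logspace(np.log10(max(hi, 1e-6)), -6, half)
    neg = -np.logspace(-6, np.log10(max(-lo, 1e-6)), half)
    grid = np.concatenate([pos, [0.0], neg])

    out = np.full(l_max + 1, np.nan)
    for l in range(l_max + 1):
        vals = np.array([_sphere_char(l, lam, kinetics, R, Dm)
                         for lam in grid])
        root = np.nan
        for i in range(len(grid) - 1):
            v0, v1 = vals[i], vals[i + 1]
            if not (np.isfinite(v0) and np.isfinite(v1)):
                continue
            if v0 == 0.0:
                root = grid[i]
                break
            if v0 * v1 < 0:
                cand = brentq(lambda x: _sphere_char(l, x, kinetics, R, Dm),
                              grid[i + 1], grid[i], xtol=1e-12)
                fc = _sphere_char(l, cand, kinetics, R, Dm)
                # a pole bracket converges onto the discontinuity, where the
                # function magnitude stays comparable to its neighbours
                if abs(fc) <= 1e-4 * max(abs(v0), abs(v1)):
                    root = cand
                    break
        out[l] = root
    return DispersionSpectrum(modes=np.arange(l_max + 1, dtype=float),
                              growth_rates=out, domain="sphere", Dm=Dm)


def model_sphere_kinetics(params: ModelParameters, Dc: float,
                          R: float | None = None,
                          state: FullState | None = None
                          ) -> tuple[SphereKinetics, float]:
    """This package's model configured for the spherical scaffold.

    The torus area is mapped onto a sphere of equal area (R = sqrt(A/4pi),
    2.5 um at the default 25 pi um^2) and the well-mixed cytosol is replaced
    by two diffusing cytosolic species with coefficient ``Dc``.  Boundary
    fluxes are scaled by the membrane shell thickness eta*R/3 so that shell
    concentrations (uM) and bulk concentrations (uM) are dimensionally
    matched.  Returns ``(kinetics, R)``.
    """
    if Dc <= 0:
        raise ValueError("cytosolic diffusion coefficient must be positive")
    if R is None:
        R = float(np.sqrt(params.area_A / (4.0 * np.pi)))
    if state is None:
        state = homogeneous_steady_state(params)
    p = params
    T = float(state.membrane.Cdc42T.flat[0])
    Bc = state.cytosol.BemGEFc
    A_mm = membrane_jacobian(params, state)
    # membrane equations' response to the cytosolic surface values
    A_mc = np.zeros((4, 2))
    A_mc[1, 0] = p.k5a
    A_mc[0, 1] = -p.k7 * T
    A_mc[2, 1] = p.k7 * T
    A_mc[3, 1] = p.k1a
    # outward cytosolic boundary flux Dc dc/dr|_R = B_cm u + B_cc c(R),
    # scaled from shell to bulk concentration units by the shell thickness
    delta = p.eta * R / 3.0
    B_cm = np.zeros((2, 4))
    B_cm[0, 1] = delta * p.k5b                  # GDI extraction of Cdc42Dm
    B_cm[1, 3] = delta * p.k1b                  # Bem1-GEF detachment
    B_cm[1, 0] = -delta * p.k7 * Bc             # recruitment by Cdc42T
    B_cc = np.array([[-delta * p.k5a, 0.0],
                     [0.0, -delta * (p.k1a + p.k7 * T)]])
    kin = SphereKinetics(A_mm=A_mm, A_mc=A_mc, B_cm=B_cm, B_cc=B_cc,
                         Dc=[Dc, Dc])
    return kin, R


# ---------------------------------------------------------------------------
# parameter sweeps (abundance correction x membrane diffusion)
# ---------------------------------------------------------------------------

def sweep_unstable_modes(base_params: ModelParameters | None = None,
                         abundance_scales=(1.0, 5.86),
                         Dm_values=(0.0025, 0.005, 0.01, 0.02, 0.03),
                         max_index: int = 12) -> "pd.DataFrame":
    """Unstable-mode counts over an (abundance scale, Dm) grid.

    The abundance grid defaults to the two-level comparison the volume
    correction defines: model-cell concentrations as-is versus scaled
    5.86-fold.  Returns a table (abundance_scale, Dm, n_unstable,
    max_growth_rate).
    """
    import pandas as pd

    if base_params is None:
        base_params = default_parameters()
    rows = []
    for scale in abundance_scales:
        for Dm in Dm_values:
            p = base_params.scaled_abundance(scale).with_(Dm=Dm)
            qs = torus_mode_lattice(p.L, max_index=max_index)
            spec = dispersion_relation_torus(p, qs)
            rows.append((scale, Dm, unstable_mode_count(spec), spec.leading()))
    return pd.DataFrame(rows, columns=["abundance_scale", "Dm", "n_unstable",
                                       "max_growth_rate"])
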