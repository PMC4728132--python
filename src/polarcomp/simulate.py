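"""Stochastic integration of the polarity model on a periodic grid.

Two steppers are provided:

``imex`` (default)
    Operator splitting per time step: (1) reactions advanced with a
    linearized backward-Euler (semi-implicit) update solved pointwise,
    which removes the severe stability restriction the fast Bem1-GEF
    binding/unbinding reactions impose on explicit schemes; (2) diffusion
    advanced with the exact exponential of the 5-point periodic Laplacian,
    evaluated in Fourier space; (3) the Euler-Maruyama noise increment.

``explicit``
    Plain Euler-Maruyama with 5-point diffusion, retained for validating
    the splitting scheme at small time steps.

After every substep the well-mixed cytosolic pools are updated by exact
mass bookkeeping: whatever net amount the membrane gained is removed from
the cytosol (weighted by the membrane-to-cytoplasm volume ratio), so both
conserved totals hold to machine precision, noise on or off.  The noise
term acts on membrane Bem1-GEF with white-noise scaling
``s * N(0,1) * sqrt(dt) / h`` per grid cell and is simultaneously removed
from the cytosolic Bem1-GEF pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from polarcomp.model import (
    CytosolState,
    FullState,
    MembraneState,
    ModelParameters,
    reaction_rates,
    total_bemgef,
    total_cdc42,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "periodic_laplacian",
    "step",
    "simulate",
    "seed_perturbations",
]


@dataclass
class SimulationConfig:
    """Numerical settings for a simulation run."""

    N: int = 64                    # grid points per side
    dt: float = 0.01               # time step (s)
    T: float = 100.0               # total simulated time (s)
    seed: int = 0
    noise: bool = True
    cadence: float = 1.0           # observer interval (s)
    stepper: str = "imex"          # "imex" | "explicit"
    clamp_tol: float = 1e-9        # largest negative excursion clamped to 0 (uM)

    def validate(self, params: ModelParameters) -> None:
        if self.stepper not in ("imex", "explicit"):
            raise ValueError(f"unknown stepper {self.stepper!r}")
        if self.N < 4 or self.dt <= 0 or self.T < 0:
            raise ValueError("invalid grid size, dt or T")
        h = params.L / self.N
        if self.stepper == "explicit" and params.Dm > 0:
            bound = h * h / (4.0 * params.Dm)
            if self.dt > bound:
                raise ValueError(
                    f"explicit stepper requires dt <= h^2/(4 Dm) = {bound:.4g} s")


@dataclass
class Trajectory:
    """Snapshots of a run at the observer cadence, with conserved totals."""

    times: list = field(default_factory=list)
    states: list = field(default_factory=list)      # FullState copies
    totals_cdc42: list = field(default_factory=list)
    totals_bemgef: list = field(default_factory=list)

    def append(self, state: FullState, params: ModelParameters) -> None:
        if self.times and state.t <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(state.t)
        self.states.append(state.copy())
        self.totals_cdc42.append(total_cdc42(state, params))
        self.totals_bemgef.append(total_bemgef(state, params))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final(self) -> FullState:
        return self.states[-1]

    def summary(self, params: ModelParameters,
                min_height: float | None = None) -> "pd.DataFrame":
        """Per-snapshot table: time, conserved totals, peak count and the
        tallest peak height of summed membrane Cdc42."""
        import pandas as pd

        from polarcomp.competition import detect_peaks

        if min_height is None:
            f0 = self.states[0].membrane.total_membrane_cdc42()
            min_height = 2.0 * float(np.median(f0))
        rows = []
        for t, state, tc, tb in zip(self.times, self.states,
                                    self.totals_cdc42, self.totals_bemgef):
            f = state.membrane.total_membrane_cdc42()
            peaks = detect_peaks(f, params.L, min_height=min_height,
                                 min_separation=0.5)
            rows.append((t, tc, tb, len(peaks),
                         peaks[0].height if peaks else np.nan))
        return pd.DataFrame(rows, columns=["t", "total_cdc42", "total_bemgef",
                                           "n_peaks", "max_peak_height"])

    def max_total_drift(self) -> float:
        """Largest relative drift of either conserved total over the run."""
        drifts = []
        for tot in (self.totals_cdc42, self.totals_bemgef):
            t0 = tot[0]
            if t0 > 0:
                drifts.append(float(np.max(np.abs(np.asarray(tot) - t0)) / t0))
        return max(drifts) if drifts else 0.0


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def periodic_laplacian(f: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with periodic wraparound on a square grid."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError(f"field must be square 2-D, got {f.shape}")
    if h <= 0:
        raise ValueError("grid spacing must be positive")
    return (np.roll(f, 1, 0) + np.roll(f, -1, 0)
            + np.roll(f, 1, 1) + np.roll(f, -1, 1) - 4.0 * f) / (h * h)


def _diffusion_propagator(N: int, h: float, Dm: float, dt: float) -> np.ndarray:
    """exp(dt * Dm * Lap5) eigenvalues on the rfft2 lattice.

    Uses the exact eigenvalues of the discrete 5-point operator so the split
    scheme integrates the same semi-discretization as the explicit stepper.
    """
    kx = np.fft.fftfreq(N) * N          # integer mode numbers
    ky = np.fft.rfftfreq(N) * N
    lam_x = -(2.0 - 2.0 * np.cos(2.0 * np.pi * kx / N)) / (h * h)
    lam_y = -(2.0 - 2.0 * np.cos(2.0 * np.pi * ky / N)) / (h * h)
    lam = lam_x[:, None] + lam_y[None, :]
    return np.exp(dt * Dm * lam)


# ---------------------------------------------------------------------------
# semi-implicit reaction kernel (pointwise 4x4 solve)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _react_imex_kernel(T, D, B42, Bm, Dc, Bc, dt, clamp_tol,
                       k1a, k1b, k2a, k2b, k3, k4a, k4b, k5a, k5b, k7):
    """Linearized backward-Euler reaction update, in place.

    Solves (I - dt*J) du = dt*R at every grid point with the cytosolic pools
    frozen.  Returns (sum of membrane Cdc42 change, sum of membrane Bem1-GEF
    change, error flag) for exact cytosol bookkeeping; error flag is 1 when a
    concentration went more negative than clamp_tol (time step too large).
    """
    n = T.size
    Tf = T.ravel()
    Df = D.ravel()
    B42f = B42.ravel()
    Bmf = Bm.ravel()
    sum_dC = 0.0
    sum_dB = 0.0
    err = 0
    A = np.empty((4, 4))
    b = np.empty(4)
    for i in range(n):
        t = Tf[i]
        d = Df[i]
        b42 = B42f[i]
        bm = Bmf[i]
        exch = (k2a * bm + k3 * b42) * d
        bind = (k4a * bm + k7 * Bc) * t
        rT = exch - k2b * t - bind + k4b * b42
        rD = k2b * t - exch - k5b * d + k5a * Dc
        rB42 = bind - k4b * b42
        rBm = k1a * Bc - k1b * bm + k4b * b42 - k4a * bm * t

        # Jacobian of (rT, rD, rB42, rBm) wrt (t, d, b42, bm)
        A[0, 0] = 1.0 - dt * (-k2b - k4a * bm - k7 * Bc)
        A[0, 1] = -dt * (k2a * bm + k3 * b42)
        A[0, 2] = -dt * (k3 * d + k4b)
        A[0, 3] = -dt * (k2a * d - k4a * t)
        A[1, 0] = -dt * k2b
        A[1, 1] = 1.0 - dt * (-(k2a * bm + k3 * b42) - k5b)
        A[1, 2] = -dt * (-k3 * d)
        A[1, 3] = -dt * (-k2a * d)
        A[2, 0] = -dt * (k4a * bm + k7 * Bc)
        A[2, 1] = 0.0
        A[2, 2] = 1.0 + dt * k4b
        A[2, 3] = -dt * (k4a * t)
        A[3, 0] = -dt * (-k4a * bm)
        A[3, 1] = 0.0
        A[3, 2] = -dt * k4b
        A[3, 3] = 1.0 - dt * (-k1b - k4a * t)
        b[0] = dt * rT
        b[1] = dt * rD
        b[2] = dt * rB42
        b[3] = dt * rBm

        # 4x4 Gaussian elimination with partial pivoting
        for col in range(3):
            piv = col
            amax = abs(A[col, col])
            for r in range(col + 1, 4):
                if abs(A[r, col]) > amax:
                    amax = abs(A[r, col])
                    piv = r
            if piv != col:
                for c in range(col, 4):
                    tmp = A[col, c]
                    A[col, c] = A[piv, c]
                    A[piv, c] = tmp
                tmp = b[col]
                b[col] = b[piv]
                b[piv] = tmp
            for r in range(col + 1, 4):
                m = A[r, col] / A[col, col]
                for c in range(col + 1, 4):
                    A[r, c] -= m * A[col, c]
                b[r] -= m * b[col]
        x3 = b[3] / A[3, 3]
        x2 = (b[2] - A[2, 3] * x3) / A[2, 2]
        x1 = (b[1] - A[1, 2] * x2 - A[1, 3] * x3) / A[1, 1]
        x0 = (b[0] - A[0, 1] * x1 - A[0, 2] * x2 - A[0, 3] * x3) / A[0, 0]

        nt = t + x0
        nd = d + x1
        nb42 = b42 + x2
        nbm = bm + x3
        if nt < 0.0:
            if nt < -clamp_tol:
                err = 1
            nt = 0.0
        if nd < 0.0:
            if nd < -clamp_tol:
                err = 1
            nd = 0.0
        if nb42 < 0.0:
            if nb42 < -clamp_tol:
                err = 1
            nb42 = 0.0
        if nbm < 0.0:
            if nbm < -clamp_tol:
                err = 1
            nbm = 0.0
        sum_dC += (nt - t) + (nd - d) + (nb42 - b42)
        sum_dB += (nb42 - b42) + (nbm - bm)
        Tf[i] = nt
        Df[i] = nd
        B42f[i] = nb42
        Bmf[i] = nbm
    return sum_dC, sum_dB, err


class _Stepper:
    """Caches grid-dependent quantities; advances raw field arrays."""

    def __init__(self, params: ModelParameters, config: SimulationConfig):
        config.validate(params)
        self.p = params
        self.cfg = config
        self.h = params.L / config.N
        self.npts = config.N * config.N
        self._prop = _diffusion_propagator(config.N, self.h, params.Dm, config.dt)
        self._noise_scale = params.noise_strength_s * np.sqrt(config.dt) / self.h

    def advance(self, fields: np.ndarray, cyt: np.ndarray,
                rng: np.random.Generator) -> None:
        """One dt, in place. fields: (4, N, N); cyt: [Cdc42Dc, BemGEFc]."""
        p, cfg = self.p, self.cfg
        if cfg.stepper == "imex":
            sum_dC, sum_dB, err = _react_imex_kernel(
                fields[0], fields[1], fields[2], fields[3],
                cyt[0], cyt[1], cfg.dt, cfg.clamp_tol,
                p.k1a, p.k1b, p.k2a, p.k2b, p.k3, p.k4a, p.k4b,
                p.k5a, p.k5b, p.k7)
            if err:
                raise FloatingPointError(
                    "reaction update drove a concentration below -clamp_tol; "
                    "reduce dt")
            cyt[0] -= p.eta * sum_dC / self.npts
            cyt[1] -= p.eta * sum_dB / self.npts
            if p.Dm > 0:
                for k in range(4):
                    fields[k] = np.fft.irfft2(
                        np.fft.rfft2(fields[k]) * self._prop, s=fields[k].shape)
        else:
            rates = reaction_rates(fields, CytosolState(cyt[0], cyt[1]), p,
                                   validate=False)
            old = fields.copy()
            for k in range(4):
                fields[k] += cfg.dt * (rates[k] + p.Dm * periodic_laplacian(
                    fields[k], self.h))
            self._clamp(fields)
            delta = fields - old
            cyt[0] -= p.eta * float(np.mean(delta[0] + delta[1] + delta[2]))
            cyt[1] -= p.eta * float(np.mean(delta[2] + delta[3]))

        if cfg.noise and p.noise_strength_s > 0:
            dW = rng.standard_normal(fields[3].shape)
            incr = self._noise_scale * dW
            fields[3] += incr
            # where the field is smaller than a noise excursion, clamp at zero
            # and charge only the realized increment to the cytosolic pool
            neg = fields[3] < 0
            if np.any(neg):
                incr = incr - np.where(neg, fields[3], 0.0)
                fields[3] = np.where(neg, 0.0, fields[3])
            cyt[1] -= p.eta * float(np.mean(incr))
        if not np.all(np.isfinite(fields)) or not np.all(np.isfinite(cyt)):
            raise FloatingPointError("simulation blew up (NaN/Inf); reduce dt")

    def _clamp(self, fields: np.ndarray) -> None:
        mn = float(fields.min())
        if mn < 0:
            if mn < -self.cfg.clamp_tol:
                raise FloatingPointError(
                    f"concentration reached {mn:.3e} uM (< -clamp_tol); reduce dt")
            np.clip(fields, 0.0, None, out=fields)


def step(state: FullState, params: ModelParameters, config: SimulationConfig,
         rng: np.random.Generator) -> FullState:
    """Advance a state by one time step (convenience wrapper)."""
    fields = state.membrane.as_array().astype(float)
    cyt = np.array([state.cytosol.Cdc42Dc, state.cytosol.BemGEFc], dtype=float)
    _Stepper(params, config).advance(fields, cyt, rng)
    return FullState(MembraneState.from_array(fields),
                     CytosolState(float(cyt[0]), float(cyt[1])),
                     state.t + config.dt)


def simulate(state0: FullState, params: ModelParameters,
             config: SimulationConfig,
             stop_condition=None) -> Trajectory:
    """Integrate from ``state0`` for ``config.T`` seconds.

    Snapshots are recorded at the observer cadence (and at t=0 and the end).
    ``stop_condition(state)``, if given, is evaluated at each snapshot and
    terminates the run early when it returns True.
    """
    config.validate(params)
    rng = np.random.default_rng(config.seed)
    stepper = _Stepper(params, config)
    fields = state0.membrane.as_array().astype(float)
    cyt = np.array([state0.cytosol.Cdc42Dc, state0.cytosol.BemGEFc], dtype=float)
    t0 = state0.t

    traj = Trajectory()
    traj.append(state0, params)
    n_steps = int(round(config.T / config.dt))
    snap_every = max(1, int(round(config.cadence / config.dt)))
    for i in range(1, n_steps + 1):
        stepper.advance(fields, cyt, rng)
        if i % snap_every == 0 or i == n_steps:
            state = FullState(MembraneState.from_array(fields.copy()),
                              CytosolState(float(cyt[0]), float(cyt[1])),
                              t0 + i * config.dt)
            traj.append(state, params)
            if stop_condition is not None and stop_condition(state):
                break
    return traj


def seed_perturbations(state: FullState, params: ModelParameters,
                       centers, amplitude: float = 20.0,
                       width: float = 0.6) -> FullState:
    """Add identical Gaussian bumps of active Cdc42 at the given centers.

    Each bump adds ``amplitude * exp(-r^2 / (2 width^2))`` (uM) to the
    membrane GTP-Cdc42 field, plus a proportional Bem1-GEF42 bump scaled by
    the ratio of the conserved totals, using the periodic (torus) distance.
    The equivalent cytosol-equivalent mass is removed from the cytoplasmic
    pools so both conserved totals are exactly unchanged.
    """
    new = state.copy()
    if len(centers) == 0:
        return new
    N = state.N
    L = params.L
    h = L / N
    xs = (np.arange(N) + 0.5) * h
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    bump = np.zeros((N, N))
    for (cx, cy) in centers:
        if not (0 <= cx <= L and 0 <= cy <= L):
            raise ValueError(f"center ({cx}, {cy}) outside domain [0, {L}]")
        dx = np.abs(X - cx)
        dy = np.abs(Y - cy)
        dx = np.minimum(dx, L - dx)
        dy = np.minimum(dy, L - dy)
        bump += amplitude * np.exp(-(dx * dx + dy * dy) / (2.0 * width * width))
    ratio = params.total_bemgef / params.total_cdc42 if params.total_cdc42 > 0 else 0.0
    bump_b = ratio * bump
    new.membrane.Cdc42T += bump
    new.membrane.BemGEF42 += bump_b
    d_cdc42 = params.eta * float(np.mean(bump + bump_b))
    d_bemgef = params.eta * float(np.mean(bump_b))
    if new.cytosol.Cdc42Dc < d_cdc42 or new.cytosol.BemGEFc < d_bemgef:
        raise ValueError("perturbation would drive a cytosolic pool negative")
    new.cytosol.Cdc42Dc -= d_cdc42
    new.cytosol.BemGEFc -= d_bemgef
    return new
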