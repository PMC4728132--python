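"""Core reaction-diffusion model of yeast Cdc42 polarity establishment.

The model tracks four membrane-bound species on a periodic square membrane
patch (a torus) and two well-mixed cytoplasmic pools:

==============  =======================================================
``Cdc42T``      GTP-loaded (active) Cdc42 on the membrane
``Cdc42Dm``     GDP-loaded Cdc42 on the membrane
``BemGEF42``    Bem1-GEF complex bound to GTP-Cdc42
``BemGEFm``     free Bem1-GEF complex on the membrane
``Cdc42Dc``     cytoplasmic GDP-Cdc42 (GDI-bound pool)
``BemGEFc``     cytoplasmic Bem1-GEF complex
==============  =======================================================

Positive feedback arises because membrane GTP-Cdc42 recruits cytoplasmic
Bem1-GEF complexes (rate ``k7``), which locally activate further Cdc42.
GAP-mediated hydrolysis is a first-order sink (``k2b``) and GDI-mediated
membrane/cytoplasm shuttling of GDP-Cdc42 is represented by first-order
exchange (``k5a``/``k5b``).

Membrane fields carry "shell" concentrations in uM; the membrane-to-cytoplasm
volume ratio ``eta`` converts between the two compartments, so the conserved
totals are cytosol-equivalent::

    total Cdc42   = eta * <Cdc42T + Cdc42Dm + BemGEF42> + Cdc42Dc
    total BemGEF  = eta * <BemGEFm + BemGEF42>          + BemGEFc

where ``< >`` denotes the spatial mean over the membrane.  With this
convention summing the governing equations gives exactly zero, i.e. both
totals are conserved along every trajectory (the stochastic membrane/cytosol
exchange term is mass-neutral by construction).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import optimize

__all__ = [
    "ModelParameters",
    "MembraneState",
    "CytosolState",
    "FullState",
    "default_parameters",
    "reaction_rates",
    "total_cdc42",
    "total_bemgef",
    "homogeneous_steady_state",
]

# names of the four membrane fields, in canonical order
MEMBRANE_SPECIES = ("Cdc42T", "Cdc42Dm", "BemGEF42", "BemGEFm")
CYTOSOL_SPECIES = ("Cdc42Dc", "BemGEFc")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, diffusion, geometry and conserved totals.

    Units: first-order rates 1/s, bimolecular rates 1/(uM s), ``Dm`` um^2/s,
    ``area_A`` um^2, totals uM (cytosol-equivalent), ``eta`` dimensionless.
    ``noise_strength_s`` multiplies unit-variance Gaussian white noise on the
    membrane Bem1-GEF equation (balanced by an opposite cytosolic term).
    """

    k1a: float = 10.0       # BemGEFc -> BemGEFm
    k1b: float = 10.0       # BemGEFm -> BemGEFc
    k2a: float = 0.16       # Cdc42Dm + BemGEFm -> Cdc42T
    k2b: float = 1.75       # Cdc42T -> Cdc42Dm (GAP)
    k3: float = 0.35        # Cdc42Dm + BemGEF42 -> Cdc42T
    k4a: float = 10.0       # BemGEFm + Cdc42T -> BemGEF42
    k4b: float = 10.0       # BemGEF42 -> BemGEFm + Cdc42T
    k5a: float = 36.0       # Cdc42Dc -> Cdc42Dm (GDI delivery)
    k5b: float = 0.65       # Cdc42Dm -> Cdc42Dc (GDI extraction)
    k7: float = 10.0        # BemGEFc + Cdc42T -> BemGEF42
    Dm: float = 0.0025      # membrane diffusion coefficient
    eta: float = 0.01       # membrane-to-cytoplasm volume ratio
    area_A: float = 25.0 * np.pi
    total_cdc42: float = 1.0
    total_bemgef: float = 0.017
    noise_strength_s: float = 1e-4

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")

    @property
    def L(self) -> float:
        """Side length of the periodic membrane patch (um)."""
        return float(np.sqrt(self.area_A))

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def scaled_abundance(self, factor: float) -> "ModelParameters":
        """Scale both conserved totals by ``factor`` (kinetics unchanged)."""
        if factor <= 0:
            raise ValueError("abundance scale factor must be positive")
        return self.with_(total_cdc42=self.total_cdc42 * factor,
                          total_bemgef=self.total_bemgef * factor)

    # -- config-file round trip ------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        """Write the parameter set as a flat key -> value config file."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def default_parameters() -> ModelParameters:
    """Default parameter set of the model."""
    return ModelParameters()


@dataclass
class MembraneState:
    """Four membrane concentration fields (uM) on an N x N periodic grid."""

    Cdc42T: np.ndarray
    Cdc42Dm: np.ndarray
    BemGEF42: np.ndarray
    BemGEFm: np.ndarray

    def __post_init__(self) -> None:
        shape = self.Cdc42T.shape
        if len(shape) != 2 or shape[0] != shape[1]:
            raise ValueError(f"membrane fields must be square 2-D, got {shape}")
        for name in MEMBRANE_SPECIES:
            if getattr(self, name).shape != shape:
                raise ValueError("membrane fields must share one grid")

    @property
    def N(self) -> int:
        return self.Cdc42T.shape[0]

    def as_array(self) -> np.ndarray:
        """Stack the four fields into shape (4, N, N) (canonical order)."""
        return np.stack([getattr(self, s) for s in MEMBRANE_SPECIES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "MembraneState":
        return cls(*(np.array(a, dtype=float) for a in arr))

    def total_membrane_cdc42(self) -> np.ndarray:
        """Summed membrane Cdc42-carrying concentration field (uM)."""
        return self.Cdc42T + self.Cdc42Dm + self.BemGEF42

    def copy(self) -> "MembraneState":
        return MembraneState(*(getattr(self, s).copy() for s in MEMBRANE_SPECIES))


@dataclass
class CytosolState:
    """Well-mixed cytoplasmic pools (uM)."""

    Cdc42Dc: float
    BemGEFc: float

    def copy(self) -> "CytosolState":
        return CytosolState(self.Cdc42Dc, self.BemGEFc)


@dataclass
class FullState:
    """Membrane fields + cytosolic pools + simulation time."""

    membrane: MembraneState
    cytosol: CytosolState
    t: float = 0.0

    @property
    def N(self) -> int:
        return self.membrane.N

    def copy(self) -> "FullState":
        return FullState(self.membrane.copy(), self.cytosol.copy(), self.t)

    @classmethod
    def uniform(cls, N: int, values: dict, t: float = 0.0) -> "FullState":
        """Spatially uniform state from a species-name -> value mapping."""
        fields = [np.full((N, N), float(values.get(s, 0.0))) for s in MEMBRANE_SPECIES]
        cyt = CytosolState(float(values.get("Cdc42Dc", 0.0)),
                           float(values.get("BemGEFc", 0.0)))
        return cls(MembraneState(*fields), cyt, t)

    # -- serialization ----------------------------------------------------
    def save(self, path, params: ModelParameters | None = None) -> None:
        meta = {"t": self.t, "N": self.N}
        if params is not None:
            meta["L"] = params.L
            meta["params_hash"] = params.hash()
        np.savez(path,
                 **{s: getattr(self.membrane, s) for s in MEMBRANE_SPECIES},
                 Cdc42Dc=self.cytosol.Cdc42Dc, BemGEFc=self.cytosol.BemGEFc,
                 meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "FullState":
        with np.load(path, allow_pickle=False) as f:
            mem = MembraneState(*(f[s] for s in MEMBRANE_SPECIES))
            cyt = CytosolState(float(f["Cdc42Dc"]), float(f["BemGEFc"]))
            t = json.loads(str(f["meta"]))["t"]
        return cls(mem, cyt, t)


# ---------------------------------------------------------------------------
# reaction kinetics
# ---------------------------------------------------------------------------

def reaction_rates(membrane, cytosol: CytosolState,
                   params: ModelParameters,
                   validate: bool = True) -> tuple[np.ndarray, ...]:
    """Pointwise reaction terms of the four membrane equations (uM/s).

    ``membrane`` may be a :class:`MembraneState` or a (4, ...) array in
    canonical species order.  Diffusion and noise are excluded; the cytosolic
    pools are treated as given.  Returns rates in canonical order
    (Cdc42T, Cdc42Dm, BemGEF42, BemGEFm).
    """
    if isinstance(membrane, MembraneState):
        T, Dm42, B42, Bm = (membrane.Cdc42T, membrane.Cdc42Dm,
                            membrane.BemGEF42, membrane.BemGEFm)
    else:
        T, Dm42, B42, Bm = np.asarray(membrane, dtype=float)
    Dc, Bc = cytosol.Cdc42Dc, cytosol.BemGEFc
    if validate:
        for arr in (T, Dm42, B42, Bm):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("negative membrane concentration")
        if Dc < 0 or Bc < 0:
            raise ValueError("negative cytosolic concentration")

    p = params
    exchange = (p.k2a * Bm + p.k3 * B42) * Dm42      # GDP->GTP loading by GEF
    binding = (p.k4a * Bm + p.k7 * Bc) * T           # Bem1-GEF capture by Cdc42T

    dT = exchange - p.k2b * T - binding + p.k4b * B42
    dDm = p.k2b * T - exchange - p.k5b * Dm42 + p.k5a * Dc
    dB42 = binding - p.k4b * B42
    dBm = p.k1a * Bc - p.k1b * Bm + p.k4b * B42 - p.k4a * Bm * T
    return dT, dDm, dB42, dBm


def cytosol_rates(membrane: MembraneState, cytosol: CytosolState,
                  params: ModelParameters) -> tuple[float, float]:
    """Deterministic reaction terms of the two cytosolic pool equations (uM/s).

    The membrane integrals ``(eta/A) * Int(...) dA`` reduce to ``eta`` times
    the spatial mean of the integrand on a uniform grid.
    """
    p = params
    dDc = p.eta * float(np.mean(p.k5b * membrane.Cdc42Dm)) - p.eta * p.k5a * cytosol.Cdc42Dc
    dBc = p.eta * (float(np.mean(p.k1b * membrane.BemGEFm))
                   - p.k1a * cytosol.BemGEFc
                   - p.k7 * cytosol.BemGEFc * float(np.mean(membrane.Cdc42T)))
    return dDc, dBc


def total_cdc42(state: FullState, params: ModelParameters) -> float:
    """Cytosol-equivalent total Cdc42 concentration (uM)."""
    mem = state.membrane
    return params.eta * float(np.mean(mem.Cdc42T + mem.Cdc42Dm + mem.BemGEF42)) \
        + state.cytosol.Cdc42Dc


def total_bemgef(state: FullState, params: ModelParameters) -> float:
    """Cytosol-equivalent total Bem1-GEF concentration (uM)."""
    mem = state.membrane
    return params.eta * float(np.mean(mem.BemGEFm + mem.BemGEF42)) \
        + state.cytosol.BemGEFc


# ---------------------------------------------------------------------------
# homogeneous steady state
# ---------------------------------------------------------------------------

def homogeneous_steady_state(params: ModelParameters, N: int = 1,
                             tol: float = 1e-12) -> FullState:
    """Spatially uniform fixed point consistent with both conserved totals.

    Solves the four membrane reaction balances together with the two
    conservation constraints (the two cytosolic balances are linearly
    dependent on these).  Raises ``RuntimeError`` if the root finder does
    not reach the requested residual norm.
    """
    p = params
    if p.total_cdc42 == 0 and p.total_bemgef == 0:
        return FullState.uniform(N, {})

    def residual(u):
        T, Dm42, B42, Bm, Dc, Bc = u
        dT, dDm, dB42, dBm = reaction_rates(
            np.array([T, Dm42, B42, Bm]), CytosolState(Dc, Bc), p,
            validate=False)
        cons_c = p.eta * (T + Dm42 + B42) + Dc - p.total_cdc42
        cons_b = p.eta * (Bm + B42) + Bc - p.total_bemgef
        return [float(dT), float(dDm), float(dB42), float(dBm), cons_c, cons_b]

    # analytic guess from the two membrane/cytosol exchange balances,
    # neglecting the (small) GTP-loaded pools
    dc0 = p.total_cdc42 / (1.0 + p.eta * p.k5a / max(p.k5b, 1e-12)) \
        if p.k5b > 0 else p.total_cdc42
    dm0 = p.k5a * dc0 / p.k5b if p.k5b > 0 else 0.0
    bc0 = p.total_bemgef / (1.0 + p.eta * p.k1a / max(p.k1b, 1e-12)) \
        if p.k1b > 0 else p.total_bemgef
    bm0 = p.k1a * bc0 / p.k1b if p.k1b > 0 else 0.0
    t0 = (p.k2a * bm0) * dm0 / max(p.k2b, 1e-12)
    guesses = [
        [t0, dm0, 1e-2 * bm0, bm0, dc0, bc0],
        [1e-2, 1e-1, 1e-3, 1e-3, 0.9 * p.total_cdc42, 0.9 * p.total_bemgef],
        [1.0, 1.0, 0.1, 0.1, 0.5 * p.total_cdc42, 0.5 * p.total_bemgef],
        [1e-4, 1e-3, 1e-5, 1e-4, p.total_cdc42, p.total_bemgef],
    ]
    # relaxation fallback: integrate the well-mixed (uniform) system, which
    # converges onto the fixed point whenever the uniform dynamics are
    # attracting, then let the root finder polish the result
    def relaxed_guess(g):
        from scipy.integrate import solve_ivp

        def rhs(_, u):
            T, Dm42, B42, Bm, Dc, Bc = u
            dT, dDm, dB42, dBm = reaction_rates(
                np.array([T, Dm42, B42, Bm]), CytosolState(Dc, Bc), p,
                validate=False)
            dDc = p.eta * (p.k5b * Dm42 - p.k5a * Dc)
            dBc = p.eta * (p.k1b * Bm - p.k1a * Bc - p.k7 * Bc * T)
            return [dT, dDm, dB42, dBm, dDc, dBc]

        g = np.asarray(g, dtype=float)
        # project onto the conservation constraints via the cytosolic pools
        g[4] = max(p.total_cdc42 - p.eta * (g[0] + g[1] + g[2]), 1e-6)
        g[5] = max(p.total_bemgef - p.eta * (g[2] + g[3]), 1e-8)
        sol = solve_ivp(rhs, (0.0, 5000.0), g, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        return sol.y[:, -1]

    rng = np.random.default_rng(12345)
    for _ in range(10):
        jitter = np.exp(rng.uniform(-1.5, 1.5, 6))
        guesses.append(list(np.asarray(guesses[0]) * jitter + 1e-8))
    best = None
    for attempt, g in enumerate(guesses):
        if attempt in (0, 4):          # polish the best guesses by relaxation
            g = relaxed_guess(g)
        sol = optimize.root(residual, g, method="hybr", options={"xtol": 1e-14})
        res = float(np.max(np.abs(residual(sol.x))))
        if np.all(np.asarray(sol.x) >= -1e-14) and (best is None or res < best[1]):
            best = (sol.x, res)
        if best is not None and best[1] < tol:
            break
    if best is None or best[1] > max(tol, 1e-9):
        raise RuntimeError(
            f"homogeneous steady state root finding failed (residual {best[1] if best else 'n/a'})")
    x = np.clip(best[0], 0.0, None)
    values = dict(zip(MEMBRANE_SPECIES + CYTOSOL_SPECIES, x))
    return FullState.uniform(N, values)
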