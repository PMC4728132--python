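"""Peak detection, waistline flux accounting and the two-peak competition assay.

A polarity peak is characterized by the contour at which the summed membrane
Cdc42 concentration (GTP-Cdc42 + membrane GDP-Cdc42 + Bem1-GEF-bound Cdc42)
falls to half its value at the peak center — the peak's "waistline".  The
content within the waistline, the diffusive escape of Cdc42 across it, and
the net delivery of Cdc42 from the cytoplasm into the enclosed disc quantify
the tug-of-war between coexisting peaks: recruitment from the common
cytoplasmic pool scales with peak size faster than diffusive loss does, so
the larger peak outcompetes the smaller one.

The diffusive outflux across the waistline (a line integral of -Dm dC/dr) is
evaluated with the divergence theorem as ``-Dm * sum(Lap C) * h^2`` over the
grid cells inside the waistline circle, using the same 5-point Laplacian the
simulator uses.  At a discrete stationary state this makes recruitment and
diffusive loss balance exactly, mirroring the continuum identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polarcomp.model import FullState, ModelParameters, homogeneous_steady_state
from polarcomp.simulate import (
    SimulationConfig,
    Trajectory,
    periodic_laplacian,
    seed_perturbations,
    simulate,
)

__all__ = [
    "PeakSummary",
    "CompetitionResult",
    "detect_peaks",
    "radial_profile",
    "periodic_distance",
    "waistline",
    "summarize_peak",
    "diffusive_flux_across_waistline",
    "cytoplasmic_flux_within_waistline",
    "rate_balance_curve",
    "balance_intersections",
    "relax_two_peak_state",
    "run_competition_experiment",
]


@dataclass
class PeakSummary:
    """A detected polarity peak and its waistline flux accounting."""

    centroid: tuple          # (x, y) um
    height: float            # uM, summed membrane Cdc42 at the peak
    radius: float | None = None          # waistline radius (um)
    content: float | None = None         # uM um^2 within the waistline
    diffusive_outflux: float | None = None   # content units / s (positive = loss)
    loss_percent_per_s: float | None = None
    cytoplasmic_influx: float | None = None  # content units / s (positive = gain)


def _periodic_delta(a: np.ndarray, b: float, L: float) -> np.ndarray:
    d = a - b
    return (d + L / 2.0) % L - L / 2.0


def periodic_distance(p1, p2, L: float) -> float:
    """Shortest torus distance between two points (um)."""
    dx = abs(p1[0] - p2[0])
    dy = abs(p1[1] - p2[1])
    dx = min(dx, L - dx)
    dy = min(dy, L - dy)
    return float(np.hypot(dx, dy))


def detect_peaks(f: np.ndarray, L: float, min_height: float,
                 min_separation: float = 0.5) -> list[PeakSummary]:
    """Local maxima of a periodic field above ``min_height``.

    Maxima closer than ``min_separation`` (torus distance, um) are merged,
    keeping the higher one.  Centroids are refined by an intensity-weighted
    center of mass over a small window around each maximum.  Returned sorted
    by height, descending.
    """
    f = np.asarray(f, dtype=float)
    N = f.shape[0]
    h = L / N
    is_max = np.ones_like(f, dtype=bool)
    any_strict = np.zeros_like(f, dtype=bool)   # plateaus are not peaks
    neighbours = [np.roll(f, sh, ax) for ax, sh in
                  ((0, 1), (0, -1), (1, 1), (1, -1))]
    neighbours += [np.roll(np.roll(f, sx, 0), sy, 1)
                   for sx in (1, -1) for sy in (1, -1)]
    for nb in neighbours:
        is_max &= f >= nb
        any_strict |= f > nb
    is_max &= any_strict & (f > min_height)
    idx = np.argwhere(is_max)
    cand = sorted(((float(f[i, j]), i, j) for i, j in idx), reverse=True)

    kept: list[tuple[float, int, int]] = []
    for height, i, j in cand:
        pos = ((i + 0.5) * h, (j + 0.5) * h)
        if all(periodic_distance(pos, ((ki + 0.5) * h, (kj + 0.5) * h), L)
               >= min_separation for _, ki, kj in kept):
            kept.append((height, i, j))

    peaks = []
    w = max(2, int(round(min_separation / h / 2)))
    for height, i, j in kept:
        # intensity-weighted centroid in a (2w+1)^2 window, periodic
        di = np.arange(-w, w + 1)
        I = (i + di) % N
        J = (j + di) % N
        patch = f[np.ix_(I, J)]
        wts = np.clip(patch - patch.min(), 0, None)
        tot = wts.sum()
        if tot > 0:
            ci = i + float((wts.sum(axis=1) * di).sum() / tot)
            cj = j + float((wts.sum(axis=0) * di).sum() / tot)
        else:
            ci, cj = float(i), float(j)
        peaks.append(PeakSummary(
            centroid=(((ci + 0.5) * h) % L, ((cj + 0.5) * h) % L),
            height=height))
    return peaks


def radial_profile(f: np.ndarray, center, L: float,
                   nbins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged profile of a periodic field around ``center``.

    Returns (radii, mean values); bin width is half a grid cell.
    """
    f = np.asarray(f, dtype=float)
    N = f.shape[0]
    h = L / N
    xs = (np.arange(N) + 0.5) * h
    dx = _periodic_delta(xs, center[0], L)
    dy = _periodic_delta(xs, center[1], L)
    r = np.sqrt(dx[:, None] ** 2 + dy[None, :] ** 2)
    if nbins is None:
        nbins = N
    edges = np.linspace(0.0, L / 2.0, nbins + 1)
    which = np.digitize(r.ravel(), edges) - 1
    which = np.clip(which, 0, nbins - 1)
    sums = np.bincount(which, weights=f.ravel(), minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    valid = counts > 0
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids[valid], sums[valid] / counts[valid]


def waistline(f: np.ndarray, peak: PeakSummary, L: float) -> float:
    """Radius (um) at which the azimuthal-mean profile first falls to half
    the peak value."""
    radii, prof = radial_profile(f, peak.centroid, L)
    half = 0.5 * peak.height
    below = np.nonzero(prof <= half)[0]
    if len(below) == 0:
        raise ValueError("profile never falls to half-maximum; peak overlaps domain")
    k = below[0]
    if k == 0:
        return float(radii[0])
    # linear interpolation between bracketing bins
    r0, r1 = radii[k - 1], radii[k]
    v0, v1 = prof[k - 1], prof[k]
    return float(r0 + (v0 - half) / (v0 - v1) * (r1 - r0))


def _disc_mask(N: int, L: float, center, radius: float) -> np.ndarray:
    h = L / N
    xs = (np.arange(N) + 0.5) * h
    dx = _periodic_delta(xs, center[0], L)
    dy = _periodic_delta(xs, center[1], L)
    r2 = dx[:, None] ** 2 + dy[None, :] ** 2
    return r2 <= radius * radius


def summarize_peak(state: FullState, peak: PeakSummary,
                   params: ModelParameters) -> PeakSummary:
    """Fill in waistline radius, content and both fluxes for a peak."""
    f = state.membrane.total_membrane_cdc42()
    L = params.L
    h = L / state.N
    peak.radius = waistline(f, peak, L)
    mask = _disc_mask(state.N, L, peak.centroid, peak.radius)
    peak.content = float(f[mask].sum() * h * h)
    flux, pct = diffusive_flux_across_waistline(f, peak, params.Dm, L)
    peak.diffusive_outflux = flux
    peak.loss_percent_per_s = pct
    peak.cytoplasmic_influx = cytoplasmic_flux_within_waistline(state, peak, params)
    return peak


def diffusive_flux_across_waistline(f: np.ndarray, peak: PeakSummary,
                                    Dm: float, L: float) -> tuple[float, float]:
    """Diffusive escape of summed membrane Cdc42 across the waistline.

    Returns ``(outflux, loss_percent_per_s)`` where outflux is the line
    integral of ``-Dm dC/dr`` around the waistline circle (uM um^2 / s,
    positive when the peak loses material), evaluated via the divergence
    theorem on the discrete grid.
    """
    if peak.radius is None:
        peak = PeakSummary(peak.centroid, peak.height,
                           radius=waistline(f, peak, L))
    N = f.shape[0]
    h = L / N
    mask = _disc_mask(N, L, peak.centroid, peak.radius)
    lap = periodic_laplacian(f, h)
    outflux = -Dm * float(lap[mask].sum()) * h * h
    content = float(f[mask].sum() * h * h)
    pct = 100.0 * outflux / content if content > 0 else np.nan
    return outflux, pct


def cytoplasmic_flux_within_waistline(state: FullState, peak: PeakSummary,
                                      params: ModelParameters) -> float:
    """Net Cdc42 delivery from the cytoplasm into the waistline disc.

    GDI-mediated exchange is the only membrane/cytoplasm Cdc42 route in the
    model, so this is the disc integral of ``k5a Cdc42Dc - k5b Cdc42Dm``
    (uM um^2 / s, positive = net recruitment).
    """
    if peak.radius is None:
        raise ValueError("waistline radius not set; call summarize_peak first")
    N = state.N
    L = params.L
    h = L / N
    mask = _disc_mask(N, L, peak.centroid, peak.radius)
    integrand = params.k5a * state.cytosol.Cdc42Dc - params.k5b * state.membrane.Cdc42Dm
    return float(integrand[mask].sum() * h * h)


# ---------------------------------------------------------------------------
# the two-peak competition experiment
# ---------------------------------------------------------------------------

@dataclass
class CompetitionResult:
    """Outcome of one seeded two-peak competition run."""

    coexistence_time: float | None      # s; None when censored
    winner: int | None                  # 0 or 1; None when censored
    censored: bool
    times: np.ndarray                   # snapshot times (s), noise phase
    peak_heights: np.ndarray            # (n_snapshots, 2)
    peak_contents: np.ndarray           # (n_snapshots, 2); NaN once extinct
    cytosol_cdc42: np.ndarray
    cytosol_bemgef: np.ndarray
    peak_recruitment: np.ndarray | None = None   # (n_snapshots, 2) content/s
    peak_outflux: np.ndarray | None = None       # (n_snapshots, 2) content/s
    growth_duration: float | None = None
    competition_duration: float | None = None
    two_peak_state: FullState | None = None
    final_state: FullState | None = None
    extinction_threshold: float = np.nan


def _two_peak_centers(L: float) -> list[tuple]:
    # diametrically opposite on the torus: offset by (L/2, L/2)
    return [(L / 4.0, L / 4.0), (3.0 * L / 4.0, 3.0 * L / 4.0)]


def relax_two_peak_state(params: ModelParameters, N: int = 64,
                         dt: float = 0.01, T_relax: float = 300.0,
                         amplitude: float = 30.0, width: float = 0.6) -> FullState:
    """Homogeneous steady state + two antipodal seeds, relaxed without noise
    to the (unstable) symmetric two-peak stationary state."""
    hss = homogeneous_steady_state(params, N=N)
    st = seed_perturbations(hss, params, _two_peak_centers(params.L),
                            amplitude=amplitude, width=width)
    cfg = SimulationConfig(N=N, dt=dt, T=T_relax, noise=False,
                           cadence=max(T_relax, dt))
    out = simulate(st, params, cfg).final
    out.t = 0.0
    return out


def run_competition_experiment(params: ModelParameters,
                               config: SimulationConfig,
                               seed: int | None = None,
                               T_relax: float = 300.0,
                               T_settle: float = 50.0,
                               amplitude: float = 30.0,
                               width: float = 0.6,
                               two_peak_state: FullState | None = None,
                               ) -> CompetitionResult:
    """Seed two antipodal peaks, relax noise-free, then compete under noise.

    The noisy phase runs until one peak's height falls below twice the
    homogeneous steady-state level of summed membrane Cdc42 (extinction), or
    ``config.T`` is exhausted (censored).  After extinction the run continues
    for ``T_settle`` so the winner reaches its one-peak steady state.
    ``two_peak_state`` lets callers reuse one relaxed symmetric state across
    seeds (the relaxation is noise-free, hence seed-independent).
    """
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    N = config.N
    L = params.L
    hss = homogeneous_steady_state(params, N=N)
    hss_level = float(hss.membrane.total_membrane_cdc42()[0, 0])
    extinct_below = 2.0 * hss_level

    if two_peak_state is None:
        two_peak_state = relax_two_peak_state(
            params, N=N, dt=config.dt, T_relax=T_relax,
            amplitude=amplitude, width=width)
    start = two_peak_state.copy()
    start.t = 0.0

    centers = _two_peak_centers(L)
    masks = [_disc_mask(N, L, c, L / (2 * np.sqrt(2))) for c in centers]

    def side_heights(state: FullState) -> tuple[float, float]:
        f = state.membrane.total_membrane_cdc42()
        return float(f[masks[0]].max()), float(f[masks[1]].max())

    extinct_seen = {"t": None}

    def stop(state: FullState) -> bool:
        h0, h1 = side_heights(state)
        if min(h0, h1) < extinct_below and extinct_seen["t"] is None:
            extinct_seen["t"] = state.t
        return (extinct_seen["t"] is not None
                and state.t >= extinct_seen["t"] + T_settle)

    cfg = SimulationConfig(**{**config.__dict__, "noise": True})
    traj = simulate(start, params, cfg, stop_condition=stop)

    times = np.asarray(traj.times)
    heights = np.array([side_heights(s) for s in traj.states])
    cyt_c = np.array([s.cytosol.Cdc42Dc for s in traj.states])
    cyt_b = np.array([s.cytosol.BemGEFc for s in traj.states])

    contents = np.full_like(heights, np.nan)
    recruit = np.full_like(heights, np.nan)
    outflux = np.full_like(heights, np.nan)
    for k, state in enumerate(traj.states):
        f = state.membrane.total_membrane_cdc42()
        for side in (0, 1):
            if heights[k, side] >= extinct_below:
                sub = np.where(masks[side], f, 0.0)
                pk = detect_peaks(sub, L, min_height=extinct_below,
                                  min_separation=0.5)
                if pk:
                    try:
                        pk0 = summarize_peak(state, pk[0], params)
                        contents[k, side] = pk0.content
                        recruit[k, side] = pk0.cytoplasmic_influx
                        outflux[k, side] = pk0.diffusive_outflux
                    except ValueError:
                        pass

    alive = heights >= extinct_below
    resolved = np.nonzero(alive.sum(axis=1) == 1)[0]
    if len(resolved) == 0:
        return CompetitionResult(
            coexistence_time=None, winner=None, censored=True,
            times=times, peak_heights=heights, peak_contents=contents,
            peak_recruitment=recruit, peak_outflux=outflux,
            cytosol_cdc42=cyt_c, cytosol_bemgef=cyt_b,
            two_peak_state=two_peak_state, final_state=traj.final,
            extinction_threshold=extinct_below)

    k_end = int(resolved[0])
    winner = int(np.argmax(heights[k_end]))
    coexistence = float(times[k_end] - times[0])

    loser = 1 - winner
    pre = contents[:k_end + 1, loser]
    growth_end_idx = int(np.nanargmax(pre)) if np.any(np.isfinite(pre)) else 0
    growth = float(times[growth_end_idx] - times[0])

    return CompetitionResult(
        coexistence_time=coexistence, winner=winner, censored=False,
        times=times, peak_heights=heights, peak_contents=contents,
        peak_recruitment=recruit, peak_outflux=outflux,
        cytosol_cdc42=cyt_c, cytosol_bemgef=cyt_b,
        growth_duration=growth,
        competition_duration=coexistence - growth,
        two_peak_state=two_peak_state, final_state=traj.final,
        extinction_threshold=extinct_below)


def rate_balance_curve(trajectory: Trajectory, params: ModelParameters,
                       min_height: float | None = None) -> pd.DataFrame:
    """Per-snapshot, per-peak fluxes versus normalized waistline content.

    Content is normalized to the largest peak content in the final snapshot
    (the winner).  Returns a table with columns
    ``t, peak, content, norm_content, recruitment, diffusive_outflux``;
    empty when no snapshot contains a peak.
    """
    L = params.L
    if min_height is None:
        hss = homogeneous_steady_state(params)
        min_height = 2.0 * float(hss.membrane.total_membrane_cdc42()[0, 0])
    rows = []
    for t, state in zip(trajectory.times, trajectory.states):
        f = state.membrane.total_membrane_cdc42()
        for i, pk in enumerate(detect_peaks(f, L, min_height=min_height,
                                            min_separation=1.0)):
            try:
                pk = summarize_peak(state, pk, params)
            except ValueError:
                continue
            rows.append((t, i, pk.content, pk.cytoplasmic_influx,
                         pk.diffusive_outflux))
    if not rows:
        return pd.DataFrame(columns=["t", "peak", "content", "norm_content",
                                     "recruitment", "diffusive_outflux"])
    df = pd.DataFrame(rows, columns=["t", "peak", "content", "recruitment",
                                     "diffusive_outflux"])
    t_last = df["t"].max()
    winner_content = df.loc[df["t"] == t_last, "content"].max()
    df["norm_content"] = df["content"] / winner_content
    return df[["t", "peak", "content", "norm_content", "recruitment",
               "diffusive_outflux"]]


def balance_intersections(curve: pd.DataFrame) -> np.ndarray:
    """Contents at which recruitment and diffusive-loss curves cross.

    Sorts the rate-balance table by content and returns the interpolated
    normalized contents where the net flux changes sign.
    """
    df = curve.sort_values("norm_content")
    x = df["norm_content"].to_numpy()
    net = (df["recruitment"] - df["diffusive_outflux"]).to_numpy()
    out = []
    for i in range(len(x) - 1):
        if net[i] == 0:
            out.append(x[i])
        elif net[i] * net[i + 1] < 0:
            w = net[i] / (net[i] - net[i + 1])
            out.append(x[i] + w * (x[i + 1] - x[i]))
    return np.asarray(out)
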