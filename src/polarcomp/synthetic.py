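"""Synthetic inputs with known ground truth for every analysis in the package.

Model-side generators produce perturbed initial conditions for the
reaction-diffusion simulator; imaging-side generators render two-channel
spot movies (diffraction-limited Gaussian spots that appear, move, blink
and disappear over a noisy background) and FRAP/FLIP intensity traces with
known kinetics, each paired with a machine-readable truth table so the
quantification pipeline can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from polarcomp.imaging import ImageStack
from polarcomp.model import FullState, ModelParameters, homogeneous_steady_state
from polarcomp.simulate import seed_perturbations

__all__ = [
    "SpotScript",
    "MovieScript",
    "TraceScript",
    "make_noisy_homogeneous_state",
    "make_two_peak_state",
    "make_spot_movie",
    "competition_movie_script",
    "make_frap_trace",
    "make_flip_traces",
]


# ---------------------------------------------------------------------------
# model-side generators
# ---------------------------------------------------------------------------

def make_noisy_homogeneous_state(params: ModelParameters,
                                 noise_amplitude: float, seed: int,
                                 N: int = 64,
                                 correlation_px: float = 2.0) -> FullState:
    """Homogeneous steady state plus smooth, zero-mean field perturbations.

    ``noise_amplitude`` is relative: each membrane field receives an
    independent spatially correlated zero-mean perturbation whose maximum
    magnitude is ``noise_amplitude`` times the field's uniform value, so
    the spatial mean of every field — and hence both conserved totals — is
    exactly unchanged.  Raises when the amplitude would drive a field
    negative (amplitude >= 1).
    """
    if noise_amplitude < 0:
        raise ValueError("noise amplitude must be >= 0")
    if noise_amplitude >= 1.0:
        raise ValueError("relative noise amplitude >= 1 would drive fields "
                         "negative")
    state = homogeneous_steady_state(params, N=N)
    if noise_amplitude == 0:
        return state
    rng = np.random.default_rng(seed)
    fields = state.membrane.as_array()
    for k in range(4):
        xi = rng.standard_normal((N, N))
        xi = gaussian_filter(xi, correlation_px, mode="wrap")
        xi -= xi.mean()
        peak = np.max(np.abs(xi))
        if peak > 0:
            xi /= peak
        fields[k] += noise_amplitude * fields[k, 0, 0] * xi
    from polarcomp.model import MembraneState

    return FullState(MembraneState.from_array(fields), state.cytosol.copy(),
                     state.t)


def make_two_peak_state(params: ModelParameters, N: int = 64,
                        separation: float | None = None,
                        amplitude: float = 30.0,
                        width: float = 0.6) -> FullState:
    """Homogeneous steady state with two identical seeded peaks.

    By default the peaks sit at diametrically opposite torus locations
    (offset L/2 along both axes — the maximal separation L/sqrt(2)); a
    smaller ``separation`` places them along the same diagonal.  The state
    is exactly symmetric under the translation mapping one peak to the
    other, and both conserved totals are unchanged.
    """
    L = params.L
    max_sep = L / np.sqrt(2.0)
    if separation is None:
        separation = max_sep
    if not 0 < separation <= max_sep + 1e-12:
        raise ValueError(f"separation must be in (0, {max_sep:.3f}] um")
    off = separation / np.sqrt(2.0)
    c1 = (L / 4.0, L / 4.0)
    c2 = ((L / 4.0 + off) % L, (L / 4.0 + off) % L)
    hss = homogeneous_steady_state(params, N=N)
    return seed_perturbations(hss, params, [c1, c2], amplitude=amplitude,
                              width=width)


# ---------------------------------------------------------------------------
# imaging-side generators
# ---------------------------------------------------------------------------

@dataclass
class SpotScript:
    """One scripted fluorescent spot.

    ``path`` maps frame -> (y, x) px; it may be a single (y, x) for a
    stationary spot or an array of shape (n_frames, 2).  ``amplitude`` is
    likewise a scalar or per-frame array of peak heights (the spot's live
    amplitude; frames outside [birth, death) render nothing).
    """

    birth: int
    death: int                     # exclusive
    path: object
    amplitude: object
    sigma_px: float = 1.5
    blink_frames: tuple = ()

    def centroid(self, frame: int) -> tuple:
        p = np.asarray(self.path, dtype=float)
        if p.ndim == 1:
            return (float(p[0]), float(p[1]))
        return (float(p[frame, 0]), float(p[frame, 1]))

    def amp(self, frame: int) -> float:
        a = np.asarray(self.amplitude, dtype=float)
        value = float(a) if a.ndim == 0 else float(a[frame])
        if value < 0:
            raise ValueError("spot amplitude must be >= 0")
        return value

    def visible(self, frame: int) -> bool:
        return (self.birth <= frame < self.death
                and frame not in self.blink_frames
                and self.amp(frame) > 0)


@dataclass
class MovieScript:
    """Recipe for a synthetic two-channel polarity movie."""

    n_frames: int = 20
    frame_interval: float = 45.0   # s
    size_px: int = 64
    pixel_size: float = 0.1        # um/px
    background: float = 100.0
    noise_sd: float = 2.0
    spots: list = field(default_factory=list)
    channel_delay_frames: int = 0  # channel 2 lags channel 1
    channel_scale: float = 1.0     # channel 2 amplitude scale
    n_channels: int = 2
    poisson: bool = False

    def validate(self) -> None:
        for s in self.spots:
            for f in range(self.n_frames):
                cy, cx = s.centroid(min(f, self.n_frames - 1))
                if not (0 <= cy < self.size_px and 0 <= cx < self.size_px):
                    raise ValueError("spot path leaves the image")


def _render_spot(img: np.ndarray, center: tuple, amplitude: float,
                 sigma: float) -> None:
    n = img.shape[0]
    yy, xx = np.mgrid[:n, :n]
    img += amplitude * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                              / (2.0 * sigma ** 2))


def make_spot_movie(script: MovieScript, seed: int = 0
                    ) -> tuple[ImageStack, pd.DataFrame]:
    """Render a movie from a script; return it with its truth table.

    The truth table has one row per (frame, visible spot) plus rows with
    spot = -1 carrying the per-frame visible-spot count; centroids and
    integrated intensities (2 pi sigma^2 A) are exact, before noise.
    """
    script.validate()
    rng = np.random.default_rng(seed)
    nf, n = script.n_frames, script.size_px
    data = np.zeros((nf, script.n_channels, n, n))
    rows = []
    for f in range(nf):
        for c in range(script.n_channels):
            img = np.full((n, n), float(script.background))
            f_eff = f - (script.channel_delay_frames if c == 1 else 0)
            scale = script.channel_scale if c == 1 else 1.0
            for i, s in enumerate(script.spots):
                if 0 <= f_eff < nf and s.visible(f_eff):
                    _render_spot(img, s.centroid(f_eff),
                                 scale * s.amp(f_eff), s.sigma_px)
            if script.poisson:
                img = rng.poisson(img).astype(float)
            if script.noise_sd > 0:
                img = img + rng.normal(0.0, script.noise_sd, img.shape)
            data[f, c] = np.clip(img, 0.0, None)
        count = 0
        for i, s in enumerate(script.spots):
            if s.visible(f):
                cy, cx = s.centroid(f)
                amp = s.amp(f)
                rows.append((f, i, cy, cx, amp,
                             2.0 * np.pi * s.sigma_px ** 2 * amp))
                count += 1
        rows.append((f, -1, np.nan, np.nan, np.nan, float(count)))
    truth = pd.DataFrame(rows, columns=["frame", "spot", "y", "x",
                                        "amplitude", "intensity"])
    stack = ImageStack(data, script.frame_interval, script.pixel_size)
    return stack, truth


def competition_movie_script(loser_death_frame: int = 12,
                             n_frames: int = 24,
                             frame_interval: float = 45.0,
                             amplitude: float = 120.0,
                             noise_sd: float = 2.0,
                             appear_frame: int = 2,
                             size_px: int = 64) -> MovieScript:
    """Two-spot competition preset: both spots appear, grow, then the loser
    shrinks to zero at the scripted frame while the winner persists.

    SNR (winner amplitude / noise sd) defaults to 60; pass a larger
    ``noise_sd`` to stress the pipeline.
    """
    if not appear_frame < loser_death_frame <= n_frames:
        raise ValueError("need appear_frame < loser_death_frame <= n_frames")
    frames = np.arange(n_frames)
    winner_amp = np.where(frames >= appear_frame, amplitude, 0.0)
    # the loser shrinks towards its death but stays well above half the
    # winner amplitude while visible, so detection matches the script
    span = max(loser_death_frame - appear_frame, 1)
    shrink = 1.0 - 0.3 * np.clip((frames - appear_frame) / span, 0.0, 1.0)
    loser_amp = np.where(
        (frames >= appear_frame) & (frames < loser_death_frame),
        amplitude * 0.9 * shrink, 0.0)
    winner = SpotScript(birth=appear_frame, death=n_frames,
                        path=(20.0, 20.0), amplitude=winner_amp)
    loser = SpotScript(birth=appear_frame, death=loser_death_frame,
                       path=(44.0, 44.0), amplitude=loser_amp)
    return MovieScript(n_frames=n_frames, frame_interval=frame_interval,
                       size_px=size_px, noise_sd=noise_sd,
                       spots=[winner, loser])


# ---------------------------------------------------------------------------
# FRAP / FLIP trace generators
# ---------------------------------------------------------------------------

@dataclass
class TraceScript:
    """Recipe for a synthetic photobleaching trace.

    For FRAP, ``k_fast``/``k_slow`` (1/s) and amplitudes describe the
    double-exponential recovery after a single bleach; for FLIP,
    ``loss_rate`` (1/s) is the exponential loss of focus signal under the
    repeated bleach schedule.
    """

    n_frames: int = 100
    frame_interval: float = 0.5    # s
    pre_bleach_frames: int = 3
    intensity: float = 1000.0      # pre-bleach plateau, camera units
    background: float = 50.0
    noise_sd_fraction: float = 0.01
    # FRAP kinetics
    k_fast: float = 2.0
    k_slow: float = 0.2
    amp_fast: float = 0.25
    amp_slow: float = 0.55
    post_bleach_level: float = 0.15
    # FLIP kinetics
    loss_rate: float = 0.05

    def validate(self) -> None:
        if self.k_fast <= self.k_slow or self.k_slow <= 0:
            raise ValueError("need k_fast > k_slow > 0")
        if self.loss_rate < 0 or self.pre_bleach_frames < 3:
            raise ValueError("invalid loss rate or pre-bleach frame count")


def make_frap_trace(script: TraceScript, seed: int = 0
                    ) -> tuple[np.ndarray, dict]:
    """Pre-bleach plateau, bleach drop, double-exponential recovery + noise.

    Returns (trace, truth) with the truth dict carrying the scripted rates
    and the expected recovery half-time ``ln2 / k_slow``.
    """
    script.validate()
    rng = np.random.default_rng(seed)
    nf, npre = script.n_frames, script.pre_bleach_frames
    t = np.arange(nf - npre) * script.frame_interval
    recovery = (script.post_bleach_level
                + script.amp_fast * (1 - np.exp(-script.k_fast * t))
                + script.amp_slow * (1 - np.exp(-script.k_slow * t)))
    norm = np.concatenate([np.ones(npre), recovery])
    trace = script.background + script.intensity * norm
    if script.noise_sd_fraction > 0:
        trace = trace + rng.normal(
            0.0, script.noise_sd_fraction * script.intensity, nf)
    truth = {"k_fast": script.k_fast, "k_slow": script.k_slow,
             "half_time": float(np.log(2.0) / script.k_slow),
             "background": script.background,
             "pre_bleach_frames": npre}
    return np.clip(trace, 0.0, None), truth


def make_flip_traces(script: TraceScript, seed: int = 0
                     ) -> tuple[dict, dict]:
    """Repeated-bleach loss traces: focus, neighbor-cell control, background.

    The focus signal decays as ``exp(-loss_rate t)`` (membrane/cytoplasm
    exchange feeding the bleached cytoplasmic pool); the neighbor cell is
    constant up to noise; the background is stationary.  Returns
    ``({"focus", "neighbor", "background", "times"}, truth)``.
    """
    script.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(script.n_frames) * script.frame_interval
    t0 = script.pre_bleach_frames * script.frame_interval
    decay = np.where(t < t0, 1.0, np.exp(-script.loss_rate * (t - t0)))
    focus = script.background + script.intensity * decay
    neighbor = script.background + 0.8 * script.intensity * np.ones_like(t)
    background = script.background * np.ones_like(t)
    if script.noise_sd_fraction > 0:
        sd = script.noise_sd_fraction * script.intensity
        focus = focus + rng.normal(0, sd, focus.shape)
        neighbor = neighbor + rng.normal(0, sd, neighbor.shape)
        background = background + rng.normal(0, 0.2 * sd, background.shape)
    traces = {"times": t, "focus": np.clip(focus, 0, None),
              "neighbor": np.clip(neighbor, 0, None),
              "background": np.clip(background, 0, None)}
    truth = {"loss_rate": script.loss_rate,
             "bleach_start": float(t0)}
    return traces, truth
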