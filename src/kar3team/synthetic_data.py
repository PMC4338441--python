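"""Ground-truthed synthetic single-molecule data.

Generates 1-D trajectories (directed / diffusive / static populations),
quantized-brightness photobleaching traces, and rendered TIRF-like image
stacks, each alongside a truth table, so the tracking and statistics layers
can be validated without any experimental input.

Coordinates are nm along the microtubule axis, minus-end positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "MotionPreset",
    "Track",
    "MovieSpec",
    "PRESETS",
    "generate_tracks",
    "generate_intensity_traces",
    "render_clean",
    "render_movie",
    "save_movie",
    "load_movie",
]


@dataclass(frozen=True)
class MotionPreset:
    """One motion population: directed, diffusive or static.

    Directed presets use ``velocity_mean/velocity_sd`` (nm/s, per-track
    Gaussian truncated at 0) and exponential run lengths with mean
    ``run_length_mean`` (nm).  Diffusive presets use a diffusion coefficient
    ``d_um2_s`` (um^2/s) and exponential residence time ``residence_tau``
    (s); static presets only the residence time.  ``localization_sd`` (nm)
    is added to every sampled position.
    """

    name: str
    state: str  # "directed" | "diffusive" | "static"
    velocity_mean: float | None = None
    velocity_sd: float | None = None
    run_length_mean: float | None = None
    d_um2_s: float | None = None
    residence_tau: float | None = None
    localization_sd: float = 30.0

    def __post_init__(self) -> None:
        if self.state not in ("directed", "diffusive", "static"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "directed":
            if not (self.velocity_mean and self.velocity_mean > 0):
                raise ValueError("directed preset needs velocity_mean > 0")
            if self.velocity_sd is None or self.velocity_sd < 0:
                raise ValueError("directed preset needs velocity_sd >= 0")
            if not (self.run_length_mean and self.run_length_mean > 0):
                raise ValueError("directed preset needs run_length_mean > 0")
        if self.state == "diffusive" and not (self.d_um2_s and self.d_um2_s > 0):
            raise ValueError("diffusive preset needs d_um2_s > 0")
        if self.state in ("diffusive", "static") and not (
            self.residence_tau and self.residence_tau > 0
        ):
            raise ValueError(f"{self.state} preset needs residence_tau > 0")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be >= 0")


#: Motility presets. Directed velocities/run lengths and the ADP-state
#: diffusion parameters follow the measured single-molecule populations;
#: where a population's spread or lifetime was not reported a plausible
#: default is used (see docstrings).
PRESETS: dict[str, MotionPreset] = {
    p.name: p
    for p in [
        MotionPreset("wt_atp", "directed", velocity_mean=77.0, velocity_sd=23.0,
                     run_length_mean=5200.0),
        MotionPreset("vik1_atp", "directed", velocity_mean=234.0, velocity_sd=29.0,
                     run_length_mean=5200.0),
        MotionPreset("chimera_atp", "directed", velocity_mean=188.0, velocity_sd=25.0,
                     run_length_mean=5200.0),
        MotionPreset("adp", "diffusive", d_um2_s=0.061, residence_tau=0.6),
        MotionPreset("mutant_atp", "diffusive", d_um2_s=0.03, residence_tau=2.0,
                     localization_sd=0.0),
        MotionPreset("apo", "static", residence_tau=30.0),
        MotionPreset("amppnp", "static", residence_tau=30.0),
    ]
}


@dataclass
class Track:
    """A single molecule's sampled 1-D trajectory."""

    track_id: int
    time_s: np.ndarray
    position_nm: np.ndarray
    intensity: np.ndarray
    censored: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.size < 2:
            raise ValueError("track must have >= 2 points")
        dts = np.diff(self.time_s)
        if np.any(dts <= 0):
            raise ValueError(f"track {self.track_id}: times must strictly increase")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {self.track_id}: frame interval must be constant")
        if np.any(self.intensity < 0):
            raise ValueError(f"track {self.track_id}: intensity must be >= 0")
        if not (self.time_s.size == self.position_nm.size == self.intensity.size):
            raise ValueError(f"track {self.track_id}: field lengths differ")

    @property
    def frame_interval(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def generate_tracks(
    preset: MotionPreset,
    n_tracks: int,
    frame_interval: float,
    seed: int | np.random.Generator,
    duration: float | None = None,
    intensity: float = 1000.0,
) -> tuple[list[Track], pd.DataFrame]:
    """Draw ``n_tracks`` trajectories from a motion preset.

    ``duration`` caps every track (movie end); runs/lifetimes exceeding it
    are truncated and flagged censored.  Returns the tracks and a truth
    table (per-track velocity, run length / lifetime, censoring).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if (
        preset.state == "diffusive"
        and preset.residence_tau is not None
        and frame_interval >= preset.residence_tau / 2
    ):
        import warnings

        warnings.warn(
            f"frame interval {frame_interval} s undersamples residence "
            f"tau {preset.residence_tau} s",
            stacklevel=2,
        )

    tracks: list[Track] = []
    rows = []
    for i in range(n_tracks):
        if preset.state == "directed":
            v = -1.0
            while v < 0:
                v = rng.normal(preset.velocity_mean, preset.velocity_sd)
            run_length = rng.exponential(preset.run_length_mean)
            lifetime = run_length / v if v > 0 else np.inf
        else:
            v = 0.0
            run_length = np.nan
            lifetime = rng.exponential(preset.residence_tau)
        censored = duration is not None and lifetime > duration
        if censored:
            lifetime = duration
        n_frames = max(2, int(np.floor(lifetime / frame_interval)) + 1)
        t = np.arange(n_frames) * frame_interval
        if preset.state == "directed":
            pos = v * t
        elif preset.state == "diffusive":
            sigma_step = np.sqrt(2.0 * preset.d_um2_s * 1e6 * frame_interval)
            pos = np.concatenate(
                [[0.0], np.cumsum(rng.normal(0.0, sigma_step, n_frames - 1))]
            )
        else:
            pos = np.zeros(n_frames)
        if preset.localization_sd > 0:
            pos = pos + rng.normal(0.0, preset.localization_sd, n_frames)
        tracks.append(
            Track(
                track_id=i,
                time_s=t,
                position_nm=pos,
                intensity=np.full(n_frames, float(intensity)),
                censored=censored,
            )
        )
        rows.append(
            {
                "track_id": i,
                "state": preset.state,
                "velocity_nm_s": v,
                "run_length_nm": run_length,
                "lifetime_s": lifetime,
                "n_frames": n_frames,
                "censored": censored,
            }
        )
    return tracks, pd.DataFrame(rows)


def generate_intensity_traces(
    n_molecules: int,
    fluors_per_molecule: int,
    bleach_rate: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    n_frames: int = 200,
    frame_interval: float = 0.1,
    step_height: float = 1.0,
    background: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Piecewise-constant photobleaching traces with Gaussian noise.

    Each molecule carries ``fluors_per_molecule`` fluorophores that bleach
    independently with exponential times at ``bleach_rate``; each bleach
    drops the trace by ``step_height``.  Returns the trace array
    (n_molecules, n_frames) and a truth table with the number of steps
    falling inside the recorded window and their times.
    """
    if fluors_per_molecule < 1:
        raise ValueError("fluors_per_molecule must be >= 1")
    if bleach_rate <= 0:
        raise ValueError("bleach_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    traces = np.empty((n_molecules, n_frames))
    rows = []
    for i in range(n_molecules):
        bleach_times = np.sort(rng.exponential(1.0 / bleach_rate, fluors_per_molecule))
        n_alive = (t[None, :] < bleach_times[:, None]).sum(axis=0)
        clean = background + step_height * n_alive
        traces[i] = clean + (rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else 0.0)
        visible = bleach_times[bleach_times < t[-1]]
        rows.append(
            {
                "molecule_id": i,
                "n_fluors": fluors_per_molecule,
                "n_steps": visible.size,
                "step_times": list(visible),
            }
        )
    return traces, pd.DataFrame(rows)


@dataclass(frozen=True)
class MovieSpec:
    """Geometry, optics and noise of a rendered image stack."""

    shape: tuple[int, int] = (64, 64)   # (rows, cols)
    n_frames: int = 50
    pixel_size_nm: float = 133.0
    frame_interval_s: float = 3.0
    psf_sigma_nm: float = 160.0
    background: float = 100.0           # counts per pixel
    read_noise_sd: float = 2.0          # Gaussian, counts
    shot_noise: bool = True
    shading_amplitude: float = 0.0      # relative amplitude of slow shading field
    axis_start: tuple[float, float] = (32.0, 4.0)   # (row, col), pixels
    axis_end: tuple[float, float] = (32.0, 60.0)
    photons_per_intensity: float = 1.0  # counts per track-intensity unit

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be > 0")
        if self.psf_sigma_nm < self.pixel_size_nm:
            import warnings

            warnings.warn("PSF sigma below one pixel; spots will alias", stacklevel=2)


def _pixel_integrated_psf(
    shape: tuple[int, int], row: float, col: float, sigma_px: float
) -> np.ndarray:
    """Unit-mass Gaussian PSF integrated over pixel areas (separable erf)."""
    r = np.arange(shape[0])
    c = np.arange(shape[1])
    s = sigma_px * np.sqrt(2.0)
    fr = 0.5 * (erf((r + 1 - row) / s) - erf((r - row) / s))
    fc = 0.5 * (erf((c + 1 - col) / s) - erf((c - col) / s))
    return np.outer(fr, fc)


def render_clean(
    tracks: list[Track],
    spec: MovieSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Noise-free float rendering: background + pixel-integrated PSF spots.

    1-D track positions are mapped onto the axis segment of ``spec`` (nm
    from ``axis_start`` toward ``axis_end``).  Returns the float stack
    (before shading/noise) and a truth table with per-frame pixel
    coordinates of every rendered molecule.
    """
    h, w = spec.shape
    a0 = np.asarray(spec.axis_start, dtype=float)
    a1 = np.asarray(spec.axis_end, dtype=float)
    axis_len_px = float(np.hypot(*(a1 - a0)))
    unit = (a1 - a0) / axis_len_px
    sigma_px = spec.psf_sigma_nm / spec.pixel_size_nm

    clean = np.full((spec.n_frames, h, w), float(spec.background))
    rows = []
    clipped = False
    for tr in tracks:
        frames = np.rint(tr.time_s / spec.frame_interval_s).astype(int)
        for k, fr in enumerate(frames):
            if not 0 <= fr < spec.n_frames:
                continue
            pos_px = a0 + unit * (tr.position_nm[k] / spec.pixel_size_nm)
            # pixel *centres* are at index + 0.5
            row, col = pos_px[0] + 0.5, pos_px[1] + 0.5
            inside = 0 <= pos_px[0] < h and 0 <= pos_px[1] < w
            if not inside:
                clipped = True
                continue
            amp = tr.intensity[k] * spec.photons_per_intensity
            clean[fr] += amp * _pixel_integrated_psf((h, w), row, col, sigma_px)
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": fr,
                    "time_s": tr.time_s[k],
                    "row_px": pos_px[0],
                    "col_px": pos_px[1],
                    "position_nm": tr.position_nm[k],
                    "intensity": tr.intensity[k],
                }
            )
    if clipped:
        import warnings

        warnings.warn("some track points fall outside the field; clipped", stacklevel=2)
    return clean, pd.DataFrame(rows)


def render_movie(
    tracks: list[Track],
    spec: MovieSpec,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks into a noisy uint16 stack (see :func:`render_clean`).

    Order: spots + background, multiplicative shading, Poisson shot noise,
    Gaussian read noise, round and clip to uint16.  Deterministic for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean, truth = render_clean(tracks, spec)
    h, w = spec.shape
    if spec.shading_amplitude > 0:
        rr, cc = np.meshgrid(np.linspace(0, np.pi, h), np.linspace(0, np.pi, w),
                             indexing="ij")
        shading = 1.0 + spec.shading_amplitude * np.sin(rr) * np.sin(cc)
        clean = clean * shading

    noisy = rng.poisson(clean).astype(float) if spec.shot_noise else clean.copy()
    if spec.read_noise_sd > 0:
        noisy += rng.normal(0.0, spec.read_noise_sd, noisy.shape)
    stack = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    return stack, truth


def save_movie(path: str | Path, stack: np.ndarray, spec: MovieSpec, seed: int | None = None) -> None:
    """Write a multi-page 16-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack)
    meta = {
        "pixel_size_nm": spec.pixel_size_nm,
        "frame_interval_s": spec.frame_interval_s,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return stack, meta
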