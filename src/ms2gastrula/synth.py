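"""Synthetic embryo generator.

Produces trace-level cohorts and rendered two-channel 4D movies with the
statistical structure the analysis pipeline assumes: two mesectoderm (MSE)
stripes flanking the mesoderm (ME), neuroectoderm (NE) outside; bursty MS2
transcription starting midway through nuclear cycle 14 (nc14); a step-up in
spot amplitude in a fraction of MSE nuclei at mesoderm invagination; shared
linear photobleaching; and dorso-ventral nuclear movement with an optional
early "rolling" peak followed by the invagination peak.  Every run returns
ground truth for recovery testing.

Conventions: time is minutes into nc14 (frame 0 = nc14 start by default);
the DV axis is y with ventral positive; all physical coordinates in µm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

NUCLEAR_CHANNEL = 0
SPOT_CHANNEL = 1

REGION_ME = "ME"
REGION_MSE = "MSE"
REGION_NE = "NE"


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class StripeGeometry:
    """Initial layout of the nuclear field (µm).

    The mesoderm occupies a central band around ``y_me``; the two
    single-cell-wide MSE stripes sit at ``y_me ± mse_offset``; NE rows start
    at ``y_me ± ne_offset`` and extend dorsally. Nuclei are placed on rows
    along x with spacing ``spacing`` plus positional jitter.
    """

    x_extent: float = 90.0
    y_me: float = 40.0
    mse_offset: float = 12.0
    ne_offset: float = 20.0
    z_center: float = 6.0
    spacing: float = 6.0
    jitter: float = 0.8


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic embryo movie."""

    n_mse: int = 24
    n_me: int = 24
    n_ne: int = 24
    stripe_geometry: StripeGeometry = field(default_factory=StripeGeometry)
    frame_interval: float = 15.0      # seconds / frame
    n_frames: int = 280               # 280 × 15 s = 70 min of nc14
    t_onset: float = 25.0             # min into nc14: earliest MSE onset
    onset_spread: float = 10.0        # min; onsets uniform on [t_onset, t_onset+spread]
    t_constriction: float = 42.0      # min into nc14
    t_invagination: float = 50.0      # min into nc14
    t_end: float = 62.0               # min into nc14: end of gastrulation
    roll_amplitude: float = 0.0       # µm dorsal drift (0 = perfectly ventral mount)
    invagination_displacement: float = 12.0   # µm ventral MSE/NE movement
    me_descent: float = 8.0           # µm ME z-descent after invagination
    p_on: float = 0.85                # per-frame OFF→ON switching probability
    p_off: float = 0.07               # per-frame ON→OFF switching probability
    p_active: float = 1.0             # fraction of MSE nuclei that transcribe at all
    amp_pre: float = 100.0            # mean ON spot amplitude (AU)
    p_step: float = 0.4               # fraction of MSE nuclei that step
    step_factor: float = 2.0          # amplitude multiplier at invagination
    step_jitter_sd: float = 2.0       # min; per-nucleus jitter of the step time
    background: float = 50.0          # B0, shared background fluorescence (AU)
    bleach_rate: float = 0.004        # fractional fluorescence loss per minute
    noise_sd: float = 5.0             # Gaussian noise at full brightness (AU)
    position_noise_sd: float = 0.15   # µm centroid jitter per frame
    voxel_xy: float = 0.36            # µm / px
    voxel_z: float = 1.0              # µm
    t0_nc14: int = 0                  # frame index of nc14 start
    seed: int = 0

    def __post_init__(self) -> None:
        dur = self.total_minutes
        if not (self.t_onset < self.t_constriction <= self.t_invagination
                < self.t_end <= dur):
            raise ConfigError(
                "timing must satisfy t_onset < t_constriction <= "
                f"t_invagination < t_end <= duration ({dur:.1f} min); got "
                f"{self.t_onset}, {self.t_constriction}, "
                f"{self.t_invagination}, {self.t_end}")
        if not 0.0 <= self.p_step <= 1.0:
            raise ConfigError("p_step must be in [0, 1]")
        if self.step_factor < 1.0:
            raise ConfigError("step_factor must be >= 1")
        if self.bleach_rate < 0:
            raise ConfigError("bleach_rate must be >= 0")
        if min(self.n_mse, self.n_me, self.n_ne) <= 0:
            raise ConfigError("region counts must be positive")
        for name in ("p_on", "p_off", "p_active"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability")
        if self.noise_sd < 0 or self.frame_interval <= 0:
            raise ConfigError("noise_sd >= 0 and frame_interval > 0 required")

    @property
    def n_nuclei(self) -> int:
        return self.n_mse + self.n_me + self.n_ne

    @property
    def total_minutes(self) -> float:
        return (self.n_frames - 1) * self.frame_interval / 60.0

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes into nc14."""
        return (np.arange(self.n_frames) - self.t0_nc14) * self.frame_interval / 60.0

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "stripe_geometry" in d and isinstance(d["stripe_geometry"], dict):
            d["stripe_geometry"] = StripeGeometry(**d["stripe_geometry"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-nucleus and per-embryo truth for recovery tests.

    ``nuclei`` has one row per nucleus: nucleus_id, region, transcribes,
    steps, true_onset (min; NaN if silent), t_step (min; NaN if not
    stepping), amp_pre, amp_post.  ``trajectories`` has one row per
    nucleus-frame: nucleus_id, frame, t_min, x_um, y_um, z_um.
    """

    nuclei: pd.DataFrame
    trajectories: pd.DataFrame
    t_constriction: float
    t_invagination: float
    t_end: float


# ---------------------------------------------------------------------------
# nucleus placement and region assignment

def _place_nuclei(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Seed positions at t=0 on region rows along x, with jitter."""
    g = cfg.stripe_geometry
    rows = []
    nid = 0

    def add_region(region, n, y_rows):
        nonlocal nid
        per_row = int(np.ceil(n / len(y_rows)))
        k = 0
        for y0 in y_rows:
            for i in range(per_row):
                if k >= n:
                    break
                x = (i + 0.5) * g.x_extent / per_row
                rows.append((nid, region, x, y0, g.z_center))
                nid += 1
                k += 1

    n_me_rows = max(1, int(round(cfg.n_me * g.spacing / g.x_extent)))
    me_rows = g.y_me + (np.arange(n_me_rows) - (n_me_rows - 1) / 2) * g.spacing
    add_region(REGION_ME, cfg.n_me, list(me_rows))
    add_region(REGION_MSE, cfg.n_mse, [g.y_me - g.mse_offset, g.y_me + g.mse_offset])
    n_ne_rows = max(2, int(round(cfg.n_ne * g.spacing / g.x_extent / 2)) * 2)
    half = n_ne_rows // 2
    ne_rows = ([g.y_me - g.ne_offset - i * g.spacing for i in range(half)]
               + [g.y_me + g.ne_offset + i * g.spacing for i in range(half)])
    add_region(REGION_NE, cfg.n_ne, ne_rows)

    df = pd.DataFrame(rows, columns=["nucleus_id", "region", "x0", "y0", "z0"])
    jit = rng.normal(0.0, g.jitter, size=(len(df), 3))
    df[["x0", "y0", "z0"]] += jit
    df["z0"] = df["z0"].clip(lower=1.0)
    return df


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# operations

def simulate_movement(cfg: SimConfig) -> pd.DataFrame:
    """Per-nucleus trajectories (x, y, z in µm per frame).

    y is constant before t_constriction. With roll_amplitude > 0 the whole
    field drifts dorsally (negative y) over [t_constriction, t_invagination]
    (tilted mounting); MSE and NE then move ventrally by
    invagination_displacement over [t_invagination, t_end] while ME nuclei
    descend in z (internalization). Both phases follow a smoothstep, so the
    speed profile peaks mid-phase.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    seeds = _place_nuclei(cfg, rng)
    t = cfg.times

    roll = -cfg.roll_amplitude * _smoothstep(
        (t - cfg.t_constriction) / (cfg.t_invagination - cfg.t_constriction)
        if cfg.t_invagination > cfg.t_constriction else (t >= cfg.t_constriction) * 1.0)
    inv = _smoothstep((t - cfg.t_invagination) / (cfg.t_end - cfg.t_invagination))

    frames = np.arange(cfg.n_frames)
    out = []
    for row in seeds.itertuples(index=False):
        y = np.full(cfg.n_frames, row.y0) + roll
        z = np.full(cfg.n_frames, row.z0)
        x = np.full(cfg.n_frames, row.x0)
        if row.region in (REGION_MSE, REGION_NE):
            # coherent ventral drift (+y) as the mesoderm internalizes
            y = y + cfg.invagination_displacement * inv
        else:
            z = z + cfg.me_descent * inv
        noise = rng.normal(0.0, cfg.position_noise_sd, size=(cfg.n_frames, 3))
        out.append(pd.DataFrame({
            "nucleus_id": row.nucleus_id, "frame": frames, "t_min": t,
            "x_um": x + noise[:, 0], "y_um": y + noise[:, 1],
            "z_um": np.clip(z + noise[:, 2], 0.5, None),
            "region": row.region,
        }))
    return pd.concat(out, ignore_index=True)


def simulate_traces(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-nucleus fluorescence traces plus ground truth.

    value(t) = b(t)·(B0 + S(t)·A(t)) + ε with b(t) = max(1 − bleach_rate·t, 0)
    the shared bleaching factor, S a two-state telegraph process started ON at
    the nucleus's onset (identically 0 before onset and for silent nuclei),
    A(t) = amp_pre before the nucleus's step time and step_factor·amp_pre
    after it (stepping MSE nuclei only), and ε ~ Normal(0, noise_sd).
    Identical config (incl. seed) gives identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    trajectories = simulate_movement(cfg)
    seeds = trajectories[trajectories.frame == 0][["nucleus_id", "region"]]
    t = cfg.times
    nt = cfg.n_frames

    bleach = np.clip(1.0 - cfg.bleach_rate * t, 0.0, None)

    nuc_rows = []
    all_values = np.empty((len(seeds), nt))
    for k, row in enumerate(seeds.itertuples(index=False)):
        transcribes = (row.region == REGION_MSE
                       and rng.random() < cfg.p_active)
        steps = bool(transcribes and rng.random() < cfg.p_step)
        onset = np.nan
        t_step = np.nan
        S = np.zeros(nt)
        A = np.full(nt, cfg.amp_pre)
        if transcribes:
            onset = cfg.t_onset + rng.random() * cfg.onset_spread
            state = 0
            started = False
            for i in range(nt):
                if t[i] < onset:
                    continue
                if not started:
                    state = 1          # start ON at onset
                    started = True
                elif state == 1:
                    if rng.random() < cfg.p_off:
                        state = 0
                else:
                    if rng.random() < cfg.p_on:
                        state = 1
                S[i] = state
            if steps:
                t_step = cfg.t_invagination + rng.normal(0.0, cfg.step_jitter_sd)
                A = np.where(t >= t_step, cfg.step_factor * cfg.amp_pre,
                             cfg.amp_pre)
        # noise tracks overall brightness, so it bleaches with the signal
        eps = rng.normal(0.0, cfg.noise_sd, nt) * bleach if cfg.noise_sd > 0 else 0.0
        all_values[k] = bleach * (cfg.background + S * A) + eps
        nuc_rows.append((row.nucleus_id, row.region, transcribes, steps,
                         onset, t_step, cfg.amp_pre,
                         cfg.step_factor * cfg.amp_pre if steps else cfg.amp_pre))

    nuclei = pd.DataFrame(nuc_rows, columns=[
        "nucleus_id", "region", "transcribes", "steps", "true_onset",
        "t_step", "amp_pre", "amp_post"])

    frames = np.arange(nt)
    table = pd.DataFrame({
        "track_id": np.repeat(seeds.nucleus_id.to_numpy(), nt),
        "frame": np.tile(frames, len(seeds)),
        "t_min": np.tile(t, len(seeds)),
        "raw_max": all_values.ravel(),
        "region": np.repeat(seeds.region.to_numpy(), nt),
    })
    gt = GroundTruth(nuclei=nuclei, trajectories=trajectories,
                     t_constriction=cfg.t_constriction,
                     t_invagination=cfg.t_invagination, t_end=cfg.t_end)
    return table, gt


# ---------------------------------------------------------------------------
# rendering

#: peak amplitude of a rendered nuclear blob (AU, pre-quantization)
NUCLEAR_PEAK = 2000.0
#: fraction of the nuclear blob leaking into the spot channel (free MCP-GFP)
SPOT_FILL = 0.15
#: nominal nuclear radius used for blob sigma and spot offsets (µm)
NUCLEUS_RADIUS = 3.0


def render_stack(trajectories: pd.DataFrame, traces: pd.DataFrame,
                 cfg: SimConfig, shape_zyx: tuple[int, int, int] | None = None,
                 ) -> "VoxelGrid":
    """Render trajectories + traces into a two-channel 16-bit movie.

    Nuclear channel: sum of anisotropic 3D Gaussian blobs (σ = r/2 scaled by
    the voxel calibration) at the centroids. Spot channel: a dim nuclear fill
    plus one bright punctum per transcribing nucleus at a per-nucleus fixed
    random offset, with peak intensity proportional to the trace value above
    background; additive Gaussian noise; quantized to uint16.
    """
    from .core import VoxelGrid  # local import to avoid cycle

    tr_frames = set(trajectories.frame.unique())
    if not set(traces.frame.unique()) <= tr_frames:
        raise ValueError("traces contain frames missing from trajectories")
    if not set(traces.track_id.unique()) <= set(trajectories.nucleus_id.unique()):
        raise ValueError("traces reference nuclei missing from trajectories")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    g = cfg.stripe_geometry
    if shape_zyx is None:
        nz = int(np.ceil(2 * g.z_center / cfg.voxel_z)) + 2
        ny = int(np.ceil(2 * g.y_me / cfg.voxel_xy))
        nx = int(np.ceil(g.x_extent / cfg.voxel_xy))
        shape_zyx = (nz, ny, nx)
    nz, ny, nx = shape_zyx
    frames = np.sort(trajectories.frame.unique())
    data = np.zeros((2, len(frames), nz, ny, nx), dtype=np.float64)

    sig_xy = NUCLEUS_RADIUS / 2.0 / cfg.voxel_xy
    sig_z = NUCLEUS_RADIUS / 2.0 / cfg.voxel_z
    spot_sig_xy = 0.5 / cfg.voxel_xy
    spot_sig_z = 0.5 / cfg.voxel_z

    # fixed per-nucleus spot offset inside the nucleus (µm)
    ids = np.sort(trajectories.nucleus_id.unique())
    offs = {}
    for nid in ids:
        v = rng.normal(size=3)
        v *= (0.4 * NUCLEUS_RADIUS * rng.random() ** (1 / 3)) / np.linalg.norm(v)
        offs[nid] = v  # (dx, dy, dz) µm

    bleach = np.clip(1.0 - cfg.bleach_rate * cfg.times, 0.0, None)
    base = cfg.background * bleach

    trace_lut = {(r.track_id, r.frame): r.raw_max
                 for r in traces.itertuples(index=False)}

    def add_gaussian(vol, cz, cy, cx, sz, sy, sx, peak):
        rz = max(1, int(np.ceil(3 * sz)))
        ry = max(1, int(np.ceil(3 * sy)))
        rx = max(1, int(np.ceil(3 * sx)))
        z0, z1 = max(0, int(cz) - rz), min(vol.shape[0], int(cz) + rz + 1)
        y0, y1 = max(0, int(cy) - ry), min(vol.shape[1], int(cy) + ry + 1)
        x0, x1 = max(0, int(cx) - rx), min(vol.shape[2], int(cx) + rx + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            return
        zz = (np.arange(z0, z1) - cz)[:, None, None]
        yy = (np.arange(y0, y1) - cy)[None, :, None]
        xx = (np.arange(x0, x1) - cx)[None, None, :]
        vol[z0:z1, y0:y1, x0:x1] += peak * np.exp(
            -0.5 * ((zz / sz) ** 2 + (yy / sy) ** 2 + (xx / sx) ** 2))

    for fi, f in enumerate(frames):
        det = trajectories[trajectories.frame == f]
        for row in det.itertuples(index=False):
            cz = row.z_um / cfg.voxel_z - 0.5
            cy = row.y_um / cfg.voxel_xy - 0.5
            cx = row.x_um / cfg.voxel_xy - 0.5
            add_gaussian(data[NUCLEAR_CHANNEL, fi], cz, cy, cx,
                         sig_z, sig_xy, sig_xy, NUCLEAR_PEAK)
            add_gaussian(data[SPOT_CHANNEL, fi], cz, cy, cx,
                         sig_z, sig_xy, sig_xy, SPOT_FILL * NUCLEAR_PEAK)
            val = trace_lut.get((row.nucleus_id, f))
            if val is not None:
                above = max(val - base[f], 0.0)
                if above > 0:
                    dx, dy, dz = offs[row.nucleus_id]
                    add_gaussian(data[SPOT_CHANNEL, fi],
                                 cz + dz / cfg.voxel_z,
                                 cy + dy / cfg.voxel_xy,
                                 cx + dx / cfg.voxel_xy,
                                 spot_sig_z, spot_sig_xy, spot_sig_xy,
                                 above * 10.0)
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    return VoxelGrid(data=data, voxel_xy=cfg.voxel_xy, voxel_z=cfg.voxel_z,
                     frame_interval=cfg.frame_interval, t0_nc14=cfg.t0_nc14)


def spot_offsets(cfg: SimConfig) -> dict[int, np.ndarray]:
    """The fixed per-nucleus spot offsets (µm) render_stack would use."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    rng2 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = np.sort(_place_nuclei(cfg, rng2).nucleus_id.unique())
    offs = {}
    for nid in ids:
        v = rng.normal(size=3)
        v *= (0.4 * NUCLEUS_RADIUS * rng.random() ** (1 / 3)) / np.linalg.norm(v)
        offs[nid] = v
    return offs


# ---------------------------------------------------------------------------
# presets

PRESETS = {
    "control": {},
    # mesoderm invagination delayed ~10 min and gastrulation slowed/stretched
    "fog_like": {"t_invagination": 60.0, "t_end": 75.0,
                 "t_constriction": 50.0, "n_frames": 340},
    # invagination fails entirely; no transcription step
    "acat_like": {"invagination_displacement": 0.0, "me_descent": 0.0,
                  "p_step": 0.0},
}


def preset(name: str, **overrides) -> SimConfig:
    """Named condition presets: control, fog_like, acat_like."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimConfig(**kw)
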