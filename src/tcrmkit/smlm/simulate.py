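"""Synthetic single-molecule TIRF data: diffusing, bleaching, labeled molecules.

Emulates the acquisition used for cell-surface antigen counting: molecules on
a rectangular cell area perform 2D Brownian motion (reflective boundaries),
each fluorescent tag photobleaches in a single step (geometric lifetime), and
detected positions carry Gaussian localization noise.  Dual-color labeling
assigns each tag a spectral channel independently, producing the mixed-color
molecules that the cotracking correction is designed to handle.  An immobile
surface-adsorbed background population and uniform false positives are
included because the analysis stage must remove them.

Defaults mirror the acquisition the pipeline targets: 32 ms per frame, image
stacks of 150 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DualColorLabeling", "SimConfig", "GroundTruth", "simulate",
           "render_movie", "misalign_channels", "LOCALIZATION_COLUMNS"]

LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um", "channel", "intensity"]
CHANNELS = ("ch1", "ch2")


@dataclass(frozen=True)
class DualColorLabeling:
    tags_per_molecule: int = 2
    color_probs: tuple[float, float] = (0.5, 0.5)

    def validate(self) -> None:
        if self.tags_per_molecule < 1:
            raise ValueError("tags_per_molecule must be >= 1")
        if len(self.color_probs) != 2 or abs(sum(self.color_probs) - 1) > 1e-9 \
                or any(not 0 <= p <= 1 for p in self.color_probs):
            raise ValueError("color_probs must be two probabilities summing to 1")


@dataclass(frozen=True)
class SimConfig:
    true_density: float = 0.8            # molecules / um^2
    diffusion_coeff: float = 0.1         # um^2 / s
    frame_interval: float = 0.032        # s
    n_frames: int = 150
    field: tuple[float, float] = (20.0, 20.0)   # um
    localization_sigma: float = 0.02     # um
    bleach_prob: float = 0.02            # per frame per tag
    detection_prob: float = 0.9          # per frame per unbleached tag
    label_model: str | DualColorLabeling = "single_color"
    immobile_density: float = 0.0        # molecules / um^2
    false_positive_rate: float = 0.0     # per frame per um^2
    seed: int = 0

    def validate(self) -> None:
        for name in ("true_density", "immobile_density", "false_positive_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bleach_prob", "detection_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if any(s <= 0 for s in self.field):
            raise ValueError("field dimensions must be > 0")
        if isinstance(self.label_model, DualColorLabeling):
            self.label_model.validate()
        elif self.label_model != "single_color":
            raise ValueError("label_model must be 'single_color' or DualColorLabeling")

    @property
    def area(self) -> float:
        return self.field[0] * self.field[1]

    @property
    def dual_color(self) -> bool:
        return isinstance(self.label_model, DualColorLabeling)


@dataclass
class GroundTruth:
    molecules: pd.DataFrame          # id, mobility, x0, y0
    tags: pd.DataFrame               # molecule_id, tag_id, channel, bleach_frame
    trajectories: np.ndarray         # (n_molecules, n_frames, 2), um
    config: SimConfig
    extras: dict = field(default_factory=dict)

    def n_mobile(self) -> int:
        return int((self.molecules["mobility"] == "mobile").sum())

    def mixed_color_fraction(self) -> float:
        """Fraction of molecules carrying tags of both colors."""
        per_mol = self.tags.groupby("molecule_id")["channel"].nunique()
        return float((per_mol == 2).mean())


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflective boundary via triangle-wave folding."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def simulate(config: SimConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Run the simulation; returns (ground truth, localization table).

    A fixed seed yields byte-identical output (single integer-seeded
    PCG64 generator, fixed draw order).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.field
    n_frames = config.n_frames

    n_mobile = rng.poisson(config.true_density * config.area)
    n_immobile = rng.poisson(config.immobile_density * config.area)
    n_mol = n_mobile + n_immobile
    mobility = np.array(["mobile"] * n_mobile + ["immobile"] * n_immobile)

    start = rng.uniform([0, 0], [w, h], size=(n_mol, 2))
    traj = np.empty((n_mol, n_frames, 2))
    traj[:, 0] = start
    step_sigma = np.sqrt(2.0 * config.diffusion_coeff * config.frame_interval)
    if n_frames > 1:
        steps = rng.normal(0.0, step_sigma, size=(n_mol, n_frames - 1, 2))
        steps[n_mobile:] = 0.0
        path = start[:, None, :] + np.cumsum(steps, axis=1)
        traj[:, 1:, 0] = _reflect(path[:, :, 0], 0.0, w)
        traj[:, 1:, 1] = _reflect(path[:, :, 1], 0.0, h)

    if config.dual_color:
        lm: DualColorLabeling = config.label_model  # type: ignore[assignment]
        tags_per = lm.tags_per_molecule
        colors = rng.choice(2, size=(n_mol, tags_per), p=list(lm.color_probs))
    else:
        tags_per = 1
        colors = np.zeros((n_mol, 1), dtype=int)

    if config.bleach_prob > 0:
        bleach = rng.geometric(config.bleach_prob, size=(n_mol, tags_per))
    else:
        bleach = np.full((n_mol, tags_per), np.iinfo(np.int64).max)

    tag_rows = []
    for m in range(n_mol):
        for t in range(tags_per):
            tag_rows.append((m, t, CHANNELS[colors[m, t]], int(bleach[m, t])))
    tags = pd.DataFrame(tag_rows, columns=["molecule_id", "tag_id", "channel",
                                           "bleach_frame"])

    detected = rng.random(size=(n_mol, tags_per, n_frames)) < config.detection_prob
    noise = rng.normal(0.0, config.localization_sigma,
                       size=(n_mol, tags_per, n_frames, 2))

    frames_idx = np.arange(n_frames)
    visible = frames_idx[None, None, :] < bleach[:, :, None]
    mm, tt, ff = np.nonzero(visible & detected)
    x = np.clip(traj[mm, ff, 0] + noise[mm, tt, ff, 0], 0.0, w)
    y = np.clip(traj[mm, ff, 1] + noise[mm, tt, ff, 1], 0.0, h)
    table = pd.DataFrame({
        "frame": ff, "x_um": x, "y_um": y,
        "channel": np.array(CHANNELS)[colors[mm, tt]],
        "intensity": np.full(len(ff), 1000.0),
    })

    if config.false_positive_rate > 0:
        n_channels = 2 if config.dual_color else 1
        n_fp = rng.poisson(config.false_positive_rate * config.area, size=n_frames)
        total = int(n_fp.sum())
        fp_frames = np.repeat(frames_idx, n_fp)
        fp_xy = rng.uniform([0, 0], [w, h], size=(total, 2))
        fp_ch = np.array(CHANNELS)[rng.integers(n_channels, size=total)]
        fp = pd.DataFrame({
            "frame": fp_frames, "x_um": fp_xy[:, 0], "y_um": fp_xy[:, 1],
            "channel": fp_ch, "intensity": np.full(total, 500.0)})
        table = pd.concat([table, fp], ignore_index=True)

    table = table.astype({"frame": int})
    table = table.sort_values(["frame", "channel", "x_um", "y_um"],
                              kind="mergesort").reset_index(drop=True)
    molecules = pd.DataFrame({
        "id": np.arange(n_mol), "mobility": mobility,
        "x0": start[:, 0], "y0": start[:, 1]})
    truth = GroundTruth(molecules=molecules, tags=tags, trajectories=traj,
                        config=config)
    return truth, table


# ---------------------------------------------------------------------------
# movie rendering (optional pixel-level fixture)
# ---------------------------------------------------------------------------

def render_movie(truth: GroundTruth, psf_sigma: float = 0.15,
                 pixel_size: float = 0.1, amplitude: float = 500.0,
                 background: float = 10.0, read_noise: float = 0.0,
                 shot_noise: bool = False, seed: int = 0,
                 shape: tuple[int, int] | None = None) -> dict[str, np.ndarray]:
    """Render Gaussian spots into per-channel image stacks.

    Spot integral is ``amplitude`` per unbleached tag per frame (conserved
    until bleaching).  Returns {channel: stack (n_frames, H, W) float}.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    w_um, h_um = cfg.field
    if shape is None:
        shape = (int(np.ceil(h_um / pixel_size)), int(np.ceil(w_um / pixel_size)))
    H, W = shape
    channels = CHANNELS if cfg.dual_color else CHANNELS[:1]
    stacks = {ch: np.full((cfg.n_frames, H, W), float(background)) for ch in channels}
    sigma_px = psf_sigma / pixel_size
    half = max(3, int(np.ceil(4 * sigma_px)))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    for tag in truth.tags.itertuples(index=False):
        m = tag.molecule_id
        stack = stacks[tag.channel]
        visible = min(int(tag.bleach_frame), cfg.n_frames)
        for f in range(visible):
            cx = truth.trajectories[m, f, 0] / pixel_size
            cy = truth.trajectories[m, f, 1] / pixel_size
            ix, iy = int(round(cx)), int(round(cy))
            dx, dy = cx - ix, cy - iy
            spot = np.exp(-((xx - dx) ** 2 + (yy - dy) ** 2) / (2 * sigma_px ** 2))
            spot *= amplitude / (2 * np.pi * sigma_px ** 2)
            y0, y1 = iy - half, iy + half + 1
            x0, x1 = ix - half, ix + half + 1
            sy0, sx0 = max(0, -y0), max(0, -x0)
            y0, x0 = max(0, y0), max(0, x0)
            y1, x1 = min(H, y1), min(W, x1)
            if y1 > y0 and x1 > x0:
                stack[f, y0:y1, x0:x1] += spot[sy0:sy0 + (y1 - y0),
                                               sx0:sx0 + (x1 - x0)]
    for ch, stack in stacks.items():
        if shot_noise:
            stack[:] = rng.poisson(np.maximum(stack, 0.0)).astype(float)
        if read_noise > 0:
            stack += rng.normal(0.0, read_noise, size=stack.shape)
    return stacks


def misalign_channels(table: pd.DataFrame, transform) -> pd.DataFrame:
    """Apply a similarity transform to the channel-2 coordinates.

    ``transform`` is an ``skimage.transform.SimilarityTransform`` (um units);
    used to exercise ``register_channels``.
    """
    params = np.asarray(transform.params, float)
    if abs(np.linalg.det(params)) < 1e-12:
        raise ValueError("transform is not invertible")
    out = table.copy()
    mask = (out["channel"] == "ch2").to_numpy()
    xy = out.loc[mask, ["x_um", "y_um"]].to_numpy(float)
    if len(xy):
        out.loc[mask, ["x_um", "y_um"]] = transform(xy)
    return out
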