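"""Cell-surface antigen quantification from single-molecule data.

Pipeline: localize (or ingest a localization table) -> link trajectories ->
remove the immobile surface-adsorbed background -> extrapolate the initial
mobile count N0 through photobleaching -> surface density rho = N0 / vCSA ->
optional dual-color double-count correction A + B - 0.5 AB -> per-cell count
rho x tCSA.

Conventions: all distances in micrometres; pixel-to-um conversion happens
only at the image I/O boundary.  Linking is frame-to-frame nearest-neighbour
assignment resolved globally per frame by minimal total displacement
(Hungarian algorithm), with gap closing; ties are deterministic given the
input order.  Colocalization uses a strict distance threshold (default
150 nm) and cotrajectories must sustain a minimum number of consecutive
steps (default 10, i.e. 320 ms at 32 ms/frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.spatial import cKDTree

__all__ = [
    "Track", "QuantConfig", "DensityResult",
    "detect_spots", "link_tracks", "remove_immobile",
    "counts_per_frame", "estimate_initial_count", "density",
    "segment_vcsa", "register_channels", "cotrack",
    "dual_color_count", "per_cell_count", "estimate_tcsa",
    "quantify_density",
]


@dataclass
class Track:
    id: int
    channel: str
    frames: np.ndarray
    xy: np.ndarray
    mobile: bool | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class QuantConfig:
    max_disp: float = 0.5          # um per frame step
    max_gap: int = 1               # frames
    coloc_threshold: float = 0.150  # um ("150 nm")
    min_cotrack_steps: int = 10    # consecutive steps ("320 ms")
    immobile_radius: float = 0.075  # um
    immobile_min_fraction: float = 0.8
    immobile_min_points: int = 4   # shorter tracks are not classifiable
    bleach_fit: str = "exponential"
    frame_interval: float = 0.032  # s
    tCSA: float = 3900.0           # um^2, mean total cell surface area
    vCSA: float | None = None      # um^2; or provide a segmentation image
    counts_from: str = "track_spans"  # or "localizations"
    fit_start_frame: int = 1

    def validate(self) -> None:
        if self.max_disp <= 0 or self.coloc_threshold <= 0:
            raise ValueError("distance thresholds must be > 0")
        if self.min_cotrack_steps < 1:
            raise ValueError("min_cotrack_steps must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.bleach_fit != "exponential":
            raise ValueError("only exponential bleach fit is supported")


@dataclass
class DensityResult:
    """Result of the counting pipeline; the algebraic identities
    rho = N0 / vCSA and per_cell = rho x tCSA hold exactly by construction."""

    N0_mobile: float
    vCSA: float
    rho: float
    per_cell: float
    dual_corrected_count: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.rho, self.N0_mobile / self.vCSA, rtol=1e-12):
            raise ValueError("rho != N0 / vCSA")
        if self.N0_mobile < 0 or self.vCSA <= 0 or self.rho < 0 or self.per_cell < 0:
            raise ValueError("negative quantity in DensityResult")


# ---------------------------------------------------------------------------
# spot detection (simplified single-emitter localizer)
# ---------------------------------------------------------------------------

def _gaussian2d(params, xx, yy):
    a, x0, y0, s, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s ** 2)) + b


def detect_spots(movie: np.ndarray, pixel_size: float, psf_sigma_px: float = 1.5,
                 threshold_factor: float = 5.0, channel: str = "ch1",
                 saturation_level: float | None = None) -> pd.DataFrame:
    """Per-frame spot detection with sub-pixel Gaussian refinement.

    Bandpass (difference of Gaussians) filtering, local maxima above a
    robust threshold (median + ``threshold_factor`` x MAD-sigma of the
    filtered frame), then least-squares 2D Gaussian fit in a window around
    each candidate.  Frames containing saturated pixels are flagged in the
    ``saturated`` column rather than silently fit.
    """
    from scipy.optimize import least_squares

    if movie.ndim != 3:
        raise ValueError("movie must be a (n_frames, H, W) stack")
    half = max(3, int(np.ceil(2.5 * psf_sigma_px)))
    rows = []
    for f, frame in enumerate(movie):
        frame = frame.astype(float)
        saturated = bool(saturation_level is not None
                         and np.any(frame >= saturation_level))
        band = gaussian_filter(frame, psf_sigma_px) - \
            gaussian_filter(frame, psf_sigma_px * 4)
        med = np.median(band)
        mad = np.median(np.abs(band - med)) * 1.4826
        thr = med + threshold_factor * max(mad, 1e-12)
        from scipy.ndimage import maximum_filter
        neigh = max(3, int(round(2 * psf_sigma_px)) | 1)
        peaks = (band == maximum_filter(band, size=neigh)) & (band > thr)
        for iy, ix in zip(*np.nonzero(peaks)):
            y0, y1 = iy - half, iy + half + 1
            x0, x1 = ix - half, ix + half + 1
            if y0 < 0 or x0 < 0 or y1 > frame.shape[0] or x1 > frame.shape[1]:
                continue
            win = frame[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
            p0 = [win.max() - win.min(), float(ix), float(iy),
                  psf_sigma_px, float(win.min())]
            try:
                fit = least_squares(
                    lambda p: (_gaussian2d(p, xx, yy) - win).ravel(), p0,
                    bounds=([0, x0, y0, 0.3, -np.inf],
                            [np.inf, x1, y1, 10 * psf_sigma_px, np.inf]))
                _, xc, yc, _, _ = fit.x
            except ValueError:
                xc, yc = float(ix), float(iy)
            rows.append((f, xc * pixel_size, yc * pixel_size, channel,
                         float(win.sum()), saturated))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "channel",
                                       "intensity", "saturated"])


# ---------------------------------------------------------------------------
# trajectory linking
# ---------------------------------------------------------------------------

def link_tracks(table: pd.DataFrame, config: QuantConfig) -> list[Track]:
    """Link localizations into trajectories (one channel at a time).

    Frame-to-frame assignment minimizes total displacement (Hungarian),
    gated at ``max_disp`` per elapsed frame; tracks unmatched for more than
    ``max_gap`` frames are closed; unmatched localizations start new tracks.
    """
    config.validate()
    channels = table["channel"].unique() if "channel" in table else ["ch1"]
    if len(channels) > 1:
        raise ValueError("link_tracks expects a single channel; split first")
    channel = str(channels[0]) if len(channels) else "ch1"
    table = table.sort_values(["frame", "x_um", "y_um"], kind="mergesort")

    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for f, grp in table.groupby("frame", sort=True):
        f = int(f)
        pts = grp[["x_um", "y_um"]].to_numpy(float)
        still, expired = [], []
        for tr in active:
            (expired if f - tr["frames"][-1] > config.max_gap + 1 else still).append(tr)
        done.extend(expired)
        active = still

        n_t, n_p = len(active), len(pts)
        assigned_pts = np.full(n_p, -1)
        if n_t and n_p:
            cost = np.full((n_t, n_p), 1e6)
            for i, tr in enumerate(active):
                gap = f - tr["frames"][-1]
                gate = config.max_disp * gap
                d = np.linalg.norm(pts - tr["xy"][-1], axis=1)
                ok = d <= gate
                cost[i, ok] = d[ok]
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < 1e6:
                    active[i]["frames"].append(f)
                    active[i]["xy"].append(pts[j])
                    assigned_pts[j] = i
        for j in range(n_p):
            if assigned_pts[j] < 0:
                active.append({"id": next_id, "frames": [f], "xy": [pts[j]]})
                next_id += 1
    done.extend(active)
    done.sort(key=lambda tr: tr["id"])
    return [Track(id=tr["id"], channel=channel,
                  frames=np.array(tr["frames"]), xy=np.array(tr["xy"]))
            for tr in done]


def remove_immobile(tracks: list[Track], config: QuantConfig) -> list[Track]:
    """Drop surface-adsorbed (stationary) tracks.

    A track is immobile when at least ``immobile_min_fraction`` of its
    localizations lie within ``immobile_radius`` of the track median
    position.  Tracks with fewer than ``immobile_min_points`` localizations
    cannot be classified reliably and are kept as mobile.  Mobility flags
    are set on all input tracks.
    """
    mobile = []
    for tr in tracks:
        if len(tr) < config.immobile_min_points:
            tr.mobile = True
            mobile.append(tr)
            continue
        med = np.median(tr.xy, axis=0)
        frac = float(np.mean(np.linalg.norm(tr.xy - med, axis=1)
                             <= config.immobile_radius))
        tr.mobile = frac < config.immobile_min_fraction
        if tr.mobile:
            mobile.append(tr)
    return mobile


def counts_per_frame(tracks: list[Track], n_frames: int,
                     mode: str = "track_spans") -> np.ndarray:
    """Molecules per frame: tracks spanning the frame, or raw localizations.

    ``track_spans`` counts a track in every frame between its first and last
    localization (robust to missed detections inside a track);
    ``localizations`` counts actual detections.
    """
    counts = np.zeros(n_frames)
    for tr in tracks:
        if mode == "track_spans":
            counts[tr.frames[0]:tr.frames[-1] + 1] += 1
        elif mode == "localizations":
            counts[tr.frames] += 1
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
    return counts


# ---------------------------------------------------------------------------
# photobleaching extrapolation and the counting equations
# ---------------------------------------------------------------------------

def estimate_initial_count(counts: np.ndarray, fit_start_frame: int = 0
                           ) -> tuple[float, float, dict]:
    """Extrapolate the initial molecule count through photobleaching.

    Fits N(t) = N0 exp(-k t) (t in frames) by nonlinear least squares,
    initialized from a log-linear regression.  Returns (N0, k, diagnostics).
    If the series does not decrease, returns the mean with ``k = 0`` and a
    warning flag.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 10:
        raise ValueError("need at least 10 frames of counts")
    if np.all(counts == 0):
        raise ValueError("all-zero counts: nothing to extrapolate")
    t = np.arange(len(counts), dtype=float)
    fit_t, fit_c = t[fit_start_frame:], counts[fit_start_frame:]
    pos = fit_c > 0
    slope, intercept = np.polyfit(fit_t[pos], np.log(fit_c[pos]), 1)
    if slope >= -1e-12:
        warnings.warn("counts do not decrease; returning mean count with k=0")
        n0 = float(np.mean(fit_c))
        return n0, 0.0, {"warning": "non_decreasing", "residual_rms": float(
            np.sqrt(np.mean((fit_c - n0) ** 2)))}
    p0 = [float(np.exp(intercept)), float(-slope)]
    popt, _ = curve_fit(lambda tt, n0, k: n0 * np.exp(-k * tt),
                        fit_t, fit_c, p0=p0, maxfev=10000)
    n0, k = float(popt[0]), float(popt[1])
    resid = fit_c - n0 * np.exp(-k * fit_t)
    return n0, k, {"residual_rms": float(np.sqrt(np.mean(resid ** 2)))}


def density(n0: float, vcsa: float) -> float:
    """Surface density rho = N0 / vCSA (molecules per um^2)."""
    if vcsa <= 0:
        raise ValueError("vCSA must be > 0")
    return n0 / vcsa


def dual_color_count(a: float, b: float, ab: float) -> float:
    """Dual-color corrected molecule number: A + B - 0.5 AB.

    A and B are the per-channel molecule numbers, AB the number of
    cotrajectories (molecules carrying both colors, counted in both
    channels).  The 0.5 factor additionally compensates same-color
    double-labeled molecules under stochastic two-tag labeling.
    """
    if a < 0 or b < 0 or ab < 0:
        raise ValueError("counts must be >= 0")
    if ab > min(a, b):
        raise ValueError(f"AB={ab} exceeds min(A, B)={min(a, b)}")
    return a + b - 0.5 * ab


def per_cell_count(rho: float, tcsa: float = 3900.0) -> float:
    """Molecules per cell = density x total cell surface area."""
    return rho * tcsa


def estimate_tcsa(contour_area: float) -> float:
    """Total cell surface area from a 2D contour area (factor-2 rule)."""
    if contour_area <= 0:
        raise ValueError("contour_area must be > 0")
    return 2.0 * contour_area


# ---------------------------------------------------------------------------
# vCSA segmentation and channel registration
# ---------------------------------------------------------------------------

def segment_vcsa(image: np.ndarray, pixel_size: float,
                 smooth_sigma: float = 2.0) -> float:
    """Visible cell surface area from background fluorescence (um^2).

    Otsu threshold on the smoothed image, largest connected foreground
    component, area = pixel count x pixel area.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    img = gaussian_filter(np.asarray(image, float), smooth_sigma)
    if img.max() - img.min() < 1e-12:
        raise ValueError("flat image: no foreground to segment")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    lab = label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return float((lab == largest).sum()) * pixel_size ** 2


def register_channels(points_a: np.ndarray, points_b: np.ndarray):
    """Similarity transform mapping channel-2 bead positions onto channel 1.

    Returns (transform, residual RMS in um).  The transform is an
    ``skimage.transform.SimilarityTransform``; apply it to channel-2
    coordinates to align them with channel 1.
    """
    from skimage.transform import SimilarityTransform, estimate_transform

    points_a = np.asarray(points_a, float)
    points_b = np.asarray(points_b, float)
    if points_a.shape != points_b.shape or len(points_a) < 3:
        raise ValueError("need >= 3 matched point pairs")
    spread = points_b - points_b.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9) < 2:
        raise ValueError("calibration points are collinear")
    tf = estimate_transform("similarity", points_b, points_a)
    if not isinstance(tf, SimilarityTransform) or not np.all(np.isfinite(tf.params)):
        raise ValueError("transform estimation failed")
    resid = tf(points_b) - points_a
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return tf, rms


# ---------------------------------------------------------------------------
# colocalization / cotracking
# ---------------------------------------------------------------------------

def cotrack(tracks_a: list[Track], tracks_b: list[Track],
            config: QuantConfig) -> tuple[int, pd.DataFrame]:
    """Count cotrajectories between two registered channels.

    Same-frame localizations from the two channels within
    ``coloc_threshold`` form colocalization events (one-to-one, resolved by
    minimal total distance).  A pair of underlying trajectories counts as a
    cotrajectory if it sustains at least ``min_cotrack_steps`` consecutive
    colocalized steps; each pair is counted once.
    Returns (count, per-pair summary table).
    """
    config.validate()
    frames_a: dict[int, list[tuple[int, np.ndarray]]] = {}
    for tr in tracks_a:
        for f, p in zip(tr.frames, tr.xy):
            frames_a.setdefault(int(f), []).append((tr.id, p))
    frames_b: dict[int, list[tuple[int, np.ndarray]]] = {}
    for tr in tracks_b:
        for f, p in zip(tr.frames, tr.xy):
            frames_b.setdefault(int(f), []).append((tr.id, p))

    pair_frames: dict[tuple[int, int], list[int]] = {}
    for f in sorted(set(frames_a) & set(frames_b)):
        ents_a, ents_b = frames_a[f], frames_b[f]
        pa = np.array([p for _, p in ents_a])
        pb = np.array([p for _, p in ents_b])
        cost = np.full((len(pa), len(pb)), 1e6)
        tree = cKDTree(pb)
        for i, hits in enumerate(tree.query_ball_point(pa, r=config.coloc_threshold)):
            for j in hits:
                cost[i, j] = np.linalg.norm(pa[i] - pb[j])
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if cost[i, j] < 1e6:
                pair_frames.setdefault((ents_a[i][0], ents_b[j][0]), []).append(f)

    rows = []
    count = 0
    for (ida, idb), fr in sorted(pair_frames.items()):
        fr = np.array(sorted(fr))
        # longest run of consecutive frames -> number of consecutive steps
        breaks = np.nonzero(np.diff(fr) != 1)[0]
        run_edges = np.concatenate([[0], breaks + 1, [len(fr)]])
        longest = int(max(np.diff(run_edges)))
        steps = longest - 1
        qualifies = steps >= config.min_cotrack_steps
        count += bool(qualifies)
        rows.append((ida, idb, len(fr), steps, qualifies))
    details = pd.DataFrame(rows, columns=[
        "track_a", "track_b", "n_coloc_frames", "max_consecutive_steps",
        "counted"])
    return count, details


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

def quantify_density(table: pd.DataFrame, config: QuantConfig, vcsa: float,
                     n_frames: int, table2: pd.DataFrame | None = None
                     ) -> DensityResult:
    """Run the full counting pipeline on one (or two) localization tables.

    Single-color: N0 is the photobleach-extrapolated initial mobile count.
    Dual-color (``table2`` given): per-channel counts A and B are corrected
    for double labeling with the cotrajectory count AB.
    """
    config.validate()
    if vcsa is None or vcsa <= 0:
        raise ValueError("vCSA must be > 0")

    def _channel_n0(tab: pd.DataFrame) -> tuple[float, dict, list[Track]]:
        tracks = link_tracks(tab, config)
        mobile = remove_immobile(tracks, config)
        counts = counts_per_frame(mobile, n_frames, mode=config.counts_from)
        n0, k, diag = estimate_initial_count(counts, config.fit_start_frame)
        diag.update({"bleach_rate_per_frame": k,
                     "n_tracks": len(tracks), "n_mobile_tracks": len(mobile),
                     "first_frame_mobile_count": float(counts[0]),
                     "counts_per_frame": counts})
        return n0, diag, mobile

    n0_a, diag_a, mobile_a = _channel_n0(table)
    dual = None
    diagnostics: dict = {"channel1": diag_a, "config": config}
    if table2 is not None:
        n0_b, diag_b, mobile_b = _channel_n0(table2)
        ab, details = cotrack(mobile_a, mobile_b, config)
        dual = dual_color_count(n0_a, n0_b, min(float(ab), min(n0_a, n0_b)))
        diagnostics.update({"channel2": diag_b, "A": n0_a, "B": n0_b,
                            "AB": ab, "cotrack_details": details})
        n0 = dual
    else:
        n0 = n0_a
    rho = density(n0, vcsa)
    return DensityResult(N0_mobile=n0, vCSA=vcsa, rho=rho,
                         per_cell=per_cell_count(rho, config.tCSA),
                         dual_corrected_count=dual, diagnostics=diagnostics)
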