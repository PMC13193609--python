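"""Single-molecule diffusion-state analysis.

Per-track MSD fits, stable-focus detection from localization composites,
In/In-out/Out overlap classification, squared-displacement CDF mixture fits
(two- and three-state), and the condensate/nucleoid/free state-fraction
accounting.

The central model is the cumulative distribution of single-frame squared
displacements r² pooled across tracks.  For a mixture of Brownian states with
diffusion coefficients D_i and weights α_i the CDF at lag τ is

    P(r², τ) = 1 − Σ_i α_i · exp(−r² / ((8/3)·D_i·τ))

with Σα_i = 1.  Fitting this curve decomposes the displacement pool into slow
(condensate-bound), intermediate (nucleoid-bound) and fast (free, D > 1 µm²/s)
subpopulations.  A flag switches the exponent scale to the standard 4·D·τ of
an ideal 2-D Brownian displacement law.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DiffusionFit",
    "FocusRegion",
    "FocusRegionSet",
    "OverlapClass",
    "TwoStateFit",
    "ThreeStateFit",
    "StateFractions",
    "fit_msd",
    "detect_stable_foci",
    "classify_trajectory",
    "classify_all",
    "pooled_squared_displacements",
    "empirical_cdf",
    "fit_three_state",
    "fit_two_state",
    "compute_state_fractions",
    "analyze_trajectory_set",
]

MIN_TRACK_FRAMES_MSD = 7
MIN_TRACK_FRAMES_POOL = 4


# ---------------------------------------------------------------------------
# per-track MSD
# ---------------------------------------------------------------------------


@dataclass
class DiffusionFit:
    D: float  # µm²/s
    sigma: float  # µm localization error
    n_lags_used: int
    residual_norm: float
    clamped: bool = False


def _track_xy(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frames = np.asarray(track["frame"], float)
    order = np.argsort(frames, kind="stable")
    return frames[order], np.asarray(track["x_um"], float)[order], np.asarray(track["y_um"], float)[order]


def fit_msd(track: pd.DataFrame, frame_interval: float, max_lag: int = 5) -> DiffusionFit:
    """Least-squares fit of MSD(kτ) = 4·D·kτ + 4·σ² over lags 1..max_lag.

    Tracks shorter than 7 frames are rejected (too few lag estimates for a
    stable slope).  A negative fitted slope is clamped to D = 0 and flagged.
    """
    frames, x, y = _track_xy(track)
    if len(frames) < MIN_TRACK_FRAMES_MSD:
        raise ValueError(
            f"track has {len(frames)} frames; at least {MIN_TRACK_FRAMES_MSD} required for MSD fitting"
        )
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for i, k in enumerate(lags):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[i] = np.mean(dx**2 + dy**2)
    t = lags * frame_interval
    # linear model msd = 4 D t + 4 sigma^2
    A = np.stack([4.0 * t, np.full_like(t, 4.0)], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, msd, rcond=None)
    D, sig2 = coef
    clamped = False
    if D < 0:
        D, clamped = 0.0, True
    sigma = math.sqrt(max(sig2, 0.0))
    resid = float(np.linalg.norm(A @ coef - msd))
    return DiffusionFit(float(D), sigma, len(lags), resid, clamped)


# ---------------------------------------------------------------------------
# stable-focus detection
# ---------------------------------------------------------------------------


@dataclass
class FocusRegion:
    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    n_supporting_tracks: int = 0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class FocusRegionSet:
    regions: list[FocusRegion]
    image_shape: tuple[int, int]
    pixel_size: float  # µm/px
    provenance: dict = field(default_factory=dict)

    def membership_mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, bool)
        for r in self.regions:
            m[r.pixels[:, 0], r.pixels[:, 1]] = True
        return m


def _localization_pixels(tracks: pd.DataFrame, pixel_size: float, shape) -> tuple[np.ndarray, np.ndarray]:
    rows = np.clip((np.asarray(tracks["y_um"], float) / pixel_size).astype(int), 0, shape[0] - 1)
    cols = np.clip((np.asarray(tracks["x_um"], float) / pixel_size).astype(int), 0, shape[1] - 1)
    return rows, cols


def detect_stable_foci(
    tracks: pd.DataFrame,
    image_shape: tuple[int, int],
    pixel_size: float,
    min_sigma: float = 3.0,
    max_sigma: float = 5.0,
    threshold: float = 0.1,
    min_tracks: int = 10,
    min_track_frames: int = 10,
    min_overlap: float = 0.7,
) -> FocusRegionSet:
    """Detect stable foci from the summed localization composite.

    All localizations are rastered one count per pixel into a composite image,
    normalized to [0, 1], and blob-detected with the Laplacian-of-Gaussian
    detector (min_sigma=3, max_sigma=5, threshold=0.1).  Each blob is
    segmented into the pixels within σ·√2 of its center; contested pixels go
    to the nearer blob.  A putative focus is kept only if at least
    `min_tracks` trajectories of at least `min_track_frames` frames each have
    at least `min_overlap` of their localizations inside it.
    """
    from skimage.feature import blob_log

    provenance = dict(
        min_sigma=min_sigma, max_sigma=max_sigma, threshold=threshold,
        min_tracks=min_tracks, min_track_frames=min_track_frames, min_overlap=min_overlap,
        pixel_size=pixel_size,
    )
    if len(tracks) == 0:
        return FocusRegionSet([], image_shape, pixel_size, provenance)

    rows, cols = _localization_pixels(tracks, pixel_size, image_shape)
    composite = np.zeros(image_shape, float)
    np.add.at(composite, (rows, cols), 1.0)
    if composite.max() > 0:
        composite = composite / composite.max()

    blobs = blob_log(composite, min_sigma=min_sigma, max_sigma=max_sigma, threshold=threshold)
    if blobs.size == 0:
        return FocusRegionSet([], image_shape, pixel_size, provenance)

    centers = blobs[:, :2]
    radii = blobs[:, 2] * math.sqrt(2.0)  # 2-D blob radius convention
    rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    dist2 = ((rr[None] - centers[:, 0, None, None]) ** 2 + (cc[None] - centers[:, 1, None, None]) ** 2)
    inside = dist2 <= (radii[:, None, None] ** 2)
    owner = np.argmin(dist2, axis=0)  # contested pixels -> nearest center

    candidate_regions = []
    for bi in range(len(blobs)):
        sel = inside[bi] & (owner == bi)
        pix = np.argwhere(sel)
        if len(pix):
            candidate_regions.append(FocusRegion(tuple(centers[bi]), float(radii[bi]), pix))

    # trajectory-support filter
    track_groups = tracks.groupby("track_id", sort=False)
    long_tracks = []
    for tid, g in track_groups:
        if len(g) >= min_track_frames:
            r, c = _localization_pixels(g, pixel_size, image_shape)
            long_tracks.append((r, c))
    kept = []
    for reg in candidate_regions:
        m = reg.mask(image_shape)
        n_support = sum(1 for r, c in long_tracks if m[r, c].mean() >= min_overlap)
        if n_support >= min_tracks:
            reg.n_supporting_tracks = n_support
            kept.append(reg)
    return FocusRegionSet(kept, image_shape, pixel_size, provenance)


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------


@dataclass
class OverlapClass:
    label: str  # "In" | "InOut" | "Out"
    overlap_fraction: float


def classify_trajectory(track: pd.DataFrame, regions: FocusRegionSet) -> OverlapClass:
    """In / In-out / Out classification by share of localizations inside foci.

    fraction = 1 -> In; 0.25 <= fraction < 1 -> InOut; < 0.25 -> Out.
    """
    if not regions.regions:
        return OverlapClass("Out", 0.0)
    mask = regions.membership_mask()
    r, c = _localization_pixels(track, regions.pixel_size, regions.image_shape)
    frac = float(mask[r, c].mean())
    if frac >= 1.0:
        label = "In"
    elif frac >= 0.25:
        label = "InOut"
    else:
        label = "Out"
    return OverlapClass(label, frac)


def classify_all(tracks: pd.DataFrame, regions: FocusRegionSet) -> pd.DataFrame:
    """Per-track classification table (track_id, label, overlap_fraction)."""
    rows = []
    for tid, g in tracks.groupby("track_id", sort=False):
        oc = classify_trajectory(g, regions)
        rows.append((tid, oc.label, oc.overlap_fraction))
    return pd.DataFrame(rows, columns=["track_id", "label", "overlap_fraction"])


# ---------------------------------------------------------------------------
# pooled displacements and the empirical CDF
# ---------------------------------------------------------------------------


def pooled_squared_displacements(
    tracks: pd.DataFrame, min_len: int = MIN_TRACK_FRAMES_POOL
) -> np.ndarray:
    """Pool consecutive-frame squared displacements from tracks of >= min_len frames."""
    out = []
    for _, g in tracks.groupby("track_id", sort=False):
        frames, x, y = _track_xy(g)
        if len(frames) < min_len:
            continue
        consec = np.diff(frames) == 1
        dx = np.diff(x)[consec]
        dy = np.diff(y)[consec]
        out.append(dx**2 + dy**2)
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def empirical_cdf(r2_pool: np.ndarray):
    """Right-continuous ECDF: fraction of pooled r² values <= query."""
    pool = np.sort(np.asarray(r2_pool, float))
    if pool.size == 0:
        raise ValueError("empty displacement pool")
    n = pool.size

    def cdf(q):
        return np.searchsorted(pool, np.asarray(q, float), side="right") / n

    return cdf


# ---------------------------------------------------------------------------
# multi-state CDF mixture fits
# ---------------------------------------------------------------------------


@dataclass
class ThreeStateFit:
    D1: float
    D2: float
    D3: float
    alpha1: float
    alpha2: float
    residual: float
    converged: bool = True
    degenerate: bool = False

    @property
    def alpha3(self) -> float:
        return 1.0 - self.alpha1 - self.alpha2


@dataclass
class TwoStateFit:
    D1: float
    D2: float
    alpha: float
    residual: float
    converged: bool = True
    degenerate: bool = False


def _cdf_scale(D: np.ndarray, tau: float, standard_factor: bool) -> np.ndarray:
    factor = 4.0 if standard_factor else 8.0 / 3.0
    return factor * D * tau


def model_cdf(r2, D, alphas, tau, standard_factor=False):
    """Mixture CDF P(r², τ) = 1 − Σ α_i exp(−r²/(c·D_i·τ)) with c = 8/3 (or 4)."""
    D = np.asarray(D, float)
    alphas = np.asarray(alphas, float)
    scale = _cdf_scale(D, tau, standard_factor)
    scale = np.maximum(scale, 1e-300)
    r2 = np.asarray(r2, float)
    return 1.0 - np.sum(alphas[:, None] * np.exp(-r2[None, :] / scale[:, None]), axis=0)


def _fit_mixture(r2_pool, tau, n_states, standard_factor, n_starts, seed):
    r2 = np.sort(np.asarray(r2_pool, float))
    if r2.size == 0:
        raise ValueError("empty displacement pool")
    y = np.arange(1, r2.size + 1) / r2.size  # ECDF at observed r²

    rng = np.random.default_rng(seed)
    mean_r2 = float(np.mean(r2))
    factor = 4.0 if standard_factor else 8.0 / 3.0
    d_guess = mean_r2 / (factor * tau)

    def unpack(p):
        D = np.asarray(p[:n_states])
        raw = np.asarray(p[n_states:])
        alphas = np.append(raw, 1.0 - raw.sum())
        return D, alphas

    def resid(p):
        D, alphas = unpack(p)
        return model_cdf(r2, D, alphas, tau, standard_factor) - y

    # weight-simplex constraint handled by bounds + penalty on alpha sum
    lo = [0.0] * n_states + [0.0] * (n_states - 1)
    hi = [np.inf] * n_states + [1.0] * (n_states - 1)

    best = None
    starts = []
    if n_states == 3:
        starts.append([0.05 * d_guess, 0.5 * d_guess, 3.0 * d_guess, 1 / 3, 1 / 3])
    else:
        starts.append([0.2 * d_guess, 2.0 * d_guess, 0.5])
    for _ in range(max(n_starts - 1, 0)):
        ds = np.sort(d_guess * 10 ** rng.uniform(-1.5, 0.8, n_states))
        if n_states == 3:
            a = rng.dirichlet([1, 1, 1])
            starts.append([*ds, a[0], a[1]])
        else:
            starts.append([*ds, rng.uniform(0.1, 0.9)])

    def penalized(p):
        r = resid(p)
        asum = np.sum(p[n_states:])
        pen = max(asum - 1.0, 0.0) * 10.0 * math.sqrt(r2.size)
        return np.append(r, pen)

    for p0 in starts:
        try:
            sol = optimize.least_squares(penalized, p0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        cost = float(np.sum(sol.fun[:-1] ** 2))
        if best is None or cost < best[1]:
            best = (sol, cost)
    if best is None:
        raise RuntimeError("mixture CDF fit failed to converge from all starts")
    sol, cost = best
    D, alphas = unpack(sol.x)
    # canonical ordering by increasing D; tie-break by larger alpha first
    order = np.lexsort((-alphas, D))
    D, alphas = D[order], alphas[order]
    residual = math.sqrt(cost / r2.size)
    degenerate = any(
        D[i + 1] > 0 and abs(D[i + 1] - D[i]) / max(D[i + 1], 1e-12) < 0.05
        for i in range(n_states - 1)
    )
    if degenerate:
        warnings.warn("mixture fit degenerate: two diffusion states within 5%", stacklevel=3)
    return D, alphas, residual, bool(sol.success), degenerate


def fit_three_state(
    r2_pool: np.ndarray,
    tau: float,
    standard_factor: bool = False,
    n_starts: int = 3,
    seed: int = 0,
) -> ThreeStateFit:
    """Three-state mixture fit of the pooled squared-displacement CDF.

    Unweighted least squares of the analytical mixture CDF against the
    empirical CDF evaluated at every observed r², with bounded parameters
    (α in the simplex, D ≥ 0) and seeded multi-start against local minima.
    States are reported in increasing-D order.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if len(r2_pool) < 100:
        warnings.warn("fewer than 100 pooled displacements; fit may be unstable", stacklevel=2)
    D, a, residual, ok, degen = _fit_mixture(r2_pool, tau, 3, standard_factor, n_starts, seed)
    return ThreeStateFit(D[0], D[1], D[2], a[0], a[1], residual, ok, degen)


def fit_two_state(
    r2_pool: np.ndarray,
    tau: float,
    standard_factor: bool = False,
    n_starts: int = 3,
    seed: int = 0,
) -> TwoStateFit:
    """Two-state analogue of :func:`fit_three_state`."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    D, a, residual, ok, degen = _fit_mixture(r2_pool, tau, 2, standard_factor, n_starts, seed)
    return TwoStateFit(D[0], D[1], a[0], residual, ok, degen)


# ---------------------------------------------------------------------------
# state-fraction accounting
# ---------------------------------------------------------------------------


@dataclass
class StateFractions:
    F_free: float
    F_condensate: float
    F_nucleoid: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.F_free, self.F_condensate, self.F_nucleoid)


def compute_state_fractions(
    full_fit: ThreeStateFit,
    subset_fit: ThreeStateFit,
    n_in: int,
    n_inout: int,
    n_total: int,
) -> StateFractions:
    """Condensate / nucleoid / free decomposition of the displacement pool.

    F_condensate = ((N_In + N_InOut) / N_total) · (α1 + α2 of the In+InOut
    subset fit); F_free = α3 of the full fit (the D3 > 1 µm²/s free state);
    F_nucleoid is the remainder.  Counts are displacement counts, so the
    fractions are shares of the analysed displacements.
    """
    if n_total == 0:
        raise ValueError("n_total displacements must be > 0")
    if full_fit.D3 <= 1.0:
        warnings.warn(
            f"full-fit D3 = {full_fit.D3:.3g} µm²/s <= 1; fast state may not be freely diffusing",
            stacklevel=2,
        )
    f_cond = ((n_in + n_inout) / n_total) * (subset_fit.alpha1 + subset_fit.alpha2)
    f_free = full_fit.alpha3
    f_nuc = 1.0 - f_free - f_cond
    if f_nuc < -1e-9:
        raise ValueError(
            f"inconsistent fits: F_nucleoid = {f_nuc:.4g} < 0 (F_free={f_free:.4g}, F_condensate={f_cond:.4g})"
        )
    return StateFractions(f_free, f_cond, max(f_nuc, 0.0))


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


def analyze_trajectory_set(
    tracks: pd.DataFrame,
    frame_interval: float,
    pixel_size: float,
    image_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> dict:
    """Full pipeline: foci -> classification -> CDF fits -> state fractions.

    Returns a dict with the focus set, per-track classes, full and subset
    three-state fits, displacement counts and the StateFractions.
    """
    if image_shape is None:
        side = int(np.ceil(max(tracks["x_um"].max(), tracks["y_um"].max()) / pixel_size)) + 1
        image_shape = (side, side)
    foci = detect_stable_foci(tracks, image_shape, pixel_size)
    classes = classify_all(tracks, foci)
    by_label = dict(tuple(classes.groupby("label")))

    def _steps(track_ids):
        sub = tracks[tracks["track_id"].isin(track_ids)]
        return pooled_squared_displacements(sub)

    r2_all = pooled_squared_displacements(tracks)
    in_ids = by_label.get("In", pd.DataFrame({"track_id": []}))["track_id"]
    inout_ids = by_label.get("InOut", pd.DataFrame({"track_id": []}))["track_id"]
    r2_in = _steps(in_ids)
    r2_inout = _steps(inout_ids)
    r2_subset = np.concatenate([r2_in, r2_inout]) if (len(r2_in) or len(r2_inout)) else np.empty(0)

    full_fit = fit_three_state(r2_all, frame_interval, seed=seed)
    if len(r2_subset) >= 100:
        subset_fit = fit_three_state(r2_subset, frame_interval, seed=seed + 1)
    else:
        # no condensate displacements worth fitting: zero condensate weight
        subset_fit = ThreeStateFit(0.0, 0.0, full_fit.D3, 0.0, 0.0, 0.0, True)
    fractions = compute_state_fractions(
        full_fit, subset_fit, len(r2_in), len(r2_inout), len(r2_all)
    )
    return {
        "foci": foci,
        "classes": classes,
        "full_fit": full_fit,
        "subset_fit": subset_fit,
        "n_in_steps": len(r2_in),
        "n_inout_steps": len(r2_inout),
        "n_total_steps": len(r2_all),
        "fractions": fractions,
    }
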