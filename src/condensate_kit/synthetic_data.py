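"""Ground-truth generators for every pipeline input.

Each generator emulates the statistical structure the corresponding analysis
assumes — Brownian trajectories from a three-state diffusion mixture,
Gaussian-spot cell images, droplet fields of disks/ellipses, exponentially
decaying rifampicin-chase counts with fixed spike-ins, and 3'-end reads
carrying untemplated terminal-A runs from per-gene zero-inflated negative
binomial laws — and returns the planted truth alongside the data so every
stage can be validated by parameter recovery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySimConfig",
    "SyntheticImageTruth",
    "DecaySimConfig",
    "PolyASimConfig",
    "simulate_trajectories",
    "render_cell_image",
    "make_cell_masks",
    "render_droplet_field",
    "simulate_decay_counts",
    "simulate_polya_reads",
]

STATE_NAMES = ("condensate", "nucleoid", "free")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySimConfig:
    """Parameters of the single-molecule trajectory simulator.

    The camera frame interval defaults to 20 ms (50 Hz acquisition) and the
    track-length law is geometric with median 10 frames, matching typical
    photoactivated single-molecule datasets where the median trajectory is
    about 10 frames long.
    """

    n_tracks: int = 1000
    frame_interval: float = 0.02  # seconds
    localization_sigma: float = 0.03  # µm, per coordinate
    state_fractions: tuple[float, float, float] = (0.25, 0.30, 0.45)
    diffusion_coeffs: tuple[float, float, float] = (0.05, 0.3, 2.0)  # µm²/s
    focus_centers: tuple[tuple[float, float], ...] = ()
    focus_radius: float = 0.25  # µm
    track_length_median: int = 10  # frames, geometric law
    field_size: tuple[float, float] = (12.8, 12.8)  # µm
    condensate_D: float | None = None  # within-focus D; defaults to D1
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.state_fractions, float)
        if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-12 or (fr < 0).any():
            raise ValueError("state_fractions must be 3 probabilities summing to 1")
        d = np.asarray(self.diffusion_coeffs, float)
        if d.shape != (3,) or not (np.diff(d) > 0).all():
            raise ValueError("diffusion_coeffs must be strictly increasing (D1<D2<D3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        if fr[0] > 0 and self.focus_centers and self.focus_radius <= 0:
            raise ValueError("focus_radius must be > 0 with a nonzero condensate fraction")
        if fr[0] > 0 and not self.focus_centers:
            raise ValueError("condensate fraction > 0 requires at least one focus center")


@dataclass
class SyntheticImageTruth:
    """Planted truth of a rendered two-channel cell image."""

    cell_masks: np.ndarray  # labelled grid, 0 = background
    focus_truth: list[tuple[tuple[float, float], float, float]]  # ((r, c), sigma_px, amplitude)
    background_level: float = 100.0
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.cell_masks)
        for (r, c), sig, amp in self.focus_truth:
            if amp <= 0:
                raise ValueError("focus amplitudes must be > 0")
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < lab.shape[0] and 0 <= ci < lab.shape[1]):
                raise ValueError("focus center outside image bounds")
            if lab[ri, ci] == 0:
                raise ValueError("focus center must lie inside a cell mask")


@dataclass
class DecaySimConfig:
    """Rifampicin-chase count simulator parameters.

    Per-gene expectation at chase time t is a*exp(-t/b) scaled by a per-sample
    library factor and Poisson-sampled; spike-in rows have time-invariant
    expectations scaled only by the library factor.  `a` is in expected counts
    at t=0 for a unit library factor, `b` in minutes.
    """

    n_genes: int = 200
    a_range: tuple[float, float] = (200.0, 2000.0)
    b_range: tuple[float, float] = (5.0, 65.0)
    timepoints: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0)
    n_replicates: int = 3
    library_size_factors: tuple[float, ...] | None = None  # per sample; default drawn
    # two dozen spike-in species log-spaced over two decades, echoing the
    # multi-species design of commercial ERCC mixes.  All sit above the 5e-4
    # relative-abundance cutoff at these depths: without a stable rRNA-like
    # bulk (not modelled here) a spike straddling the cutoff would drift in
    # and out of the qualifying set as the library total decays, shifting the
    # qualifying median over time
    ercc_abundances: tuple[float, ...] = tuple(
        float(round(v)) for v in np.geomspace(500.0, 50_000.0, 24)
    )
    no_decay: bool = False  # b -> infinity: flat expectations
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, float)
        if t.size == 0:
            raise ValueError("timepoints must be nonempty")
        if (t < 0).any() or not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be nonnegative and increasing")
        if self.library_size_factors is not None and (
            np.asarray(self.library_size_factors, float) <= 0
        ).any():
            raise ValueError("library_size_factors must be > 0")


@dataclass
class PolyASimConfig:
    """Poly(A)-read simulator parameters for the 2x2 genotype x starvation design."""

    n_genes: int = 50
    condition_means: np.ndarray | None = None  # (n_genes, 4) expected tail length
    zero_inflation: float = 0.3
    overdispersion: float = 0.5  # NB2 alpha: var = mu + alpha*mu^2
    reads_per_gene: int = 200  # per condition (summed over replicates)
    n_replicates: int = 4
    contig: str = "chr"
    contig_length: int = 2_000_000
    gene_spacing: int = 3000
    read_length: int = 75
    seed: int = 0
    conditions: tuple[str, ...] = ("WT_N0", "WT_N24", "dppk_N0", "dppk_N24")

    def __post_init__(self) -> None:
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def _geometric_p_for_median(median: int) -> float:
    # P(L >= m) = (1-p)^(m-1); median m solves (1-p)^(m-1) = 0.5 -> support {1,2,...}
    return 1.0 - 0.5 ** (1.0 / (median - 0.5))


def _reflect_into_disk(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back inside a disk (reflecting boundary)."""
    d = pos - center
    r = math.hypot(d[0], d[1])
    if r <= radius or r == 0.0:
        return pos
    r_new = 2.0 * radius - r
    r_new = max(r_new, 0.0)
    # a step more than 2R outside cannot occur for realistic D*tau << R^2;
    # clamp to the boundary if it does
    r_new = min(r_new, radius)
    return center + d * (r_new / r)


def simulate_trajectories(config: TrajectorySimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Brownian tracks from the three-state mixture.

    Returns ``(tracks, truth)``: `tracks` has columns
    ``track_id, frame, x_um, y_um`` and `truth` one row per track with its
    state label (condensate / nucleoid / free) and length.

    Condensate-state tracks start inside a randomly chosen focus and are
    reflected at the focus boundary; the other states diffuse freely in the
    field (periodic-free; positions are not clipped).  I.i.d. Gaussian
    localization noise of sd `localization_sigma` is added per coordinate.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_tracks)
    cols = {"track_id": [], "frame": [], "x_um": [], "y_um": []}
    truth_rows = []
    if n == 0:
        tracks = pd.DataFrame(cols).astype({"track_id": int, "frame": int})
        truth = pd.DataFrame(columns=["track_id", "state", "n_frames"])
        return tracks, truth

    p_len = _geometric_p_for_median(config.track_length_median)
    states = rng.choice(3, size=n, p=np.asarray(config.state_fractions, float))
    # minimum 2 frames so every track yields at least one displacement
    lengths = np.maximum(rng.geometric(p_len, size=n), 2)
    d_cond = config.condensate_D if config.condensate_D is not None else config.diffusion_coeffs[0]
    fx, fy = config.field_size
    centers = np.asarray(config.focus_centers, float).reshape(-1, 2)

    for tid in range(n):
        s = int(states[tid])
        L = int(lengths[tid])
        if s == 0:
            ci = rng.integers(len(centers))
            center = centers[ci]
            # uniform start inside the focus disk
            u, th = rng.random(), rng.random() * 2 * math.pi
            r0 = config.focus_radius * math.sqrt(u)
            pos = center + r0 * np.array([math.cos(th), math.sin(th)])
            D = d_cond
        else:
            pos = np.array([rng.random() * fx, rng.random() * fy])
            D = config.diffusion_coeffs[s]
        step_sd = math.sqrt(2.0 * D * config.frame_interval)
        xs = np.empty(L)
        ys = np.empty(L)
        for k in range(L):
            if k > 0:
                pos = pos + rng.normal(0.0, step_sd, size=2)
                if s == 0:
                    pos = _reflect_into_disk(pos, center, config.focus_radius)
            xs[k] = pos[0]
            ys[k] = pos[1]
        if config.localization_sigma > 0:
            xs = xs + rng.normal(0.0, config.localization_sigma, size=L)
            ys = ys + rng.normal(0.0, config.localization_sigma, size=L)
        cols["track_id"].extend([tid] * L)
        cols["frame"].extend(range(L))
        cols["x_um"].extend(xs)
        cols["y_um"].extend(ys)
        truth_rows.append((tid, STATE_NAMES[s], L))

    tracks = pd.DataFrame(cols)
    truth = pd.DataFrame(truth_rows, columns=["track_id", "state", "n_frames"])
    return tracks, truth


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------


def make_cell_masks(
    shape: tuple[int, int] = (256, 256),
    n_cells: int = 12,
    cell_radii: tuple[float, float] = (9.0, 16.0),
    seed: int = 0,
) -> np.ndarray:
    """Labelled grid of non-overlapping elliptical 'cells' on background 0."""
    from skimage.draw import ellipse

    rng = np.random.default_rng(seed)
    lab = np.zeros(shape, dtype=np.int32)
    placed = 0
    attempts = 0
    while placed < n_cells and attempts < 500:
        attempts += 1
        a = rng.uniform(*cell_radii)
        b = rng.uniform(*cell_radii)
        r = rng.uniform(a + 2, shape[0] - a - 2)
        c = rng.uniform(b + 2, shape[1] - b - 2)
        rr, cc = ellipse(r, c, a, b, shape=shape)
        if (lab[rr, cc] != 0).any():
            continue
        placed += 1
        lab[rr, cc] = placed
    return lab


def render_cell_image(
    truth: SyntheticImageTruth,
    seed: int = 0,
    second_channel_corr: float | None = None,
) -> np.ndarray:
    """Render a (2, H, W) float image: background + Gaussian spots + noise.

    Channel 0 carries the planted spots.  Channel 1 is an independent noise
    channel unless `second_channel_corr` is given, in which case it is a
    mixture ``corr*ch0 + sqrt(1-corr^2)*noise`` (rescaled around background)
    so per-cell rank correlation against channel 0 is tunable.
    """
    rng = np.random.default_rng(seed)
    shape = truth.cell_masks.shape
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    spots = np.zeros(shape, float)
    for (r, c), sig, amp in truth.focus_truth:
        spots += amp * np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sig**2)))
    ch0 = truth.background_level + spots
    if truth.noise_sigma > 0:
        ch0 = ch0 + rng.normal(0.0, truth.noise_sigma, shape)
    noise1 = rng.normal(0.0, max(truth.noise_sigma, 1e-12), shape)
    if second_channel_corr is None:
        ch1 = truth.background_level + noise1
    else:
        rho = float(second_channel_corr)
        ch1 = truth.background_level + rho * (ch0 - truth.background_level) + math.sqrt(
            max(0.0, 1.0 - rho**2)
        ) * noise1
    return np.stack([ch0, ch1])


# ---------------------------------------------------------------------------
# droplet fields
# ---------------------------------------------------------------------------


@dataclass
class ShapeSpec:
    """A disk/ellipse/rectangle to rasterize into a droplet field."""

    kind: str  # "disk" | "ellipse" | "square"
    center: tuple[float, float]  # (row, col) px
    size: tuple[float, float]  # (r_radius, c_radius) px; square: half-sides
    rotation: float = 0.0  # radians, ellipses only


def render_droplet_field(
    shapes: list[ShapeSpec],
    shape: tuple[int, int] = (512, 512),
    background: float = 0.2,
    amplitude: float = 0.6,
    noise_sigma: float = 0.02,
    seed: int = 0,
    allow_overlap: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render bright shapes on a noisy background; truth table per shape.

    Truth records the rasterized pixel area and the major/minor axis ratio.
    Overlapping shapes are rejected unless `allow_overlap`.
    """
    from skimage.draw import disk as draw_disk
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(seed)
    img = np.full(shape, background, float)
    occupied = np.zeros(shape, bool)
    rows = []
    for i, sp in enumerate(shapes):
        if sp.kind == "disk":
            rr, cc = draw_disk(sp.center, sp.size[0], shape=shape)
            ratio = 1.0
        elif sp.kind == "ellipse":
            rr, cc = draw_ellipse(
                sp.center[0], sp.center[1], sp.size[0], sp.size[1], shape=shape, rotation=sp.rotation
            )
            ratio = max(sp.size) / min(sp.size)
        elif sp.kind == "square":
            r0 = int(round(sp.center[0] - sp.size[0]))
            r1 = int(round(sp.center[0] + sp.size[0]))
            c0 = int(round(sp.center[1] - sp.size[1]))
            c1 = int(round(sp.center[1] + sp.size[1]))
            rr, cc = np.mgrid[max(r0, 0) : min(r1, shape[0]), max(c0, 0) : min(c1, shape[1])]
            rr, cc = rr.ravel(), cc.ravel()
            ratio = max(sp.size) / min(sp.size)
        else:
            raise ValueError(f"unknown shape kind {sp.kind!r}")
        if not allow_overlap and occupied[rr, cc].any():
            raise ValueError(f"shape {i} overlaps a previously placed shape")
        occupied[rr, cc] = True
        img[rr, cc] = background + amplitude
        rows.append((i, sp.kind, len(rr), ratio))
    img = img + rng.normal(0.0, noise_sigma, shape)
    truth = pd.DataFrame(rows, columns=["shape_id", "kind", "area_px", "axis_ratio"])
    return img, truth


# ---------------------------------------------------------------------------
# rifampicin-chase counts
# ---------------------------------------------------------------------------


def simulate_decay_counts(
    config: DecaySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a (genes + ERCC) x samples count matrix with planted (a, b).

    Returns ``(counts, samples, truth)``:  `counts` is indexed by gene name
    (spike-ins prefixed ``ERCC-``), `samples` holds timepoint_min / replicate /
    library factor per column, `truth` the planted a (expected counts at t=0,
    unit library factor) and b (minutes) per gene.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, float)
    n_samples = t.size * config.n_replicates
    if config.library_size_factors is None:
        lib = rng.uniform(0.6, 1.6, size=n_samples)
    else:
        lib = np.asarray(config.library_size_factors, float)
        if lib.size != n_samples:
            raise ValueError("library_size_factors length must equal timepoints*replicates")
    a = rng.uniform(*config.a_range, size=config.n_genes)
    b = rng.uniform(*config.b_range, size=config.n_genes)

    sample_names, tp_col, rep_col = [], [], []
    for rep in range(config.n_replicates):
        for tp in t:
            sample_names.append(f"t{int(tp)}_rep{rep + 1}")
            tp_col.append(tp)
            rep_col.append(rep + 1)
    tp_arr = np.asarray(tp_col, float)

    if config.no_decay:
        expect_gene = a[:, None] * np.ones_like(tp_arr)[None, :]
    else:
        expect_gene = a[:, None] * np.exp(-tp_arr[None, :] / b[:, None])
    expect_gene = expect_gene * lib[None, :]
    ercc = np.asarray(config.ercc_abundances, float)
    expect_ercc = ercc[:, None] * lib[None, :]

    gene_counts = rng.poisson(expect_gene)
    ercc_counts = rng.poisson(expect_ercc)
    gene_names = [f"gene_{i:04d}" for i in range(config.n_genes)]
    ercc_names = [f"ERCC-{i:05d}" for i in range(ercc.size)]
    counts = pd.DataFrame(
        np.vstack([gene_counts, ercc_counts]), index=gene_names + ercc_names, columns=sample_names
    )
    samples = pd.DataFrame(
        {"sample": sample_names, "timepoint_min": tp_col, "replicate": rep_col, "lib_factor": lib}
    ).set_index("sample")
    truth = pd.DataFrame({"gene": gene_names, "a": a, "b": b}).set_index("gene")
    return counts, samples, truth


# ---------------------------------------------------------------------------
# poly(A) reads
# ---------------------------------------------------------------------------


def _zinb_sample(rng, mu: float, alpha: float, pi: float, size: int) -> np.ndarray:
    """Zero-inflated NB2 draw: var = mu + alpha*mu^2 for the NB component."""
    out = np.zeros(size, dtype=np.int64)
    active = rng.random(size) >= pi
    n_active = int(active.sum())
    if n_active and mu > 0:
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mu * alpha, size=n_active)
        out[active] = rng.poisson(lam)
    return out


def default_gene_annotation(config: PolyASimConfig) -> pd.DataFrame:
    """Evenly spaced genes on alternating strands (1-based inclusive coords)."""
    rows = []
    for i in range(config.n_genes):
        start = 10_000 + i * config.gene_spacing
        end = start + 1200 - 1
        strand = "+" if i % 2 == 0 else "-"
        rows.append((f"gene_{i:04d}", config.contig, start, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def simulate_polya_reads(
    config: PolyASimConfig, annotation: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate 3'-window reads with untemplated terminal-A runs.

    Every read is placed so its mapped interval lies inside the -50/+250
    window around its gene's 3' end (transcription direction) on the matching
    strand, and its stored sequence begins with a terminal 'T' run whose
    length is a ZINB draw from the gene/condition law (the sequencing-adapter
    orientation turns 3' A-tails into leading read Ts).

    Returns ``(reads, annotation, truth)``.  `reads` columns:
    read_id, gene_true, condition, replicate, contig, start, end (0-based
    half-open), strand, sequence, true_tail.
    """
    rng = np.random.default_rng(config.seed)
    if annotation is None:
        annotation = default_gene_annotation(config)
    n_cond = len(config.conditions)
    if config.condition_means is None:
        base = rng.uniform(3.0, 9.0, size=config.n_genes)
        means = np.tile(base[:, None], (1, n_cond))
    else:
        means = np.asarray(config.condition_means, float)
        if means.shape != (config.n_genes, n_cond):
            raise ValueError("condition_means must be (n_genes, n_conditions)")

    bases = np.array(list("ACG"))  # inner sequence avoids T so the run is unambiguous
    rows = []
    rid = 0
    for gi, g in enumerate(annotation.itertuples(index=False)):
        end3 = g.end if g.strand == "+" else g.start  # 1-based 3' end
        if g.strand == "+":
            win_lo, win_hi = end3 - 50, end3 + 250  # 1-based inclusive
        else:
            win_lo, win_hi = end3 - 250, end3 + 50
        if win_lo < 1 or win_hi > config.contig_length:
            raise ValueError(f"3' window of {g.gene_id} outside contig bounds")
        for ci, cond in enumerate(config.conditions):
            tails = _zinb_sample(
                rng, means[gi, ci], config.overdispersion, config.zero_inflation,
                config.reads_per_gene,
            )
            reps = rng.integers(1, config.n_replicates + 1, size=config.reads_per_gene)
            for tail, rep in zip(tails, reps):
                # uniform placement of the read interval inside the window
                span = min(config.read_length, win_hi - win_lo + 1)
                start1 = int(rng.integers(win_lo, win_hi - span + 2))  # 1-based
                inner = "".join(rng.choice(bases, size=max(span - int(tail), 0)))
                seq = "T" * int(tail) + inner
                rows.append(
                    (
                        f"read_{rid:07d}",
                        g.gene_id,
                        cond,
                        int(rep),
                        g.contig,
                        start1 - 1,  # 0-based half-open
                        start1 - 1 + span,
                        g.strand,
                        seq,
                        int(tail),
                    )
                )
                rid += 1
    reads = pd.DataFrame(
        rows,
        columns=[
            "read_id", "gene_true", "condition", "replicate",
            "contig", "start", "end", "strand", "sequence", "true_tail",
        ],
    )
    truth = pd.DataFrame(
        means, index=annotation["gene_id"], columns=list(config.conditions)
    )
    truth["zero_inflation"] = config.zero_inflation
    truth["overdispersion"] = config.overdispersion
    return reads, annotation, truth
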