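"""Rifampicin-chase transcript stability.

Spike-in normalization (total-count scaling, then rescaling of genomic
features by the median relative abundance of qualifying ERCC spike-ins),
per-gene exponential decay fits y = a*exp(-t/b) with the 'dogbox' optimizer,
non-negative bounds and (a, b) initialized to (0.001, 20), BH q-value /
R-squared fit filtering, the four-way genotype stability classification, and
the unpaired Wilcoxon rank-sum comparison of half-life distributions.

`b` is the exponential decay time constant tau in minutes; the measurable
window is 5-65 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecayFit",
    "normalize_counts",
    "fit_decay",
    "fit_all_genes",
    "filter_and_classify",
    "classify_stability",
    "compare_half_lives",
    "ERCC_PREFIX",
    "MEASURABLE_TAU",
]

ERCC_PREFIX = "ERCC-"
ERCC_MIN_REL_ABUNDANCE = 5e-4
MEASURABLE_TAU = (5.0, 65.0)  # minutes
STABLE_TAU = 65.0
UNSTABLE_TAU = 55.0
DIRECTIONAL_MARGIN = 10.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_counts(
    counts: pd.DataFrame, spikein_prefix: str = ERCC_PREFIX,
    min_spikein_abundance: float = ERCC_MIN_REL_ABUNDANCE,
) -> tuple[pd.DataFrame, pd.Series]:
    """ERCC-anchored per-cell abundance estimates.

    Per sample, every row is converted to a relative abundance (count /
    sample total); genomic rows are then divided by the median relative
    abundance of the spike-ins whose relative abundance exceeds
    `min_spikein_abundance`.  Returns the normalized genomic matrix and the
    per-sample spike-in factors.
    """
    is_spike = counts.index.str.startswith(spikein_prefix)
    if not is_spike.any():
        raise ValueError(f"no spike-in rows with prefix {spikein_prefix!r}")
    rel = counts / counts.sum(axis=0)
    factors = {}
    for s in counts.columns:
        spikes = rel.loc[is_spike, s]
        qual = spikes[spikes > min_spikein_abundance]
        if qual.empty:
            raise ValueError(f"sample {s!r}: no spike-in above relative abundance {min_spikein_abundance}")
        factors[s] = float(qual.median())
    factors = pd.Series(factors, name="ercc_median_rel_abundance")
    normalized = rel.loc[~is_spike].div(factors, axis=1)
    return normalized, factors


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    a: float
    b: float  # tau, minutes
    r_squared: float
    p_value: float  # for b, from its t-statistic (df = n - 2)
    converged: bool
    n_points: int
    b_se: float = float("nan")

    @property
    def measurable(self) -> bool:
        return MEASURABLE_TAU[0] <= self.b <= MEASURABLE_TAU[1]


def _decay_model(t, a, b):
    return a * np.exp(-t / np.maximum(b, 1e-12))


def fit_decay(times: np.ndarray, abundances: np.ndarray) -> DecayFit:
    """Fit y = a*exp(-t/b) to one gene's (t, abundance) observations.

    Replicates enter as separate observations (preserving degrees of freedom
    for the b t-statistic).  Bounded 'dogbox' least squares, both parameters
    non-negative, initialized at a=0.001, b=20.  The p-value for b comes from
    its estimate / standard-error t-statistic with df = n - 2.
    """
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    if t.size < 3:
        raise ValueError("at least 3 observations required")

    def _try(p0):
        try:
            popt, pcov = optimize.curve_fit(
                _decay_model, t, y, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                method="dogbox", maxfev=10000,
            )
            return popt, pcov, bool(np.isfinite(pcov).all())
        except RuntimeError:
            return None

    fit = _try([0.001, 20.0])
    # steep decays on an arbitrary abundance scale can trap the optimizer on
    # the b=0 boundary; restart from the observed t=0 level if that happens
    if fit is None or fit[0][1] < 1e-9:
        a0 = float(np.mean(y[t == t.min()])) if (t == t.min()).any() else float(y.mean())
        retry = _try([max(a0, 1e-12), 20.0])
        if retry is not None and fit is not None:
            resid_old = np.sum((y - _decay_model(t, *fit[0])) ** 2)
            resid_new = np.sum((y - _decay_model(t, *retry[0])) ** 2)
            fit = retry if resid_new < resid_old else fit
        elif retry is not None:
            fit = retry
    if fit is None:
        return DecayFit(float("nan"), float("nan"), float("nan"), float("nan"), False, t.size)
    popt, pcov, converged = fit
    a, b = popt
    resid = y - _decay_model(t, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    b_se = math.sqrt(pcov[1, 1]) if np.isfinite(pcov[1, 1]) else float("inf")
    df = t.size - 2
    if b_se > 0 and np.isfinite(b_se):
        tstat = b / b_se
        p = 2.0 * stats.t.sf(abs(tstat), df)
    else:
        p, converged = 1.0, False
    return DecayFit(float(a), float(b), r2, float(p), bool(converged), t.size, float(b_se))


def fit_all_genes(
    normalized: pd.DataFrame, samples: pd.DataFrame, timepoint_col: str = "timepoint_min"
) -> pd.DataFrame:
    """Per-gene decay fits over all samples; genes with all-zero counts skipped."""
    t = samples.loc[normalized.columns, timepoint_col].to_numpy(float)
    rows = []
    for gene, y in normalized.iterrows():
        yv = y.to_numpy(float)
        if not (yv > 0).any():
            continue
        f = fit_decay(t, yv)
        rows.append((gene, f.a, f.b, f.r_squared, f.p_value, f.converged, f.measurable))
    return pd.DataFrame(
        rows, columns=["gene", "a", "b", "r_squared", "p_value", "converged", "measurable"]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# filtering and classification
# ---------------------------------------------------------------------------


def classify_stability(tau_wt: float, tau_mut: float) -> str:
    """Four-way stability category from the two genotypes' decay constants.

    stable-vs-unstable: tau > 65 min in one genotype and < 55 min in the
    other; directional (WT>mut / mut>WT): both below 65 min and one larger by
    at least 10 min; anything else unclassified.
    """
    if tau_wt > STABLE_TAU and tau_mut < UNSTABLE_TAU:
        return "stable_vs_unstable_WT"
    if tau_mut > STABLE_TAU and tau_wt < UNSTABLE_TAU:
        return "stable_vs_unstable_mut"
    if tau_wt < STABLE_TAU and tau_mut < STABLE_TAU:
        if tau_wt - tau_mut >= DIRECTIONAL_MARGIN:
            return "WT_gt_mut"
        if tau_mut - tau_wt >= DIRECTIONAL_MARGIN:
            return "mut_gt_WT"
    return "unclassified"


def filter_and_classify(
    fits_wt: pd.DataFrame, fits_mut: pd.DataFrame,
    q_max: float = 0.1, r2_min: float = 0.5,
) -> pd.DataFrame:
    """BH-correct, filter (q < 0.1 and R² > 0.5 in both genotypes), classify.

    Returns a per-gene table with both taus, q-values, a `kept` flag and the
    stability category; genes fit in only one genotype are unclassified with
    the reason recorded.
    """
    out = {}
    for name, fits in (("WT", fits_wt), ("mut", fits_mut)):
        f = fits.copy()
        ok = f["converged"] & f["p_value"].notna()
        q = np.full(len(f), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(f.loc[ok, "p_value"], method="fdr_bh")[1]
        f["q_value"] = q
        out[name] = f
    genes = out["WT"].index.union(out["mut"].index)
    rows = []
    for g in genes:
        in_wt, in_mut = g in out["WT"].index, g in out["mut"].index
        if not (in_wt and in_mut):
            rows.append((g, np.nan, np.nan, np.nan, np.nan, False, "unclassified",
                         "present in one genotype only"))
            continue
        w, m = out["WT"].loc[g], out["mut"].loc[g]
        kept = (
            w["q_value"] < q_max and m["q_value"] < q_max
            and w["r_squared"] > r2_min and m["r_squared"] > r2_min
        )
        cat = classify_stability(w["b"], m["b"]) if kept else "unclassified"
        reason = "" if kept else "failed q/R2 filter"
        rows.append((g, w["b"], m["b"], w["q_value"], m["q_value"], bool(kept), cat, reason))
    return pd.DataFrame(
        rows,
        columns=["gene", "tau_WT", "tau_mut", "q_WT", "q_mut", "kept", "category", "reason"],
    ).set_index("gene")


def compare_half_lives(tau_wt: np.ndarray, tau_mut: np.ndarray) -> tuple[float, float]:
    """Median shift of mutant vs WT decay constants + Wilcoxon rank-sum p.

    shift = (median_mut - median_WT) / median_WT (so -0.14 is a 14% decrease
    in median half-life); the p-value is the two-sided unpaired Wilcoxon
    (Mann-Whitney) rank-sum test.  Also usable for comparing a gene subset's
    per-gene half-life changes against the complement.
    """
    w = np.asarray(tau_wt, float)
    m = np.asarray(tau_mut, float)
    if w.size < 3 or m.size < 3:
        raise ValueError("need at least 3 values per group")
    shift = (np.median(m) - np.median(w)) / np.median(w)
    if np.array_equal(np.sort(w), np.sort(m)):
        return float(shift), 1.0
    p = stats.mannwhitneyu(m, w, alternative="two-sided").pvalue
    return float(shift), float(p)
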