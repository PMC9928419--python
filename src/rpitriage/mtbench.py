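"""Scoring RNA:protein interactions in cells from high-content spot data.

A bait RNA-binding protein tethered to microtubules enriches endogenous mRNA
along filaments; in each well, elongated bait-rich spots are detected on the
bait (GFP) channel, and the per-spot mRNA enrichment (spot / cytoplasm
intensity ratio) regressed on bait intensity gives a slope that scores the
bait's mRNA affinity.  Slopes are normalised per plate (bait-free control →
0, DMSO-treated bait → 1), assay quality is summarised by the strictly
standardized mean difference (SSMD) of positive vs negative control wells,
compounds are called hits when they significantly decrease the normalised
slope relative to DMSO (paired t-test), and dose series are fitted with a
four-parameter logistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage import measure

SPOT_COLUMNS = ["well", "cell", "spot", "gfp_mean", "mrna_spot", "mrna_cyto",
                "width", "length"]

#: Spot-shape cutoff: keep only microtubule-shaped (elongated) components.
RATIO_MAX = 0.22

#: Bait-enrichment cutoff: spot GFP mean over cytoplasm GFP mean.
BAIT_ENRICHMENT_MIN = 2.0

#: Minimum usable spots per well for a slope fit.
MIN_SPOTS = 30


# ---------------------------------------------------------------------------
# Spot detection on synthetic two-channel images
# ---------------------------------------------------------------------------

def detect_spots(
    gfp_image: np.ndarray,
    mrna_image: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    k: float = 3.0,
    min_area: int = 4,
    well: str = "",
) -> pd.DataFrame:
    """Detect bait-rich spots and measure their shape and channel intensities.

    The bait channel is thresholded at background mean + ``k``·SD (background
    estimated by one sigma-clipping pass); connected components of at least
    ``min_area`` px become spots.  Length and width are 4·sqrt of the
    eigenvalues of the pixel-coordinate second-moment matrix (the axes of the
    equal-moment ellipse, with the 1/12 px² quantisation term).  Each spot
    records its bait mean, mRNA mean, and the image-wide cytoplasm means
    (non-spot, non-nucleus pixels) of both channels.
    """
    gfp = np.asarray(gfp_image, dtype=float)
    mrna = np.asarray(mrna_image, dtype=float)
    if gfp.shape != mrna.shape or gfp.ndim != 2:
        raise ValueError("images must be single-plane arrays of identical shape")
    if np.issubdtype(np.asarray(gfp_image).dtype, np.integer):
        sat = np.iinfo(np.asarray(gfp_image).dtype).max
        if (np.asarray(gfp_image) == sat).any():
            warnings.warn("bait channel contains saturated pixels", stacklevel=2)

    bg = gfp[gfp <= gfp.mean() + k * gfp.std()]
    thr = bg.mean() + k * bg.std()
    mask = gfp > thr
    if not mask.any():
        return pd.DataFrame(columns=SPOT_COLUMNS)

    labels = measure.label(mask, connectivity=2)
    nuc = np.zeros_like(mask) if nucleus_mask is None else nucleus_mask.astype(bool)
    cyto = (~mask) & (~nuc)
    cyto_mrna = float(mrna[cyto].mean()) if cyto.any() else np.nan
    cyto_gfp = float(gfp[cyto].mean()) if cyto.any() else np.nan

    rows = []
    for i, region in enumerate(measure.regionprops(labels)):
        if region.area < min_area:
            continue
        coords = region.coords.astype(float)
        cov = np.cov(coords.T, ddof=0) + np.eye(2) / 12.0
        lam = np.linalg.eigvalsh(cov)           # ascending
        width, length = 4.0 * np.sqrt(lam)
        sel = labels == region.label
        rows.append(dict(
            well=well, cell=0, spot=i,
            gfp_mean=float(gfp[sel].mean()),
            mrna_spot=float(mrna[sel].mean()),
            mrna_cyto=cyto_mrna,
            width=float(width), length=float(length),
            gfp_cyto=cyto_gfp,
        ))
    return pd.DataFrame(rows, columns=SPOT_COLUMNS + ["gfp_cyto"])


def filter_spots(
    spots: pd.DataFrame,
    ratio_max: float = RATIO_MAX,
    bait_enrichment_min: float = BAIT_ENRICHMENT_MIN,
) -> pd.DataFrame:
    """Keep microtubule-shaped, bait-enriched spots.

    Strict inequalities: width/length < ``ratio_max`` and, when a cytoplasm
    bait level is available (``gfp_cyto`` column), spot bait mean >
    ``bait_enrichment_min`` × cytoplasm bait mean.  Idempotent; output is a
    subset of the input rows.
    """
    if len(spots) == 0:
        return spots
    keep = (spots["width"] / spots["length"]) < ratio_max
    if "gfp_cyto" in spots.columns:
        with np.errstate(invalid="ignore"):
            keep &= spots["gfp_mean"] > bait_enrichment_min * spots["gfp_cyto"]
    return spots.loc[keep]


def enrichment(spots: pd.DataFrame) -> pd.Series:
    """Per-spot mRNA enrichment = spot mean / cytoplasm mean.

    Spots with non-positive cytoplasm signal are dropped with a warning.
    """
    bad = spots["mrna_cyto"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} spots with no cytoplasm signal",
                      stacklevel=2)
    ok = spots.loc[~bad]
    return ok["mrna_spot"] / ok["mrna_cyto"]


# ---------------------------------------------------------------------------
# Per-well slope and plate statistics
# ---------------------------------------------------------------------------

@dataclass
class SlopeFit:
    well: str
    slope: float
    intercept: float
    ci95_low: float
    ci95_high: float
    n_spots: int
    n_cells: int
    usable: bool = True
    note: str = ""


def well_slope(spots: pd.DataFrame, well: str = "", min_spots: int = MIN_SPOTS,
               ) -> SlopeFit:
    """OLS slope of mRNA enrichment on bait intensity across a well's spots.

    The 95% CI uses the t-distribution on the slope's standard error.  Wells
    with fewer than ``min_spots`` usable spots, or zero bait variance, are
    flagged unusable.
    """
    enr = enrichment(spots)
    x = spots.loc[enr.index, "gfp_mean"].to_numpy(float)
    y = enr.to_numpy(float)
    n = x.size
    n_cells = spots["cell"].nunique() if "cell" in spots.columns else 0
    if n < min_spots:
        return SlopeFit(well, np.nan, np.nan, np.nan, np.nan, n, n_cells,
                        usable=False, note=f"only {n} spots (<{min_spots})")
    if np.ptp(x) == 0:
        return SlopeFit(well, np.nan, np.nan, np.nan, np.nan, n, n_cells,
                        usable=False, note="zero bait variance")
    res = stats.linregress(x, y)
    half = stats.t.ppf(0.975, n - 2) * res.stderr
    return SlopeFit(well, float(res.slope), float(res.intercept),
                    float(res.slope - half), float(res.slope + half), n, n_cells)


def slopes_by_well(spots: pd.DataFrame, min_spots: int = MIN_SPOTS) -> pd.DataFrame:
    """Slope fits for every well in a spot table."""
    rows = []
    for wid, grp in spots.groupby("well", sort=False):
        f = well_slope(grp, well=str(wid), min_spots=min_spots)
        rows.append(vars(f))
    return pd.DataFrame(rows).set_index("well")


def normalize_plate(slopes: pd.Series, layout: pd.DataFrame) -> pd.Series:
    """Affine per-plate normalisation: bait-free mean → 0, DMSO-bait mean → 1.

    ``layout`` must give a role per well; roles 'negative' (bait-free GFP
    control) and 'dmso' (bait + vehicle) anchor the map.
    """
    roles = layout.set_index("well")["role"] if "well" in layout.columns else layout["role"]
    gfp_wells = roles.index[roles == "negative"].intersection(slopes.index)
    dmso_wells = roles.index[roles == "dmso"].intersection(slopes.index)
    if len(gfp_wells) == 0 or len(dmso_wells) == 0:
        raise ValueError("plate needs both bait-free ('negative') and 'dmso' wells")
    lo = slopes.loc[gfp_wells].mean()
    hi = slopes.loc[dmso_wells].mean()
    if hi == lo:
        raise ValueError("control means coincide; normalisation undefined")
    return (slopes - lo) / (hi - lo)


def ssmd(
    pos: Sequence[float], neg: Sequence[float],
    variant: Literal["sumvar", "pooled"] = "sumvar",
) -> float:
    """Strictly standardized mean difference between control groups.

    ``sumvar`` (default): (μ⁺−μ⁻)/sqrt(σ⁺²+σ⁻²); ``pooled`` divides by the
    pooled SD instead (√2 larger for equal group SDs).
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 wells per control group")
    vp, vn = pos.var(ddof=1), neg.var(ddof=1)
    if vp == 0 and vn == 0:
        raise ValueError("zero variance in both control groups; SSMD undefined")
    if variant == "sumvar":
        denom = np.sqrt(vp + vn)
    elif variant == "pooled":
        denom = np.sqrt(((pos.size - 1) * vp + (neg.size - 1) * vn)
                        / (pos.size + neg.size - 2))
    else:
        raise ValueError(f"unknown SSMD variant {variant!r}")
    return float((pos.mean() - neg.mean()) / denom)


def call_hits(
    norm_slopes: pd.Series, layout: pd.DataFrame, alpha: float = 0.05,
    correction: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Paired t-test of each compound's normalised slopes against DMSO.

    Wells are paired by replicate index within the plate.  A compound is a
    significant hit iff p < ``alpha`` and its mean normalised slope is below
    the DMSO mean (decreases only).  Optional Benjamini-Hochberg correction.
    """
    lay = layout.set_index("well") if "well" in layout.columns else layout
    lay = lay.loc[lay.index.intersection(norm_slopes.index)]
    dmso = lay[lay["role"] == "dmso"]
    if len(dmso) == 0:
        raise ValueError("no DMSO wells on plate")
    dmso_by_rep = norm_slopes.loc[dmso.index].groupby(dmso["replicate"]).mean()

    rows = []
    treated = lay[lay["role"] == "treated"]
    for comp, grp in treated.groupby("compound"):
        reps = grp["replicate"]
        t_vals = norm_slopes.loc[grp.index].to_numpy(float)
        d_vals = dmso_by_rep.reindex(reps).to_numpy(float)
        if np.isnan(d_vals).any():
            raise ValueError(f"compound {comp}: replicate without matching DMSO well")
        diffs = t_vals - d_vals
        if np.ptp(diffs) == 0:
            warnings.warn(f"compound {comp}: zero-variance paired differences",
                          stacklevel=2)
            p = 0.0 if diffs[0] != 0 else 1.0
        else:
            p = float(stats.ttest_rel(t_vals, d_vals).pvalue)
        rows.append(dict(compound=comp, mean_effect=float(t_vals.mean()),
                         dmso_mean=float(d_vals.mean()), p_value=p,
                         decrease=bool(t_vals.mean() < d_vals.mean())))
    out = pd.DataFrame(rows).set_index("compound")
    pv = out["p_value"].to_numpy()
    if correction == "bh":
        order = np.argsort(pv)
        m = len(pv)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order))[::-1]:
            prev = min(prev, pv[idx] * m / (rank + 1))
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = (out["p_adjusted"] < alpha) & out["decrease"]
    else:
        out["significant"] = (out["p_value"] < alpha) & out["decrease"]
    return out


@dataclass
class PlateStats:
    slopes: pd.DataFrame
    normalized_slopes: pd.Series
    ssmd: float
    hit_calls: pd.DataFrame


def score_plate(
    spots: pd.DataFrame, layout: pd.DataFrame,
    ratio_max: float = RATIO_MAX, min_spots: int = MIN_SPOTS,
    alpha: float = 0.05, prefiltered: bool = False,
) -> PlateStats:
    """Full plate pipeline: filter → slopes → normalise → SSMD → hit calls.

    SSMD compares positive (untreated bait) against negative (bait-free)
    control wells on the normalised scale; if the plate has no 'positive'
    wells the DMSO wells stand in (vehicle-treated bait).
    """
    if not prefiltered:
        spots = filter_spots(spots, ratio_max=ratio_max)
    slopes = slopes_by_well(spots, min_spots=min_spots)
    usable = slopes.loc[slopes["usable"], "slope"]
    norm = normalize_plate(usable, layout)
    lay = layout.set_index("well") if "well" in layout.columns else layout
    lay = lay.loc[lay.index.intersection(norm.index)]
    pos_wells = lay.index[lay["role"] == "positive"]
    if len(pos_wells) < 2:
        pos_wells = lay.index[lay["role"] == "dmso"]
    neg_wells = lay.index[lay["role"] == "negative"]
    plate_ssmd = ssmd(norm.loc[pos_wells], norm.loc[neg_wells])
    hits = call_hits(norm, layout, alpha=alpha)
    return PlateStats(slopes, norm, plate_ssmd, hits)


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    compound: str
    points: pd.DataFrame
    ec50: float
    hill: float
    top: float
    bottom: float
    fit_ok: bool
    note: str = ""


def _logistic4(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - log_ec50) * hill))


def fit_dose_response(
    points: pd.DataFrame, compound: str = "", min_range: float = 0.2,
) -> DoseResponse:
    """Four-parameter logistic fit of normalised slope vs log concentration.

    ``points`` needs columns conc_uM (>0) and response.  ``fit_ok`` is False
    when the response range is below ``min_range`` (flat curve) or the fitted
    EC50 falls outside the tested concentration range.
    """
    pts = points.sort_values("conc_uM")
    conc = pts["conc_uM"].to_numpy(float)
    resp = pts["response"].to_numpy(float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if conc.size < 5 or np.log10(conc.max() / conc.min()) < 1.5:
        raise ValueError("need ≥5 concentrations spanning ≥1.5 log units")
    logc = np.log10(conc)

    if np.ptp(resp) < min_range:
        return DoseResponse(compound, pts, np.nan, np.nan,
                            float(resp.max()), float(resp.min()),
                            fit_ok=False, note="flat response")
    # decreasing response expected for an inhibitor; warn on gross violation
    if resp[-1] > resp[0] + min_range:
        warnings.warn(f"{compound}: response increases with dose", stacklevel=2)

    p0 = [resp.min(), resp.max(), float(np.median(logc)), 1.0]
    try:
        popt, _ = optimize.curve_fit(_logistic4, logc, resp, p0=p0, maxfev=20000)
    except RuntimeError:
        return DoseResponse(compound, pts, np.nan, np.nan, np.nan, np.nan,
                            fit_ok=False, note="fit did not converge")
    bottom, top, log_ec50, hill = popt
    ec50 = float(10.0 ** log_ec50)
    ok = bool(conc.min() <= ec50 <= conc.max())
    return DoseResponse(compound, pts, ec50, float(hill), float(top),
                        float(bottom), fit_ok=ok,
                        note="" if ok else "EC50 outside tested range")
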