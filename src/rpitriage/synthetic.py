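"""Seeded generators emulating the statistical structure of every input stage.

Each generator draws from an independent, deterministically derived random
stream (the stage name is hashed into the seed sequence), returns the data in
the same containers the analysis functions consume, and returns the planted
ground truth alongside — so every estimator in the package can be exercised
as a generator → estimator round trip without any external data.

What is emulated, per stage:

* ``energy``   — Ornstein-Uhlenbeck fluctuations of the ligand-protein and
  ligand-water interaction enthalpies around planted means (per-frame noise
  SD in the 2-7 kcal/mol range typical of such traces).
* ``bar``      — Gaussian work distributions per λ window satisfying the
  Crooks fluctuation theorem: W_f ~ N(ΔF + σ²/2RT, σ²),
  W_r ~ N(−ΔF + σ²/2RT, σ²); 40 windows by default.
* ``csp``      — a ligand × residue CSP matrix (15 × 20 by default) built
  from cluster-mean rows plus Gaussian noise, with optional outlier rows.
* ``competition`` — per-residue (u, v, w) displacement triplets; competitive
  residues get w = αu + (1−α)v, additive ones w = u + v, plus noise.
* ``titration``  — 1:1 fast-exchange peak tables: fraction bound from the
  quadratic binding equation, observed shift linear in fraction bound.
* ``itc``      — single-site injection heats under the standard titration
  schedule with multiplicative noise.
* ``plate``    — per-well spot tables (optionally rendered as two-channel
  images of bars and disks) with a planted enrichment-vs-bait slope per role.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import rt
from .energetics import EnergyTrace
from .free_energy import ItcExperiment, WindowSamples, wiseman_heats
from .nmr import N_SCALE, ShiftTriplet


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Independent stream per (seed, stage); adding stages never perturbs others.

    The stage key uses a process-independent hash so outputs are
    bit-reproducible across sessions.
    """
    key = zlib.crc32(stage.encode("utf-8")) % 2**31
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed) % 2**31, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Energy traces
# ---------------------------------------------------------------------------

def gen_energy_trace(
    seed: int,
    n_frames: int = 5000,
    mean_lp: float = -30.0,
    mean_lw: float = -25.0,
    sd: float = 3.0,
    tau_frames: float = 5.0,
    dt_ns: float = 0.002,
    ligand_id: str = "synthetic",
) -> tuple[EnergyTrace, dict]:
    """OU-correlated energy trace with planted ΔΔH = mean_lp − mean_lw.

    Both energy terms follow independent Ornstein-Uhlenbeck processes with
    stationary SD ``sd``/√2 each (so the difference has SD ≈ ``sd``) and
    correlation time ``tau_frames`` frames.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if tau_frames <= 0:
        raise ValueError("correlation time must be positive")
    rng = _rng(seed, "energy")
    phi = np.exp(-1.0 / tau_frames)
    innov_sd = (sd / np.sqrt(2.0)) * np.sqrt(1 - phi**2)

    def ou(mean: float) -> np.ndarray:
        x = np.empty(n_frames)
        x[0] = rng.normal(0.0, sd / np.sqrt(2.0))
        eps = rng.normal(0.0, innov_sd, n_frames - 1)
        for i in range(1, n_frames):
            x[i] = phi * x[i - 1] + eps[i - 1]
        return mean + x

    t = np.arange(n_frames) * dt_ns
    trace = EnergyTrace(ligand_id, t, ou(mean_lp), ou(mean_lw))
    truth = {"ddH_mean": mean_lp - mean_lw, "ddH_sd": sd,
             "tau_frames": tau_frames}
    return trace, truth


# ---------------------------------------------------------------------------
# BAR windows
# ---------------------------------------------------------------------------

def gen_bar_windows(
    seed: int,
    n_windows: int = 40,
    n_samples: int = 5000,
    total_dg: float = -7.2,
    sigma: float = 0.5,
    temperature: float = 298.15,
) -> tuple[list[WindowSamples], dict]:
    """Per-window Gaussian work pairs satisfying the fluctuation theorem.

    The planted total ΔG is split equally over windows.  Forward work is
    N(ΔF_i + σ²/2RT, σ²) and reverse work N(−ΔF_i + σ²/2RT, σ²); samples are
    stored in the ΔU convention (``du_reverse`` = −reverse work).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _rng(seed, "bar")
    df_i = total_dg / n_windows
    bias = sigma**2 / (2.0 * rt(temperature))
    windows = []
    for i in range(n_windows):
        w_f = rng.normal(df_i + bias, sigma, n_samples)
        w_r = rng.normal(-df_i + bias, sigma, n_samples)
        windows.append(WindowSamples(i, w_f, -w_r, temperature))
    truth = {"total_dg": total_dg, "df_per_window": df_i, "sigma": sigma}
    return windows, truth


# ---------------------------------------------------------------------------
# CSP matrices
# ---------------------------------------------------------------------------

def gen_csp_matrix(
    seed: int,
    n_ligands: int = 15,
    n_residues: int = 20,
    n_clusters: int = 4,
    n_outliers: int = 1,
    effect: float = 0.04,
    noise: float = 0.004,
    outlier_scale: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Ligand × residue CSP matrix with planted ligand clusters and outliers.

    Each cluster has its own non-negative mean CSP profile (magnitude
    ``effect`` ppm, the scale of real pocket CSPs); outlier rows get an
    ``outlier_scale``-amplified idiosyncratic profile.  Values are clipped at
    zero (CSPs are magnitudes).
    """
    if n_clusters > n_ligands - n_outliers:
        raise ValueError("more clusters than non-outlier ligands")
    rng = _rng(seed, "csp")
    profiles = rng.uniform(0.0, 2 * effect, size=(n_clusters, n_residues))
    n_regular = n_ligands - n_outliers
    labels = np.sort(np.arange(n_regular) % n_clusters)
    rows = profiles[labels] + rng.normal(0, noise, (n_regular, n_residues))
    out_rows = (rng.uniform(0, 2 * effect * outlier_scale, (n_outliers, n_residues))
                + rng.normal(0, noise, (n_outliers, n_residues)))
    data = np.clip(np.vstack([rows, out_rows]), 0.0, None)
    ligands = [f"L{i+1}" for i in range(n_ligands)]
    residues = [f"R{j+1}" for j in range(n_residues)]
    matrix = pd.DataFrame(data, index=ligands, columns=residues)
    truth = {"labels": {ligands[i]: int(labels[i]) for i in range(n_regular)},
             "outliers": set(ligands[n_regular:])}
    return matrix, truth


# ---------------------------------------------------------------------------
# Competition triplets
# ---------------------------------------------------------------------------

def gen_competition_set(
    seed: int,
    n_residues: int = 40,
    frac_competitive: float = 0.5,
    alpha: float = 0.5,
    scale: float = 0.05,
    noise_frac: float = 0.0,
) -> tuple[list[ShiftTriplet], dict]:
    """Displacement triplets with planted competition/additivity regimes.

    Competitive residues: w = αu + (1−α)v with 0 < α < 1 (the ligand pulls
    the RNA-complex peak back between the two single-condition positions), so
    SP = −α(1−α)|u−v|² < 0.  Additive residues: w = u + v, so SP = u·v; the
    generator draws u, v with a positive dot product there (perturbations in
    compatible directions — the geometry additivity means) and keeps both
    |u−v|² and u·v above a margin so the planted sign survives small noise.
    Gaussian noise of SD ``noise_frac``·``scale`` is added to w.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    rng = _rng(seed, "competition")
    n_comp = int(round(frac_competitive * n_residues))
    margin = 0.5 * scale**2
    triplets, regimes = [], {}
    for i in range(n_residues):
        competitive = i < n_comp
        u = rng.normal(0, scale, 2)
        v = rng.normal(0, scale, 2)
        if competitive:
            while np.sum((u - v) ** 2) < margin:
                v = rng.normal(0, scale, 2)
            w = alpha * u + (1 - alpha) * v
        else:
            while float(np.dot(u, v)) < margin:
                u = rng.normal(0, scale, 2)
                v = rng.normal(0, scale, 2)
            w = u + v
        w = w + rng.normal(0, noise_frac * scale, 2)
        rid = f"R{i+1}"
        triplets.append(ShiftTriplet(rid, u, v, w))
        regimes[rid] = "competition" if competitive else "additive"
    return triplets, {"regimes": regimes, "alpha": alpha}


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

def gen_titration(
    seed: int,
    kd_uM: float = 6.0,
    protein_uM: float = 50.0,
    ligand_uM: Sequence[float] | None = None,
    n_residues: int = 10,
    max_shift_h: float = 0.05,
    max_shift_n: float = 0.4,
    noise_ppm: float = 0.0,
) -> tuple[list[pd.DataFrame], dict]:
    """1:1 fast-exchange titration peak tables over a ligand series.

    Fraction bound comes from the quadratic binding equation
    f = (P+L+Kd − sqrt((P+L+Kd)² − 4PL)) / 2P and the observed shift is
    δ_free + f·(δ_bound − δ_free), so every residue's trajectory is a straight
    line toward its bound position.  16 points, 10-1000 µM by default.
    """
    if kd_uM <= 0:
        raise ValueError("Kd must be positive")
    rng = _rng(seed, "titration")
    if ligand_uM is None:
        ligand_uM = np.geomspace(10.0, 1000.0, 16)
    ligand_uM = np.asarray(ligand_uM, float)

    residues = [f"R{i+1}" for i in range(n_residues)]
    free_h = rng.uniform(7.0, 9.5, n_residues)
    free_n = rng.uniform(105.0, 130.0, n_residues)
    dh_bound = rng.uniform(-max_shift_h, max_shift_h, n_residues)
    dn_bound = rng.uniform(-max_shift_n, max_shift_n, n_residues)

    p = protein_uM
    tables = [pd.DataFrame({"dH_ppm": free_h, "dN_ppm": free_n}, index=residues)]
    fracs = []
    for lig in ligand_uM:
        s = p + lig + kd_uM
        f = (s - np.sqrt(s**2 - 4 * p * lig)) / (2 * p)
        fracs.append(float(f))
        tables.append(pd.DataFrame({
            "dH_ppm": free_h + f * dh_bound + rng.normal(0, noise_ppm, n_residues),
            "dN_ppm": free_n + f * dn_bound
            + rng.normal(0, noise_ppm / N_SCALE, n_residues),
        }, index=residues))
    truth = {"kd_uM": kd_uM, "fraction_bound": np.array(fracs),
             "bound_dH": dh_bound, "bound_dN": dn_bound,
             "ligand_uM": ligand_uM}
    return tables, truth


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def gen_itc(
    seed: int,
    kd_uM: float = 6.0,
    dh_kcal: float = -10.0,
    n_sites: float = 1.0,
    cell_conc_uM: float = 14.0,
    syringe_conc_uM: float = 200.0,
    n_injections: int = 26,
    injection_uL: float = 1.5,
    cell_volume_mL: float = 0.2,
    noise_frac: float = 0.01,
) -> tuple[ItcExperiment, dict]:
    """Single-site injection heats under the standard schedule, with noise.

    Noise is Gaussian with SD = ``noise_frac`` × the largest |heat|.
    """
    rng = _rng(seed, "itc")
    vols = np.full(n_injections, injection_uL)
    heats = wiseman_heats(kd_uM, dh_kcal, n_sites, cell_conc_uM,
                          syringe_conc_uM, vols, cell_volume_mL)
    heats = heats + rng.normal(0, noise_frac * np.abs(heats).max(), heats.size)
    exp = ItcExperiment(cell_conc_uM, syringe_conc_uM, vols, heats,
                        cell_volume_mL)
    return exp, {"kd_uM": kd_uM, "dh_kcal": dh_kcal, "n_sites": n_sites}


# ---------------------------------------------------------------------------
# Plates (spot tables and optional images)
# ---------------------------------------------------------------------------

@dataclass
class PlateTruth:
    slopes: dict
    layout: pd.DataFrame
    intercept: float
    hit_compounds: set


def default_layout(
    n_dmso: int = 8, n_negative: int = 8, n_positive: int = 0,
    compounds: dict | None = None, n_replicates: int = 4,
) -> pd.DataFrame:
    """Plate layout table: DMSO/negative/positive controls plus treated wells.

    ``compounds`` maps compound name → concentration (µM); each gets
    ``n_replicates`` wells.
    """
    rows = []
    idx = 1
    for _ in range(n_dmso):
        rep = (idx - 1) % n_replicates + 1
        rows.append(("W%03d" % idx, "dmso", "DMSO", 0.0, rep)); idx += 1
    for _ in range(n_negative):
        rep = (idx - 1) % n_replicates + 1
        rows.append(("W%03d" % idx, "negative", "", 0.0, rep)); idx += 1
    for _ in range(n_positive):
        rep = (idx - 1) % n_replicates + 1
        rows.append(("W%03d" % idx, "positive", "", 0.0, rep)); idx += 1
    for comp, conc in (compounds or {}).items():
        for rep in range(1, n_replicates + 1):
            rows.append(("W%03d" % idx, "treated", comp, float(conc), rep)); idx += 1
    return pd.DataFrame(rows, columns=["well", "role", "compound", "conc_uM",
                                       "replicate"])


def gen_plate(
    seed: int,
    layout: pd.DataFrame | None = None,
    slope_dmso: float = 0.15,
    slope_negative: float = 0.0,
    compound_slope_factors: dict | None = None,
    intercept: float = 1.0,
    n_cells: int = 25,
    spots_per_cell: tuple[int, int] = (10, 50),
    bait_range: tuple[float, float] = (1.0, 10.0),
    noise: float = 0.15,
    well_slope_jitter: float = 0.006,
) -> tuple[pd.DataFrame, PlateTruth]:
    """Per-well spot tables with a planted enrichment-vs-bait slope per role.

    Each well draws 10-50 spots per cell; spot enrichment is
    intercept + slope·bait + N(0, noise), realised through mRNA spot/cyto
    intensities.  ``compound_slope_factors`` maps compound → multiplier on the
    DMSO slope (e.g. 0.5 for a planted inhibitor); unlisted compounds keep
    the DMSO slope.  Per-well slope jitter models well-to-well variability.
    """
    rng = _rng(seed, "plate")
    if layout is None:
        layout = default_layout(compounds={"CMP1": 10.0})
    factors = compound_slope_factors or {}
    needed = {"well", "role", "compound", "conc_uM", "replicate"}
    if not needed.issubset(layout.columns):
        raise ValueError(f"layout missing columns: {needed - set(layout.columns)}")

    cyto = 100.0
    frames = []
    well_truth = {}
    for _, wrow in layout.iterrows():
        role = wrow["role"]
        if role == "negative":
            base = slope_negative
        elif role in ("dmso", "positive"):
            base = slope_dmso
        elif role == "treated":
            base = slope_dmso * factors.get(wrow["compound"], 1.0)
        else:
            raise ValueError(f"unknown role {role!r} in layout")
        slope = base + rng.normal(0, well_slope_jitter)
        well_truth[wrow["well"]] = slope
        per_cell = rng.integers(spots_per_cell[0], spots_per_cell[1] + 1, n_cells)
        n_sp = int(per_cell.sum())
        bait = rng.uniform(*bait_range, n_sp)
        enr = intercept + slope * bait + rng.normal(0, noise, n_sp)
        length = rng.uniform(15, 30, n_sp)
        width = rng.uniform(0.08, 0.20, n_sp) * length
        frames.append(pd.DataFrame({
            "well": wrow["well"],
            "cell": np.repeat(np.arange(n_cells), per_cell),
            "spot": np.arange(n_sp),
            "gfp_mean": bait,
            "mrna_spot": np.clip(enr, 0.0, None) * cyto,
            "mrna_cyto": cyto,
            "width": width, "length": length,
        }))
    spots = pd.concat(frames, ignore_index=True)
    hits = {c for c, f in factors.items() if f < 1.0}
    return spots, PlateTruth(well_truth, layout, intercept, hits)


def gen_control_plate(
    seed: int,
    beta: float = 8.0,
    n_pos: int = 48,
    n_neg: int = 48,
    slope_pos: float = 0.15,
    n_cells: int = 25,
    noise: float = 0.15,
) -> tuple[pd.DataFrame, PlateTruth]:
    """48+48 control plate with a planted well-level standardized difference.

    Positive (bait) wells get slope ``slope_pos``, negative (bait-free) wells
    slope 0; the per-well slope jitter is set so the true SSMD of the two
    well populations is ``beta``: σ = slope_pos / (β·√2) per group.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    jitter = slope_pos / (beta * np.sqrt(2.0))
    layout = default_layout(n_dmso=0, n_negative=n_neg, n_positive=n_pos)
    spots, truth = gen_plate(
        seed, layout=layout, slope_dmso=slope_pos, slope_negative=0.0,
        n_cells=n_cells, noise=noise, well_slope_jitter=jitter)
    return spots, truth


# --- image rendering ------------------------------------------------------

def render_well_image(
    seed: int,
    n_bars: int = 60,
    shape: tuple[int, int] = (160, 160),
    slope: float = 0.15,
    intercept: float = 1.0,
    bait_range: tuple[float, float] = (40.0, 200.0),
    bar_len: tuple[int, int] = (14, 24),
    bar_wid: int = 2,
    background: float = 10.0,
    cyto_mrna: float = 50.0,
    noise: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a bait/mRNA image pair of elongated bars on a flat background.

    Bars (microtubule-shaped spots) carry a bait intensity drawn uniformly
    and an mRNA intensity cyto·(intercept + slope·bait/100 + noise); the
    planted per-well enrichment slope is returned in the truth dict (bait in
    image counts, enrichment per 100 counts to keep numbers O(1)).
    """
    rng = _rng(seed, "image")
    gfp = rng.normal(background, noise, shape).clip(0)
    mrna = rng.normal(cyto_mrna, noise, shape).clip(0)
    h, w = shape
    placed = 0
    truth_bait, truth_enr = [], []
    attempts = 0
    occupied = np.zeros(shape, bool)
    while placed < n_bars and attempts < n_bars * 30:
        attempts += 1
        L = int(rng.integers(bar_len[0], bar_len[1] + 1))
        horizontal = bool(rng.integers(0, 2))
        bh, bw = (bar_wid, L) if horizontal else (L, bar_wid)
        r = int(rng.integers(1, h - bh - 1))
        c = int(rng.integers(1, w - bw - 1))
        sl = (slice(r, r + bh), slice(c, c + bw))
        if occupied[max(r - 2, 0):r + bh + 2, max(c - 2, 0):c + bw + 2].any():
            continue
        bait = float(rng.uniform(*bait_range))
        enr = intercept + slope * bait / 100.0 + float(rng.normal(0, 0.02))
        gfp[sl] = bait + rng.normal(0, noise, (bh, bw))
        mrna[sl] = cyto_mrna * enr + rng.normal(0, noise, (bh, bw))
        occupied[sl] = True
        truth_bait.append(bait)
        truth_enr.append(enr)
        placed += 1
    truth = {"n_bars": placed, "bait": np.array(truth_bait),
             "enrichment": np.array(truth_enr),
             "slope_per_count": slope / 100.0, "intercept": intercept}
    return gfp, mrna, truth


def gen_image_plate(
    seed: int,
    layout: pd.DataFrame,
    slope_dmso: float = 0.15,
    slope_negative: float = 0.0,
    compound_slope_factors: dict | None = None,
    n_bars: int = 60,
    shape: tuple[int, int] = (160, 160),
) -> tuple[dict, PlateTruth]:
    """Image pairs for every well of a layout, with planted per-role slopes.

    Returns {well: (gfp_image, mrna_image)} plus the planted truth.  Slopes
    here are per bait count; the detector/regression pipeline should recover
    the planted ordering and the hit set.
    """
    factors = compound_slope_factors or {}
    images = {}
    well_truth = {}
    base_rng = _rng(seed, "image-plate")
    for _, wrow in layout.iterrows():
        role = wrow["role"]
        if role == "negative":
            s = slope_negative
        elif role in ("dmso", "positive"):
            s = slope_dmso
        elif role == "treated":
            s = slope_dmso * factors.get(wrow["compound"], 1.0)
        else:
            raise ValueError(f"unknown role {role!r}")
        sub = int(base_rng.integers(0, 2**31 - 1))
        gfp, mrna, t = render_well_image(sub, n_bars=n_bars, shape=shape, slope=s)
        images[wrow["well"]] = (gfp, mrna)
        well_truth[wrow["well"]] = t["slope_per_count"]
    hits = {c for c, f in factors.items() if f < 1.0}
    return images, PlateTruth(well_truth, layout, 1.0, hits)
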