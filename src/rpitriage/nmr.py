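"""Chemical-shift analytics for ligand screening against an RNA-binding domain.

Inputs are assigned ¹H-¹⁵N peak lists (one table per condition).  The module
computes weighted chemical shift perturbations (CSPs), pocket averages and
binder calls; mines a ligand × residue CSP matrix by PCA with SPE/Hotelling-T²
outlier tests and k-means clustering; classifies per-residue RNA-competition
regimes from the scalar product of pair displacement vectors; and computes
saturation-transfer-difference (STD) quantities for ligand epitope mapping.

Conventions: the ¹⁵N axis is scaled by 0.14 everywhere, matching the CSP
weighting; the default CSP form is Δδ = sqrt(0.5·[ΔδH² + (0.14·ΔδN)²]), with
the no-square-root variant available as ``form="literal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: ¹⁵N scaling factor relative to ¹H in combined shift space.
N_SCALE = 0.14

#: Pocket residues carrying the flavonoid/quercetin-site signal.
POCKET_RESIDUES = ("W65", "V84", "F85", "V86", "G116", "K118", "G119", "A120")


def read_peaks(path: str | Path, condition_id: str | None = None) -> pd.DataFrame:
    """Read a peak list CSV (residue,dH_ppm,dN_ppm) indexed by residue."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    df = df.rename(columns={cols["residue"]: "residue",
                            cols["dh_ppm"]: "dH_ppm", cols["dn_ppm"]: "dN_ppm"})
    if df["residue"].duplicated().any():
        dups = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residues in {path}: {dups}")
    out = df.set_index("residue")[["dH_ppm", "dN_ppm"]].astype(float)
    out.attrs["condition_id"] = condition_id or Path(path).stem
    return out


def csp(
    ref: pd.DataFrame,
    bound: pd.DataFrame,
    nscale: float = N_SCALE,
    form: Literal["sqrt", "literal"] = "sqrt",
) -> pd.Series:
    """Per-residue weighted CSP between a reference and a bound condition.

    ``sqrt`` form (default): Δδ = sqrt(0.5·[ΔδH² + (nscale·ΔδN)²]);
    ``literal`` form: 0.5·[ΔδH² + (nscale·ΔδN)²] without the square root.
    Residues absent from either table are reported in a warning, never
    silently dropped.
    """
    shared = ref.index.intersection(bound.index)
    if len(shared) == 0:
        raise ValueError("peak tables share no residues")
    missing = ref.index.symmetric_difference(bound.index)
    if len(missing):
        warnings.warn(f"residues present in only one condition: {list(missing)}",
                      stacklevel=2)
    d_h = bound.loc[shared, "dH_ppm"] - ref.loc[shared, "dH_ppm"]
    d_n = bound.loc[shared, "dN_ppm"] - ref.loc[shared, "dN_ppm"]
    val = 0.5 * (d_h**2 + (nscale * d_n) ** 2)
    if form == "sqrt":
        val = np.sqrt(val)
    elif form != "literal":
        raise ValueError(f"unknown CSP form {form!r}")
    return pd.Series(val, index=shared, name="csp")


def pocket_average(csp_values: pd.Series, pocket: Sequence[str] = POCKET_RESIDUES,
                   ) -> float:
    """Arithmetic mean CSP over the pocket residues."""
    pocket = list(pocket)
    if not pocket:
        raise ValueError("pocket set is empty")
    missing = [r for r in pocket if r not in csp_values.index]
    if missing:
        raise KeyError(f"pocket residues missing from CSP table: {missing}")
    return float(csp_values.loc[pocket].mean())


def binding_call(
    csp_values: pd.Series,
    pocket: Sequence[str] = POCKET_RESIDUES,
    n_sd: float = 1.0,
) -> tuple[str, dict]:
    """Call a ligand binder if the pocket-average CSP clears background.

    Default policy: binder when pocket mean > mean + ``n_sd``·SD of the
    non-pocket residues — the same-spectrum background sets the significance
    reference; the threshold multiplier is configurable.
    """
    pocket = [r for r in pocket if r in csp_values.index]
    non_pocket = csp_values.drop(pocket)
    if len(non_pocket) < 3:
        raise ValueError("need at least 3 non-pocket residues to set a background")
    pm = pocket_average(csp_values, pocket)
    cutoff = float(non_pocket.mean() + n_sd * non_pocket.std(ddof=1))
    call = "binder" if pm > cutoff and pm > 0 else "non-binder"
    return call, {"pocket_mean": pm, "cutoff": cutoff,
                  "background_mean": float(non_pocket.mean()),
                  "background_sd": float(non_pocket.std(ddof=1))}


# ---------------------------------------------------------------------------
# PCA mining of the ligand × residue CSP matrix
# ---------------------------------------------------------------------------

@dataclass
class PcaReport:
    variance_ratios: np.ndarray
    cumulative_ratio: float
    loadings: pd.DataFrame        # components × features
    scores: pd.DataFrame          # samples × components
    spe: pd.Series
    t2: pd.Series
    spe_limit: float
    t2_limit: float
    outliers: set = field(default_factory=set)
    clusters: dict = field(default_factory=dict)
    top_features: list = field(default_factory=list)


def _spe_limit_jackson_mudholkar(residual_eigs: np.ndarray, alpha: float) -> float:
    """(1−alpha) SPE control limit from the residual-space eigenvalues."""
    ev = residual_eigs[residual_eigs > 1e-12]
    if ev.size == 0:
        return 0.0
    th1, th2, th3 = ev.sum(), (ev**2).sum(), (ev**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-3
    ca = stats.norm.ppf(1 - alpha)
    inner = (ca * np.sqrt(2 * th2 * h0**2) / th1
             + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2)
    return float(th1 * np.sign(inner) * np.abs(inner) ** (1.0 / h0))


def pca_mine(
    matrix: pd.DataFrame,
    transpose: bool = False,
    n_components: int = 6,
    alpha: float = 0.05,
    k_clusters: int = 5,
    scale: bool = False,
    seed: int = 0,
) -> PcaReport:
    """Mine a CSP matrix by PCA with outlier tests and score clustering.

    Columns are mean-centered (variance scaling optional; CSPs share units).
    Per-sample SPE (squared residual off the retained subspace) and
    Hotelling's T² (Mahalanobis distance within it) are tested against their
    (1−alpha) control limits: Jackson-Mudholkar for SPE and the Phase-I
    beta form of the T² limit, (n−1)²/n · B(1−alpha; k/2, (n−k−1)/2) — the
    version appropriate when the tested samples are the ones the model was
    built from (the Phase-II F form exceeds the attainable maximum
    (n−1)²/n at these sample sizes and can never flag anything).  Samples
    exceeding either limit are flagged as outliers.  Scores are clustered
    with k-means (50 restarts, fixed seed).
    """
    X = matrix.T if transpose else matrix
    if X.isna().any().any():
        raise ValueError("matrix has missing cells; impute before mining")
    labels = list(X.index)
    n, p = X.shape
    max_k = min(n - 1, p)
    if n_components > max_k:
        warnings.warn(f"n_components clipped from {n_components} to {max_k}",
                      stacklevel=2)
        n_components = max_k

    data = X.to_numpy(float)
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1) if scale else np.ones(p)
    sd[sd == 0] = 1.0
    Z = (data - mu) / sd

    if np.allclose(Z, 0.0):
        # identical rows: nothing to decompose, nothing to flag
        k = n_components
        zero_s = pd.Series(np.zeros(n), index=labels)
        return PcaReport(
            variance_ratios=np.zeros(k), cumulative_ratio=0.0,
            loadings=pd.DataFrame(np.zeros((k, p)), columns=list(X.columns),
                                  index=[f"PC{j+1}" for j in range(k)]),
            scores=pd.DataFrame(np.zeros((n, k)), index=labels,
                                columns=[f"PC{j+1}" for j in range(k)]),
            spe=zero_s.rename("SPE"), t2=zero_s.rename("T2"),
            spe_limit=0.0, t2_limit=np.inf, outliers=set(),
            clusters={lab: 0 for lab in labels},
            top_features=[list(X.columns)[0]] * k,
        )

    pca = PCA(n_components=max_k, svd_solver="full")
    all_scores = pca.fit_transform(Z)
    eigs = pca.explained_variance_               # sample covariance eigenvalues
    ratios = pca.explained_variance_ratio_

    k = n_components
    scores_k = all_scores[:, :k]
    resid = Z - scores_k @ pca.components_[:k]
    spe = (resid**2).sum(axis=1)
    lam = np.where(eigs[:k] > 1e-12, eigs[:k], np.inf)
    t2 = ((scores_k**2) / lam).sum(axis=1)

    spe_lim = _spe_limit_jackson_mudholkar(eigs[k:], alpha)
    if n > k + 1:
        t2_lim = ((n - 1) ** 2 / n
                  * stats.beta.ppf(1 - alpha, k / 2.0, (n - k - 1) / 2.0))
    else:
        t2_lim = np.inf

    out = {labels[i] for i in range(n)
           if t2[i] > t2_lim or (spe_lim > 0 and spe[i] > spe_lim)}

    km = KMeans(n_clusters=min(k_clusters, n), n_init=50, random_state=seed)
    cl = km.fit_predict(scores_k)
    clusters = {labels[i]: int(cl[i]) for i in range(n)}

    feat = list(X.columns)
    top = [feat[int(np.argmax(np.abs(pca.components_[j])))] for j in range(k)]

    return PcaReport(
        variance_ratios=ratios[:k],
        cumulative_ratio=float(ratios[:k].sum()),
        loadings=pd.DataFrame(pca.components_[:k], columns=feat,
                              index=[f"PC{j+1}" for j in range(k)]),
        scores=pd.DataFrame(scores_k, index=labels,
                            columns=[f"PC{j+1}" for j in range(k)]),
        spe=pd.Series(spe, index=labels, name="SPE"),
        t2=pd.Series(t2, index=labels, name="T2"),
        spe_limit=spe_lim, t2_limit=float(t2_lim),
        outliers=out, clusters=clusters, top_features=top,
    )


# ---------------------------------------------------------------------------
# RNA-competition scalar product
# ---------------------------------------------------------------------------

@dataclass
class ShiftTriplet:
    """Displacements from apo in scaled (¹H, 0.14·¹⁵N) ppm coordinates.

    u: ligand-only, v: RNA-only, w: RNA+ligand.
    """

    residue_id: str
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        self.w = np.asarray(self.w, float)
        for vec in (self.u, self.v, self.w):
            if vec.shape != (2,) or not np.all(np.isfinite(vec)):
                raise ValueError("u, v, w must be finite 2-vectors")


def competition_sp(triplet: ShiftTriplet, eps: float = 1e-6) -> tuple[float, str]:
    """SP = (v − w)·(u − w) and its regime.

    A residue whose RNA+ligand peak sits opposite the ligand-only and RNA-only
    displacements has SP < 0 (the ligand pulls the peak back: competition);
    SP > 0 means the two perturbations add.  |SP| ≤ eps is indeterminate.
    """
    sp = float(np.dot(triplet.v - triplet.w, triplet.u - triplet.w))
    if sp < -eps:
        regime = "competition"
    elif sp > eps:
        regime = "additive"
    else:
        regime = "indeterminate"
    return sp, regime


def triplets_from_conditions(
    apo: pd.DataFrame, ligand: pd.DataFrame, rna: pd.DataFrame, both: pd.DataFrame,
    nscale: float = N_SCALE,
) -> tuple[list[ShiftTriplet], list[str]]:
    """Build per-residue (u, v, w) triplets from four condition peak tables.

    Residues missing from any condition are skipped and reported.
    """
    shared = apo.index
    for t in (ligand, rna, both):
        shared = shared.intersection(t.index)
    skipped = sorted(set(apo.index) - set(shared))
    if skipped:
        warnings.warn(f"residues skipped (missing conditions): {skipped}",
                      stacklevel=2)

    def disp(table: pd.DataFrame, res: str) -> np.ndarray:
        return np.array([
            table.at[res, "dH_ppm"] - apo.at[res, "dH_ppm"],
            nscale * (table.at[res, "dN_ppm"] - apo.at[res, "dN_ppm"]),
        ])

    trip = [ShiftTriplet(r, disp(ligand, r), disp(rna, r), disp(both, r))
            for r in shared]
    return trip, skipped


# ---------------------------------------------------------------------------
# STD quantities
# ---------------------------------------------------------------------------

def std_quantities(
    records: pd.DataFrame, L_total_uM: float, E_total_uM: float
) -> pd.DataFrame:
    """Fractional STD, amplification factor and relative percentages per proton.

    A_STD = (I_off − I_on)/I_off;  STD_AF = A_STD·[L]_T/[E]_T;
    rel_percent = 100·A_STD/max(A_STD).  Input needs columns
    proton,I_on,I_off.  All-zero A_STD leaves rel_percent undefined (flagged).
    """
    if L_total_uM <= 0 or E_total_uM <= 0:
        raise ValueError("concentrations must be positive")
    df = records.copy()
    cols = {c.lower(): c for c in df.columns}
    df = df.rename(columns={cols["proton"]: "proton",
                            cols["i_on"]: "I_on", cols["i_off"]: "I_off"})
    if (df["I_off"] <= 0).any():
        raise ValueError("I_off must be positive for every proton")
    df["A_STD"] = (df["I_off"] - df["I_on"]) / df["I_off"]
    df["STD_AF"] = df["A_STD"] * (L_total_uM / E_total_uM)
    amax = df["A_STD"].max()
    if amax <= 0:
        warnings.warn("all A_STD are zero; relative percentages undefined",
                      stacklevel=2)
        df["rel_percent"] = np.nan
    else:
        df["rel_percent"] = 100.0 * df["A_STD"] / amax
    return df[["proton", "I_on", "I_off", "A_STD", "STD_AF", "rel_percent"]]


# ---------------------------------------------------------------------------
# Titration linearity
# ---------------------------------------------------------------------------

def titration_linearity(
    series: Sequence[pd.DataFrame],
    nscale: float = N_SCALE,
    r2_threshold: float = 0.98,
    min_displacement: float = 0.005,
) -> pd.DataFrame:
    """Straight-line test of per-residue titration trajectories.

    For each residue the (ΔδH, nscale·ΔδN) points across the titration are
    fitted by total least squares (first principal axis); R² is the fraction
    of in-plane variance the axis explains.  A straight path (R² above the
    threshold) indicates a single fast-exchange binding mode; curvature
    indicates multi-site behaviour.  Residues moving less than
    ``min_displacement`` (scaled ppm) are 'not-shifting'.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 titration points")
    ref = series[0]
    shared = ref.index
    for t in series[1:]:
        shared = shared.intersection(t.index)
    rows = []
    for res in shared:
        pts = np.array([
            [t.at[res, "dH_ppm"] - ref.at[res, "dH_ppm"],
             nscale * (t.at[res, "dN_ppm"] - ref.at[res, "dN_ppm"])]
            for t in series])
        span = float(np.linalg.norm(pts.max(0) - pts.min(0)))
        if span < min_displacement:
            rows.append((res, np.nan, span, "not-shifting"))
            continue
        centered = pts - pts.mean(0)
        ev = np.linalg.eigvalsh(centered.T @ centered)[::-1]
        r2 = float(ev[0] / ev.sum()) if ev.sum() > 0 else np.nan
        verdict = "single-mode" if r2 >= r2_threshold else "multi-mode"
        rows.append((res, r2, span, verdict))
    return pd.DataFrame(rows, columns=["residue", "r2", "span", "verdict"]
                        ).set_index("residue")
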