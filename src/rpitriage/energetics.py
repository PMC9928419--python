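"""Statistical-mechanics filter for MD-refined ligand poses.

A ligand bound in a surface pocket is scored from two trajectory-derived
observables:

* ``ΔΔH = H_LP − H_LW``, the per-frame difference between ligand-protein and
  ligand-water interaction enthalpies.  A negative time average means the
  ligand prefers the pocket over the solvent; the fluctuation (sample SD)
  carries the statistical error of that preference.
* ``c``, the mean number of unique interatomic ligand-pocket contacts per
  interacting ligand atom, counted on a single MD-refined structure.

The weighted score ``S = w_c·c + w_ΔΔH·<ΔΔH>`` (defaults ``w_c = 4``,
``w_ΔΔH = −1``) is positive for ligands expected to reside in the pocket.
Ligands with non-positive S are retained as "possible" when the statistical
error on ΔΔH could flip the sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import kj_to_kcal

Classification = Literal["hit", "possible", "rejected", "left_pocket"]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the two filter observables; defaults follow the published filter."""

    w_c: float = 4.0
    w_ddH: float = -1.0


@dataclass
class EnergyTrace:
    """Per-frame ligand-protein and ligand-water interaction energies.

    Energies are stored in kcal/mol; traces tagged ``kJ/mol`` are converted
    on construction.
    """

    ligand_id: str
    time_ns: np.ndarray
    h_lp: np.ndarray
    h_lw: np.ndarray
    unit_tag: str = "kcal/mol"

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.h_lp = np.asarray(self.h_lp, dtype=float)
        self.h_lw = np.asarray(self.h_lw, dtype=float)
        if self.time_ns.size < 2:
            raise ValueError("energy trace needs at least 2 frames")
        if not (self.time_ns.size == self.h_lp.size == self.h_lw.size):
            raise ValueError("time and energy columns differ in length")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("frame times must be strictly increasing")
        tag = self.unit_tag.lower().replace(" ", "")
        if tag in ("kj/mol", "kj"):
            self.h_lp = kj_to_kcal(self.h_lp)
            self.h_lw = kj_to_kcal(self.h_lw)
            self.unit_tag = "kcal/mol"
        elif tag in ("kcal/mol", "kcal"):
            self.unit_tag = "kcal/mol"
        else:
            raise ValueError(f"unknown energy unit tag {self.unit_tag!r}")

    @property
    def n_frames(self) -> int:
        return int(self.time_ns.size)


@dataclass
class ContactSet:
    """Unique ligand-pocket interatomic contacts on one refined structure."""

    ligand_id: str
    contacts: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.contacts = frozenset(tuple(p) for p in self.contacts)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def ligand_atoms_in_contact(self) -> int:
        return len({la for la, _ in self.contacts})


@dataclass
class FilterScore:
    """Filter observables, weighted score and hit classification for one ligand."""

    ligand_id: str
    ddH_mean: float
    ddH_sd: float
    c: float
    S: float
    classification: Classification


def delta_delta_H(trace: EnergyTrace) -> tuple[float, float]:
    """Time average and sample SD of the per-frame ΔΔH = H_LP − H_LW.

    Returns (mean, sd) in kcal/mol.  The SD is the n−1 sample standard
    deviation of the per-frame values; no autocorrelation correction is
    applied (frames are treated as the filter's nominal sample).
    """
    ddh = trace.h_lp - trace.h_lw
    return float(np.mean(ddh)), float(np.std(ddh, ddof=1))


def contact_ratio(contacts: ContactSet) -> float:
    """Unique contacts per interacting ligand atom, c = |contacts| / n_atoms.

    An empty contact set flags an effectively unbound ligand and returns 0.0
    with a warning rather than raising.
    """
    n_atoms = contacts.ligand_atoms_in_contact
    if n_atoms == 0:
        warnings.warn(
            f"ligand {contacts.ligand_id}: empty contact set, c set to 0 (unbound)",
            stacklevel=2,
        )
        return 0.0
    return contacts.n_contacts / n_atoms


def score_and_classify(
    ddH: tuple[float, float],
    c: float,
    weights: ScoreWeights = ScoreWeights(),
    stayed_in_pocket: bool = True,
    ligand_id: str = "",
    possible_policy: Literal["error_adjusted", "sigma_exceeds_mean"] = "error_adjusted",
) -> FilterScore:
    """Compute S = w_c·c + w_ΔΔH·<ΔΔH> and classify the ligand.

    Classification:

    * ``left_pocket`` — the ligand failed the short-MD retention check.
    * ``hit`` — S > 0.
    * ``possible`` — S ≤ 0 but within statistical error of positive.  With the
      default ``error_adjusted`` policy that is S + σ_ΔΔH > 0; the alternative
      ``sigma_exceeds_mean`` policy retains ligands whose σ exceeds |<ΔΔH>|.
    * ``rejected`` — otherwise.
    """
    mean, sd = ddH
    for name, v in (("ddH mean", mean), ("ddH sd", sd), ("c", c)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if sd < 0:
        raise ValueError("ddH sd must be non-negative")
    s = weights.w_c * c + weights.w_ddH * mean
    if not stayed_in_pocket:
        cls: Classification = "left_pocket"
    elif s > 0:
        cls = "hit"
    else:
        if possible_policy == "error_adjusted":
            borderline = s + sd > 0
        elif possible_policy == "sigma_exceeds_mean":
            borderline = sd > abs(mean)
        else:
            raise ValueError(f"unknown possible_policy {possible_policy!r}")
        cls = "possible" if borderline else "rejected"
    return FilterScore(ligand_id, mean, sd, c, s, cls)


# ---------------------------------------------------------------------------
# File readers (tables exported by any MD engine)
# ---------------------------------------------------------------------------

def read_energy_trace(path: str | Path, ligand_id: str | None = None) -> EnergyTrace:
    """Read a trace from CSV with columns time,H_LP,H_LW[,unit].

    The optional ``unit`` column must be constant ('kcal/mol' or 'kJ/mol').
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        t = df[cols["time"]].to_numpy()
        lp = df[cols["h_lp"]].to_numpy()
        lw = df[cols["h_lw"]].to_numpy()
    except KeyError as e:
        raise ValueError(f"missing column in {path}: {e}") from e
    unit = "kcal/mol"
    if "unit" in cols:
        units = df[cols["unit"]].unique()
        if len(units) != 1:
            raise ValueError(f"mixed units in {path}: {units}")
        unit = str(units[0])
    return EnergyTrace(ligand_id or Path(path).stem, t, lp, lw, unit)


def read_energy_terms(
    lp_path: str | Path, lw_path: str | Path,
    ligand_id: str = "", unit: str = "kcal/mol",
) -> EnergyTrace:
    """Read H_LP and H_LW from two whitespace (time, energy) files on a shared grid."""
    lp = np.loadtxt(lp_path)
    lw = np.loadtxt(lw_path)
    if lp.shape != lw.shape:
        raise ValueError("H_LP and H_LW files differ in shape")
    if not np.allclose(lp[:, 0], lw[:, 0]):
        raise ValueError("H_LP and H_LW time grids differ")
    return EnergyTrace(ligand_id, lp[:, 0], lp[:, 1], lw[:, 1], unit)


def read_contacts(path: str | Path, ligand_id: str | None = None) -> ContactSet:
    """Read a contact list from CSV with columns ligand_atom,protein_atom."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        pairs = zip(df[cols["ligand_atom"]], df[cols["protein_atom"]])
    except KeyError as e:
        raise ValueError(f"missing column in {path}: {e}") from e
    return ContactSet(ligand_id or Path(path).stem, frozenset(pairs))


def score_table(
    traces: Iterable[EnergyTrace],
    contact_sets: Iterable[ContactSet],
    weights: ScoreWeights = ScoreWeights(),
    stayed: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Score a batch of ligands; returns one row per ligand."""
    by_id = {c.ligand_id: c for c in contact_sets}
    rows = []
    for tr in traces:
        if tr.ligand_id not in by_id:
            raise ValueError(f"no contact set for ligand {tr.ligand_id}")
        fs = score_and_classify(
            delta_delta_H(tr),
            contact_ratio(by_id[tr.ligand_id]),
            weights=weights,
            stayed_in_pocket=True if stayed is None else stayed.get(tr.ligand_id, True),
            ligand_id=tr.ligand_id,
        )
        rows.append(
            dict(ligand=fs.ligand_id, ddH_mean=fs.ddH_mean, ddH_sd=fs.ddH_sd,
                 c=fs.c, S=fs.S, classification=fs.classification)
        )
    return pd.DataFrame(rows)
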