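"""Residue-resolved NMR analysis of membrane-bound alpha-synuclein.

Covers the three profile types used to map membrane interactions of an
intrinsically disordered protein:

* averaged amide chemical-shift deviation between two states,
  ``sqrt(0.5 * (dH^2 + dN^2 / 25))`` — the nitrogen difference is
  down-weighted by its larger shift dispersion (the factor 25 is fixed);
* secondary carbon shifts, measured minus sequence- and temperature-
  corrected random-coil reference (positive CA values indicate helix);
* lipid/free peak-intensity ratios — a vesicle-bound residue is broadened
  beyond detection, so the ratio measures the unbound fraction at each
  residue — with a logistic fit to locate a binding boundary.

Also includes re-referencing of the carbon dimension of a mutant dataset
against the wild type by zeroing the signed mean difference over a
C-terminal window (residues 111-130 by default, outside the membrane-
binding domain).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ResidueTableError
from .types import CARBON_COLUMNS, RandomCoilTable, ResidueProfile, ResidueTable

__all__ = [
    "amide_csd",
    "secondary_shift",
    "rereference_carbon",
    "intensity_ratio_profile",
    "fit_binding_boundary",
    "region_summary",
    "load_random_coil_table",
    "BoundaryFit",
    "DEFAULT_CSD_RANGE",
    "DEFAULT_REREF_WINDOW",
    "DEFAULT_REGIONS",
]

# The C-terminal tail does not contact the micelle, so deviation profiles
# default to the N-terminal 102 residues.
DEFAULT_CSD_RANGE = (1, 102)
DEFAULT_REREF_WINDOW = (111, 130)
# Helix boundaries of the broken-helix (micelle-bound) state; configurable
# conventions, not measured constants.
DEFAULT_REGIONS: Dict[str, Tuple[int, int]] = {
    "helix-1": (3, 37),
    "helix-2": (45, 92),
    "C-terminal": (103, 140),
}

_N_WEIGHT = 25.0  # fixed down-weighting of the nitrogen shift difference


def load_random_coil_table() -> RandomCoilTable:
    """Load the packaged random-coil CA/CB reference table."""
    with resources.files("synquant.data").joinpath("random_coil_ca_cb.csv").open() as fh:
        values = pd.read_csv(fh, comment="#")
    return RandomCoilTable(values)


def _merge(mut: ResidueTable, wt: ResidueTable, columns,
           suffixes: tuple = ("_mut", "_wt")) -> pd.DataFrame:
    m = mut.indexed().reindex(columns=list(columns))
    w = wt.indexed().reindex(columns=list(columns))
    merged = m.join(w, how="inner", lsuffix=suffixes[0], rsuffix=suffixes[1])
    if merged.empty:
        raise ResidueTableError("tables share no residues")
    return merged


def amide_csd(mut: ResidueTable, wt: ResidueTable,
              residue_range: Optional[tuple] = DEFAULT_CSD_RANGE) -> ResidueProfile:
    """Averaged amide chemical-shift deviation of ``mut`` from ``wt``.

    Residues missing an amide entry in either table (prolines,
    unassigned) are skipped, never zero-filled.
    """
    merged = _merge(mut, wt, ("H", "N"))
    if residue_range is not None:
        lo, hi = residue_range
        merged = merged.loc[(merged.index >= lo) & (merged.index <= hi)]
    merged = merged.dropna()
    if merged.empty:
        raise ResidueTableError("no residues with amide shifts in both tables")
    d_h = merged["H_mut"] - merged["H_wt"]
    d_n = merged["N_mut"] - merged["N_wt"]
    csd = np.sqrt(0.5 * (d_h ** 2 + d_n ** 2 / _N_WEIGHT))
    return ResidueProfile(residues=merged.index.to_numpy(), values=csd.to_numpy(),
                          quantity="amide_csd", units="ppm")


def secondary_shift(table: ResidueTable, rc: Optional[RandomCoilTable] = None,
                    temperature: float = 298.0, nucleus: str = "CA") -> ResidueProfile:
    """Secondary carbon shift: measured minus corrected random-coil value.

    Corrections applied to the random-coil reference are the per-residue
    neighbor terms (if the table carries a ``neighbor_corr_{nucleus}``
    column) and the linear temperature term from the reference table.
    """
    if nucleus not in CARBON_COLUMNS:
        raise ValueError("nucleus must be 'CA' or 'CB'")
    if rc is None:
        rc = load_random_coil_table()
    data = table.data
    if nucleus not in data.columns or not data[nucleus].notna().any():
        raise ResidueTableError(f"no {nucleus} shifts present")
    corr_col = f"neighbor_corr_{nucleus}"
    residues, values = [], []
    for _, row in data.iterrows():
        measured = row.get(nucleus, np.nan)
        if pd.isna(measured):
            continue
        neighbor = float(row[corr_col]) if corr_col in data.columns and pd.notna(row.get(corr_col)) else 0.0
        reference = rc.shift(row["aa"], nucleus, temperature=temperature,
                             neighbor_correction=neighbor)
        residues.append(int(row["residue"]))
        values.append(float(measured) - reference)
    return ResidueProfile(residues=np.array(residues), values=np.array(values),
                          quantity=f"secondary_{nucleus}", units="ppm")


def rereference_carbon(mut: ResidueTable, wt: ResidueTable,
                       window: tuple = DEFAULT_REREF_WINDOW,
                       min_residues: int = 5) -> tuple:
    """Re-reference the carbon dimension of ``mut`` against ``wt``.

    The offset is the signed mean of (wt - mut) over all carbon shifts in
    the window; adding it to every carbon column of ``mut`` zeroes the mean
    difference there (to rounding).  Amide columns are untouched.
    Returns (offset_ppm, corrected_table).
    """
    merged = _merge(mut, wt, CARBON_COLUMNS)
    lo, hi = window
    merged = merged.loc[(merged.index >= lo) & (merged.index <= hi)]
    diffs = []
    n_residues_used = 0
    for _, row in merged.iterrows():
        used = False
        for col in CARBON_COLUMNS:
            m, w = row[f"{col}_mut"], row[f"{col}_wt"]
            if pd.notna(m) and pd.notna(w):
                diffs.append(w - m)
                used = True
        n_residues_used += used
    if n_residues_used < min_residues:
        raise ResidueTableError(
            f"only {n_residues_used} carbon-bearing residues in window {window}; "
            f"need >= {min_residues}")
    offset = float(np.mean(diffs))
    corrected = mut.copy()
    for col in CARBON_COLUMNS:
        if col in corrected.data.columns:
            corrected.data[col] = corrected.data[col] + offset
    return offset, corrected


def intensity_ratio_profile(lipid: ResidueTable, free: ResidueTable,
                            floor: float = 0.0) -> ResidueProfile:
    """Per-residue lipid/free peak-intensity ratio (unbound fraction).

    Residues whose lipid-free intensity is at or below ``floor`` are
    excluded and listed on the profile; ratios above 1.1 are flagged
    (bound samples should not gain intensity).
    """
    merged = _merge(lipid, free, ("intensity",), suffixes=("_lipid", "_free"))
    merged = merged.dropna()
    usable = merged[merged["intensity_free"] > floor]
    excluded = tuple(int(r) for r in merged.index.difference(usable.index))
    if usable.empty:
        raise ResidueTableError("all residues excluded by the intensity floor")
    ratio = usable["intensity_lipid"] / usable["intensity_free"]
    flagged = tuple(int(r) for r in usable.index[ratio > 1.1])
    return ResidueProfile(residues=usable.index.to_numpy(), values=ratio.to_numpy(),
                          quantity="intensity_ratio", units="",
                          excluded_residues=excluded, flagged_residues=flagged)


@dataclass
class BoundaryFit:
    """Logistic fit of a binding-boundary intensity-ratio profile."""

    midpoint: float
    bound_level: float
    unbound_level: float
    width: float


def fit_binding_boundary(profile: ResidueProfile) -> BoundaryFit:
    """Fit r(i) = b + (u - b) / (1 + exp(-(i - m) / w)) to an intensity-
    ratio profile and return the transition midpoint m (the residue where
    membrane binding is lost)."""
    x = profile.residues.astype(float)
    y = profile.values
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ResidueTableError("too few residues to fit a binding boundary")

    def logistic(i, b, u, m, w):
        return b + (u - b) / (1.0 + np.exp(-(i - m) / w))

    lo, hi = float(np.min(y)), float(np.max(y))
    p0 = (lo, hi, float(np.median(x)), 2.0)
    bounds = ([-0.5, -0.5, x.min(), 0.1], [1.5, 1.5, x.max(), 50.0])
    params, _ = curve_fit(logistic, x, y, p0=p0, bounds=bounds, maxfev=20000)
    b, u, m, w = (float(v) for v in params)
    return BoundaryFit(midpoint=m, bound_level=b, unbound_level=u, width=w)


def region_summary(profile: ResidueProfile,
                   regions: Optional[Dict[str, tuple]] = None) -> pd.DataFrame:
    """Mean and SD of a profile over named residue ranges.

    Returns a DataFrame indexed by region name with columns start, stop,
    n, mean, sd; raises when a region holds no residues after missing-
    value removal.
    """
    if regions is None:
        regions = DEFAULT_REGIONS
    series = profile.as_series().dropna()
    rows = []
    for name, (lo, hi) in regions.items():
        vals = series[(series.index >= lo) & (series.index <= hi)]
        if vals.empty:
            raise ResidueTableError(f"region {name!r} ({lo}-{hi}) holds no residues")
        rows.append({"region": name, "start": lo, "stop": hi, "n": len(vals),
                     "mean": float(vals.mean()), "sd": float(vals.std(ddof=0))})
    return pd.DataFrame(rows).set_index("region")
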