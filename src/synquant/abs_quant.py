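"""Densitometry to absolute intracellular protein concentration.

The chain: normalize each blot lane by its nonspecific-band loading
control, fit a linear calibration of band density vs known standard
concentration, interpolate unknown lysate concentrations, convert to a
per-cell amount via loaded volume and cell equivalents, and finally to a
volumetric cellular concentration (ug/ml and uM) using the mean cell
volume and the sequence-derived molecular mass.

Sequence-derived constants: average-mass molecular weight (sum of residue
masses minus peptide-bond waters) and the 280 nm extinction coefficient
(5500 per Trp + 1490 per Tyr + 125 per cystine; cystines default to 0 for
a reduced protein — for human alpha-synuclein, 0 Trp and 4 Tyr give
exactly 5960 per M per cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, SequenceError
from .types import CalibrationFit, DensitometryTable, ProteinSequence

__all__ = [
    "ASYN_HUMAN",
    "normalize_loading",
    "fit_calibration",
    "interpolate_concentration",
    "per_cell_amount",
    "cellular_concentration",
    "molecular_weight",
    "extinction_coefficient",
    "CellularConcentration",
    "DEFAULT_CELL_VOLUME_UM3",
]

# Mean cell volume (um^3) from 3-D confocal reconstruction of 50 cells.
DEFAULT_CELL_VOLUME_UM3 = 2627.0

WATER_MASS = 18.01528  # Da, lost per peptide bond

# Average (isotope-abundance-weighted) free amino-acid masses, Da.
AA_MASS = {
    "G": 75.0669, "A": 89.0932, "S": 105.0926, "P": 115.1305, "V": 117.1463,
    "T": 119.1192, "C": 121.1582, "L": 131.1729, "I": 131.1729, "N": 132.1179,
    "D": 133.1027, "Q": 146.1445, "K": 146.1876, "E": 147.1293, "M": 149.2113,
    "H": 155.1546, "F": 165.1891, "R": 174.2010, "Y": 181.1885, "W": 204.2252,
}

EPS_TRP = 5500.0   # M^-1 cm^-1 at 280 nm
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0


def _load_asyn() -> ProteinSequence:
    with resources.files("synquant.data").joinpath("asyn_human.fasta").open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    seq = "".join(ln for ln in lines if not ln.startswith(">"))
    return ProteinSequence(seq, name="alpha-synuclein (human)")


ASYN_HUMAN = _load_asyn()


def normalize_loading(table: DensitometryTable) -> tuple:
    """Correct lane-to-lane loading via the three nonspecific bands.

    Each lane's band density is scaled by (grand mean of lane loading
    means) / (this lane's loading mean).  Returns (corrected table,
    factors) where ``factors`` maps lane id to the applied divisor; a
    divisor off by more than 25% from 1 is flagged with a warning.
    """
    data = table.data.copy()
    loads = data[list(DensitometryTable.LOADING_COLS)].to_numpy(dtype=float)
    if (loads <= 0).any():
        raise CalibrationError("every lane needs three positive loading densities")
    lane_means = loads.mean(axis=1)
    reference = lane_means.mean()
    factors = lane_means / reference
    for lane, f in zip(data["lane"], factors):
        if abs(f - 1.0) > 0.25:
            warnings.warn(f"lane {lane} loading correction factor {f:.3f} "
                          "deviates from 1 by more than 25%", stacklevel=2)
    data["band_density"] = data["band_density"] / factors
    return DensitometryTable(data), dict(zip(data["lane"], factors))


def fit_calibration(standards: pd.DataFrame, through_origin: bool = False) -> CalibrationFit:
    """Ordinary least-squares line of band density vs standard
    concentration (free intercept by default; blots commonly carry a
    nonzero background offset)."""
    conc = standards["known_conc"].to_numpy(dtype=float)
    dens = standards["band_density"].to_numpy(dtype=float)
    if len(conc) < 3 or len(np.unique(conc)) < 3:
        raise CalibrationError("need at least three distinct standard concentrations")
    if through_origin:
        slope = float(np.dot(conc, dens) / np.dot(conc, conc))
        intercept = 0.0
        pred = slope * conc
        ss_res = float(((dens - pred) ** 2).sum())
        ss_tot = float(((dens - dens.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(conc, dens)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue ** 2)
    return CalibrationFit(slope=slope, intercept=intercept, r_squared=r2,
                          conc_range=(float(conc.min()), float(conc.max())))


def interpolate_concentration(fit: CalibrationFit, band_density: float) -> float:
    """Concentration (ug/ml) for a band density on the calibration line.

    Densities mapping outside the fitted standard range are flagged as
    extrapolation; negative concentrations are floored at 0 with a flag.
    """
    conc = (band_density - fit.intercept) / fit.slope
    lo, hi = fit.conc_range
    if not lo <= conc <= hi:
        warnings.warn(f"density {band_density:.4g} maps to {conc:.4g} ug/ml, "
                      f"outside the standard range [{lo}, {hi}] (extrapolation)",
                      stacklevel=2)
    if conc < 0:
        warnings.warn("negative interpolated concentration floored at 0", stacklevel=2)
        conc = 0.0
    return float(conc)


def per_cell_amount(lysate_conc: float, loaded_volume: float,
                    cell_equivalents: float) -> float:
    """Protein per cell (pg) from lysate concentration (ug/ml), loaded
    volume (ml) and the number of cell equivalents in the lane."""
    if loaded_volume <= 0:
        raise ValueError("loaded volume must be positive")
    if cell_equivalents <= 0:
        raise ValueError("cell equivalents must be positive")
    amount_ug = lysate_conc * loaded_volume
    return float(amount_ug * 1e6 / cell_equivalents)  # ug -> pg


@dataclass
class CellularConcentration:
    """Volumetric cellular concentration in mass and molar units."""

    mass_ug_per_ml: float
    molar_uM: float
    molar_uM_rounded: int
    molecular_weight_da: float


def cellular_concentration(amount: float, cell_volume: float = DEFAULT_CELL_VOLUME_UM3,
                           sequence: ProteinSequence = ASYN_HUMAN) -> CellularConcentration:
    """Convert a per-cell amount (pg) to cellular concentration.

    1 pg/um^3 is exactly 1 g/ml, so mass concentration (ug/ml) is
    ``amount / cell_volume * 1e6``; the molar value divides by the
    sequence-derived molecular weight.  A nearest-integer uM convenience
    field is included because reported values are typically rounded.
    """
    if cell_volume <= 0:
        raise ValueError("cell volume must be positive")
    mw = molecular_weight(sequence)
    mass_ug_ml = amount / cell_volume * 1e6
    molar_um = mass_ug_ml / mw * 1e3  # (mg/L) / (g/mol) -> umol/L
    return CellularConcentration(mass_ug_per_ml=float(mass_ug_ml),
                                 molar_uM=float(molar_um),
                                 molar_uM_rounded=int(round(molar_um)),
                                 molecular_weight_da=mw)


def molecular_weight(sequence: ProteinSequence) -> float:
    """Average molecular weight (Da): residue masses minus (n-1) waters."""
    seq = sequence.sequence
    try:
        total = sum(AA_MASS[aa] for aa in seq)
    except KeyError as exc:  # ProteinSequence already validates; belt and braces
        raise SequenceError(f"unknown residue {exc.args[0]!r}") from exc
    return float(total - (len(seq) - 1) * WATER_MASS)


def extinction_coefficient(sequence: ProteinSequence, n_cystine: int = 0) -> float:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    Computed from aromatic content: 5500 per Trp, 1490 per Tyr, 125 per
    cystine (disulfide-bonded pair; 0 for a reduced protein).  A protein
    with no chromophores gets 0 and a warning, since A280 quantification
    is then impossible.
    """
    eps = EPS_TRP * sequence.count("W") + EPS_TYR * sequence.count("Y") \
        + EPS_CYSTINE * n_cystine
    if eps == 0:
        warnings.warn("sequence has no Trp, Tyr or cystine; A280 "
                      "quantification is impossible", stacklevel=2)
    return float(eps)
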