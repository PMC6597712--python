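"""Core data containers shared across the synquant modules.

The containers are deliberately thin: time courses are a pair of numpy
arrays with epoch annotations, images are numpy arrays plus a boolean cell
mask and a physical pixel size, and tabular data (residue tables,
densitometry tables, event lists) are pandas DataFrames wrapped with just
enough validation to catch unit and numbering mistakes early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidAnnotationError, SequenceError

__all__ = [
    "TimeSeriesTrace",
    "ExoResult",
    "TirfMovie",
    "EventList",
    "MaskedImagePair",
    "ShellResult",
    "ResidueTable",
    "RandomCoilTable",
    "ResidueProfile",
    "DensitometryTable",
    "CalibrationFit",
    "ProteinSequence",
    "QuenchCurve",
]

RESIDUE_COLUMNS = ("H", "N", "CA", "CB", "intensity")
CARBON_COLUMNS = ("CA", "CB")


@dataclass
class TimeSeriesTrace:
    """A fluorescence time course with optional epoch annotations.

    times are seconds (strictly increasing), values are arbitrary
    fluorescence units.  ``t_stim`` marks stimulant addition, ``t_nh4cl``
    the NH4Cl dequench, ``t_baf`` an optional bafilomycin pre-treatment.
    """

    times: np.ndarray
    values: np.ndarray
    t_stim: Optional[float] = None
    t_nh4cl: Optional[float] = None
    t_baf: Optional[float] = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidAnnotationError("times and values must be matching 1-D arrays")
        if self.times.size < 2:
            raise InvalidAnnotationError("a trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidAnnotationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidAnnotationError("trace values must be finite")
        if self.t_stim is not None and self.t_nh4cl is not None:
            if not self.t_stim < self.t_nh4cl:
                raise InvalidAnnotationError("t_stim must precede t_nh4cl")

    def window(self, start: float, stop: float) -> np.ndarray:
        """Values with start <= t < stop."""
        sel = (self.times >= start) & (self.times < stop)
        return self.values[sel]

    def with_values(self, values: np.ndarray) -> "TimeSeriesTrace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class ExoResult:
    """Outcome of the percent-exocytosis computation on one trace."""

    pct_exocytosis: float
    basal_mean: float
    stim_mean: float
    nh4cl_mean: float
    basal_window: tuple
    stim_window: tuple
    nh4cl_window: tuple
    clipped_negative: bool = False
    exceeds_100: bool = False


@dataclass
class TirfMovie:
    """A TIRF frame stack: frames[t, row, col], frame interval in s,
    pixel size in nm."""

    frames: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a (t, row, col) stack with >= 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame interval and pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class EventList:
    """Detected (or injected) exocytic flash events.

    ``events`` is a DataFrame with columns t (s), frame, row, col (px),
    amplitude (a.u.); ``params`` snapshots the detection settings.
    """

    events: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"t", "frame", "row", "col", "amplitude"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"event table must have columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class MaskedImagePair:
    """Two-channel still image plus a cell mask.

    Channels are nonnegative background-subtracted intensities; negatives
    produced by subtraction are clipped to zero and flagged.
    """

    channel_r: np.ndarray
    channel_g: np.ndarray
    cell_mask: np.ndarray
    pixel_size: float = 100.0
    clipped_negative: bool = False

    def __post_init__(self) -> None:
        self.channel_r = np.asarray(self.channel_r, dtype=float)
        self.channel_g = np.asarray(self.channel_g, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if not (self.channel_r.shape == self.channel_g.shape == self.cell_mask.shape):
            raise ValueError("channels and mask must share one 2-D shape")
        if self.channel_r.ndim != 2:
            raise ValueError("images must be 2-D")
        if not self.cell_mask.any():
            raise ValueError("cell mask is empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        for name in ("channel_r", "channel_g"):
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"{name} contains non-finite values")
            if (ch < 0).any():
                setattr(self, name, np.clip(ch, 0, None))
                self.clipped_negative = True

    def channel(self, which: str) -> np.ndarray:
        which = which.upper()
        if which == "R":
            return self.channel_r
        if which == "G":
            return self.channel_g
        raise ValueError("channel must be 'R' or 'G'")


@dataclass
class ShellResult:
    """Membrane-proximal intensity fraction for one image."""

    shell_fraction: float
    shell_width_nm: float
    shell_pixel_count: int
    mask_pixel_count: int
    shell_is_whole_mask: bool = False


class ResidueTable:
    """Per-residue NMR quantities aligned to a 1-based protein sequence.

    Wraps a DataFrame with columns ``residue`` (1-based int), ``aa``
    (one-letter code) and any subset of H, N (amide shifts, ppm), CA, CB
    (carbon shifts, ppm), intensity (a.u.).  Missing values are NaN and
    propagate as absent, never as zero.  Prolines carry no amide entries.
    """

    PHYSICAL_RANGES = {"H": (5.0, 12.0), "N": (100.0, 140.0), "CA": (10.0, 80.0), "CB": (10.0, 80.0)}

    def __init__(self, data: pd.DataFrame, check_ranges: bool = True):
        data = data.copy()
        if "residue" not in data.columns or "aa" not in data.columns:
            raise ValueError("residue table needs 'residue' and 'aa' columns")
        data["residue"] = data["residue"].astype(int)
        if data["residue"].duplicated().any():
            raise ValueError("residue numbers must be unique")
        if (data["residue"] < 1).any():
            raise ValueError("residue numbering is 1-based")
        data = data.sort_values("residue").reset_index(drop=True)
        self.data = data
        self.flagged_out_of_range: list = []
        if check_ranges:
            for col, (lo, hi) in self.PHYSICAL_RANGES.items():
                if col in data.columns:
                    vals = data[col]
                    bad = data.loc[vals.notna() & ((vals < lo) | (vals > hi)), "residue"]
                    self.flagged_out_of_range.extend((col, int(r)) for r in bad)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    @property
    def sequence(self) -> str:
        return "".join(self.data["aa"])

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            return pd.Series(np.nan, index=self.data.index)
        return self.data[name]

    def has_column(self, name: str) -> bool:
        return name in self.data.columns and self.data[name].notna().any()

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("residue")

    def copy(self) -> "ResidueTable":
        return ResidueTable(self.data.copy(), check_ranges=False)


class RandomCoilTable:
    """Random-coil CA/CB reference shifts per amino acid.

    ``values`` maps one-letter code -> {CA, CB} in ppm (CB is NaN for
    glycine).  Optional per-residue neighbor corrections and temperature
    coefficients (ppm/K, relative to ``t_ref`` K) default to zero.
    """

    def __init__(self, values: pd.DataFrame, t_ref: float = 298.0):
        values = values.copy()
        if "aa" not in values.columns:
            raise ValueError("random-coil table needs an 'aa' column")
        for col in ("CA", "CB"):
            if col not in values.columns:
                raise ValueError(f"random-coil table needs a '{col}' column")
        for col in ("dCA_dT", "dCB_dT"):
            if col not in values.columns:
                values[col] = 0.0
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(values["aa"])
        if missing:
            raise ValueError(f"random-coil table is missing residues: {sorted(missing)}")
        self.values = values.set_index("aa")
        self.t_ref = t_ref

    def shift(self, aa: str, nucleus: str, temperature: float = 298.0,
              neighbor_correction: float = 0.0) -> float:
        if aa not in self.values.index:
            from .errors import ResidueTableError
            raise ResidueTableError(f"residue type {aa!r} absent from random-coil table")
        base = float(self.values.loc[aa, nucleus])
        slope = float(self.values.loc[aa, f"d{nucleus}_dT"])
        return base + neighbor_correction + slope * (temperature - self.t_ref)


@dataclass
class ResidueProfile:
    """A per-residue scalar profile (CSD, secondary shift, or intensity
    ratio) with provenance metadata."""

    residues: np.ndarray
    values: np.ndarray
    quantity: str
    units: str = ""
    excluded_residues: tuple = ()
    flagged_residues: tuple = ()

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residues.shape != self.values.shape:
            raise ValueError("residues and values must align")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.residues, name=self.quantity)

    def argmax_residue(self) -> int:
        return int(self.residues[int(np.nanargmax(self.values))])


class DensitometryTable:
    """Blot lane densities: standards plus unknowns.

    Columns: lane (id), role ('standard' or 'unknown'), band_density (a.u.,
    gel background already subtracted), loading_1..loading_3 (nonspecific
    band densities, the loading control), known_conc (ug/ml, standards
    only), cell_equivalents (count per lane, unknowns), loaded_volume_ml.
    """

    LOADING_COLS = ("loading_1", "loading_2", "loading_3")

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        required = {"lane", "role", "band_density"}
        if not required.issubset(data.columns):
            raise ValueError(f"densitometry table needs columns {sorted(required)}")
        if (data["band_density"] < 0).any():
            raise ValueError("band densities must be nonnegative")
        roles = set(data["role"])
        if not roles.issubset({"standard", "unknown"}):
            raise ValueError("role must be 'standard' or 'unknown'")
        self.data = data.reset_index(drop=True)

    @property
    def standards(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "standard"]

    @property
    def unknowns(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "unknown"]

    def copy(self) -> "DensitometryTable":
        return DensitometryTable(self.data.copy())


@dataclass
class CalibrationFit:
    """Linear band-density-vs-concentration calibration."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple  # (min, max) standard concentration, ug/ml

    def __post_init__(self) -> None:
        if self.slope <= 0:
            from .errors import CalibrationError
            raise CalibrationError("calibration slope must be positive")


CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A one-letter protein sequence restricted to canonical residues."""

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise SequenceError("empty protein sequence")
        bad = sorted(set(seq) - CANONICAL_AA)
        if bad:
            raise SequenceError(f"non-canonical residues in {self.name or 'sequence'}: {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def count(self, aa: str) -> int:
        return self.sequence.count(aa)


@dataclass
class QuenchCurve:
    """A stimulated-endocytosis quench time course.

    The trace clock has t = 0 at stimulation; samples at t < 0 are the
    pre-stimulation baseline.  ``endpoint_window`` is the length (s) of the
    final window summarized as the endpoint fluorescence.
    """

    trace: TimeSeriesTrace
    paired_control_id: str = ""
    endpoint_window: float = 100.0

    def __post_init__(self) -> None:
        if self.endpoint_window <= 0:
            raise ValueError("endpoint window must be positive")

    @property
    def pre_stim_values(self) -> np.ndarray:
        return self.trace.values[self.trace.times < 0]

    @property
    def post_stim(self) -> tuple:
        sel = self.trace.times >= 0
        return self.trace.times[sel], self.trace.values[sel]
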