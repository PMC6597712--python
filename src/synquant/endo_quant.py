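"""Stimulated-endocytosis quantification from fluorescence-quench curves.

Receptor-bound FITC fluorescence is quenched as crosslinked receptor
complexes internalize into acidic endosomes.  Curves are normalized so the
pre-stimulation mean is 1.0; the fractional quench is 1 minus the endpoint
fluorescence, and each test sample is reported relative to its paired
empty-vector control (set at 100% endocytosis).

The endpoint statistic is the mean over a final window (default 100 s of a
~1500 s course) rather than a single point, for noise robustness; an
integrated (area-based) statistic is available as an alternative without
any claim of equivalence to the endpoint convention.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .errors import QuenchCurveError
from .types import QuenchCurve

__all__ = ["normalize_quench", "fractional_quench", "relative_endocytosis"]


def normalize_quench(curve: QuenchCurve) -> QuenchCurve:
    """Divide the curve by its pre-stimulation mean so F(t<0) averages 1."""
    pre = curve.pre_stim_values
    if pre.size == 0:
        raise QuenchCurveError("no pre-stimulation samples (t < 0)")
    mean = float(pre.mean())
    if mean <= 0:
        raise QuenchCurveError(f"nonpositive pre-stimulation mean {mean:.4g}")
    trace = curve.trace.with_values(curve.trace.values / mean)
    return replace(curve, trace=trace)


def fractional_quench(curve: QuenchCurve, statistic: str = "endpoint") -> float:
    """Fraction of fluorescence lost to internalization, in [0, 1].

    endpoint: 1 - mean(F) over the final ``endpoint_window`` seconds.
    integrated: 1 - time-averaged F over the whole post-stimulation epoch
    (weights the full course, not just the plateau).
    Values outside [0, 1] are clipped with a warning.
    """
    curve = normalize_quench(curve)
    times, values = curve.post_stim
    if times.size == 0:
        raise QuenchCurveError("no post-stimulation samples")
    if statistic == "endpoint":
        t_end = float(times[-1])
        sel = times > t_end - curve.endpoint_window
        if not sel.any():
            raise QuenchCurveError("endpoint window holds no samples")
        quench = 1.0 - float(values[sel].mean())
    elif statistic == "integrated":
        quench = 1.0 - float(np.trapezoid(values, times) / (times[-1] - times[0])) \
            if times.size > 1 else 1.0 - float(values[0])
    else:
        raise ValueError("statistic must be 'endpoint' or 'integrated'")
    if quench < 0 or quench > 1:
        warnings.warn(f"fractional quench {quench:.4g} outside [0, 1]; clipped",
                      stacklevel=2)
        quench = min(1.0, max(0.0, quench))
    return quench


def relative_endocytosis(test: QuenchCurve, control: QuenchCurve,
                         statistic: str = "endpoint") -> float:
    """Endocytosis of ``test`` as a percentage of its paired control."""
    control_q = fractional_quench(control, statistic=statistic)
    if control_q <= 0:
        raise QuenchCurveError("paired control shows no quench; nothing to "
                               "normalize against")
    return 100.0 * fractional_quench(test, statistic=statistic) / control_q
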