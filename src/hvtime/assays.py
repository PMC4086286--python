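"""Assay arithmetic: XTT viability fold change, IC50 interpolation and
Livak ΔΔCt relative quantification.

The viability fold change of a well series is the ratio of mean absorbance
at 24 h to mean absorbance at time 0. The IC50 is the dilution factor at
which relative viability (fold change normalized to the untreated control)
crosses 0.5, found by linear interpolation against log10 concentration
(concentration = 1 / dilution factor); no sigmoidal model is fitted. The
Livak method assumes perfect amplification efficiency:
fold = 2^(-ΔΔCt) with
ΔΔCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .containers import PcrQuartet, ViabilitySeries
from .errors import InvalidAbsorbance, NoCrossing

__all__ = ["viability_fold_change", "interpolate_ic50", "ddct_fold_change"]


def viability_fold_change(abs_t24: Sequence[float], abs_t0: Sequence[float]) -> float:
    """Fold change in viability: mean(24 h absorbance) / mean(0 h absorbance)."""
    t0 = float(np.mean(np.asarray(abs_t0, dtype=float)))
    t24 = float(np.mean(np.asarray(abs_t24, dtype=float)))
    if t0 <= 0:
        raise InvalidAbsorbance(f"mean t0 absorbance must be > 0, got {t0}")
    return t24 / t0


def relative_viability(series: ViabilitySeries) -> dict[float, float]:
    """Per-dilution fold change normalized to the untreated control (= 1)."""
    control = viability_fold_change(series.control_t24, series.control_t0)
    if control <= 0:
        raise InvalidAbsorbance("untreated-control fold change must be > 0")
    out = {}
    for d in series.dilution_factors:
        fold = viability_fold_change(series.absorbance_t24[d], series.absorbance_t0[d])
        out[float(d)] = fold / control
    return out


def interpolate_ic50(series: ViabilitySeries) -> float:
    """Dilution factor at which relative viability crosses 0.5.

    Viability is interpolated linearly against log10 concentration
    (-log10 dilution factor); dilutions are sorted internally, so input
    order is irrelevant. With several crossings the one at the lowest
    concentration is returned with a warning.
    """
    rel = relative_viability(series)
    d = np.array(sorted(rel.keys(), reverse=True), dtype=float)  # dilute -> dose
    x = -np.log10(d)  # ascending log-concentration
    v = np.array([rel[k] for k in d])
    crossings = []
    for i in range(len(d)):
        if v[i] == 0.5:
            crossings.append(x[i])
        if i + 1 < len(d) and (v[i] - 0.5) * (v[i + 1] - 0.5) < 0:
            t = (0.5 - v[i]) / (v[i + 1] - v[i])
            crossings.append(x[i] + t * (x[i + 1] - x[i]))
    if not crossings:
        raise NoCrossing("relative viability never crosses 0.5 in tested range")
    if len(crossings) > 1:
        warnings.warn(
            f"{len(crossings)} crossings of 0.5; returning the lowest concentration"
        )
    return float(10 ** (-min(crossings)))


def ddct_fold_change(quartet: PcrQuartet) -> float:
    """Livak relative quantification: fold = 2^(-ΔΔCt)."""
    ddct = (quartet.ct_target_treated - quartet.ct_reference_treated) - (
        quartet.ct_target_control - quartet.ct_reference_control
    )
    return float(2.0 ** (-ddct))
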