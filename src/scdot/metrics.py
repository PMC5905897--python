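"""Image-quality metrics for reconstructed chromophore maps.

Three standard measures are used.  Average contrast (AC) is the mean
recovered value over the activation region — the nodes whose recovered
change exceeds half the maximum recovered change — divided by the true
value there; 1 is perfect.  Pearson correlation (PC) measures the joint
variability of recovered and true maps.  PSNR is ``10 log10(MAX^2 / MSE)``
in dB with the MSE taken over the whole field and MAX the peak of the
ground-truth field (so the score is comparable across methods on one
phantom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DimensionError, ParameterError

__all__ = [
    "MetricsReport",
    "activation_region",
    "average_contrast",
    "pearson_correlation",
    "psnr",
    "metrics_report",
]


def activation_region(delta_field: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Indices of nodes with |value| >= fraction * max |value|.

    Thresholding uses magnitudes so negative activations (deoxyhemoglobin
    decreases) are handled symmetrically.  An all-zero field yields an empty
    set with a warning.
    """
    v = np.abs(np.asarray(delta_field, dtype=float))
    if v.size == 0:
        raise ParameterError("field is empty")
    m = v.max()
    if m == 0:
        warnings.warn("all-zero field: activation region is empty", stacklevel=2)
        return np.array([], dtype=np.int64)
    return np.flatnonzero(v >= fraction * m)


def average_contrast(recon: np.ndarray, truth_value: float, region: np.ndarray) -> float:
    """Mean recovered value over the region divided by the true value."""
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ParameterError("activation region is empty")
    if truth_value == 0:
        raise ParameterError("truth value must be nonzero")
    return float(np.mean(np.asarray(recon, float)[region]) / truth_value)


def pearson_correlation(recon: np.ndarray, truth: np.ndarray) -> float:
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise DimensionError("fields must share a shape")
    if np.std(recon) == 0 or np.std(truth) == 0:
        raise ParameterError("Pearson correlation undefined for a constant field")
    return float(stats.pearsonr(recon, truth).statistic)


def psnr(recon: np.ndarray, truth: np.ndarray, max_value: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; MSE over all nodes, peak from the
    ground truth unless overridden.  Returns inf for an exact match."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise DimensionError("fields must share a shape")
    mse = float(np.mean((recon - truth) ** 2))
    peak = float(np.abs(truth).max()) if max_value is None else float(max_value)
    if mse == 0.0:
        return float("inf")
    if peak == 0.0:
        return float("nan")  # undefined for an all-zero reference
    return float(10.0 * np.log10(peak**2 / mse))


@dataclass
class MetricsReport:
    """AC/PC/PSNR per chromophore plus the activation sets used for AC."""

    ac: dict
    pc: dict
    psnr: dict
    activation_nodes: dict

    def as_dict(self) -> dict:
        return {
            name: {"AC": self.ac[name], "PC": self.pc[name], "PSNR": self.psnr[name]}
            for name in self.ac
        }


def metrics_report(recon_delta: dict, truth_delta: dict) -> MetricsReport:
    """Evaluate recovered concentration changes against the ground truth.

    Both arguments map chromophore name to a per-node change field.  The AC
    truth value is the ground-truth change at its own peak-magnitude node
    (the inclusion contrast for piecewise-constant phantoms).
    """
    ac, pc, ps, regions = {}, {}, {}, {}
    for name, rec in recon_delta.items():
        tru = np.asarray(truth_delta[name], dtype=float)
        rec = np.asarray(rec, dtype=float)
        region = activation_region(rec)
        regions[name] = region
        truth_value = float(tru[np.argmax(np.abs(tru))]) if np.any(tru) else 0.0
        ac[name] = (
            average_contrast(rec, truth_value, region)
            if region.size and truth_value != 0
            else float("nan")
        )
        try:
            pc[name] = pearson_correlation(rec, tru)
        except ParameterError:
            pc[name] = float("nan")
        ps[name] = psnr(rec, tru)
    return MetricsReport(ac, pc, ps, regions)
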