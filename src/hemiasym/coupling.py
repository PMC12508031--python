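"""Amplitude–asymmetry coupling at vertex and network level.

Stronger task-evoked activation tends to accompany stronger hemispheric
differentiation; these routines quantify that association as Pearson
correlations across subjects — per vertex (averaged over epochs) or per
(network, epoch) cell — along with amplitude-binned group summaries and a
linear-versus-polynomial model comparison by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import cohens_d_from_r
from .networks import NetworkEpochMatrix


@dataclass
class CouplingResult:
    """Correlation estimates with effect sizes, at vertex or network level.

    At vertex level ``r`` is the across-epoch average r-map (vector per
    vertex) and ``per_epoch_r`` the epoch × vertex array behind it.  At
    network level ``r``/``p``/``d`` are (network, epoch) DataFrames.
    """

    r: np.ndarray | pd.DataFrame
    p: np.ndarray | pd.DataFrame | None
    d: np.ndarray | pd.DataFrame | None
    n: int
    level: str  # {"vertex", "network"}
    per_epoch_r: np.ndarray | None = None
    n_undefined: int = 0


def _pearson_over_subjects(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r along axis 0 of two equally shaped (S, ...) arrays."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom


def vertexwise_coupling(
    amplitudes: np.ndarray,
    asymmetries: np.ndarray,
    fisher_z: bool = False,
) -> CouplingResult:
    """Average vertex-wise amplitude–asymmetry correlation across epochs.

    Inputs are (subjects, epochs, vertices) arrays of bilateral amplitude
    and asymmetry.  Per epoch, Pearson r is computed across subjects at
    every vertex; the returned map is the arithmetic mean of the
    per-epoch r-maps (or the inverse-transformed mean of Fisher-z values
    with ``fisher_z=True``).
    """
    amplitudes = np.asarray(amplitudes, float)
    asymmetries = np.asarray(asymmetries, float)
    if amplitudes.shape != asymmetries.shape:
        raise ValueError("amplitude and asymmetry arrays must share shape")
    n = amplitudes.shape[0]
    if n < 3:
        raise ValueError("coupling requires at least 3 subjects")
    per_epoch = _pearson_over_subjects(amplitudes, asymmetries)  # (E, V)
    n_undefined = int(np.isnan(per_epoch).sum())
    if fisher_z:
        z = np.arctanh(np.clip(per_epoch, -1 + 1e-15, 1 - 1e-15))
        avg = np.tanh(np.nanmean(z, axis=0))
    else:
        avg = np.nanmean(per_epoch, axis=0)
    return CouplingResult(
        r=avg, p=None, d=None, n=n, level="vertex",
        per_epoch_r=per_epoch, n_undefined=n_undefined,
    )


def network_coupling(
    matrix_a: NetworkEpochMatrix, matrix_d: NetworkEpochMatrix
) -> CouplingResult:
    """Pearson r between amplitude and asymmetry per (network, epoch) cell.

    Both matrices must share subjects, networks and epochs.  Cells with
    zero variance in either measure yield NaN r (flagged, not errored).
    """
    if list(matrix_a.values.index) != list(matrix_d.values.index):
        raise ValueError("matrices must share the same subjects in the same order")
    if list(matrix_a.values.columns) != list(matrix_d.values.columns):
        raise ValueError("matrices must share networks and epochs")
    networks, epochs = matrix_a.networks, matrix_a.epochs
    n = len(matrix_a.values)
    r = pd.DataFrame(np.nan, index=networks, columns=epochs)
    p = pd.DataFrame(np.nan, index=networks, columns=epochs)
    d = pd.DataFrame(np.nan, index=networks, columns=epochs)
    n_undef = 0
    for k in networks:
        for e in epochs:
            x = matrix_a.cell(k, e)
            y = matrix_d.cell(k, e)
            if np.std(x) == 0 or np.std(y) == 0:
                n_undef += 1
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[k, e] = rr
            p.loc[k, e] = pp
            if abs(rr) < 1:
                d.loc[k, e] = cohens_d_from_r(rr)
    return CouplingResult(r=r, p=p, d=d, n=n, level="network", n_undefined=n_undef)


def bin_by_amplitude(
    amplitude: np.ndarray,
    other: np.ndarray,
    group_size: int = 10,
    ids=None,
) -> pd.DataFrame:
    """Group subjects by ranked amplitude and return per-group means.

    Subjects are sorted ascending by amplitude (ties broken by subject
    id), chunked into consecutive groups of ``group_size`` (the final
    group may be smaller), and the mean of both variables is returned per
    group.  A presentation-level summary: subject-level statistics should
    always be reported alongside.
    """
    amplitude = np.asarray(amplitude, float)
    other = np.asarray(other, float)
    if amplitude.size == 0:
        raise ValueError("cannot bin an empty sample")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if ids is None:
        ids = np.arange(amplitude.size)
    order = np.lexsort((np.asarray(ids), amplitude))
    rows = []
    for start in range(0, amplitude.size, group_size):
        sel = order[start : start + group_size]
        rows.append(
            {
                "group": len(rows),
                "n": sel.size,
                "amplitude_mean": amplitude[sel].mean(),
                "other_mean": other[sel].mean(),
            }
        )
    return pd.DataFrame(rows)


def compare_poly_aic(
    x: np.ndarray, y: np.ndarray, max_degree: int = 3, parsimony_delta: float = 2.0
) -> pd.DataFrame:
    """Compare polynomial fits of degree 1..max_degree by AIC.

    Least-squares polynomial fits under a Gaussian likelihood with
    k = degree + 2 parameters (coefficients plus the noise variance);
    AIC = 2k − 2·logLik.  The returned frame has one row per degree with
    columns ``aic``, ``delta_aic`` (vs the linear fit), ``delta_aic_pct``
    (100·(AIC₁ − AIC_d)/|AIC₁|) and ``selected``.

    Selection follows the usual parsimony convention: the smallest degree
    whose AIC lies within ``parsimony_delta`` of the minimum (models
    within ~2 AIC units are considered equally supported, so the simpler
    one is preferred).  ``parsimony_delta=0`` gives the pure minimum-AIC
    degree, smallest degree on exact ties.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n <= max_degree + 2:
        raise ValueError(f"need n > max_degree + 2 = {max_degree + 2}, got n = {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; polynomial fits are degenerate")
    # residual sums of squares at or below rounding error count as exact fits
    exact_tol = n * max(np.var(y), 1.0) * 1e-24
    rows = []
    for deg in range(1, max_degree + 1):
        coefs = np.polyfit(x, y, deg)
        resid = y - np.polyval(coefs, x)
        rss = float(resid @ resid)
        if rss <= exact_tol:
            aic = -np.inf
        else:
            sigma2 = rss / n  # MLE variance
            loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
            aic = 2 * (deg + 2) - 2 * loglik
        rows.append({"degree": deg, "k": deg + 2, "aic": aic, "rss": rss})
    out = pd.DataFrame(rows)
    aic_lin = out.loc[out["degree"] == 1, "aic"].iloc[0]
    with np.errstate(invalid="ignore"):
        out["delta_aic"] = aic_lin - out["aic"]
        out["delta_aic_pct"] = 100.0 * out["delta_aic"] / abs(aic_lin)
    out["selected"] = False
    exact = out["rss"] <= exact_tol
    if exact.any():
        best = int(out.index[exact][0])
    else:
        within = out["aic"] <= out["aic"].min() + parsimony_delta
        best = int(out.index[within][0])
    out.loc[best, "selected"] = True
    return out


def selected_degree(aic_table: pd.DataFrame) -> int:
    """The degree marked selected by :func:`compare_poly_aic`."""
    return int(aic_table.loc[aic_table["selected"], "degree"].iloc[0])
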