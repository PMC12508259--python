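"""Post-search processing: left-censored imputation, protein aggregation and
variance-stabilising normalisation.

The stage order is fixed — impute at peptide level, average peptides to
proteins (requiring at least two peptides), then calibrate and glog-transform
the protein matrix.  Each function checks the scale/shape contract of its
input so the stages cannot be silently permuted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_formats import PeptideTable, ProteinMatrix, RunConfig, Scale
from .synthetic import substream

logger = logging.getLogger(__name__)

__all__ = [
    "impute_missing",
    "aggregate_proteins",
    "vsn_normalize",
    "detection_call",
    "CalibrationParams",
]


def impute_missing(
    peptides: PeptideTable, config: RunConfig, seed: int | None = None
) -> PeptideTable:
    """Fill censored cells with draws from N(q, s^2) on the log2 scale.

    ``q`` is the ``config.impute_quantile`` quantile of all detected log2
    intensities (global by default, per sample if ``config.impute_per_sample``)
    and ``s`` the median over peptides of the per-peptide SD of detected log2
    values — a low, narrow distribution that encodes the left-censoring
    assumption: a missing peptide was most likely below the detection limit.
    Detected cells are untouched and the detection mask is preserved.
    """
    det = peptides.detected.to_numpy()
    if not det.any():
        raise ValueError("no detected values to impute from")
    if det.all():
        return peptides.copy()

    vals = peptides.intensities.to_numpy(dtype=float)
    log2 = np.where(det, np.log2(np.where(det, vals, 1.0)), np.nan)

    # median per-peptide SD over peptides with >= 2 detected values
    counts = det.sum(axis=1)
    eligible = counts >= 2
    if not eligible.any():
        raise ValueError(
            "cannot estimate imputation SD: no peptide has >= 2 detected values"
        )
    with np.errstate(invalid="ignore"):
        pep_sd = np.nanstd(log2[eligible], axis=1, ddof=1)
    s = float(np.median(pep_sd))

    rng = substream(config.seed if seed is None else seed, "impute")
    out = vals.copy()
    if config.impute_per_sample:
        for j in range(out.shape[1]):
            col_det = det[:, j]
            q = float(np.nanquantile(log2[col_det, j], config.impute_quantile))
            n_miss = int((~col_det).sum())
            out[~col_det, j] = np.exp2(rng.normal(q, s, size=n_miss))
    else:
        q = float(np.nanquantile(log2[det], config.impute_quantile))
        miss = ~det
        out[miss] = np.exp2(rng.normal(q, s, size=int(miss.sum())))

    logger.info("imputed %d censored cells (q=%.3f log2, s=%.3f)",
                int((~det).sum()), q, s)
    return PeptideTable(
        peptides.protein_ids.copy(),
        pd.DataFrame(out, index=peptides.peptide_ids, columns=peptides.sample_ids),
        peptides.detected.copy(),
    )


def aggregate_proteins(peptides: PeptideTable, config: RunConfig) -> ProteinMatrix:
    """Average peptide intensities per protein; drop proteins with too few
    peptides.

    Aggregation runs after imputation, so every peptide contributes in every
    sample; the minimum-peptide rule (default 2) guards against one-hit
    quantification.
    """
    if (~peptides.detected.to_numpy()).any() and (
        peptides.intensities.to_numpy() <= 0
    ).any():
        raise ValueError("peptide table still contains censored cells: impute first")

    n_pep = peptides.protein_ids.groupby(peptides.protein_ids).size()
    keep = n_pep[n_pep >= config.min_peptides]
    if keep.empty:
        raise ValueError("all proteins dropped by the minimum-peptide rule")
    dropped = len(n_pep) - len(keep)
    if dropped:
        logger.info("dropped %d proteins with < %d peptides", dropped,
                    config.min_peptides)

    means = peptides.intensities.groupby(peptides.protein_ids).mean()
    means = means.loc[keep.index].sort_index()
    return ProteinMatrix(means, Scale.LINEAR, keep.sort_index().astype(int))


@dataclass
class CalibrationParams:
    """Fitted per-sample affine calibration of the glog transform.

    ``offsets[i]`` and ``scales[i]`` are the (a_i, b_i) of
    ``t = arcsinh((x - a_i) / b_i)``; the first sample is the gauge
    (a = 0, b = 1) because the model is invariant to a common affine change.
    """

    offsets: pd.Series
    scales: pd.Series
    iterations: int
    objective: float
    trimmed_proteins: list[str]

    def __post_init__(self) -> None:
        if (self.scales <= 0).any():
            raise ValueError("calibration scales must be positive")


def _vsn_objective_grad(params, x, ref, offset_scale):
    """Negative profile log-likelihood of the arcsinh calibration model and
    its gradient in (a_i / offset_scale, log b_i) for all non-reference
    samples.

    obj = (N/2) log SSR + 0.5 * sum log(b^2 + (x - a)^2)
    with SSR the pooled within-protein sum of squared residuals of
    t = arcsinh((x - a)/b).  Offsets are optimised in units of
    ``offset_scale`` (a typical intensity) so both parameter blocks are O(1)
    for the quasi-Newton line search.
    """
    p, n = x.shape
    a = np.zeros(n)
    logb = np.zeros(n)
    free = [j for j in range(n) if j != ref]
    a[free] = params[: len(free)] * offset_scale
    logb[free] = params[len(free):]
    b = np.exp(logb)

    xa = x - a[None, :]
    u = xa / b[None, :]
    t = np.arcsinh(u)
    r = t - t.mean(axis=1, keepdims=True)
    # tiny floor keeps the perfect-fit corner case (identical columns) finite
    ssr = float((r * r).sum()) + 1e-300
    N = x.size
    d2 = b[None, :] ** 2 + xa * xa  # = (b * sqrt(1 + u^2))^2
    obj = 0.5 * N * np.log(ssr) + 0.5 * np.log(d2).sum()

    d = np.sqrt(d2)
    # dt/da = -1/d ; dt/d(logb) = -xa/d ; jacobian-term derivatives per cell
    ga = (N / ssr) * (r * (-1.0 / d)).sum(axis=0) - (-xa / d2).sum(axis=0)
    gb = (N / ssr) * (r * (-xa / d)).sum(axis=0) + (b[None, :] ** 2 / d2).sum(axis=0)
    grad = np.concatenate([ga[free] * offset_scale, gb[free]])
    return obj, grad


def vsn_normalize(
    proteins: ProteinMatrix,
    trim: float = 0.25,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[ProteinMatrix, CalibrationParams]:
    """Variance-stabilising normalisation of a linear-scale protein matrix.

    Fits per-sample affine calibrations ``(a_i, b_i)`` so that
    ``t = arcsinh((x - a_i)/b_i)`` has within-protein variance independent of
    the mean, by minimising the negative profile log-likelihood of the
    additive-multiplicative error model.  Robustness comes from least-trimmed
    squares: each outer iteration refits after discarding the ``trim``
    fraction of proteins with the largest within-protein residuals, so
    subtype-specific marker programs do not distort the per-sample
    calibration; the default fraction (25%) must exceed the share of
    genuinely differential proteins in the cohort.  The
    first sample is fixed at (a=0, b=1) for identifiability; ``b`` is
    optimised as ``log b`` so it can never go non-positive.

    Returns the transformed matrix (scale GLOG, all proteins, including
    trimmed ones) and the fitted calibration.
    """
    if proteins.scale is not Scale.LINEAR:
        raise ValueError(f"vsn_normalize expects a LINEAR matrix, got {proteins.scale}")
    x = proteins.values.to_numpy(dtype=float)
    p, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples to calibrate")
    ref = 0

    # moment initialisation: match medians and spreads to the reference sample
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None, :]), axis=0)
    mad = np.where(mad <= 0, 1.0, mad)
    b0 = mad / mad[ref]
    a0 = med - b0 * med[ref]
    free = [j for j in range(n) if j != ref]
    offset_scale = float(np.median(np.abs(x))) or 1.0
    params = np.concatenate([a0[free] / offset_scale, np.log(b0[free])])
    bounds = [(-10.0, 10.0)] * len(free) + [(-15.0, 15.0)] * len(free)

    n_trim = int(np.floor(trim * p))
    keep = np.ones(p, dtype=bool)
    prev_obj = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        res = minimize(
            _vsn_objective_grad,
            params,
            args=(x[keep], ref, offset_scale),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        params = res.x
        obj = float(res.fun)

        # rank proteins by within-protein residual under the current fit
        a = np.zeros(n)
        logb = np.zeros(n)
        a[free] = params[: len(free)] * offset_scale
        logb[free] = params[len(free):]
        t = np.arcsinh((x - a[None, :]) / np.exp(logb)[None, :])
        resid = ((t - t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        new_keep = np.ones(p, dtype=bool)
        if n_trim > 0:
            new_keep[np.argsort(resid)[-n_trim:]] = False

        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * abs(prev_obj):
            keep = new_keep
            break
        if np.array_equal(new_keep, keep) and iterations > 1:
            break
        keep = new_keep
        prev_obj = obj

    a = np.zeros(n)
    logb = np.zeros(n)
    a[free] = params[: len(free)] * offset_scale
    logb[free] = params[len(free):]
    b = np.exp(logb)
    t = np.arcsinh((x - a[None, :]) / b[None, :])

    calib = CalibrationParams(
        offsets=pd.Series(a, index=proteins.sample_ids),
        scales=pd.Series(b, index=proteins.sample_ids),
        iterations=iterations,
        objective=float(obj),
        trimmed_proteins=[pid for pid, k in zip(proteins.protein_ids, keep) if not k],
    )
    out = ProteinMatrix(
        pd.DataFrame(t, index=proteins.protein_ids, columns=proteins.sample_ids),
        Scale.GLOG,
        proteins.n_peptides,
    )
    return out, calib


def detection_call(peptides: PeptideTable, config: RunConfig) -> pd.DataFrame:
    """Protein x sample detection matrix from pre-imputation peptide flags.

    A protein counts as detected in a sample when at least
    ``config.min_peptides`` of its peptides were observed there — the same
    evidence bar as for quantification.
    """
    per_protein = peptides.detected.groupby(peptides.protein_ids).sum()
    return (per_protein >= config.min_peptides).sort_index()
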