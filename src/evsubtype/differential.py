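"""Per-protein subtype enrichment, ternary subtype fractions, biomarker
signature derivation with healthy-plasma filtering, and patient projection.

The volcano statistic is a Welch two-sample t-test on glog values with
Benjamini-Hochberg q-values over all tested proteins; the subtype signatures
then pass through three audited filters (significant -> detected in patients
-> not seen in healthy-plasma EVs) before being averaged per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    CELL_LINE_SUBTYPES,
    ProteinMatrix,
    RunConfig,
    SampleDesign,
    Scale,
    Subtype,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CONTRASTS",
    "contrast_samples",
    "differential_enrichment",
    "bh_qvalues",
    "storey_qvalues",
    "ternary_fractions",
    "TernaryTable",
    "SubtypeSignature",
    "derive_subtype_signatures",
    "patient_subtype_score",
]

#: Named contrasts of the study design: (label, group A subtypes, group B subtypes).
CONTRASTS = {
    "ARpos_vs_ARneg": (
        (Subtype.AR_POS,),
        (Subtype.AR_NEG_NE_POS, Subtype.AR_NEG_NE_NEG),
    ),
    "ARnegNEneg_vs_rest": (
        (Subtype.AR_NEG_NE_NEG,),
        (Subtype.AR_POS, Subtype.AR_NEG_NE_POS),
    ),
    "ARnegNEpos_vs_rest": (
        (Subtype.AR_NEG_NE_POS,),
        (Subtype.AR_POS, Subtype.AR_NEG_NE_NEG),
    ),
}

#: Which contrast derives each subtype's biomarker list.
SUBTYPE_CONTRAST = {
    Subtype.AR_POS: "ARpos_vs_ARneg",
    Subtype.AR_NEG_NE_NEG: "ARnegNEneg_vs_rest",
    Subtype.AR_NEG_NE_POS: "ARnegNEpos_vs_rest",
}


def contrast_samples(
    design: SampleDesign, contrast: str
) -> tuple[list[str], list[str]]:
    """Sample ids of the two sides of a named contrast."""
    try:
        groups_a, groups_b = CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {list(CONTRASTS)}"
        ) from None
    a = [s for g in groups_a for s in design.samples_of(g)]
    b = [s for g in groups_b for s in design.samples_of(g)]
    return a, b


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def storey_qvalues(pvalues: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate."""
    p = np.asarray(pvalues, dtype=float)
    pi0 = min(1.0, (p > lambda_).mean() / (1.0 - lambda_))
    return np.minimum(bh_qvalues(p) * pi0, 1.0)


def differential_enrichment(
    matrix: ProteinMatrix,
    design: SampleDesign,
    contrast: str,
    config: RunConfig,
) -> pd.DataFrame:
    """Welch t-test per protein with FDR q-values for one subtype contrast.

    Returns a data frame indexed by protein with columns ``group_a``,
    ``group_b``, ``mean_diff`` (glog units, A minus B), ``t_stat``,
    ``p_value``, ``q_value``, ``enriched_in`` and ``significant``.
    """
    if matrix.scale is not Scale.GLOG:
        raise ValueError("differential_enrichment expects a GLOG matrix")
    samples_a, samples_b = contrast_samples(design, contrast)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")

    A = matrix.values[samples_a].to_numpy(dtype=float)
    B = matrix.values[samples_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    diff = A.mean(axis=1) - B.mean(axis=1)
    # degenerate rows (zero variance both sides): identical values -> null
    degenerate = np.isnan(p)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    # zero variance but nonzero diff: infinitely strong evidence
    p = np.where(np.isnan(p), np.nextafter(0, 1), p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    q = storey_qvalues(p) if config.qvalue_method == "storey" else bh_qvalues(p)
    group_a, group_b = CONTRASTS[contrast]
    label_a = "+".join(g.value for g in group_a)
    label_b = "+".join(g.value for g in group_b)
    out = pd.DataFrame(
        {
            "group_a": label_a,
            "group_b": label_b,
            "mean_diff": diff,
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "enriched_in": np.where(diff > 0, label_a, label_b),
            "significant": q < config.q_threshold,
        },
        index=matrix.protein_ids,
    )
    logger.info(
        "%s: %d/%d proteins significant at q < %g",
        contrast, int(out["significant"].sum()), len(out), config.q_threshold,
    )
    return out


@dataclass
class TernaryTable:
    """Per-protein subtype fractions on the 3-subtype simplex.

    ``fractions`` columns are percentages in [0, 100] summing to 100 per
    protein; ``density`` counts proteins per sub-triangle of a triangular
    grid with ``grid_levels`` divisions per edge.
    """

    fractions: pd.DataFrame
    density: dict[tuple[int, int, str], int]
    grid_levels: int
    excluded: list[str] = field(default_factory=list)


def _triangle_bin(f: np.ndarray, levels: int) -> tuple[int, int, str]:
    """Map simplex fractions (summing to 1) to an (i, j, up/down) sub-triangle.

    The floors of the scaled coordinates sum to ``levels - 1`` (upward
    triangle) or ``levels - 2`` (downward); lattice points on bin boundaries
    are pushed into an adjacent upward triangle so every protein lands in
    exactly one bin.
    """
    scaled = np.minimum(np.asarray(f, dtype=float) * levels, levels - 1e-9)
    fl = np.floor(scaled).astype(int)
    total = int(fl.sum())
    while total > levels - 1:  # exact-boundary point
        fr = np.where(fl > 0, scaled - fl, np.inf)
        fl[int(np.argmin(fr))] -= 1
        total -= 1
    orientation = "up" if total == levels - 1 else "down"
    return int(fl[0]), int(fl[1]), orientation


def ternary_fractions(
    matrix: ProteinMatrix, design: SampleDesign, grid_levels: int = 6
) -> TernaryTable:
    """Percent of total mean signal per subtype for every protein.

    Requires the *linear*-scale aggregated matrix: percentages of signal are
    only meaningful for non-negative values, so the glog matrix is refused.
    """
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("ternary_fractions expects a LINEAR matrix")
    means = {}
    for st in CELL_LINE_SUBTYPES:
        samples = design.samples_of(st)
        if not samples:
            raise ValueError(f"subtype {st.value} has no samples in the design")
        means[st.value] = matrix.values[samples].mean(axis=1)
    m = pd.DataFrame(means)
    totals = m.sum(axis=1)
    excluded = list(m.index[totals == 0])
    if excluded:
        logger.warning("excluding %d proteins with zero total signal", len(excluded))
        m = m.loc[totals > 0]
        totals = totals.loc[m.index]
    frac = m.div(totals, axis=0)
    density: dict[tuple[int, int, str], int] = {}
    for row in frac.to_numpy():
        key = _triangle_bin(row, grid_levels)
        density[key] = density.get(key, 0) + 1
    return TernaryTable(100.0 * frac, density, grid_levels, excluded)


@dataclass
class SubtypeSignature:
    """Per-subtype biomarker lists with filter provenance.

    ``proteins`` holds the final list per subtype, ordered by q-value then
    |mean difference|; ``counts`` records (n significant, n also detected in
    patients, n after healthy-plasma removal) so the filter chain is
    auditable.
    """

    proteins: dict[str, list[str]]
    counts: dict[str, tuple[int, int, int]]
    healthy_removed: dict[str, list[str]] = field(default_factory=dict)


def derive_subtype_signatures(
    diff_results: dict[Subtype, pd.DataFrame],
    patient_matrix: ProteinMatrix,
    healthy_list: set[str] | list[str],
    config: RunConfig,
) -> SubtypeSignature:
    """Three-stage biomarker derivation per subtype.

    Stage 1: proteins significantly enriched in the subtype's contrast side.
    Stage 2: intersect with the proteins present in the patient matrix.
    Stage 3: remove proteins also identified in EVs from healthy plasma.
    """
    healthy = {g.upper() for g in healthy_list}
    patient_proteins = set(patient_matrix.protein_ids)
    proteins: dict[str, list[str]] = {}
    counts: dict[str, tuple[int, int, int]] = {}
    removed: dict[str, list[str]] = {}
    for subtype in CELL_LINE_SUBTYPES:
        if subtype not in diff_results:
            raise ValueError(f"missing differential results for {subtype.value}")
        df = diff_results[subtype]
        enriched = df[(df["significant"]) & (df["mean_diff"] > 0)]
        ordered = enriched.sort_values(
            ["q_value", "mean_diff"], ascending=[True, False],
            key=lambda c: c.abs() if c.name == "mean_diff" else c,
        )
        stage1 = list(ordered.index)
        stage2 = [p for p in stage1 if p in patient_proteins]
        final = [p for p in stage2 if p not in healthy]
        proteins[subtype.value] = final
        counts[subtype.value] = (len(stage1), len(stage2), len(final))
        removed[subtype.value] = [p for p in stage2 if p in healthy]
        logger.info(
            "%s signature: %d significant -> %d patient-detected -> %d after "
            "healthy-plasma filter",
            subtype.value, len(stage1), len(stage2), len(final),
        )
    return SubtypeSignature(proteins, counts, removed)


def patient_subtype_score(
    patient_matrix: ProteinMatrix,
    signature: SubtypeSignature,
    method: str = "zscore",
) -> pd.DataFrame:
    """Average signature-protein level per patient and subtype.

    ``zscore`` (default) averages each protein's z-score across patients so
    subtypes with different absolute levels are comparable; ``raw`` averages
    the matrix values directly.
    """
    vals = patient_matrix.values
    if method == "zscore":
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1).replace(0.0, np.nan)
        vals = vals.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    elif method != "raw":
        raise ValueError(f"unknown method {method!r}")
    out = {}
    for subtype, prots in signature.proteins.items():
        found = [p for p in prots if p in vals.index]
        out[subtype] = vals.loc[found].mean(axis=0) if found else pd.Series(
            np.nan, index=vals.columns
        )
    return pd.DataFrame(out)
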