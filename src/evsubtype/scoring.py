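"""Signature activity scores, clustering/PCA summaries and overlap counts.

The activity score is the summative z-score: each signature gene is z-scored
across samples, the per-sample z's are summed over the genes found, and the
sums are min-max rescaled to [0, 1] across the cohort.  The neuroendocrine
score instead correlates each sample's z-scored profile with a reference
NEPC profile.  Structure summaries follow the classic proteomics recipe:
average-linkage (UPGMA) hierarchical clustering on 1 - Pearson correlation
and PCA of the row-centred matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .io_formats import (
    CELL_LINE_SUBTYPES,
    ProteinMatrix,
    SampleDesign,
    SignatureCollection,
    Subtype,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "ClusterResult",
    "zscore_signature_score",
    "correlation_ne_score",
    "score_signatures",
    "signature_coverage",
    "hierarchical_cluster",
    "pca_project",
    "overlap_counts",
    "cohort_overlap",
]


@dataclass
class ScoreTable:
    """Per-sample signature scores with coverage bookkeeping.

    ``scores`` is sample x signature; RESCALED01 entries live in [0, 1] and
    CORRELATION entries in [-1, 1].  ``coverage`` maps each signature to
    (genes found in the matrix, signature size).  ``degenerate`` flags
    signatures whose raw scores were constant (all entries set to 0.5).
    """

    scores: pd.DataFrame
    score_kind: str  # "RESCALED01" | "CORRELATION"
    coverage: dict[str, tuple[int, int]] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Dendrogram + PCA summary of a matrix axis."""

    items: list[str]
    linkage_matrix: np.ndarray | None = None  # scipy (n-1) x 4 format
    leaf_order: list[str] | None = None
    pca_coordinates: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    zero_variance_items: list[str] = field(default_factory=list)


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    sd = sd.replace(0.0, np.nan)
    return values.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def zscore_signature_score(
    matrix: ProteinMatrix,
    genes: list[str],
    name: str = "signature",
    design: SampleDesign | None = None,
    replicate_policy: str = "each",
) -> ScoreTable:
    """Summative z-score of a gene set, min-max rescaled to [0, 1].

    ``replicate_policy="mean-of-replicates"`` averages the raw (summed z)
    scores of a cell line's replicates before rescaling, so the reported
    range endpoints are attained by cell lines rather than isolations.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score across the cohort")
    found = [g for g in genes if g in matrix.protein_ids]
    cov = {name: (len(found), len(genes))}
    if not found:
        scores = pd.Series(np.nan, index=matrix.sample_ids, name=name)
        return ScoreTable(scores.to_frame(), "RESCALED01", cov)

    z = _zscore_rows(matrix.values.loc[found])
    raw = z.sum(axis=0)

    if replicate_policy == "mean-of-replicates":
        if design is None:
            raise ValueError("mean-of-replicates policy needs a design")
        lines = pd.Series(
            {s: design.cell_line_of(s) for s in raw.index}, name="cell_line"
        )
        raw = raw.groupby(lines).mean()
    elif replicate_policy != "each":
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")

    lo, hi = float(raw.min()), float(raw.max())
    degenerate = []
    if hi == lo:
        rescaled = pd.Series(0.5, index=raw.index)
        degenerate.append(name)
    else:
        rescaled = (raw - lo) / (hi - lo)
    rescaled.name = name
    return ScoreTable(rescaled.to_frame(), "RESCALED01", cov, degenerate)


def correlation_ne_score(
    matrix: ProteinMatrix,
    signature: SignatureCollection,
    set_name: str,
    method: str = "pearson",
) -> ScoreTable:
    """Correlation of each sample's z-scored profile with a reference profile.

    Used for the neuroendocrine score: genes of the NE set present in both
    the matrix and the reference profile are z-scored across samples, and
    each sample's vector is correlated with the reference levels.
    """
    if signature.reference_profile is None:
        raise ValueError("signature collection carries no reference profile")
    genes = signature[set_name]
    ref = signature.reference_profile
    found = [g for g in genes if g in matrix.protein_ids and g in ref.index]
    cov = {set_name: (len(found), len(genes))}
    if len(found) < 3:
        scores = pd.Series(np.nan, index=matrix.sample_ids, name=set_name)
        return ScoreTable(scores.to_frame(), "CORRELATION", cov)

    z = _zscore_rows(matrix.values.loc[found])
    refv = ref.loc[found].to_numpy(dtype=float)
    out = {}
    for s in z.columns:
        v = z[s].to_numpy()
        if method == "pearson":
            if v.std() == 0 or refv.std() == 0:
                out[s] = 0.0
            else:
                out[s] = float(np.corrcoef(v, refv)[0, 1])
        elif method == "spearman":
            out[s] = float(spearmanr(v, refv).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    scores = pd.Series(out, name=set_name).reindex(matrix.sample_ids)
    return ScoreTable(scores.to_frame(), "CORRELATION", cov)


def score_signatures(
    matrix: ProteinMatrix,
    collection: SignatureCollection,
    design: SampleDesign | None = None,
    replicate_policy: str = "each",
) -> ScoreTable:
    """Summative z-score every set of a collection into one score table."""
    frames, coverage, degenerate = [], {}, []
    for name in collection.names():
        st = zscore_signature_score(
            matrix, collection[name], name, design, replicate_policy
        )
        frames.append(st.scores)
        coverage.update(st.coverage)
        degenerate.extend(st.degenerate)
    return ScoreTable(pd.concat(frames, axis=1), "RESCALED01", coverage, degenerate)


def signature_coverage(
    matrix: ProteinMatrix, collection: SignatureCollection
) -> dict[str, tuple[int, int]]:
    """(genes found, signature size) per set; the reported fraction is the
    coverage statistic quoted alongside every score."""
    present = set(matrix.protein_ids)
    return {
        name: (sum(g in present for g in collection[name]), len(collection[name]))
        for name in collection.names()
    }


def _pearson_distance(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Condensed 1 - Pearson distance between columns; zero-variance columns
    get correlation 0 (distance 1) with every other column."""
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flagged = [c for c, s in zip(values.columns, sd) if s == 0]
    n = x.shape[1]
    corr = np.zeros((n, n))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(x[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    iu = np.triu_indices(n, k=1)
    return dist[iu], flagged


def hierarchical_cluster(
    matrix: ProteinMatrix, axis: str = "samples"
) -> ClusterResult:
    """UPGMA (average linkage) on 1 - Pearson correlation distances.

    Items are sorted lexicographically before linkage so equal-distance
    merges resolve deterministically by item id.
    """
    values = matrix.values if axis == "samples" else matrix.values.T
    items = sorted(map(str, values.columns))
    values = values[items]
    if len(items) < 3:
        raise ValueError("need >= 3 items to cluster")
    condensed, flagged = _pearson_distance(values)
    Z = linkage(condensed, method="average")
    order = [items[i] for i in leaves_list(Z)]
    return ClusterResult(
        items=items,
        linkage_matrix=Z,
        leaf_order=order,
        zero_variance_items=flagged,
    )


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat cluster labels from cutting the tree into ``k`` groups."""
    labels = fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(result.items, map(int, labels)))


def pca_project(matrix: ProteinMatrix, n_components: int | None = None) -> ClusterResult:
    """PCA of samples after per-protein (row) centring."""
    if matrix.values.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    X = matrix.values.T.to_numpy(dtype=float)  # samples x proteins
    if n_components is None:
        n_components = min(X.shape) - 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return ClusterResult(
        items=matrix.sample_ids,
        pca_coordinates=pd.DataFrame(coords, index=matrix.sample_ids, columns=cols),
        explained_variance=pca.explained_variance_ratio_,
    )


@dataclass
class VennSummary:
    """Per-subtype consensus detection sets and their Venn regions.

    A protein belongs to a subtype's set when it was detected in *every* EV
    isolation of that subtype.  ``core`` is the all-subtype intersection;
    ``core_percent`` expresses it relative to all proteins in the detection
    matrix.
    """

    subtype_sets: dict[str, set[str]]
    regions: dict[frozenset, set[str]]
    core: set[str]
    core_percent: float
    n_total: int

    def region(self, *subtypes: str) -> set[str]:
        return self.regions[frozenset(subtypes)]


def overlap_counts(
    detections: pd.DataFrame, design: SampleDesign
) -> VennSummary:
    """Venn regions of the per-subtype 'detected in all isolations' sets."""
    subtype_sets: dict[str, set[str]] = {}
    for st in CELL_LINE_SUBTYPES:
        samples = design.samples_of(st)
        if not samples:
            logger.warning("subtype %s has no samples; excluded from Venn", st.value)
            continue
        mask = detections[samples].all(axis=1)
        subtype_sets[st.value] = set(detections.index[mask])

    names = list(subtype_sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(subtype_sets[c] for c in combo))
            outside = set().union(
                *(subtype_sets[c] for c in names if c not in combo), set()
            )
            regions[frozenset(combo)] = inside - outside
    core = set.intersection(*subtype_sets.values()) if subtype_sets else set()
    n_total = int(detections.shape[0])
    return VennSummary(
        subtype_sets=subtype_sets,
        regions=regions,
        core=core,
        core_percent=100.0 * len(core) / n_total if n_total else 0.0,
        n_total=n_total,
    )


def cohort_overlap(
    matrix_a: ProteinMatrix, matrix_b: ProteinMatrix
) -> tuple[set[str], set[str], set[str]]:
    """(shared, a-only, b-only) protein ids between two cohorts."""
    a, b = set(matrix_a.protein_ids), set(matrix_b.protein_ids)
    return a & b, a - b, b - a
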