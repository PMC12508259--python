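"""Gene-set enrichment analysis: signal-to-noise ranking, weighted
Kolmogorov-Smirnov enrichment statistic, and a gene_set permutation null.

This mirrors the desktop GSEA configuration used for small proteomics
cohorts: the ranking metric is signal-to-noise with the canonical SD floors,
the enrichment score uses the weighted statistic (weight 1), and — because a
handful of samples cannot support phenotype permutation — the null is built
by drawing random gene sets of matching size from the ranked universe.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ProteinMatrix, RunConfig, SampleDesign, SignatureCollection
from .differential import contrast_samples

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "signal2noise_rank",
    "enrichment_score",
    "permutation_test",
]

#: Canonical SD floors of the signal-to-noise metric (relative, absolute).
SD_FLOOR_REL = 0.2
SD_FLOOR_ABS = 0.2


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending, ties broken by id."""

    metric: pd.Series  # index: gene, sorted descending

    def __post_init__(self) -> None:
        if self.metric.index.duplicated().any():
            raise ValueError("duplicate genes in ranked list")

    @property
    def genes(self) -> list[str]:
        return list(self.metric.index)

    def __len__(self) -> int:
        return len(self.metric)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    size: int
    at_p_floor: bool = False


def signal2noise_rank(
    matrix: ProteinMatrix,
    design: SampleDesign,
    contrast: str,
) -> RankedList:
    """Signal-to-noise ranking metric ``(mu_A - mu_B) / (s_A + s_B)``.

    Each group SD is floored at ``max(0.2 * |mu|, 0.2)``, the desktop
    implementation's rule, so near-constant genes cannot dominate the
    ranking.  Genes are sorted descending with lexicographic tie-break.
    """
    samples_a, samples_b = contrast_samples(design, contrast)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("signal-to-noise needs >= 2 samples per group")
    A = matrix.values[samples_a].to_numpy(dtype=float)
    B = matrix.values[samples_b].to_numpy(dtype=float)

    def floored_sd(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        return np.maximum(sd, np.maximum(SD_FLOOR_REL * np.abs(mu), SD_FLOOR_ABS))

    r = (A.mean(axis=1) - B.mean(axis=1)) / (floored_sd(A) + floored_sd(B))
    series = pd.Series(r, index=matrix.protein_ids, name="signal2noise")
    order = sorted(series.index, key=lambda g: (-series[g], g))
    return RankedList(series.loc[order])


def enrichment_score(
    ranked: RankedList,
    gene_set: list[str] | set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score along the ranked list.

    Walking the list, a hit advances the running sum by ``|r|^weight``
    (normalised over the set's hits) and a miss retreats it by
    ``1/(N - N_hits)``; the enrichment score is the running sum's signed
    extremum and the leading edge the hits at or before it (positive ES) or
    strictly after it (negative ES).  With ``weight = 0`` this reduces to the
    classical KS statistic on hit positions.
    """
    genes = ranked.genes
    hits = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")

    r = np.abs(ranked.metric.to_numpy(dtype=float))
    w = r**weight if weight != 0 else np.ones(n)
    hit_weight = np.where(hits, w, 0.0)
    total = hit_weight.sum()
    if total == 0:  # all hit metrics are zero: fall back to uniform steps
        hit_weight = hits.astype(float)
        total = float(n_hit)
    increments = hit_weight / total - (~hits) / (n - n_hit)
    running = np.cumsum(increments)

    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = [g for g, h in zip(genes[: extremum + 1], hits[: extremum + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[extremum:], hits[extremum:]) if h]
    return es, running, leading


def _set_rng(seed: int, set_name: str) -> np.random.Generator:
    """Independent substream per gene set, so results do not depend on the
    order or number of other sets in the collection."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(set_name.encode())])
    )


def permutation_test(
    ranked: RankedList,
    collection: SignatureCollection,
    config: RunConfig,
    seed: int | None = None,
) -> list[GseaResult]:
    """gene_set-permutation GSEA over a signature collection.

    For each set, the null distribution of the enrichment score comes from
    random gene sets of identical size drawn without replacement from the
    ranked universe.  The nominal p uses only same-sign null scores with the
    +1 pseudocount floor; NES divides ES by the mean magnitude of same-sign
    nulls.  FDR follows the sign-stratified NES pooling of the original
    method (``config.gsea_fdr = "bh"`` switches to Benjamini-Hochberg on the
    nominal p-values).
    """
    seed = config.seed if seed is None else seed
    genes = np.array(ranked.genes)
    universe = set(genes)
    n_perm = config.n_permutations
    weight = config.gsea_weight

    observed: dict[str, tuple[float, list[str], int]] = {}
    null_es: dict[str, np.ndarray] = {}
    for name in collection.names():
        members = [g for g in collection[name] if g in universe]
        if not members or len(members) == len(genes):
            logger.warning("set %s skipped (size %d of %d)", name, len(members),
                           len(genes))
            continue
        es, _, leading = enrichment_score(ranked, members, weight)
        rng = _set_rng(seed, name)
        nulls = np.empty(n_perm)
        k = len(members)
        for i in range(n_perm):
            random_set = genes[rng.choice(len(genes), size=k, replace=False)]
            nulls[i], _, _ = enrichment_score(ranked, random_set, weight)
        observed[name] = (es, leading, k)
        null_es[name] = nulls

    results: list[GseaResult] = []
    nes_obs: dict[str, float] = {}
    nes_null_pooled: list[np.ndarray] = []
    for name, (es, leading, k) in observed.items():
        nulls = null_es[name]
        same_sign = nulls[nulls >= 0] if es >= 0 else nulls[nulls < 0]
        at_floor = same_sign.size == 0
        if at_floor:
            p = 1.0 / (n_perm + 1)
            nes = np.sign(es) * np.inf if es != 0 else 0.0
        else:
            extreme = (same_sign >= es).sum() if es >= 0 else (same_sign <= es).sum()
            p = (1.0 + extreme) / (1.0 + same_sign.size)
            mean_mag = np.abs(same_sign).mean()
            nes = es / mean_mag if mean_mag > 0 else 0.0
        # normalise the full null by sign-specific mean magnitudes for pooling
        pos, neg = nulls[nulls >= 0], nulls[nulls < 0]
        parts = []
        if pos.size and pos.mean() > 0:
            parts.append(pos / pos.mean())
        if neg.size:
            parts.append(neg / np.abs(neg).mean())
        if parts:
            nes_null_pooled.append(np.concatenate(parts))
        nes_obs[name] = nes
        results.append(
            GseaResult(name, es, float(nes), float(p), np.nan, leading,
                       n_perm, k, at_floor)
        )

    pooled = np.concatenate(nes_null_pooled) if nes_null_pooled else np.array([])
    obs_vals = np.array([nes_obs[r.set_name] for r in results])
    for r in results:
        if config.gsea_fdr == "bh" or pooled.size == 0:
            continue
        nes = nes_obs[r.set_name]
        if nes >= 0:
            frac_null = (pooled >= nes).mean()
            frac_obs = max((obs_vals >= nes).mean(), 1.0 / len(results))
        else:
            frac_null = (pooled <= nes).mean()
            frac_obs = max((obs_vals <= nes).mean(), 1.0 / len(results))
        r.fdr_q = float(min(1.0, frac_null / frac_obs))
    if config.gsea_fdr == "bh":
        from .differential import bh_qvalues

        qs = bh_qvalues(np.array([r.p_value for r in results]))
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    return results
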