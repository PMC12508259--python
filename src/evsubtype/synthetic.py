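"""Synthetic EV-proteome cohorts with known ground truth.

The generator emulates the structure of a label-free shotgun-proteomics study
of extracellular vesicles from prostate cancer cell lines: nine cell lines in
three molecular subtypes (AR+, AR-/NE+, AR-/NE-), two replicate EV isolations
each, peptide-level intensities under the Rocke-Durbin additive-multiplicative
error model, intensity-dependent (left-censored) detection, and a plasma
patient cohort whose profiles are simplex mixtures of the subtype means plus a
shared plasma background.  Every stochastic quantity is recorded in a
:class:`SyntheticTruth` so each downstream stage has a recovery test.

Error model per peptide *j* of protein *p* in sample *i*::

    x = a_i + b_i * exp(eta) * L_pj * 2**(delta * member(p, subtype_i)) + eps
    eta ~ N(0, sigma_mult**2),  eps ~ N(0, sigma_add**2)

with ``L_pj = 2**(mu_p + e_j)`` the true peptide level (log-normal protein
abundance ``mu_p`` plus a per-peptide ionisation efficiency ``e_j`` shared
across samples).  Detection is Bernoulli with probability
``logistic((log2 x - m0) / k)``: censoring concentrates at low intensity, the
regime the 1%-quantile imputation is built for.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CELL_LINE_SUBTYPES,
    PeptideTable,
    ProteinMatrix,
    SampleDesign,
    Scale,
    SignatureCollection,
    Subtype,
)

__all__ = [
    "SyntheticTruth",
    "default_design",
    "simulate_cellline_cohort",
    "simulate_patient_cohort",
    "truth_signatures",
    "write_truth",
    "read_truth",
    "substream",
]

#: Cell-line panel mirrored by the default design (subtype -> lines).
DEFAULT_PANEL = {
    Subtype.AR_POS: ["LNCAP", "LNCAP95", "C42", "22RV1"],
    Subtype.AR_NEG_NE_POS: ["NCIH660", "EF1", "LASCPC01"],
    Subtype.AR_NEG_NE_NEG: ["PC3", "DU145"],
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a master seed.

    Each pipeline stage draws from its own substream so inserting a stage
    never shifts the randomness of the stages after it.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``signature_membership`` maps each cell-line subtype to the proteins whose
    abundance is shifted by ``+delta`` log2 units in that subtype; the sets
    are disjoint.  ``calibration`` holds the per-sample affine distortion
    ``(a_i, b_i)`` that variance-stabilising normalisation must undo.
    """

    signature_membership: dict[str, list[str]]
    delta: float
    calibration: dict[str, tuple[float, float]]
    sigma_add: float
    sigma_mult: float
    m0: float
    slope: float
    protein_log2_mu: pd.Series = field(repr=False)
    subtype_log2_profiles: pd.DataFrame = field(repr=False)
    background_proteins: list[str] = field(default_factory=list)
    healthy_proteins: list[str] = field(default_factory=list)
    patient_mixtures: dict[str, dict[str, float]] = field(default_factory=dict)

    def members_of(self, subtype: Subtype | str) -> set[str]:
        return set(self.signature_membership.get(Subtype(subtype).value, []))


def default_design(n_replicates: int = 2) -> SampleDesign:
    """Nine cell lines x ``n_replicates`` EV isolations in three subtypes."""
    rows = []
    for subtype, lines in DEFAULT_PANEL.items():
        for line in lines:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{line}_{rep}",
                        "cell_line": line,
                        "subtype": subtype.value,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cellline_cohort(
    design: SampleDesign | None = None,
    n_proteins: int = 2000,
    n_signature: int = 150,
    delta: float = 1.5,
    peptides_per_protein: float = 4.0,
    sigma_add: float = 30.0,
    sigma_mult: float = 0.15,
    calibration: dict[str, tuple[float, float]] | None = None,
    m0: float = 7.0,
    slope: float = 1.0,
    log2_abundance: tuple[float, float] = (10.0, 1.5),
    peptide_spread: float = 0.7,
    seed: int = 0,
) -> tuple[PeptideTable, SyntheticTruth]:
    """Simulate a peptide-level cell-line cohort with known truth.

    Parameters
    ----------
    n_signature
        Number of subtype-marker proteins per subtype (disjoint sets), each
        shifted ``+delta`` log2 units in its subtype's samples.
    peptides_per_protein
        Poisson mean; every protein gets ``Poisson(lambda) + 1`` peptides.
    calibration
        Optional per-sample ``(a_i, b_i)`` affine distortion; defaults to the
        identity ``(0, 1)`` for every sample.
    m0, slope
        Logistic detection midpoint (log2 intensity at 50% detection) and
        scale; ``m0 = -inf`` disables censoring, ``slope = 0`` makes the
        threshold hard.
    """
    if design is None:
        design = default_design()
    if n_proteins < 50:
        raise ValueError("n_proteins must be >= 50")
    if peptides_per_protein <= 0:
        raise ValueError("peptides_per_protein (Poisson mean) must be > 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if 3 * n_signature > n_proteins:
        raise ValueError("signature sets exceed the proteome")

    rng = substream(seed, "cellline")
    samples = design.sample_ids
    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]

    # disjoint subtype marker sets
    order = rng.permutation(n_proteins)
    membership: dict[str, list[str]] = {}
    for k, subtype in enumerate(CELL_LINE_SUBTYPES):
        idx = order[k * n_signature : (k + 1) * n_signature]
        membership[subtype.value] = sorted(proteins[i] for i in idx)

    mu = rng.normal(log2_abundance[0], log2_abundance[1], size=n_proteins)
    protein_log2_mu = pd.Series(mu, index=proteins)

    n_pep = rng.poisson(peptides_per_protein, size=n_proteins) + 1
    pep_protein = np.repeat(np.arange(n_proteins), n_pep)
    n_total = int(n_pep.sum())
    pep_ids = [
        f"{proteins[p]}_{j+1}"
        for p, cnt in zip(range(n_proteins), n_pep)
        for j in range(cnt)
    ]
    eff = rng.normal(0.0, peptide_spread, size=n_total)

    if calibration is None:
        calibration = {s: (0.0, 1.0) for s in samples}
    for s in samples:
        a_i, b_i = calibration[s]
        if b_i <= 0:
            raise ValueError(f"multiplicative factor b must be > 0 (sample {s})")

    # subtype shift matrix: protein x sample, delta where the protein marks
    # the sample's subtype
    member_code = np.zeros((n_proteins, len(samples)))
    prot_index = {p: i for i, p in enumerate(proteins)}
    for subtype in CELL_LINE_SUBTYPES:
        rows = [prot_index[p] for p in membership[subtype.value]]
        cols = [j for j, s in enumerate(samples)
                if design.subtype_of(s) is subtype]
        member_code[np.ix_(rows, cols)] = delta

    log2_level = mu[pep_protein, None] + eff[:, None] + member_code[pep_protein, :]
    level = np.exp2(log2_level)

    a = np.array([calibration[s][0] for s in samples])
    b = np.array([calibration[s][1] for s in samples])
    eta = rng.normal(0.0, sigma_mult, size=level.shape) if sigma_mult > 0 else 0.0
    eps = rng.normal(0.0, sigma_add, size=level.shape) if sigma_add > 0 else 0.0
    x = a[None, :] + b[None, :] * np.exp(eta) * level + eps

    positive = x > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log2x = np.where(positive, np.log2(np.where(positive, x, 1.0)), -np.inf)
    if np.isneginf(m0):
        p_det = np.where(positive, 1.0, 0.0)
    elif slope == 0:
        p_det = np.where(positive & (log2x >= m0), 1.0, 0.0)
    else:
        p_det = np.where(positive, _logistic((log2x - m0) / slope), 0.0)
    detected = rng.random(size=x.shape) < p_det
    x = np.where(detected, x, 0.0)

    table = PeptideTable(
        protein_ids=pd.Series([proteins[p] for p in pep_protein], index=pep_ids),
        intensities=pd.DataFrame(x, index=pep_ids, columns=samples),
        detected=pd.DataFrame(detected, index=pep_ids, columns=samples),
    )
    profiles = pd.DataFrame(
        {
            st.value: mu + np.where(
                np.isin(proteins, membership[st.value]), delta, 0.0
            )
            for st in CELL_LINE_SUBTYPES
        },
        index=proteins,
    )
    truth = SyntheticTruth(
        signature_membership=membership,
        delta=delta,
        calibration={s: tuple(calibration[s]) for s in samples},
        sigma_add=sigma_add,
        sigma_mult=sigma_mult,
        m0=m0,
        slope=slope,
        protein_log2_mu=protein_log2_mu,
        subtype_log2_profiles=profiles,
    )
    return table, truth


def simulate_patient_cohort(
    truth: SyntheticTruth,
    n_patients: int = 27,
    mixtures: dict[str, dict[str, float]] | None = None,
    n_background: int = 300,
    background_boost: float = 2.0,
    healthy_extra_fraction: float = 0.4,
    detect_m0: float = 7.5,
    detect_slope: float = 0.5,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ProteinMatrix, SyntheticTruth]:
    """Simulate a plasma patient cohort as mixtures of subtype profiles.

    Each patient's log2 profile is ``sum_s w_s * profile_s + w_bg * bg`` with
    simplex weights over the three subtypes plus a plasma-background
    component, then i.i.d. Gaussian noise.  Background proteins (boosted in
    the ``bg`` profile) are a subset of the healthy-plasma list by
    construction; the healthy list additionally contains a random fraction of
    the whole proteome, mimicking abundant proteins seen in non-cancer
    controls.  Proteins fall out of the patient matrix by a logistic
    detection rule on their mixed abundance, so the patient cohort covers
    only part of the cell-line proteome.

    Returns the patient matrix (scale LOG2) and the truth updated in place
    with mixtures, background and healthy lists.
    """
    rng = substream(seed, "patient")
    proteins = list(truth.protein_log2_mu.index)
    marker = set().union(*truth.signature_membership.values())
    non_marker = [p for p in proteins if p not in marker]
    if n_background > len(non_marker):
        raise ValueError("n_background exceeds available non-marker proteins")
    background = sorted(
        rng.choice(non_marker, size=n_background, replace=False).tolist()
    )
    extra = rng.choice(
        proteins,
        size=int(healthy_extra_fraction * len(proteins)),
        replace=False,
    ).tolist()
    healthy = sorted(set(background) | set(extra))

    components = [s.value for s in CELL_LINE_SUBTYPES] + ["background"]
    if mixtures is None:
        ids = [f"PT{i:02d}" for i in range(1, n_patients + 1)]
        w = rng.dirichlet(np.full(4, 1.5), size=n_patients)
        mixtures = {pid: dict(zip(components, map(float, wi))) for pid, wi in zip(ids, w)}
    else:
        ids = list(mixtures)
        for pid, wts in mixtures.items():
            w = np.array([wts.get(c, 0.0) for c in components])
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {pid} are off the simplex")

    bg_profile = truth.protein_log2_mu.copy()
    bg_profile.loc[background] += background_boost

    profs = truth.subtype_log2_profiles
    data = np.empty((len(proteins), len(ids)))
    for j, pid in enumerate(ids):
        wts = mixtures[pid]
        mix = sum(
            wts.get(s.value, 0.0) * profs[s.value].to_numpy()
            for s in CELL_LINE_SUBTYPES
        ) + wts.get("background", 0.0) * bg_profile.to_numpy()
        data[:, j] = mix + rng.normal(0.0, sigma, size=len(proteins))

    mean_level = data.mean(axis=1)
    p_det = _logistic((mean_level - detect_m0) / detect_slope)
    keep = rng.random(len(proteins)) < p_det

    matrix = ProteinMatrix(
        values=pd.DataFrame(
            data[keep], index=np.array(proteins)[keep], columns=ids
        ),
        scale=Scale.LOG2,
    )
    truth.background_proteins = background
    truth.healthy_proteins = healthy
    truth.patient_mixtures = mixtures
    return matrix, truth


def simulate_ne_reference_cohort(
    n_genes: int = 50,
    n_high: int = 4,
    n_background: int = 20,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[ProteinMatrix, SignatureCollection, list[str]]:
    """Cohort for exercising the correlation-based neuroendocrine score.

    A gene-wise reference profile is drawn N(0, 1); "NE-high" samples equal
    the reference plus small noise while background samples are independent
    standard-normal profiles, so the NE-high group should correlate strongly
    with the reference and the background should sit near zero.  Returns the
    matrix (scale LOG2), a single-set signature collection carrying the
    reference profile, and the NE-high sample ids.
    """
    rng = substream(seed, "ne-reference")
    genes = [f"NE{i:03d}" for i in range(1, n_genes + 1)]
    ref = pd.Series(rng.normal(0.0, 1.0, n_genes), index=genes)
    high_ids = [f"NEHIGH_{i}" for i in range(1, n_high + 1)]
    bg_ids = [f"BG_{i}" for i in range(1, n_background + 1)]
    cols = {}
    for s in high_ids:
        cols[s] = ref.to_numpy() + rng.normal(0.0, noise, n_genes)
    for s in bg_ids:
        cols[s] = rng.normal(0.0, 1.0, n_genes)
    matrix = ProteinMatrix(
        pd.DataFrame(cols, index=genes), Scale.LOG2
    )
    signature = SignatureCollection({"NE_SET": genes}, reference_profile=ref)
    return matrix, signature, high_ids


def truth_signatures(truth: SyntheticTruth) -> SignatureCollection:
    """The true subtype marker sets as a signature collection (GMT-ready)."""
    return SignatureCollection(
        {f"TRUE_{k}": list(v) for k, v in truth.signature_membership.items()}
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "signature_membership": truth.signature_membership,
        "delta": truth.delta,
        "calibration": {k: list(v) for k, v in truth.calibration.items()},
        "sigma_add": truth.sigma_add,
        "sigma_mult": truth.sigma_mult,
        "m0": truth.m0,
        "slope": truth.slope,
        "protein_log2_mu": truth.protein_log2_mu.to_dict(),
        "subtype_log2_profiles": truth.subtype_log2_profiles.to_dict(),
        "background_proteins": truth.background_proteins,
        "healthy_proteins": truth.healthy_proteins,
        "patient_mixtures": truth.patient_mixtures,
    }
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=False))


def read_truth(path: str | Path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        signature_membership=d["signature_membership"],
        delta=d["delta"],
        calibration={k: tuple(v) for k, v in d["calibration"].items()},
        sigma_add=d["sigma_add"],
        sigma_mult=d["sigma_mult"],
        m0=d["m0"],
        slope=d["slope"],
        protein_log2_mu=pd.Series(d["protein_log2_mu"]),
        subtype_log2_profiles=pd.DataFrame(d["subtype_log2_profiles"]),
        background_proteins=d["background_proteins"],
        healthy_proteins=d["healthy_proteins"],
        patient_mixtures=d["patient_mixtures"],
    )
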