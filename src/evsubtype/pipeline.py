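"""End-to-end orchestration of the EV subtyping analysis.

Stage order is fixed by the method: simulate/load -> impute -> aggregate ->
VSN -> detection/overlap -> clustering/PCA -> signature scores -> volcano
contrasts -> GSEA -> ternary fractions -> patient signatures.  A single
master seed feeds named substreams so that adding or removing a stage never
shifts the randomness of the others, and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import gsea as gsea_mod
from . import preprocess, scoring, synthetic
from .io_formats import (
    RunConfig,
    SignatureCollection,
    Subtype,
    write_design,
    write_gene_list,
    write_gmt,
    write_peptide_table,
    write_protein_matrix,
)
from .synthetic import substream, truth_signatures, write_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline", "make_fixture"]


@dataclass
class PipelineReport:
    """Serialisable summary of one pipeline run."""

    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    ne_scores: pd.DataFrame | None = None
    patient_scores: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {"config": self.config, "stages": self.stages}
        if self.scores is not None:
            payload["scores"] = self.scores.round(6).to_dict()
        if self.ne_scores is not None:
            payload["ne_scores"] = self.ne_scores.round(6).to_dict()
        if self.patient_scores is not None:
            payload["patient_scores"] = self.patient_scores.round(6).to_dict()
        return json.dumps(payload, indent=1, sort_keys=True)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    n_proteins: int = 2000,
    n_signature: int = 150,
    delta: float = 1.5,
    n_patients: int = 27,
    n_decoy_sets: int = 50,
) -> PipelineReport:
    """Run the full analysis on a simulated cohort and write a report.

    This is the simulate-enabled driver used by the CLI ``run`` subcommand
    and the test fixture; file-based inputs go through the individual stage
    commands instead.
    """
    report = PipelineReport(config=config.to_dict())
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    design = synthetic.default_design()
    peptides, truth = synthetic.simulate_cellline_cohort(
        design, n_proteins=n_proteins, n_signature=n_signature, delta=delta,
        seed=config.seed,
    )
    n_background = min(300, (n_proteins - 3 * n_signature) // 2)
    patients, truth = synthetic.simulate_patient_cohort(
        truth, n_patients=n_patients, n_background=n_background, seed=config.seed
    )
    report.stages["simulate"] = {
        "n_peptides": int(peptides.intensities.shape[0]),
        "n_proteins": n_proteins,
        "n_samples": len(design.sample_ids),
        "n_patients": patients.values.shape[1],
        "censored_cells": peptides.n_missing(),
    }

    # --- preprocess -------------------------------------------------------
    imputed = preprocess.impute_missing(peptides, config)
    linear = preprocess.aggregate_proteins(imputed, config)
    glog, calib = preprocess.vsn_normalize(linear, trim=config.vsn_trim)
    detections = preprocess.detection_call(peptides, config)
    report.stages["preprocess"] = {
        "imputed_cells": peptides.n_missing(),
        "proteins_quantified": int(linear.values.shape[0]),
        "proteins_dropped": int(n_proteins - linear.values.shape[0]),
        "vsn_iterations": calib.iterations,
        "vsn_scales": calib.scales.round(4).to_dict(),
    }

    # --- structure --------------------------------------------------------
    venn = scoring.overlap_counts(detections, design)
    tree = scoring.hierarchical_cluster(glog, axis="samples")
    pca = scoring.pca_project(glog)
    report.stages["structure"] = {
        "core_proteins": len(venn.core),
        "core_percent": round(venn.core_percent, 1),
        "subtype_set_sizes": {k: len(v) for k, v in venn.subtype_sets.items()},
        "leaf_order": tree.leaf_order,
        "explained_variance": [round(float(v), 4) for v in
                               pca.explained_variance[:5]],
    }

    # --- signature scores -------------------------------------------------
    signatures = truth_signatures(truth)
    score_table = scoring.score_signatures(glog, signatures, design)
    # NE reference profile: mean z-scored glog level of the NE+ isolations
    # over the NE set genes — the cohort-internal analogue of correlating
    # against a published NEPC meta-profile.
    ne_name = f"TRUE_{Subtype.AR_NEG_NE_POS.value}"
    ne_found = [g for g in signatures[ne_name] if g in glog.protein_ids]
    zvals = glog.values.loc[ne_found]
    zvals = zvals.sub(zvals.mean(axis=1), axis=0).div(
        zvals.std(axis=1, ddof=1), axis=0
    )
    ne_ref = zvals[design.samples_of(Subtype.AR_NEG_NE_POS)].mean(axis=1)
    ne_sig = SignatureCollection(
        {ne_name: signatures[ne_name]}, reference_profile=ne_ref
    )
    ne_scores = scoring.correlation_ne_score(
        glog, ne_sig, ne_name, method=config.ne_correlation
    )
    report.scores = score_table.scores
    report.ne_scores = ne_scores.scores
    report.stages["scores"] = {
        "coverage": {k: list(v) for k, v in score_table.coverage.items()},
        "degenerate": score_table.degenerate,
    }

    # --- differential + GSEA ---------------------------------------------
    diff_by_subtype: dict[Subtype, pd.DataFrame] = {}
    gsea_summary = {}
    for subtype, contrast in diff.SUBTYPE_CONTRAST.items():
        res = diff.differential_enrichment(glog, design, contrast, config)
        diff_by_subtype[subtype] = res
        ranked = gsea_mod.signal2noise_rank(glog, design, contrast)
        decoys = _decoy_collection(
            signatures, subtype, ranked, n_decoy_sets, config.seed
        )
        gsea_res = gsea_mod.permutation_test(ranked, decoys, config)
        planted = f"TRUE_{subtype.value}"
        by_nes = sorted(gsea_res, key=lambda r: -r.nes)
        gsea_summary[contrast] = {
            "n_significant": int(res["significant"].sum()),
            "planted_set_nes_rank": 1 + [r.set_name for r in by_nes].index(planted),
            "planted_set_p": next(
                r.p_value for r in gsea_res if r.set_name == planted
            ),
        }
    report.stages["gsea"] = gsea_summary

    # --- ternary ----------------------------------------------------------
    ternary = diff.ternary_fractions(linear, design)
    report.stages["ternary"] = {
        "n_proteins": int(ternary.fractions.shape[0]),
        "n_excluded": len(ternary.excluded),
        "grid_levels": ternary.grid_levels,
    }

    # --- patient signatures ----------------------------------------------
    shared, cell_only, patient_only = scoring.cohort_overlap(glog, patients)
    sig = diff.derive_subtype_signatures(
        diff_by_subtype, patients, truth.healthy_proteins, config
    )
    patient_scores = diff.patient_subtype_score(
        patients, sig, method=config.patient_score
    )
    report.patient_scores = patient_scores
    report.stages["patient"] = {
        "overlap": len(shared),
        "cellline_only": len(cell_only),
        "patient_only": len(patient_only),
        "signature_counts": {k: list(v) for k, v in sig.counts.items()},
    }

    if outdir is not None:
        write_design(design, outdir / "design.tsv")
        write_peptide_table(peptides, outdir / "peptides.tsv")
        write_protein_matrix(linear, outdir / "protein_linear.tsv")
        write_protein_matrix(glog, outdir / "protein_glog.tsv")
        write_protein_matrix(patients, outdir / "patients.tsv")
        write_gmt(signatures, outdir / "signatures.gmt")
        write_gene_list(truth.healthy_proteins, outdir / "healthy.txt")
        write_truth(truth, outdir / "truth.json")
        score_table.scores.to_csv(outdir / "scores.tsv", sep="\t")
        patient_scores.to_csv(outdir / "patient_scores.tsv", sep="\t")
        for subtype, res in diff_by_subtype.items():
            res.to_csv(outdir / f"volcano_{subtype.value}.tsv", sep="\t")
        ternary.fractions.to_csv(outdir / "ternary.tsv", sep="\t")
        (outdir / "report.json").write_text(report.to_json())
    return report


def _decoy_collection(
    signatures: SignatureCollection,
    subtype: Subtype,
    ranked: "gsea_mod.RankedList",
    n_decoys: int,
    seed: int,
) -> SignatureCollection:
    """The planted subtype set plus size-matched random decoy sets."""
    planted = f"TRUE_{subtype.value}"
    genes = np.array(ranked.genes)
    rng = substream(seed, f"decoys:{planted}")
    size = len(signatures[planted])
    sets = {planted: signatures[planted]}
    for i in range(n_decoys):
        sets[f"DECOY_{i:03d}"] = sorted(
            genes[rng.choice(len(genes), size=size, replace=False)].tolist()
        )
    return SignatureCollection(sets)


def make_fixture(
    outdir: str | Path,
    tiny: bool = True,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a small self-consistent input bundle for tests and demos.

    The bundle holds peptide table, design, true-signature GMT, healthy-plasma
    list, patient matrix and the JSON ground truth, all generated from the
    named substreams of ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_proteins, n_signature = (200, 20) if tiny else (2000, 150)
    design = synthetic.default_design()
    peptides, truth = synthetic.simulate_cellline_cohort(
        design, n_proteins=n_proteins, n_signature=n_signature, seed=seed
    )
    patients, truth = synthetic.simulate_patient_cohort(
        truth, n_patients=9 if tiny else 27, n_background=30 if tiny else 300,
        seed=seed,
    )
    paths = {
        "design": outdir / "design.tsv",
        "peptides": outdir / "peptides.tsv",
        "signatures": outdir / "signatures.gmt",
        "healthy": outdir / "healthy.txt",
        "patients": outdir / "patients.tsv",
        "truth": outdir / "truth.json",
    }
    write_design(design, paths["design"])
    write_peptide_table(peptides, paths["peptides"])
    write_gmt(truth_signatures(truth), paths["signatures"])
    write_gene_list(truth.healthy_proteins, paths["healthy"])
    write_protein_matrix(patients, paths["patients"])
    write_truth(truth, paths["truth"])
    return paths
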