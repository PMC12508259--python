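import pandas as pd
import pytest

import evsubtype as ev
from evsubtype.io_formats import RunConfig

#: master seed of the test suite; every stochastic fixture derives from it
SEED = 20250917 % (2**31)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale synthetic cohort: 9 lines x 2 reps, 2000 proteins,
    150 markers per subtype at +1.5 log2 — preprocessed once per session."""
    cfg = RunConfig(seed=SEED)
    design = ev.default_design()
    peptides, truth = ev.simulate_cellline_cohort(design, seed=SEED)
    imputed = ev.impute_missing(peptides, cfg)
    linear = ev.aggregate_proteins(imputed, cfg)
    glog, calib = ev.vsn_normalize(linear)
    return {
        "config": cfg,
        "design": design,
        "peptides": peptides,
        "truth": truth,
        "linear": linear,
        "glog": glog,
        "calib": calib,
    }


@pytest.fixture(scope="session")
def patient_cohort(study_cohort):
    matrix, truth = ev.simulate_patient_cohort(
        study_cohort["truth"], seed=SEED
    )
    return {"matrix": matrix, "truth": truth}


@pytest.fixture(scope="module")
def small_cohort():
    """300-protein cohort for cheap per-module checks."""
    cfg = RunConfig(seed=SEED + 1)
    design = ev.default_design()
    peptides, truth = ev.simulate_cellline_cohort(
        design, n_proteins=300, n_signature=30, seed=SEED + 1
    )
    return {"config": cfg, "design": design, "peptides": peptides, "truth": truth}


@pytest.fixture()
def toy_peptides():
    """Hand-built 6-peptide, 3-sample table: P1 has 3 peptides, P2 has 2,
    P3 has 1 (dropped by the 2-peptide rule); one censored cell."""
    ids = ["pep1", "pep2", "pep3", "pep4", "pep5", "pep6"]
    proteins = pd.Series(["P1", "P1", "P1", "P2", "P2", "P3"], index=ids)
    inten = pd.DataFrame(
        {
            "s1": [100.0, 200.0, 300.0, 40.0, 60.0, 10.0],
            "s2": [110.0, 210.0, 0.0, 44.0, 66.0, 11.0],
            "s3": [90.0, 190.0, 310.0, 36.0, 54.0, 9.0],
        },
        index=ids,
    )
    detected = inten > 0
    return ev.PeptideTable(proteins, inten, detected)


@pytest.fixture()
def toy_design():
    return ev.SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "cell_line": ["A", "B", "C"],
                "subtype": ["AR_POS", "AR_NEG_NE_POS", "AR_NEG_NE_NEG"],
                "replicate": [1, 1, 1],
            }
        )
    )
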