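"""Shared fixtures: small synthetic cohorts built once per session."""

import numpy as np
import pandas as pd
import pytest

from xenoplasma import normalize, screen, synthetic


@pytest.fixture(scope="session")
def nsclc_truth():
    design = synthetic.nsclc_design(seed=11)
    return design, synthetic.make_truth(design.cell_lines, n_analytes=200,
                                        seed=11)


@pytest.fixture(scope="session")
def nsclc_raw(nsclc_truth):
    """Raw (artifact-laden, noisy) two-line NSCLC cohort at default SNR."""
    design, truth = nsclc_truth
    samples, _ = synthetic.generate_cohort(design)
    dataset = synthetic.generate_rfu(truth, samples, seed=11)
    return design, truth, dataset


@pytest.fixture(scope="session")
def nsclc_normalized(nsclc_raw):
    design, truth, dataset = nsclc_raw
    normalized, factors = normalize.normalize_pipeline(
        dataset, truth.hyb_reference, truth.calibrator_reference)
    return design, truth, normalized, factors


@pytest.fixture(scope="session")
def nsclc_screens(nsclc_normalized):
    """Per-group screen results plus the control screen."""
    design, truth, normalized, _ = nsclc_normalized
    screens = {
        group: screen.screen_group(normalized, group)
        for group in ("H1650", "H1975", "control")
    }
    return design, truth, normalized, screens


def make_noiseless_dataset(volumes, analytes, line="H1650", seed=0):
    """Tiny hand-held dataset: given volumes, given AnalyteTruth rows,
    no noise, no artifacts — for exact arithmetic checks."""
    samples = pd.DataFrame({
        "AnimalId": [f"a{i}" for i in range(len(volumes))],
        "Group": line,
        "CellLine": line,
        "StudyDay": list(range(len(volumes))),
        "PlateId": "P1",
        "SampleType": "study",
        "TumorVolume_mm3": volumes,
    }, index=pd.Index([f"s{i}" for i in range(len(volumes))],
                      name="SampleId"))
    hyb_ref = pd.Series(np.logspace(2, 4.5, 12),
                        index=[f"hce.{j:02d}" for j in range(12)])
    truth = synthetic.TruthLedger(
        {t.analyte_id: t for t in analytes}, hyb_ref,
        pd.Series({t.analyte_id: t.baseline for t in analytes}))
    dataset = synthetic.generate_rfu(truth, samples, seed=seed,
                                     include_noise=False,
                                     include_artifacts=False)
    return truth, dataset
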