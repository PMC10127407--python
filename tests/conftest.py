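import numpy as np
import pytest

from woundstage.io_formats import ExpressionDataset
from woundstage.pipeline import PipelineConfig, run_pipeline_data
from woundstage.synthdata import CohortSpec, generate_cohort

TIMES8 = np.array([0.0, 6.0, 12.0, 24.0, 72.0, 120.0, 168.0, 240.0])


def make_dataset(
    values,
    gene_ids=None,
    timepoints=None,
    dataset_id="toy",
    species="mouse",
    time_intervals=None,
):
    """ExpressionDataset from a (gene, time, replicate) array-like."""
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(values.shape[0])]
    if timepoints is None:
        timepoints = np.array([0.0] + [6.0 * (j + 1) for j in range(values.shape[1] - 1)])
    return ExpressionDataset(
        dataset_id=dataset_id,
        species=species,
        gene_ids=list(gene_ids),
        timepoints_h=np.asarray(timepoints, dtype=float),
        intensities=values,
        time_intervals_h=time_intervals,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (the study conditions), generated once."""
    spec = CohortSpec(seed=0)
    datasets, ortholog_map, truth = generate_cohort(spec)
    return spec, datasets, ortholog_map, truth


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Full pipeline result on the default cohort."""
    spec, datasets, ortholog_map, truth = default_cohort
    roles = {ds.dataset_id: "train" for ds in datasets}
    config = PipelineConfig(datasets=[], top_k=spec.n_signature, seed=0)
    result = run_pipeline_data(datasets, roles, ortholog_map, config)
    return spec, datasets, ortholog_map, truth, result
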