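import numpy as np
import pandas as pd
import pytest

from plfcs.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small disease cohort with hub-proportional loss (20 regions)."""
    spec = CohortSpec(
        n_regions=20,
        n_subjects={"NC": 5, "MCI": 5, "AD": 5},
        n_timepoints=120,
        hub_exponent=2.0,
        loss_coefficient={"NC": 0.0, "MCI": 0.2, "AD": 0.4},
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture
def toy_atlas_files(tmp_path):
    """Two-region 2x2x2 atlas volume + region table + reference mask on disk."""
    import nibabel as nib

    vol = np.zeros((2, 2, 2), dtype=np.int16)
    vol[0, :, :] = 1
    vol[1, :, :] = 2
    label_path = tmp_path / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(vol, np.eye(4)), label_path)
    table = pd.DataFrame(
        {"label_id": [1, 2], "name": ["A", "B"], "hemisphere": ["L", "R"]}
    )
    table_path = tmp_path / "regions.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    return {"label": label_path, "table": table_path, "volume": vol, "tmp": tmp_path}
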