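import numpy as np
import pytest

from radstab.volume import RoiMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_roi(rng):
    """Small random volume + ball mask (< 10^3 masked voxels)."""
    shape = (10, 12, 12)
    zz, yy, xx = np.meshgrid(np.arange(shape[0]) - 4.5,
                             np.arange(shape[1]) - 5.5,
                             np.arange(shape[2]) - 5.5, indexing="ij")
    mask = (zz**2 + yy**2 + xx**2) <= 4.5**2
    arr = rng.uniform(0.0, 2048.0, size=shape)
    return VolumeGrid(arr, (1.0, 1.0, 1.0)), RoiMask(mask, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def benchmark_cv_reports():
    """Fivefold CV reports of the constructed-truth stability benchmark,
    three seeds; shared by generalizability tests."""
    from radstab.evaluation import CVPlan, run_cv
    from radstab.stability import joint_partition
    from radstab.synthetic import stability_benchmark_panel

    reports = []
    for seed in (0, 1, 2):
        tables = stability_benchmark_panel(n_subjects=400, seed=seed)
        partition, _ = joint_partition(tables)
        ref = tables["S2"]
        test_ids = set(ref["nodule_id"][300:])
        trainval = ref[~ref["nodule_id"].isin(test_ids)].reset_index(drop=True)
        test_tables = {
            sid: df[df["nodule_id"].isin(test_ids)].reset_index(drop=True)
            for sid, df in tables.items()
        }
        reports.append(run_cv(trainval, test_tables, partition,
                              CVPlan(n_folds=5, seed=seed)))
    return reports
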