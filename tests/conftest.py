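"""Shared fixtures: small rendered cohorts and derived artifacts."""

import numpy as np
import pytest

import tmenet as tm


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients, two 128x128 cores each, planted hot/cold structure."""
    cfg = tm.two_class_config(n_patients=6, core_size=128, seed=11)
    cores, table, gt = tm.generate_cohort(cfg)
    return cfg, cores, table, gt


@pytest.fixture(scope="session")
def small_patchsets(small_cohort):
    _, cores, table, _ = small_cohort
    return tm.build_patchsets(cores, table, d=64)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, small_patchsets):
    _, _, table, _ = small_cohort
    return tm.assemble_dataset(small_patchsets, table)


def grid_patchset(rows, cols, d=8, seed=0, patient="pt", n_cores=1):
    """A synthetic PatchSet on a rows x cols grid with random embeddings."""
    rng = np.random.default_rng(seed)
    coords, embs = [], []
    shapes = []
    for k in range(n_cores):
        for r in range(rows):
            for c in range(cols):
                coords.append((k, r, c))
                embs.append(rng.normal(size=d))
        shapes.append((rows, cols))
    return tm.PatchSet(patient_id=patient, embeddings=np.array(embs),
                       coords=np.array(coords, dtype=int),
                       core_ids=[f"{patient}_{k}" for k in range(n_cores)],
                       grid_shapes=shapes)
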