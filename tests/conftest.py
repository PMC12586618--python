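import numpy as np
import pandas as pd
import pytest

import artikin as ak
from artikin.synth import CohortDesign, GestureArchetype


@pytest.fixture(scope="session")
def small_cohort():
    """Small single-archetype-per-group cohort (fast, deterministic)."""
    design = CohortDesign(
        n_subjects_per_group={"AWS": 3, "FS": 3},
        n_repetitions=3,
        n_frames_mean=40,
        duration_jitter_sd=2.0,
        group_archetypes={
            "AWS": (GestureArchetype(ttr_amp=1.4, ttr_shift=3.0),),
            "FS": (GestureArchetype(),),
        },
        seed=11,
    )
    return ak.gen_trajectories(design)


@pytest.fixture(scope="session")
def small_tset(small_cohort):
    return ak.assemble(small_cohort.data)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noiseless rendered trial per group plus its ground truth."""
    design = CohortDesign(
        n_subjects_per_group={"AWS": 1, "FS": 1},
        n_repetitions=1,
        n_frames_mean=30,
        duration_jitter_sd=0.0,
        seed=5,
    )
    bundle = ak.gen_trajectories(design)
    spec = ak.PhantomSpec()
    seqs, truth = ak.render_phantom(bundle, spec)
    return seqs, truth, spec


def make_trajectory_table(curves: dict, site: str = "LA") -> pd.DataFrame:
    """Long trajectory table from {(subject, group, repetition): 1-D array}."""
    rows = []
    for (subj, grp, rep), y in curves.items():
        y = np.asarray(y, dtype=float)
        rows.append(
            pd.DataFrame(
                {"subject": subj, "group": grp, "repetition": rep, "site": site,
                 "frame": np.arange(y.size), "width_px": y}
            )
        )
    return pd.concat(rows, ignore_index=True)
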