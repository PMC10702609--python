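import numpy as np
import pytest
from hypothesis import settings

import strucnet as sn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atlas():
    return sn.packaged_atlas()


@pytest.fixture(scope="session")
def toy_atlas(tmp_path_factory):
    """Six-region bilateral toy atlas (3 per hemisphere)."""
    p = tmp_path_factory.mktemp("atlas") / "toy.tsv"
    rows = ["name\tabbreviation\themisphere",
            "alpha\tA\tL", "beta\tB\tL", "gamma\tC\tL",
            "alpha\tRA\tR", "beta\tRB\tR", "gamma\tRC\tR"]
    p.write_text("\n".join(rows) + "\n")
    return sn.load_atlas(p, expect_regions=None)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (9 WT / 10 KO), fixed seed."""
    return sn.generate_cohort(sn.CohortConfig(rng_seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """Exchangeable-groups cohort (no knockout effect), fixed seed."""
    return sn.generate_cohort(sn.CohortConfig(rng_seed=11).null())


def toy_subject(counts, atlas, group="WT", subject_id="t1"):
    c = np.asarray(counts)
    return sn.SubjectConnectome(subject_id=subject_id, group=group, counts=c)
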