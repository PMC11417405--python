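import numpy as np
import pandas as pd
import pytest

from corec.clusters import TFCluster, TFClusterSet
from corec.motifs import CorecPPM, MotifStrengthScore
from corec.synthetic import random_reference_motifs, synthetic_design
from corec.types import ZProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240821)


@pytest.fixture(scope="session")
def small_refs():
    return random_reference_motifs(6, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_design(small_refs):
    return synthetic_design(small_refs, n_background=60, rng=np.random.default_rng(7))


def make_zprofile(zmap: dict, meta: dict | None = None) -> ZProfile:
    s = pd.Series(zmap, dtype=float)
    return ZProfile(z=s, log_f=s.copy(), background=None, meta=dict(meta or {}))


def make_ppm(P, ppm_id="q", probeset_id="ps", ms=5.0, beta=1.0, meta=None) -> CorecPPM:
    return CorecPPM(id=ppm_id, probeset_id=probeset_id, P=np.asarray(P, float),
                    beta=beta, ms=MotifStrengthScore(ms, ()), meta=dict(meta or {}))


def singleton_clusters(refs) -> TFClusterSet:
    return TFClusterSet([TFCluster(f"C{i + 1:03d}", r.id, (r.id,))
                         for i, r in enumerate(refs)])


def random_ppm_matrix(rng, L):
    m = rng.dirichlet(np.ones(4), size=L)
    return m / m.sum(axis=1, keepdims=True)
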