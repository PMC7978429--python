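import numpy as np
import pandas as pd
import pytest

import archolimb as al
from archolimb import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210319)


@pytest.fixture(scope="session")
def default_limb():
    """Synthetic limb with the full default recipe set + sidecar truth."""
    params = sim.LimbGenParams(recipes=sim.DEFAULT_RECIPES)
    return sim.generate_limb(params)


@pytest.fixture(scope="session")
def study_tree():
    return al.study_tree()


@pytest.fixture(scope="session")
def four_taxon_tree():
    """4 tips, pendant lengths (1, 2, 1, 3), internal edges (1, 2)."""
    return al.read_tree("((A:1.0,B:2.0)N1:1.0,(C:1.0,D:3.0)N2:2.0)R;")


def sphere_samples(center, radius, n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


def cylinder_samples(axis_point, axis_dir, radius, half_length, n, rng):
    w = np.asarray(axis_dir, float)
    w = w / np.linalg.norm(w)
    ref = np.array([1.0, 0, 0]) if abs(w[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    phi = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-half_length, half_length, n)
    return (
        np.asarray(axis_point)
        + radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        + z[:, None] * w
    )


@pytest.fixture(scope="session")
def synthetic_ace_tables(rng):
    """Deterministic (MTU x node) tables in all five families, with a mix of
    constant, trending and sign-switching muscles."""
    nodes = list(al.phylo.STUDY_NODES)
    k = np.arange(len(nodes))
    tables = {}
    gen = np.random.default_rng(7)
    for family, (joint, dof) in al.tables.FAMILIES.items():
        mtus = {
            "hip": al.muscles.HIP_MTUS,
            "knee": al.muscles.KNEE_MTUS,
            "ankle": al.muscles.ANKLE_MTUS,
        }[joint]
        rows = {}
        for i, m in enumerate(mtus):
            base = gen.uniform(0.02, 0.3) * (1 if i % 2 else -1)
            trend = gen.uniform(-0.4, 0.4)
            rows[m] = base * (1 + trend * k / k[-1]) + gen.normal(
                0, 0.002, len(nodes)
            )
        df = pd.DataFrame(rows, index=nodes).T
        df.index.name = "MTU"
        tables[family] = df
    return tables
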