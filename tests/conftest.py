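import numpy as np
import pandas as pd
import pytest

from surfwave.icosphere import icosphere


@pytest.fixture(scope="session")
def ico2():
    return icosphere(2).mesh


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3).mesh


@pytest.fixture(scope="session")
def torus_mesh():
    """Genus-1 triangulated torus (for topology rejection tests)."""
    nu, nv = 12, 8
    r_big, r_small = 10.0, 3.0
    verts = []
    for i in range(nu):
        a = 2 * np.pi * i / nu
        for j in range(nv):
            b = 2 * np.pi * j / nv
            verts.append([(r_big + r_small * np.cos(b)) * np.cos(a),
                          (r_big + r_small * np.cos(b)) * np.sin(a),
                          r_small * np.sin(b)])
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = i * nv + j
            b = i * nv + (j + 1) % nv
            c = ((i + 1) % nu) * nv + j
            d = ((i + 1) % nu) * nv + (j + 1) % nv
            faces += [[a, b, c], [b, d, c]]
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


@pytest.fixture(scope="session")
def template_param():
    """A small template with its conformal parameterization, shared by
    conformal/resampling tests to avoid repeated solves."""
    from surfwave.conformal import conformal_to_sphere
    from surfwave.synthetic import make_template

    template = make_template(level=3, radius=80.0, bumpiness=3.0, seed=7)
    param = conformal_to_sphere(template, puncture=0)
    return template, param


def make_feature_matrix(x, labels=None, ages=None, sexes=None):
    """Wrap a plain array as a FeatureMatrix with placeholder metadata."""
    from surfwave.features import FeatureMatrix

    x = np.asarray(x, dtype=float)
    n, p = x.shape
    ids = [f"s{i:03d}" for i in range(n)]
    xdf = pd.DataFrame(x, index=pd.Index(ids, name="id"))
    prov = pd.DataFrame({"region": ["synthetic"] * p, "level": [2] * p,
                         "vertex": range(p)})
    cov = pd.DataFrame({
        "age": ages if ages is not None else np.full(n, 30.0),
        "sex": (list(sexes) if sexes is not None
                else (["M", "F"] * (n // 2 + 1))[:n]),
    }, index=xdf.index)
    lab = pd.Series(list(labels) if labels is not None else [None] * n,
                    index=xdf.index, name="label")
    return FeatureMatrix(xdf, prov, cov, lab)
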