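"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from vertemech import (MaterialParams, SpecimenModel, human_like_spec,
                       make_vertebra_phantom, porcine_like_spec, pseudo_experiment)


@pytest.fixture(scope="session")
def human_phantom():
    """Default human-like phantom (well-separated greyscale mixture)."""
    spec = human_like_spec(seed=20)
    vol, truth = make_vertebra_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def porcine_phantom():
    """Default porcine-like phantom (overlapping greyscale mixture)."""
    spec = porcine_like_spec(seed=22)
    vol, truth = make_vertebra_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def phantom_set4():
    """Two human-like + two porcine-like phantoms with their ground truth:
    the standard small cross-species study set."""
    out = []
    for i, maker in enumerate([human_like_spec, human_like_spec,
                               porcine_like_spec, porcine_like_spec]):
        spec = maker(seed=20 + i)
        vol, truth = make_vertebra_phantom(spec)
        name = "human_like" if i < 2 else "porcine_like"
        out.append((f"{name[0]}{i}", name, spec, vol, truth))
    return out


@pytest.fixture(scope="session")
def truth_models4(phantom_set4):
    """SpecimenModel list on ground-truth fields (measured filled per law by
    the test) plus forward stiffness at k_true for the linear law."""
    k_true = 0.33
    params = MaterialParams(k=k_true, exponent=1)
    models, s_true = [], []
    for sid, species, spec, vol, truth in phantom_set4:
        _, st = pseudo_experiment(truth, params, specimen_id=sid, species=species)
        models.append(SpecimenModel(id=sid, bvtv=truth.bvtv_coarse,
                                    labels=truth.labels_coarse,
                                    measured_stiffness=st,
                                    height_mm=truth.height_mm,
                                    area_mm2=truth.area_mm2, species=species))
        s_true.append(st)
    return models, np.array(s_true), k_true
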