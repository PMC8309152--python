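"""Shared fixtures: one synthetic study and one fitted model per session."""

from types import SimpleNamespace

import pytest

import solqspr as sq


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (270 molecules, replicate histogram)."""
    return sq.generate_study(seed=7)


@pytest.fixture(scope="session")
def curated(study):
    return sq.curate(study.records, study.descriptors, strategy="mean")


@pytest.fixture(scope="session")
def fitted(curated):
    """Feature selection, scaling and a fully-trained network (seed 7)."""
    sel = sq.select_top_k(curated.X, curated.y, k=10)
    scaling = sq.fit_scaling(curated.X[sel.selected], curated.y)
    model = sq.train_mlp(scaling.transform_features(curated.X[sel.selected]),
                         scaling.transform_target(curated.y),
                         sq.MlpConfig(seed=7),
                         scaling=scaling, feature_names=sel.selected)
    return SimpleNamespace(selection=sel, scaling=scaling, model=model,
                           null=sq.null_fit(curated.y))
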