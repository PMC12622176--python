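import numpy as np
import pytest

from psymap import (ExpressionMatrix, SyntheticSpec, gen_expression,
                    gen_parcel_atlas)


@pytest.fixture(scope="session")
def atlas60():
    return gen_parcel_atlas(60, seed=11, n_missing=4)


@pytest.fixture(scope="session")
def clustered_expression(atlas60):
    """30 genes in 3 planted clusters on 56 usable parcels, moderate noise."""
    spec = SyntheticSpec(n_parcels=60, n_genes=30, n_clusters=3,
                         noise_sd=0.2, spatial_scale=15.0, seed=7)
    return gen_expression(atlas60, spec)


def make_white_expression(atlas, n_genes, seed):
    """Expression with no planted structure at all (pure white columns)."""
    rng = np.random.default_rng(seed)
    ok = atlas.nonmissing
    values = rng.standard_normal((atlas.n_parcels, n_genes))
    sub = values[ok]
    values[ok] = (sub - sub.mean(0)) / sub.std(0, ddof=1)
    values[~ok] = np.nan
    genes = tuple(f"W{i:04d}" for i in range(n_genes))
    return ExpressionMatrix(atlas=atlas, genes=genes, values=values,
                            missing_mask=~ok)


@pytest.fixture(scope="session")
def white_expression(atlas60):
    return make_white_expression(atlas60, 120, seed=5)
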