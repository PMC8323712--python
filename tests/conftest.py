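import numpy as np
import pytest

from lipomr.containers import HarmonizedPanel, SummaryStatSet, VariantAssociation


def make_panel(bx, sex, by, sey, exposures=None, **kw) -> HarmonizedPanel:
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1 and np.asarray(by).size > 1:
        bx = bx.T
    J, K = bx.shape
    sex = np.broadcast_to(np.asarray(sex, float), (J, K)).copy()
    return HarmonizedPanel(
        variant_ids=[f"rs{i+1}" for i in range(J)],
        exposure_names=exposures or [f"X{k+1}" for k in range(K)],
        bX=bx,
        seX=sex,
        bY=np.asarray(by, float),
        seY=np.asarray(sey, float),
        **kw,
    )


def make_stats(name, rows, trait_type="quantitative") -> SummaryStatSet:
    """rows: iterable of dicts with VariantAssociation fields."""
    return SummaryStatSet(name, trait_type, [VariantAssociation(**r) for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    J = 20
    bx = rng.normal(0.1, 0.03, size=J)
    sey = np.full(J, 0.05)
    by = 0.4 * bx + rng.normal(0, 0.05, size=J)
    return make_panel(bx, 0.01, by, sey)
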