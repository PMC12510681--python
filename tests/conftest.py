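import hypothesis
import pytest
from hypothesis import strategies as st

import comppart as cp

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=100
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def grassland():
    return cp.load_fixture("grassland")


@pytest.fixture(scope="session")
def trees():
    return cp.load_fixture("trees")


@pytest.fixture(scope="session")
def bromus_dactylis(grassland):
    return next(c for c in grassland if c.mixture_id == "Bromus:Dactylis")


def community_strategy(
    min_species=2, max_species=5, with_partial=True, equal_ry=False
):
    """Random valid replacement-design communities (d_total = d_full)."""

    @st.composite
    def build(draw):
        n = draw(st.integers(min_species, max_species))
        pos = st.floats(0.1, 100.0, allow_nan=False, allow_infinity=False)
        nonneg = st.floats(0.0, 100.0, allow_nan=False, allow_infinity=False)
        m_full = [draw(pos) for _ in range(n)]
        y_obs = [draw(nonneg) for _ in range(n)]
        m_partial = [draw(pos) for _ in range(n)] if with_partial else [None] * n
        if equal_ry:
            ry = [1.0 / n] * n
        else:
            raw = [draw(st.floats(0.05, 1.0)) for _ in range(n)]
            total = sum(raw)
            ry = [r / total for r in raw]
        density = draw(st.floats(1.0, 50.0))
        return cp.make_two_species_community(
            "hyp",
            m_full,
            y_obs,
            m_partial=m_partial,
            ry=ry,
            density_full=density,
            species_ids=[f"sp{i}" for i in range(n)],
        )

    return build()
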