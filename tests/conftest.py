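import numpy as np
import pytest

from greyrank import Panel, Series


@pytest.fixture
def simple_panel() -> Panel:
    """The hand-checkable 3-point panel used in the worked examples."""
    return Panel(
        Series("ref", [1.0, 2.0, 3.0]),
        (Series("down", [3.0, 2.0, 1.0]), Series("same", [1.0, 2.0, 3.0])),
    )


def random_panel(rng: np.random.Generator, m: int, n: int) -> Panel:
    """A small random panel with positive values, safe for every model."""
    ref = Series("ref", rng.uniform(0.5, 10.0, size=m))
    comps = tuple(
        Series(f"c{j}", rng.uniform(0.5, 10.0, size=m)) for j in range(1, n + 1)
    )
    return Panel(ref, comps)
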