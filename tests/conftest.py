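import pytest

import multicom as mc


@pytest.fixture
def two_triangles() -> mc.Layer:
    """Two disjoint triangles: the canonical two-community toy graph."""
    return mc.Layer.from_edges(
        "tri", [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    )


@pytest.fixture
def two_cliques_bridge() -> mc.Layer:
    """Two 4-cliques joined by one bridge edge."""
    left = ["a", "b", "c", "d"]
    right = ["e", "f", "g", "h"]
    edges = [(x, y) for grp in (left, right) for i, x in enumerate(grp) for y in grp[i + 1:]]
    edges.append(("d", "e"))
    return mc.Layer.from_edges("cliques", edges)


@pytest.fixture(scope="session")
def planted():
    """Default planted multilayer network (3 communities of 30, L=3)."""
    return mc.simulate_multilayer(seed=42)


@pytest.fixture(scope="session")
def planted_sweep(planted):
    net, _ = planted
    return mc.sweep(net, seed=42)


@pytest.fixture(scope="session")
def fine_planted():
    """8 communities of 12: planted structure survives the whole default
    grid (the community count exceeds gamma_max), enabling full-persistence
    checks at n = 8."""
    return mc.simulate_multilayer(sizes=[12] * 8, seed=0)


@pytest.fixture(scope="session")
def fine_sweep(fine_planted):
    net, _ = fine_planted
    return mc.sweep(net, seed=0)
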