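"""Shared fixtures: parameter sets, random tree/chain generators, SWC files."""

from __future__ import annotations

import numpy as np
import pytest

from cabletree import presets
from cabletree.morphology import CT, HH, ElementSpec, SWCPoint, tree_from_specs, write_swc


@pytest.fixture(scope="session")
def squid():
    return presets.classic_squid()


@pytest.fixture(scope="session")
def node_params():
    return presets.mammalian_node_params()


def random_mixed_chain(seed: int):
    """Random unbranched mixed CT/HH chain (N ≤ 100), axon-like structure.

    One of: a uniform passive chain (optionally myelinated), a uniform
    active chain, or an alternating node/internode pattern (short HH blocks
    between long myelinated CT blocks).  Element size and diameter are
    uniform along the chain, as in the stability derivation's assumptions.
    """
    rng = np.random.default_rng(seed)
    d = float(rng.uniform(0.5e-6, 2e-6))
    dx = float(rng.uniform(1e-6, 10e-6))
    kind = int(rng.integers(0, 3))
    if kind == 0:
        n_my = int(rng.integers(0, 26))
        blocks = [(CT, n_my)] * int(rng.integers(30, 101))
    elif kind == 1:
        blocks = [(HH, 0)] * int(rng.integers(30, 101))
    else:
        n_my = int(rng.integers(5, 31))
        blocks = []
        while len(blocks) < 100:
            blocks += [(HH, 0)] * int(rng.integers(2, 6))
            if len(blocks) >= 100:
                break
            blocks += [(CT, n_my)] * int(rng.integers(15, 36))
        blocks = blocks[:100]
    root = ElementSpec(mm=blocks[0][0], dx=dx, d=d, n_my=blocks[0][1], h_my=1e-8)
    tip = root
    for mm, nm in blocks[1:]:
        nxt = ElementSpec(mm=mm, dx=dx, d=d, n_my=nm, h_my=1e-8)
        tip.children.append(nxt)
        tip = nxt
    return tree_from_specs(root)


def random_tree(seed: int, n_elements: int = 40):
    """Random valid branched tree (mixed geometry) for enumeration tests."""
    rng = np.random.default_rng(seed)
    root = ElementSpec(mm=CT, dx=float(rng.uniform(1e-6, 1e-5)),
                       d=float(rng.uniform(5e-7, 5e-6)))
    nodes = [root]
    for _ in range(n_elements - 1):
        # attach to any spec with < 2 children (root limited to 1)
        cands = [s for s in nodes
                 if len(s.children) < (1 if s is root else 2)]
        parent = cands[int(rng.integers(0, len(cands)))]
        child = ElementSpec(mm=CT if rng.random() < 0.8 else HH,
                            dx=float(rng.uniform(1e-6, 1e-5)),
                            d=float(rng.uniform(5e-7, 5e-6)))
        parent.children.append(child)
        nodes.append(child)
    return tree_from_specs(root)


@pytest.fixture
def bifurcation_swc(tmp_path):
    """5-point SWC with exactly one bifurcation: 1-2-3, 3->(4, 5)."""
    pts = [
        SWCPoint(1, 3, 0, 0, 0, 1.0, -1),
        SWCPoint(2, 3, 10, 0, 0, 1.0, 1),
        SWCPoint(3, 3, 20, 0, 0, 0.8, 2),
        SWCPoint(4, 3, 30, 5, 0, 0.5, 3),
        SWCPoint(5, 3, 30, -5, 0, 0.5, 3),
    ]
    path = tmp_path / "bif.swc"
    write_swc(pts, path)
    return path
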