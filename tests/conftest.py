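import numpy as np
import pytest

import aphseg


@pytest.fixture(scope="session")
def two_level_img():
    """Noiseless 16x16 image, left half 0, right half 255."""
    img = np.zeros((16, 16), dtype=np.uint8)
    img[:, 8:] = 255
    return img


@pytest.fixture(scope="session")
def nested_phantom():
    img, gt = aphseg.make_nested_phantom([40, 120, 200], size=(48, 48))
    return img, gt


@pytest.fixture(scope="session")
def nested_ladder(nested_phantom):
    img, _ = nested_phantom
    return aphseg.build_nested_ladder(img, [1, 4, 16])


@pytest.fixture(scope="session")
def nodule_phantom():
    spec = aphseg.PhantomSpec()
    img, gt, seeds = aphseg.make_nodule_phantom(spec)
    return spec, img, gt, seeds


@pytest.fixture(scope="session")
def clean_nodule_phantom():
    spec = aphseg.PhantomSpec(noise_sigma=0.0)
    img, gt, seeds = aphseg.make_nodule_phantom(spec)
    return spec, img, gt, seeds


def make_random_tree(rng, max_nodes=12):
    """Random tree via random parent assignment (root first)."""
    parents = [-1]
    for i in range(1, int(rng.integers(3, max_nodes + 1))):
        parents.append(int(rng.integers(0, i)))
    return aphseg.tree_from_parents(parents)


def enumerate_valid_labelings(tree, n_labels=2):
    """Brute-force oracle: all (selected node, label) antichain covers."""
    def enum(node):
        opts = [[(node, k)] for k in range(1, n_labels + 1)]
        if tree.children[node]:
            prods = [[]]
            for ch in tree.children[node]:
                prods = [p + q for p in prods for q in enum(ch)]
            opts += prods
        return opts

    return enum(tree.root)
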