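import numpy as np
import pytest

from sdtail import canonical_inventory
from sdtail.tails import BSUB_AUCU_TAIL, BSUB_UCU_TAIL, ECOLI_TAIL


@pytest.fixture(scope="session")
def inventory_ucu():
    return canonical_inventory("UCU")


@pytest.fixture(scope="session")
def tails():
    return {"Ec": ECOLI_TAIL, "Bs-UCU": BSUB_UCU_TAIL, "Bs-AUCU": BSUB_AUCU_TAIL}


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)


def random_window(rng, length=30, probs=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(np.array(list("ACGU")), size=length, p=np.asarray(probs)))


def brute_force_matches(window: str, comp: str, min_len: int = 4):
    """Independent triple-loop oracle: all maximal (window_pos, tail_pos, L)
    common substrings of length >= min_len."""
    out = set()
    W, C = len(window), len(comp)
    for i in range(W):
        for j in range(C):
            for L in range(min_len, min(W - i, C - j) + 1):
                if window[i : i + L] != comp[j : j + L]:
                    continue
                left_ext = i > 0 and j > 0 and window[i - 1] == comp[j - 1]
                right_ext = i + L < W and j + L < C and window[i + L] == comp[j + L]
                if not left_ext and not right_ext:
                    out.add((i, j, L))
    return out
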