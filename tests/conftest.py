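"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from first principles (literal
enumeration, definitional DBSCAN) so they stay independent of the library
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STRICT = "p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
WILD_OK = set(AA20) | {"X"}


def strict_pattern_oracle(seq: str) -> set[tuple[int, int]]:
    """Literal enumeration of the strict consensus on one sequence.

    Enumerates every (phosphoacceptor position, gap length) pair and checks
    each pattern position by hand; returns the set of 1-based
    (phospho_pos, anchor_pos) pairs.  Independent of the pattern parser
    and scanner.
    """
    hits = set()
    n = len(seq)
    for i in range(n):  # 0-based phospho position
        if seq[i] not in "ST":
            continue
        if i + 1 >= n or seq[i + 1] != "P":
            continue
        for gap in range(4, 11):
            j = i + 2 + gap  # anchor position (0-based)
            if j + 5 >= n:
                continue
            if seq[j] not in "RK" or seq[j + 1] != "V":
                continue
            if seq[j + 2] not in WILD_OK or seq[j + 3] not in WILD_OK:
                continue
            if seq[j + 4] not in "VI" or seq[j + 5] != "R":
                continue
            if any(c not in WILD_OK for c in seq[i + 2 : i + 2 + gap]):
                continue
            hits.add((i + 1, j + 1))
    return hits


def dbscan_oracle(D: np.ndarray, eps: float, min_pts: int):
    """Definitional DBSCAN on a precomputed distance matrix.

    Returns (core_mask, components) where components is a list of sets of
    core-point indices (density-connected components); border points are
    not assigned -- the caller checks that each border point neighbors a
    core point of the cluster it was given.
    """
    n = len(D)
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]  # includes self
    core = np.array([len(neighbors[i]) >= min_pts for i in range(n)])
    seen = set()
    components = []
    for i in range(n):
        if not core[i] or i in seen:
            continue
        comp = set()
        stack = [i]
        while stack:
            p = stack.pop()
            if p in comp:
                continue
            comp.add(p)
            seen.add(p)
            for q in neighbors[p]:
                if core[q] and q not in comp:
                    stack.append(q)
        components.append(comp)
    return core, components


@pytest.fixture(scope="session")
def strict():
    import slimdock as sd

    return sd.parse_pattern(STRICT)


@pytest.fixture(scope="session")
def p107_record():
    import slimdock as sd

    # p107 M612-R626 reconstructed from stated residue identities
    return sd.ProteinRecord(id="RBL1_R1", sequence="MPMSPLMHPRVKEVR")


def random_protein(rng: np.random.Generator, max_len: int = 200) -> str:
    length = int(rng.integers(10, max_len + 1))
    # bias toward motif-forming letters so matches actually occur
    letters = AA20 + "SPTRKVI" * 3 + "X"
    return "".join(letters[k] for k in rng.integers(0, len(letters), length))
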