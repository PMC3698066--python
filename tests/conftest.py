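"""Shared fixtures: synthetic panels and an independent alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from phagemarker import ReferencePanel, SynthConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel: 5 clusters x 2 subclusters x 4 members."""
    cfg = SynthConfig(seed=42)
    genomes, genes, truth = generate_panel(cfg)
    labels = truth.to_label_table()
    return genomes, genes, truth, labels


@pytest.fixture(scope="session")
def gene_panel(default_panel):
    _, genes, _, labels = default_panel
    return ReferencePanel(genes, labels)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def oracle_align_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 12.0,
    gap_extend: float = 3.0,
    free_end_gaps: bool = True,
) -> float:
    """Brute-force single-matrix DP with explicit gap-length scans.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``. Since a
    mismatch (-4) is always cheaper than two adjacent opposing gaps
    (>= 2 * 12), optimal alignments never contain interior gap-vs-gap
    adjacencies and the single-matrix formulation is exact. End gaps are
    charged nothing when ``free_end_gaps``.
    """
    def gc(k: int) -> float:
        return 0.0 if k == 0 else gap_open + (k - 1) * gap_extend

    n, m = len(a), len(b)
    H = [[-float("inf")] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        H[i][0] = 0.0 if free_end_gaps else -gc(i)
    for j in range(1, m + 1):
        H[0][j] = 0.0 if free_end_gaps else -gc(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = H[i - 1][j - 1] + s
            for k in range(1, i + 1):  # gap in b: skip k residues of a
                cost = 0.0 if (free_end_gaps and j == m) else gc(k)
                cand = H[i - k][j] - cost
                if cand > best:
                    best = cand
            for k in range(1, j + 1):  # gap in a: skip k residues of b
                cost = 0.0 if (free_end_gaps and i == n) else gc(k)
                cand = H[i][j - k] - cost
                if cand > best:
                    best = cand
            H[i][j] = best
    return H[n][m]
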