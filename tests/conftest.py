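import numpy as np
import pandas as pd
import pytest

from thtargets import CountMatrix, SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One simulated experiment at the default study design (seed 11)."""
    cfg = SimConfig(seed=11)
    matrix, truth, promoters = simulate(cfg)
    return cfg, matrix, truth, promoters


@pytest.fixture
def tiny_matrix():
    """6 genes x (2 conditions x 3 reps), hand-sized for unit checks."""
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"ctrl_{i}" for i in range(3)] + [f"trt_{i}" for i in range(3)]
    counts = pd.DataFrame(
        rng.integers(10, 200, size=(6, 6)), index=genes, columns=samples
    )
    conditions = pd.Series(
        ["control"] * 3 + ["treated"] * 3, index=samples
    )
    lengths = pd.Series(rng.integers(500, 3000, size=6), index=genes)
    return CountMatrix(counts, conditions, lengths)


def naive_scan(seq: str, pattern: str, budget: int, both_strands: bool):
    """Brute-force pattern scan: every start x strand, Hamming count at
    non-N pattern positions.  Returns (start, strand, window, mismatches)
    tuples sorted by (start, strand)."""
    from thtargets import reverse_complement

    k = len(pattern)
    informative = [(i, b) for i, b in enumerate(pattern) if b != "N"]
    out = []

    def scan_one(s, strand, coord):
        for j in range(len(s) - k + 1):
            window = s[j : j + k]
            mm = sum(window[i] != b for i, b in informative)
            if mm <= budget:
                out.append((coord(j), strand, window, mm))

    scan_one(seq, "+", lambda j: j)
    if both_strands:
        rc = reverse_complement(seq)
        scan_one(rc, "-", lambda j: len(seq) - k - j)
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def naive_n50(lengths, frac=0.5):
    """Descending cumulative-sum walk, independent of the library routine."""
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= frac * total:
            return L
    raise AssertionError("unreachable for non-empty input")
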