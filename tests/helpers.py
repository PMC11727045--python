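"""Independent oracles and small generators shared across the test suite.

Everything here is deliberately naive (per-position loops, explicit
double sums, random tree agglomeration) so it cannot share a code path
with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """Enumerate every (start, end, motif, motif_len, n_repeats) tract by
    testing each (position, motif length) pair exhaustively."""
    n = len(seq)
    found = set()
    for L, thr in thresholds.items():
        for s in range(n - L + 1):
            motif = seq[s : s + L]
            if "N" in motif:
                continue
            if any(L % d == 0 and motif == motif[:d] * (L // d) for d in range(1, L)):
                continue  # not primitive: reported at the smaller length
            if s >= 1 and seq[s - 1] == seq[s + L - 1]:
                continue  # extendable left: not the run start
            count = 1
            while seq[s + count * L : s + (count + 1) * L] == motif:
                count += 1
            if count >= thr:
                found.add((s, s + count * L, motif, L, count))
    return found


def random_sequence_with_repeats(rng: np.random.Generator, length: int = 2000) -> str:
    """Random sequence with a few repeats planted at random (no guards:
    the oracle and the finder must agree on whatever arises)."""
    arr = rng.choice(np.frombuffer(b"ACGTN", dtype=np.uint8), size=length,
                     p=[0.245, 0.245, 0.245, 0.245, 0.02])
    for _ in range(rng.integers(2, 6)):
        L = int(rng.integers(1, 7))
        n_rep = int(rng.integers(3, 14))
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
        tract = (motif * n_rep).encode()
        pos = int(rng.integers(0, length - len(tract)))
        arr[pos : pos + len(tract)] = np.frombuffer(tract, dtype=np.uint8)
    return arr.tobytes().decode()


def thue_morse(n: int, alphabet: str = "AC") -> str:
    """Cube-free binary sequence: contains no tandem repeat of 3+ copies,
    so it is guaranteed SSR-free at every detection threshold."""
    return "".join(alphabet[bin(i).count("1") % 2] for i in range(n))


def pic_double_sum(p: np.ndarray) -> float:
    """Definitional PIC with an explicit i<j double loop."""
    s = 1.0 - float(np.sum(p**2))
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            s -= 2.0 * p[i] ** 2 * p[j] ** 2
    return s


def random_ultrametric(rng: np.random.Generator, n: int):
    """Random ultrametric distance matrix built by agglomerating leaves
    at strictly increasing heights; returns (ids, matrix)."""
    ids = [f"t{i}" for i in range(n)]
    clusters: list[list[int]] = [[i] for i in range(n)]
    d = np.zeros((n, n))
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return ids, d
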