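"""Independent naive-counting oracles used to cross-check the encoders.

Everything here is written by direct window enumeration over the residue
string with dictionary counters — deliberately sharing no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import product

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}


def oracle_aac(s: str) -> dict[str, float]:
    c = Counter(s)
    return {a: c[a] / len(s) for a in ALPHABET}


def oracle_kmer(s: str, k: int, alphabet=ALPHABET) -> dict[str, float]:
    windows = [s[i : i + k] for i in range(len(s) - k + 1)]
    c = Counter(windows)
    denom = len(s) - k + 1
    return {"".join(p): c["".join(p)] / denom for p in product(alphabet, repeat=k)}


def oracle_dde(s: str) -> dict[str, float]:
    dc = oracle_kmer(s, 2)
    n = len(s)
    out = {}
    for x in ALPHABET:
        for y in ALPHABET:
            tm = (CODONS[x] / 61) * (CODONS[y] / 61)
            tv = tm * (1 - tm) / (n - 1)
            out[x + y] = (dc[x + y] - tm) / math.sqrt(tv)
    return out


def recode(s: str, groups: dict[str, str] | list[str], names=None) -> str:
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(str(i + 1), g) for i, g in enumerate(groups)]
    mapping = {}
    for name, members in items:
        for aa in members:
            mapping[aa] = name
    return "|".join(mapping[c] for c in s)  # '|' keeps multi-char tokens apart


def oracle_grouped_kmer(s: str, k: int, groups: dict[str, str]) -> dict[str, float]:
    mapping = {aa: name for name, members in groups.items() for aa in members}
    tokens = [mapping[c] for c in s]
    windows = ["".join(tokens[i : i + k]) for i in range(len(tokens) - k + 1)]
    c = Counter(windows)
    denom = len(s) - k + 1
    return {
        "".join(p): c["".join(p)] / denom for p in product(groups.keys(), repeat=k)
    }


def oracle_cksaagp(s: str, groups: dict[str, str], max_gap: int = 5) -> dict[str, float]:
    mapping = {aa: name for name, members in groups.items() for aa in members}
    tokens = [mapping[c] for c in s]
    out = {}
    for k in range(max_gap + 1):
        pairs = [tokens[i] + tokens[i + k + 1] for i in range(len(tokens) - k - 1)]
        c = Counter(pairs)
        denom = len(s) - k - 1
        for x in groups:
            for y in groups:
                out[f"{x}{y}.k{k}"] = c[x + y] / denom
    return out


def oracle_ctdc(s: str, properties: dict[str, tuple[str, str, str]]) -> dict[str, float]:
    out = {}
    for prop, grps in properties.items():
        for gi, members in enumerate(grps, start=1):
            out[f"{prop}.G{gi}"] = sum(s.count(aa) for aa in members) / len(s)
    return out


def oracle_ctdt(s: str, properties: dict[str, tuple[str, str, str]]) -> dict[str, float]:
    out = {}
    for prop, grps in properties.items():
        mapping = {aa: gi for gi, members in enumerate(grps, start=1) for aa in members}
        g = [mapping[c] for c in s]
        adj = list(zip(g[:-1], g[1:]))
        for x, y in [(1, 2), (2, 3), (3, 1)]:
            count = sum(1 for p in adj if p == (x, y) or p == (y, x))
            out[f"{prop}.Tr{x}{y}"] = count / (len(s) - 1)
    return out


def oracle_ctriad(s: str, classes: tuple[str, ...]) -> dict[str, float]:
    mapping = {aa: str(ci + 1) for ci, members in enumerate(classes) for aa in members}
    t = "".join(mapping[c] for c in s)
    windows = [t[i : i + 3] for i in range(len(t) - 2)]
    c = Counter(windows)
    return {
        "".join(p): c["".join(p)] / (len(s) - 2)
        for p in product("1234567", repeat=3)
    }


def oracle_pagerank(
    nodes: list[str], edges: dict[tuple[str, str], float], damping: float
) -> dict[str, float]:
    """Dense power iteration with uniform teleport and uniform dangling mass."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for (src, dst), w in edges.items():
        W[idx[src], idx[dst]] = w
    out_sum = W.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if out_sum[i] > 0:
            P[i] = W[i] / out_sum[i]
    x = np.full(n, 1.0 / n)
    for _ in range(100000):
        dangling = x[out_sum == 0].sum()
        new = damping * (x @ P + dangling / n) + (1 - damping) / n
        if np.abs(new - x).sum() < 1e-14:
            x = new
            break
        x = new
    return {v: x[idx[v]] for v in nodes}


def oracle_anova_f(groups: list[list[float]]) -> float:
    """One-way ANOVA F by the textbook sum-of-squares decomposition."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ss_between / df1) / (ss_within / df2)
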