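"""Brute-force reference implementations used only to check the package.

Everything here is written as plainly as possible (explicit double loops,
full enumeration) and independently of the library code paths it validates.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# alignment-level statistics, complete deletion applied longhand
# ---------------------------------------------------------------------------

def usable_columns(ingroup: list[str]) -> list[int]:
    L = len(ingroup[0])
    cols = []
    for c in range(L):
        if all(seq[c] not in "-N" for seq in ingroup):
            cols.append(c)
    return cols


def segregating_sites(ingroup: list[str]) -> int:
    count = 0
    for c in usable_columns(ingroup):
        states = {seq[c] for seq in ingroup}
        if len(states) >= 2:
            count += 1
    return count


def mean_pairwise_differences(ingroup: list[str]) -> float:
    n = len(ingroup)
    cols = usable_columns(ingroup)
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            for c in cols:
                if ingroup[i][c] != ingroup[j][c]:
                    total += 1
    return total / npairs


def pi_per_site(ingroup: list[str]) -> float:
    return mean_pairwise_differences(ingroup) / len(usable_columns(ingroup))


def unfolded_sfs(ingroup: list[str], outgroup: str) -> list[int]:
    n = len(ingroup)
    xi = [0] * (n - 1)
    for c in usable_columns(ingroup):
        if outgroup[c] in "-N":
            continue
        states = sorted({seq[c] for seq in ingroup})
        if len(states) != 2:
            continue
        og = outgroup[c]
        if og not in states:
            continue
        derived = [s for s in states if s != og][0]
        count = sum(1 for seq in ingroup if seq[c] == derived)
        xi[count - 1] += 1
    return xi


# ---------------------------------------------------------------------------
# neutrality statistics, written from the published formulas
# ---------------------------------------------------------------------------

def tajimas_D(S: int, pi_count: float, n: int) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_count - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_H_norm(xi: list[int], n: int) -> float:
    S = sum(xi)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    bn1 = sum(1.0 / i**2 for i in range(1, n + 1))
    theta_pi = sum(x * 2.0 * i * (n - i) for i, x in zip(range(1, n), xi)) \
        / (n * (n - 1))
    theta_L = sum(x * i for i, x in zip(range(1, n), xi)) / (n - 1)
    theta_W = S / a1
    theta_sq = S * (S - 1.0) / (a1 * a1 + a2)
    var = theta_W * (n - 2.0) / (6.0 * (n - 1.0)) \
        + theta_sq * (18.0 * n * n * (3.0 * n + 2.0) * bn1
                      - (88.0 * n**3 + 9.0 * n * n - 13.0 * n + 6.0)) \
        / (9.0 * n * (n - 1.0) ** 2)
    return (theta_pi - theta_L) / math.sqrt(var)


# ---------------------------------------------------------------------------
# codon arithmetic by exhaustive enumeration
# ---------------------------------------------------------------------------

def syn_sites(codon: str) -> float:
    aa = translate(codon)
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            if translate(codon[:pos] + alt + codon[pos + 1:]) == aa:
                syn += 1
    return syn / 3.0


def pathway_differences(a: str, b: str) -> tuple[float, float]:
    """Average (syn, rep) steps over stop-free orderings of the changes."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if translate(nxt) == "*":
                ok = False
                break
            steps.append(translate(cur) == translate(nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None
    syn = sum(sum(p) for p in paths) / len(paths)
    return (syn, len(diff) - syn)


# ---------------------------------------------------------------------------
# Fisher's exact test by enumeration over the hypergeometric support
# ---------------------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum P(table) over tables with fixed marginals and P <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x: int) -> float:
        # table (x, r1-x, c1-x, r2-c1+x)
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(N, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total
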