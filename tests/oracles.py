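"""Independent brute-force oracles used to check the implementation.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy import stats


def welch_oracle(a: list[float], b: list[float]) -> tuple[float, float, float]:
    """Textbook Welch t, Welch-Satterthwaite df, two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(p: list[float]) -> list[float]:
    """Exhaustive Benjamini-Hochberg step-up on the sorted vector."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        # step-up: min over j >= pos of min(1, m * p(j) / (j+1))
        q[idx] = min(min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, m))
    return q


def es_oracle(metric: list[float], hits: set[int], weight: float) -> tuple[float, list[float], int]:
    """Direct evaluation of the weighted-KS running enrichment score.

    ``hits`` are 0-based rank positions of the set members. Returns
    (es, running profile, peak position), ties at max |deviation| resolved
    to the earliest position.
    """
    n = len(metric)
    n_hits = len(hits)
    if weight == 0:
        hit_w = {i: 1.0 for i in hits}
    else:
        hit_w = {i: abs(metric[i]) ** weight for i in hits}
    total = sum(hit_w.values())
    profile = []
    p_hit = p_miss = 0.0
    for i in range(n):
        if i in hits:
            p_hit += hit_w[i] / total if total > 0 else 1.0 / n_hits
        else:
            p_miss += 1.0 / (n - n_hits)
        profile.append(p_hit - p_miss)
    peak, best = 0, 0.0
    for i, v in enumerate(profile):
        if abs(v) > best:
            best, peak = abs(v), i
    return profile[peak], profile, peak


def exact_geneset_p(metric: list[float], hits: set[int], weight: float) -> float:
    """Exact same-sign permutation p by enumerating every membership."""
    n = len(metric)
    es_obs, _, _ = es_oracle(metric, hits, weight)
    if es_obs == 0:
        return 1.0
    sign = 1 if es_obs > 0 else -1
    same = extreme = 0
    for combo in combinations(range(n), len(hits)):
        es, _, _ = es_oracle(metric, set(combo), weight)
        if es * sign > 0:
            same += 1
            if abs(es) >= abs(es_obs):
                extreme += 1
    return extreme / max(same, 1)


def leading_edge_oracle(
    genes: list[str], hits: set[int], profile: list[float]
) -> list[str]:
    """Scan the profile for its extremum; collect hits on the correct side."""
    peak, best = 0, 0.0
    for i, v in enumerate(profile):
        if abs(v) > best:
            best, peak = abs(v), i
    es = profile[peak]
    if es == 0:
        return []
    if es > 0:
        argmax = max(range(len(profile)), key=lambda i: (profile[i], -i))
        return [genes[i] for i in sorted(hits) if i <= argmax]
    argmin = max(range(len(profile)), key=lambda i: (-profile[i], -i))
    return [genes[i] for i in sorted(hits) if i >= argmin]


def score_oracle(signature: dict[str, str], perturbations: dict[str, str]) -> int:
    """Plus one per reversed signature gene, minus one per aggravated."""
    score = 0
    pert = {g.upper(): d for g, d in perturbations.items()}
    for gene, disease_dir in signature.items():
        ing_dir = pert.get(gene.upper())
        if ing_dir is None:
            continue
        score += 1 if ing_dir != disease_dir else -1
    return score
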