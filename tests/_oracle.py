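"""Independent loop-based transcription of the SLE equations.

Deliberately written with plain Python loops and the ``statistics`` module —
no shared code with the package — so it can serve as an oracle for the
vectorised implementation.
"""

from __future__ import annotations

import math
import statistics


def abs_pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return abs(num / (dx * dy))


def weights(center: list[float], neighbors: list[list[float]]) -> list[float]:
    rs = [abs_pearson(nb, center) for nb in neighbors]
    total = sum(rs)
    if total == 0.0:
        return [1.0 / len(neighbors)] * len(neighbors)
    return [r / total for r in rs]


def entropy(p: list[float]) -> float:
    m = len(p)
    if m == 1:
        return 0.0
    h = -sum(pi * math.log(pi) for pi in p if pi > 0)
    return h / math.log(m)


def global_sle_oracle(
    adjacency: dict[str, set[str]],
    ref: dict[str, list[float]],
    case: dict[str, float],
    divisor: str = "scoreable",
) -> float:
    """Global SLE score by direct transcription of the per-local formulas."""
    total = 0.0
    scored = 0
    for gene in sorted(adjacency):
        nbrs = sorted(adjacency[gene])
        if len(nbrs) < 2:
            continue
        center_ref = ref[gene]
        center_mix = ref[gene] + [case[gene]]
        p_ref = weights(center_ref, [ref[nb] for nb in nbrs])
        p_mix = weights(center_mix, [ref[nb] + [case[nb]] for nb in nbrs])
        h_ref = entropy(p_ref)
        h_mix = entropy(p_mix)
        dsd = abs(statistics.stdev(center_mix) - statistics.stdev(center_ref))
        total += dsd * abs(h_mix - h_ref)
        scored += 1
    if scored == 0:
        raise ValueError("no scoreable local network")
    k = scored if divisor == "scoreable" else len(adjacency)
    return total / k


def local_perturbation_oracle(
    center: str,
    neighbors: list[str],
    ref: dict[str, list[float]],
    case: dict[str, float],
) -> float:
    p_ref = weights(ref[center], [ref[nb] for nb in neighbors])
    p_mix = weights(
        ref[center] + [case[center]], [ref[nb] + [case[nb]] for nb in neighbors]
    )
    dsd = abs(
        statistics.stdev(ref[center] + [case[center]]) - statistics.stdev(ref[center])
    )
    return dsd * abs(entropy(p_mix) - entropy(p_ref))
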