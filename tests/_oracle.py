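"""Brute-force information-theory oracle.

Pure-Python dictionary summation over explicit outcome tuples, written
independently of the package's vectorised code path; used to cross-check
specific information, I_min redundancy, PID atoms and transfer terms on
small discrete joints.
"""

import itertools
import math
from collections import defaultdict


def marginal(joint, dims):
    out = defaultdict(float)
    for outcome, p in joint.items():
        out[tuple(outcome[d] for d in dims)] += p
    return dict(out)


def mutual_info(joint, x_dims, y_dims):
    p_x = marginal(joint, x_dims)
    p_y = marginal(joint, y_dims)
    p_xy = marginal(joint, list(x_dims) + list(y_dims))
    mi = 0.0
    for (xy), p in p_xy.items():
        if p <= 0:
            continue
        x = xy[: len(x_dims)]
        y = xy[len(x_dims):]
        mi += p * math.log2(p / (p_x[x] * p_y[y]))
    return mi


def specific_info(joint, y_dims, src_dims, y):
    p_y = marginal(joint, y_dims)[y]
    p_s = marginal(joint, src_dims)
    p_ys = marginal(joint, list(y_dims) + list(src_dims))
    total = 0.0
    for ys, p in p_ys.items():
        if ys[: len(y_dims)] != y or p <= 0:
            continue
        s = ys[len(y_dims):]
        p_y_given_s = p / p_s[s]
        total += (p / p_y) * (math.log2(1.0 / p_y) - math.log2(1.0 / p_y_given_s))
    return total


def i_min(joint, y_dims, sources):
    p_y = marginal(joint, y_dims)
    total = 0.0
    for y, p in p_y.items():
        if p <= 0:
            continue
        total += p * min(specific_info(joint, y_dims, src, y) for src in sources)
    return total


def pid_two_sources(joint, y_dims, a_dims, b_dims):
    r = i_min(joint, y_dims, [a_dims, b_dims])
    i_ya = mutual_info(joint, a_dims, y_dims)
    i_yb = mutual_info(joint, b_dims, y_dims)
    total = mutual_info(joint, list(a_dims) + list(b_dims), y_dims)
    return {
        "total": total,
        "redundancy": r,
        "unique_a": i_ya - r,
        "unique_b": i_yb - r,
        "synergy": total - i_ya - i_yb + r,
    }


def transfer_terms(joint, y_dims, a_dims, b_dims, x_dims):
    ab = list(a_dims) + list(b_dims)
    imin_ab_x = i_min(joint, y_dims, [ab, x_dims])
    imin_a_x = i_min(joint, y_dims, [a_dims, x_dims])
    imin_b_x = i_min(joint, y_dims, [b_dims, x_dims])
    return {
        "transfer_from_neural": imin_ab_x - imin_b_x,
        "transfer_from_env": imin_ab_x - imin_a_x,
        "transfer_redundant": i_min(joint, y_dims, [a_dims, b_dims, x_dims]),
        "total_in_x": mutual_info(joint, x_dims, y_dims),
    }


def random_joint(rng, sizes):
    """Random sparse joint over variables with the given outcome counts."""
    outcomes = list(itertools.product(*[range(s) for s in sizes]))
    keep = rng.random(len(outcomes)) < 0.7
    if not keep.any():
        keep[0] = True
    weights = rng.random(len(outcomes)) * keep
    weights /= weights.sum()
    return {o: w for o, w in zip(outcomes, weights) if w > 0}
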