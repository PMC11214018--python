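"""JIT-compiled inner loop of the hourly scheduler.

One call handles one feeding hour: present flocks, in pre-shuffled order,
each pick the (patch, resource) pair with the best intake rate, consume for
one hour, and deplete the patch before the next flock chooses (exploitative
competition).  Logic mirrors ``foragers.best_patch_resource`` exactly; the
pure-python version is the tested reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def assign_and_feed(order, rooted_b, rooted_avail, area, n_birds,
                    attack, handling, max_intake, floating_fraction,
                    cum_depl, chosen_patch, chosen_res, intake_out):
    """Sequential rate-maximizing patch choice with within-hour depletion.

    Mutates ``rooted_b`` and ``cum_depl`` in place; writes each flock's
    chosen patch index (-1 = none), resource (0 rooted / 1 floating) and
    per-bird intake (g h^-1) into the output arrays.
    """
    n_patches = rooted_b.shape[0]
    for k in range(order.shape[0]):
        f = order[k]
        best_rate = 0.0
        best_p = -1
        best_r = 0
        for p in range(n_patches):
            b = rooted_b[p]
            if b > 0.0:
                if rooted_avail[p]:
                    r = attack * b / (1.0 + attack * handling * b)
                    if r > max_intake:
                        r = max_intake
                    if r > best_rate:
                        best_rate = r
                        best_p = p
                        best_r = 0
                bf = floating_fraction * b
                if bf > 0.0:
                    r = attack * bf / (1.0 + attack * handling * bf)
                    if r > max_intake:
                        r = max_intake
                    if r > best_rate:
                        best_rate = r
                        best_p = p
                        best_r = 1
        chosen_patch[f] = best_p
        chosen_res[f] = best_r
        if best_p >= 0:
            g = best_rate
            total = g * n_birds[f]
            stock = rooted_b[best_p] * area[best_p]
            if total > stock:
                total = stock
                g = total / n_birds[f]
            removed = total / area[best_p]
            rooted_b[best_p] -= removed
            if rooted_b[best_p] < 0.0:
                rooted_b[best_p] = 0.0
            cum_depl[best_p] += removed
            intake_out[f] = g
        else:
            intake_out[f] = 0.0
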