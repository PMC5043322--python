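"""Compiled inner loop for long evolutionary runs.

The public driver (:func:`labsim.engine.run_simulation`) exposes two
backends with identical model semantics: a readable pure-Python path built
from the ops in :mod:`labsim.core` / :mod:`labsim.evolution`, and this
numba-compiled kernel, which makes million-step populations tractable.
The kernel keeps the population in flat arrays, stores only *published*
hypotheses (unpublished novel negatives can never be replicated and leave
no trace), maintains the replicable-hypothesis index as an array-backed set
with O(1) insert/remove/sample, and holds the capped literature in a ring
buffer.

Random draws come from a single seeded stream.  Per investigating lab, the
draw order is: investigate, replication choice, [target index | latent
truth], experiment outcome, [communication for replications].  The
evolution stage draws the two tournament samples (partial Fisher-Yates),
tie-breaks, and the three mutation decisions in that order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def run_kernel(seed, n_steps, sample_interval, N, b, eta, w0, e0, r0,
               c_r_pos, c_r_neg, v_n, v_r_pos, v_r_neg, v_o_pos, v_o_neg,
               d, mu_r, mu_e, mu_w, sigma_r, sigma_e, sigma_w, lit_capacity):
    np.random.seed(seed)

    # population state (one slot per living lab)
    power = np.full(N, w0)
    effort = np.full(N, e0)
    rep = np.full(N, r0)
    age = np.zeros(N, np.int64)
    payoff = np.zeros(N)
    h = 1.0 - eta * np.log10(effort)
    alpha = power / (1.0 + (1.0 - power) * effort)

    # lab identity bookkeeping: ids are dense integers, at most N + n_steps
    max_ids = N + n_steps + 1
    id_alive = np.zeros(max_ids, np.uint8)
    id_slot = np.zeros(max_ids, np.int64)
    slot_id = np.zeros(N, np.int64)
    for i in range(N):
        slot_id[i] = i
        id_alive[i] = 1
        id_slot[i] = i
    next_id = N

    # published hypotheses (amortised doubling)
    hyp_cap = 1024
    hyp_truth = np.zeros(hyp_cap, np.uint8)
    hyp_orig = np.zeros(hyp_cap, np.int64)
    pos_count = np.zeros(hyp_cap, np.int64)
    set_pos = np.full(hyp_cap, -1, np.int64)
    rep_set = np.zeros(hyp_cap, np.int64)   # hyp ids with >=1 retained positive
    rep_set_size = 0
    n_hyp = 0

    # literature ring buffer; at most N appends happen between truncations
    rec_cap = lit_capacity + N + 8
    rec_hyp = np.zeros(rec_cap, np.int64)
    rec_pos = np.zeros(rec_cap, np.uint8)
    rec_head = 0
    rec_count = 0

    perm = np.zeros(N, np.int64)
    idxs = np.zeros(N, np.int64)

    n_samples = n_steps // sample_interval
    metrics = np.full((n_samples, 9), np.nan)
    s_out = 0

    for t in range(n_steps):
        # --- Science stage: labs act in a fresh random order ---
        for i in range(N):
            perm[i] = i
        for i in range(N - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp

        n_pub = 0
        n_pos_pub = 0
        n_false_pos = 0
        n_repl_pub = 0

        for k in range(N):
            i = perm[k]
            if np.random.random() >= h[i]:
                continue
            is_rep = False
            if rep[i] > 0.0 and np.random.random() < rep[i] and rep_set_size > 0:
                is_rep = True
            if is_rep:
                hid = rep_set[np.random.randint(0, rep_set_size)]
                truth = hyp_truth[hid]
            else:
                truth = 1 if np.random.random() < b else 0
                hid = -1
            p_pos = power[i] if truth == 1 else alpha[i]
            pos = 1 if np.random.random() < p_pos else 0
            if is_rep:
                c = c_r_pos if pos == 1 else c_r_neg
                pub = c >= 1.0 or np.random.random() < c
            else:
                pub = pos == 1  # positive novel always; negative novel never
            if not pub:
                continue

            if not is_rep:
                if n_hyp == hyp_cap:
                    new_cap = hyp_cap * 2
                    g1 = np.zeros(new_cap, np.uint8)
                    g1[:hyp_cap] = hyp_truth
                    hyp_truth = g1
                    g2 = np.zeros(new_cap, np.int64)
                    g2[:hyp_cap] = hyp_orig
                    hyp_orig = g2
                    g3 = np.zeros(new_cap, np.int64)
                    g3[:hyp_cap] = pos_count
                    pos_count = g3
                    g4 = np.full(new_cap, -1, np.int64)
                    g4[:hyp_cap] = set_pos
                    set_pos = g4
                    g5 = np.zeros(new_cap, np.int64)
                    g5[:rep_set_size] = rep_set[:rep_set_size]
                    rep_set = g5
                    hyp_cap = new_cap
                hid = n_hyp
                hyp_truth[hid] = truth
                hyp_orig[hid] = slot_id[i]
                n_hyp += 1

            p = rec_head + rec_count
            if p >= rec_cap:
                p -= rec_cap
            rec_hyp[p] = hid
            rec_pos[p] = pos
            rec_count += 1
            if pos == 1:
                pos_count[hid] += 1
                if pos_count[hid] == 1:
                    set_pos[hid] = rep_set_size
                    rep_set[rep_set_size] = hid
                    rep_set_size += 1

            if is_rep:
                payoff[i] += v_r_pos if pos == 1 else v_r_neg
                oid = hyp_orig[hid]
                if oid != slot_id[i] and id_alive[oid] == 1:
                    payoff[id_slot[oid]] += v_o_pos if pos == 1 else v_o_neg
                n_repl_pub += 1
            else:
                payoff[i] += v_n
            n_pub += 1
            if pos == 1:
                n_pos_pub += 1
                if truth == 0:
                    n_false_pos += 1

        # --- ageing ---
        for i in range(N):
            age[i] += 1

        # --- Evolution stage: death tournament (oldest of d, ties random) ---
        for i in range(N):
            idxs[i] = i
        for j in range(d):
            r_ = j + np.random.randint(0, N - j)
            tmp = idxs[j]
            idxs[j] = idxs[r_]
            idxs[r_] = tmp
        dead = idxs[0]
        best_age = age[dead]
        nb = 1
        for j in range(1, d):
            cand = idxs[j]
            if age[cand] > best_age:
                dead = cand
                best_age = age[cand]
                nb = 1
            elif age[cand] == best_age:
                nb += 1
                if np.random.random() < 1.0 / nb:
                    dead = cand
        id_alive[slot_id[dead]] = 0

        # birth tournament over the post-death population (highest pay-off)
        m2 = 0
        for i in range(N):
            if i != dead:
                idxs[m2] = i
                m2 += 1
        if m2 == 0:
            parent = dead  # degenerate single-lab population
        else:
            dd = d if d <= m2 else m2
            for j in range(dd):
                r_ = j + np.random.randint(0, m2 - j)
                tmp = idxs[j]
                idxs[j] = idxs[r_]
                idxs[r_] = tmp
            parent = idxs[0]
            best_p = payoff[parent]
            nb = 1
            for j in range(1, dd):
                cand = idxs[j]
                if payoff[cand] > best_p:
                    parent = cand
                    best_p = payoff[cand]
                    nb = 1
                elif payoff[cand] == best_p:
                    nb += 1
                    if np.random.random() < 1.0 / nb:
                        parent = cand

        # offspring replaces the dead slot; traits mutate then clamp
        w = power[parent]
        e = effort[parent]
        rr = rep[parent]
        if np.random.random() < mu_w:
            w += np.random.normal(0.0, sigma_w)
            if w < 0.0:
                w = 0.0
            elif w > 1.0:
                w = 1.0
        if np.random.random() < mu_e:
            e += np.random.normal(0.0, sigma_e)
            if e < 1.0:
                e = 1.0
            elif e > 100.0:
                e = 100.0
        if np.random.random() < mu_r:
            rr += np.random.normal(0.0, sigma_r)
            if rr < 0.0:
                rr = 0.0
            elif rr > 1.0:
                rr = 1.0
        power[dead] = w
        effort[dead] = e
        rep[dead] = rr
        age[dead] = 0
        payoff[dead] = 0.0
        slot_id[dead] = next_id
        id_alive[next_id] = 1
        id_slot[next_id] = dead
        next_id += 1
        h[dead] = 1.0 - eta * np.log10(e)
        alpha[dead] = w / (1.0 + (1.0 - w) * e)

        # --- literature truncation to capacity ---
        while rec_count > lit_capacity:
            idx = rec_head
            rec_head += 1
            if rec_head == rec_cap:
                rec_head = 0
            rec_count -= 1
            if rec_pos[idx] == 1:
                h2 = rec_hyp[idx]
                pos_count[h2] -= 1
                if pos_count[h2] == 0:
                    sp = set_pos[h2]
                    last = rep_set[rep_set_size - 1]
                    rep_set[sp] = last
                    set_pos[last] = sp
                    rep_set_size -= 1
                    set_pos[h2] = -1

        # --- sampling ---
        if (t + 1) % sample_interval == 0:
            metrics[s_out, 0] = t + 1
            metrics[s_out, 1] = power.mean()
            metrics[s_out, 2] = effort.mean()
            metrics[s_out, 3] = rep.mean()
            metrics[s_out, 4] = alpha.mean()
            if n_pos_pub > 0:
                metrics[s_out, 5] = n_false_pos / n_pos_pub
            metrics[s_out, 6] = n_pub
            metrics[s_out, 7] = n_pos_pub
            metrics[s_out, 8] = n_repl_pub
            s_out += 1

    lit_size = rec_count
    return metrics, power, effort, rep, age, payoff, slot_id, lit_size
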