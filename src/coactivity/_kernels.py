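"""Numba inner loops for shuffling, SHARC reassignment, training and counting.

These kernels mutate their array arguments in place and use numba's own RNG;
callers seed them with 32-bit integers drawn from a numpy Generator so that
every run is reproducible from one master seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def swap_shuffle_blocks(neu, starts, lens, occ, seed, max_retries):
    """Randomly swap neuron identities between block pairs.

    Every block is attempted at least once; a swap is committed only if
    neither neuron ends up with overlapping activity.  Preserves per-frame
    column sums and per-neuron block counts exactly.  Returns the number of
    blocks skipped after exhausting retries.
    """
    np.random.seed(seed)
    nb = neu.shape[0]
    n_skipped = 0
    if nb < 2:
        return 0
    order = np.random.permutation(nb)
    for oi in range(nb):
        b = order[oi]
        done = False
        for _ in range(max_retries):
            c = np.random.randint(0, nb)
            if c == b:
                continue
            a = neu[b]
            d = neu[c]
            if a == d:
                done = True  # identity swap; marginals trivially intact
                break
            # remove both blocks, test feasibility, commit or restore;
            # adjacency counts as a conflict so blocks never merge
            F = occ.shape[1]
            for f in range(starts[b], starts[b] + lens[b]):
                occ[a, f] = 0
            for f in range(starts[c], starts[c] + lens[c]):
                occ[d, f] = 0
            ok = True
            for f in range(max(starts[b] - 1, 0), min(starts[b] + lens[b] + 1, F)):
                if occ[d, f]:
                    ok = False
                    break
            if ok:
                for f in range(max(starts[c] - 1, 0), min(starts[c] + lens[c] + 1, F)):
                    if occ[a, f]:
                        ok = False
                        break
            if ok:
                for f in range(starts[b], starts[b] + lens[b]):
                    occ[d, f] = 1
                for f in range(starts[c], starts[c] + lens[c]):
                    occ[a, f] = 1
                neu[b] = d
                neu[c] = a
                done = True
                break
            else:
                for f in range(starts[b], starts[b] + lens[b]):
                    occ[a, f] = 1
                for f in range(starts[c], starts[c] + lens[c]):
                    occ[d, f] = 1
        if not done:
            n_skipped += 1
    return n_skipped


@njit(cache=True, inline="always")
def _remove_block(occ, bmap, s, overlap, neuron, start, end):
    for f in range(start, end):
        occ[neuron, f] = 0
        bmap[neuron, f] = -1
    length = end - start
    s[neuron] -= length
    N = occ.shape[0]
    for f in range(start, end):
        for k in range(N):
            if occ[k, f]:
                overlap[neuron, k] -= 1
                overlap[k, neuron] -= 1
    overlap[neuron, neuron] = s[neuron]


@njit(cache=True, inline="always")
def _insert_block(occ, bmap, s, overlap, neuron, start, end, block_id):
    length = end - start
    s[neuron] += length
    N = occ.shape[0]
    for f in range(start, end):
        for k in range(N):
            if occ[k, f]:
                overlap[neuron, k] += 1
                overlap[k, neuron] += 1
        occ[neuron, f] = 1
        bmap[neuron, f] = block_id
    overlap[neuron, neuron] = s[neuron]


@njit(cache=True)
def sharc_passes(
    neu, starts, lens, occ, bmap, s, overlap, net, target,
    n_passes, max_net_gain, max_net_loss, temperature, seed,
):
    """Correlation-guided block reassignment (the SHARC inner loop).

    For each randomly visited block, scores every neuron by how much
    assigning the block to it would move the running correlation matrix
    toward ``target``, weighted by temporal overlap with already-placed
    blocks; neurons active during the block's frames are ineligible, and
    per-neuron activity budgets bound net block gain/loss to
    ``[-max_net_loss, +max_net_gain]``.  When no neuron has a positive score
    the recipient is drawn with probability softmax(net / temperature),
    pushing activity budgets back toward balance.

    Returns ``(n_fallback, n_kept, n_donor_blocked)``.
    """
    np.random.seed(seed)
    N, F = occ.shape
    nb = neu.shape[0]
    P = np.empty(N)
    ovl = np.empty(N, np.bool_)
    n_fallback = 0
    n_kept = 0
    n_donor_blocked = 0
    for _ in range(n_passes):
        order = np.random.permutation(nb)
        for oi in range(nb):
            b = order[oi]
            a = neu[b]
            if net[a] - 1 < -max_net_loss:
                n_donor_blocked += 1
                continue
            st = starts[b]
            L = lens[b]
            en = st + L
            _remove_block(occ, bmap, s, overlap, a, st, en)

            for k in range(N):
                P[k] = 0.0
                ovl[k] = False
            # accumulate guesses from every overlapping, already-placed block
            for nj in range(N):
                f = st
                while f < en:
                    if occ[nj, f]:
                        j = bmap[nj, f]
                        rj = 0
                        while f < en and occ[nj, f] and bmap[nj, f] == j:
                            rj += 1
                            f += 1
                        ovl[nj] = True
                        coef = rj / (L * lens[j])
                        sn = s[nj]
                        dn = F * sn - sn * sn
                        for k in range(N):
                            if k == nj:
                                continue
                            sk = s[k]
                            dk = F * sk - sk * sk
                            if dn > 0 and dk > 0:
                                cprime = (F * overlap[nj, k] - sn * sk) / np.sqrt(
                                    dn * 1.0 * dk
                                )
                            else:
                                cprime = 0.0
                            P[k] += coef * (target[nj, k] - cprime)
                    else:
                        f += 1

            # neurons active immediately before/after the block would merge
            # with it; treat them like overlapping neurons
            if st > 0:
                for k in range(N):
                    if occ[k, st - 1]:
                        ovl[k] = True
            if en < F:
                for k in range(N):
                    if occ[k, en]:
                        ovl[k] = True

            # eligibility: not active during the block, within the gain budget
            best = -1.0e300
            n_elig = 0
            for k in range(N):
                if ovl[k]:
                    continue
                if k != a and net[k] + 1 > max_net_gain:
                    continue
                n_elig += 1
                if P[k] > best:
                    best = P[k]
            if n_elig == 0:
                _insert_block(occ, bmap, s, overlap, a, st, en, b)
                n_kept += 1
                continue

            chosen = -1
            if best > 0.0:
                nties = 0
                for k in range(N):
                    if ovl[k] or (k != a and net[k] + 1 > max_net_gain):
                        continue
                    if P[k] == best:
                        nties += 1
                pick = np.random.randint(0, nties)
                for k in range(N):
                    if ovl[k] or (k != a and net[k] + 1 > max_net_gain):
                        continue
                    if P[k] == best:
                        if pick == 0:
                            chosen = k
                            break
                        pick -= 1
            else:
                # weighted fallback toward net block recipients
                n_fallback += 1
                maxnet = -1.0e300
                for k in range(N):
                    if ovl[k] or (k != a and net[k] + 1 > max_net_gain):
                        continue
                    v = net[k] / temperature
                    if v > maxnet:
                        maxnet = v
                total = 0.0
                for k in range(N):
                    if ovl[k] or (k != a and net[k] + 1 > max_net_gain):
                        continue
                    total += np.exp(net[k] / temperature - maxnet)
                u = np.random.random() * total
                acc = 0.0
                for k in range(N):
                    if ovl[k] or (k != a and net[k] + 1 > max_net_gain):
                        continue
                    acc += np.exp(net[k] / temperature - maxnet)
                    if u <= acc:
                        chosen = k
                        break
                if chosen == -1:  # numerical guard
                    for k in range(N - 1, -1, -1):
                        if not ovl[k] and (k == a or net[k] + 1 <= max_net_gain):
                            chosen = k
                            break

            _insert_block(occ, bmap, s, overlap, chosen, st, en, b)
            neu[b] = chosen
            if chosen != a:
                net[a] -= 1
                net[chosen] += 1
    return n_fallback, n_kept, n_donor_blocked


@njit(cache=True)
def delta_rule_train(X, z, orders, w, lr):
    """Online delta-rule training of the output weights.

    ``X`` is (n_frames, n_hidden) hidden-unit activity, ``z`` the 0/1 frame
    labels, ``orders`` one frame permutation per pass.  Updates ``w`` in
    place and returns the running mean logistic loss per pass.
    """
    n_passes, n = orders.shape
    H = w.shape[0]
    losses = np.empty(n_passes)
    for p in range(n_passes):
        loss = 0.0
        for t in range(n):
            f = orders[p, t]
            acc = 0.0
            for i in range(H):
                acc += w[i] * X[f, i]
            y = 1.0 / (1.0 + np.exp(-acc))
            zt = z[f]
            yc = min(max(y, 1e-12), 1.0 - 1e-12)
            loss += -(zt * np.log(yc) + (1.0 - zt) * np.log(1.0 - yc))
            g = lr * y * (1.0 - y) * (zt - y)
            if g != 0.0:
                for i in range(H):
                    w[i] += g * X[f, i]
        losses[p] = loss / n
    return losses


@njit(cache=True)
def triplet_codes(occ, frames, max_active):
    """Encoded 3-neuron combinations for every eligible frame.

    For each frame in ``frames`` with k >= 3 active neurons, emits all
    C(k, 3) unordered triplets as int64 codes ``(i * N + j) * N + k`` with
    i < j < k.  Frames with more than ``max_active`` active neurons raise.
    """
    N = occ.shape[0]
    buf = np.empty(max_active, np.int64)
    # first pass: total number of codes
    total = 0
    for fi in range(frames.shape[0]):
        f = frames[fi]
        k = 0
        for n in range(N):
            if occ[n, f]:
                k += 1
        if k > max_active:
            raise ValueError("frame has more active neurons than max_active")
        if k >= 3:
            total += k * (k - 1) * (k - 2) // 6
    out = np.empty(total, np.int64)
    pos = 0
    for fi in range(frames.shape[0]):
        f = frames[fi]
        k = 0
        for n in range(N):
            if occ[n, f]:
                buf[k] = n
                k += 1
        if k < 3:
            continue
        for i in range(k - 2):
            for j in range(i + 1, k - 1):
                base = (buf[i] * N + buf[j]) * N
                for m in range(j + 1, k):
                    out[pos] = base + buf[m]
                    pos += 1
    return out
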