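"""Numba kernels for the base-pair-level Monte-Carlo break simulator.

States are packed into an int64 key with 4 bits per lesion category
(isolated SSB, SSB+, SSB++, SSB+++, DSB, DSB+, DSB++, BD) so a trial's
outcome is a single integer and a full run reduces to ``np.unique`` on the
key array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# placement-convention ids (keep in sync with mc_oracle.CONVENTIONS)
CONV_UNIFORM_BP = 0
CONV_SITE_RESOLVED = 1
CONV_TABLE_CALIBRATED = 2
CONV_LADDER_MATCHED = 3

_MAX_BREAKS = 32


@njit(cache=True)
def _components(pos, nb, window, labels):
    """Label breaks by connected component (|dpos| <= window links)."""
    for i in range(nb):
        labels[i] = i
    changed = True
    while changed:
        changed = False
        for i in range(nb):
            for j in range(i + 1, nb):
                if abs(pos[i] - pos[j]) <= window and labels[i] != labels[j]:
                    m = min(labels[i], labels[j])
                    labels[i] = m
                    labels[j] = m
                    changed = True
    # compact representative labels to 0..ncomp-1
    ncomp = 0
    for i in range(nb):
        if labels[i] == i:
            for j in range(nb):
                if labels[j] == i:
                    labels[j] = -(ncomp + 1)
            ncomp += 1
    for i in range(nb):
        labels[i] = -labels[i] - 1
    return ncomp


@njit(cache=True)
def classify_pack(pos, strand, nb, window, bd):
    """Classify a break set and pack category counts into an int64 key."""
    labels = np.empty(_MAX_BREAKS, np.int64)
    ncomp = _components(pos, nb, window, labels)
    iso = 0
    plus = 0
    pp = 0
    ppp = 0
    dsb_s = 0
    dsb_plus = 0
    dsb_pp = 0
    for c in range(ncomp):
        size = 0
        is_dsb = False
        for i in range(nb):
            if labels[i] != c:
                continue
            size += 1
            for j in range(i + 1, nb):
                if (labels[j] == c and strand[i] != strand[j]
                        and abs(pos[i] - pos[j]) <= window):
                    is_dsb = True
        if is_dsb:
            if size == 2:
                dsb_s += 1
            elif size == 3:
                dsb_plus += 1
            else:
                dsb_pp += 1
        else:
            if size == 1:
                iso += 1
            elif size == 2:
                plus += 1
            elif size == 3:
                pp += 1
            else:
                ppp += 1
    b = bd
    if b > 15:
        b = 15
    return (iso | (plus << 4) | (pp << 8) | (ppp << 12) | (dsb_s << 16)
            | (dsb_plus << 20) | (dsb_pp << 24) | (b << 28))


@njit(cache=True)
def _place_positional(pos, strand, nb, n_bp):
    """Uniform position + fair-coin strand; a re-hit site collapses."""
    p = 1 + int(np.random.random() * n_bp)
    if p > n_bp:
        p = n_bp
    s = 1 if np.random.random() < 0.5 else 0
    for i in range(nb):
        if pos[i] == p and strand[i] == s:
            return nb  # occupied site: no new break
    pos[nb] = p
    strand[nb] = s
    return nb + 1


@njit(cache=True)
def _place_ladder(pos, strand, nb, n_bp, window, q0_ladder):
    """Ladder-matched placement: isolate-vs-attach drawn from q0(k)."""
    k = nb + 1
    q0 = q0_ladder[k] if k < q0_ladder.shape[0] else 0.0
    if nb == 0 or np.random.random() < q0:
        # isolated: rejection-sample a position > window from all breaks
        p = 1
        s = 0
        for _ in range(4000):
            p = 1 + int(np.random.random() * n_bp)
            if p > n_bp:
                p = n_bp
            s = 1 if np.random.random() < 0.5 else 0
            good = True
            for i in range(nb):
                if abs(pos[i] - p) <= window:
                    good = False
                    break
            if good:
                break
        pos[nb] = p
        strand[nb] = s
        return nb + 1
    # attach: pick an existing lesion uniformly, commit the strand by fair
    # coin (the two attachment strands are equally probable by assumption),
    # then rejection-sample the position only, so the same/opposite-strand
    # split stays exactly 1/2 regardless of site occupancy or edges
    labels = np.empty(_MAX_BREAKS, np.int64)
    ncomp = _components(pos, nb, window, labels)
    target = int(np.random.random() * ncomp)
    if target >= ncomp:
        target = ncomp - 1
    members = 0
    for i in range(nb):
        if labels[i] == target:
            members += 1
    s = 1 if np.random.random() < 0.5 else 0
    for attempt in range(2):
        # second pass drops the no-bridging constraint as a fallback so the
        # break is never lost (merging lesions is then resolved geometrically)
        for _ in range(4000):
            midx = int(np.random.random() * members)
            seen = 0
            anchor = 0
            for i in range(nb):
                if labels[i] == target:
                    if seen == midx:
                        anchor = i
                        break
                    seen += 1
            delta = int(np.random.random() * (2 * window + 1)) - window
            p = pos[anchor] + delta
            if p < 1 or p > n_bp:
                continue
            ok = True
            for i in range(nb):
                if pos[i] == p and strand[i] == s:
                    ok = False  # occupied site
                    break
                if (attempt == 0 and labels[i] != target
                        and abs(pos[i] - p) <= window):
                    ok = False  # would bridge into another lesion
                    break
            if ok:
                pos[nb] = p
                strand[nb] = s
                return nb + 1
    return nb  # fully blocked (degenerate geometry): drop the break


@njit(cache=True)
def simulate_kernel(j_a, j_b, n_bp, window, q0_ladder, r1, r2,
                    convention, n_trials, seed):
    """Simulate ``n_trials`` segments for an (A, B) event composition.

    Returns one packed classification key per trial.
    """
    np.random.seed(seed)
    out = np.empty(n_trials, np.int64)
    pos = np.empty(_MAX_BREAKS, np.int64)
    strand = np.empty(_MAX_BREAKS, np.int64)
    for t in range(n_trials):
        nb = 0
        bd = 0
        for e in range(j_a + j_b):
            make_break = True
            if e >= j_a:
                u = np.random.random()
                if u < r1:
                    make_break = True
                elif u < r1 + r2:
                    bd += 1
                    make_break = False
                else:
                    make_break = False
            if not make_break:
                continue
            if convention == CONV_LADDER_MATCHED:
                nb = _place_ladder(pos, strand, nb, n_bp, window, q0_ladder)
            else:
                nb = _place_positional(pos, strand, nb, n_bp)
        out[t] = classify_pack(pos, strand, nb, window, bd)
    return out
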