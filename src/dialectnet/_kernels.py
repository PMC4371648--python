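"""Compiled inner loops for settling, backpropagation through time, and
online weight updates.

Everything here operates on plain float64 arrays; the public interface
lives in :mod:`dialectnet.network`.  Weight matrices are stored
(pre-synaptic, post-synaptic), so a layer's net input is ``W.T @ a``.

State update order per settling step t (synchronous):

    c_t = sigmoid(W_pc.T p_{t-1} + b_c)
    p_t = sigmoid(W_hp.T h + W_pp.T p_{t-1} + W_cp.T c_{t-1}
                  + W_xp.T ctx + b_p)

with ``p_t`` overwritten by the clamp pattern for the first
``clamp_steps`` steps of a clamped (speech) trial.  Hidden units have no
recurrent input, so ``h`` is computed once per trial; trials without an
orthographic input leave the reading pathway (hidden layer) silent, so
spoken-word learning is carried by the phonological attractor weights.
Cross-entropy is accumulated over the final ``target_steps`` steps,
scaled per trial.
"""

import numpy as np
from numba import njit

EPS = 1e-7


@njit(cache=True, fastmath=True, inline="always")
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=True, inline="always")
def _add_Wt_x(W, x, out):
    # out += W.T @ x, exploiting zeros in x (sparse inputs, clamps)
    for i in range(W.shape[0]):
        xi = x[i]
        if xi != 0.0:
            for j in range(W.shape[1]):
                out[j] += W[i, j] * xi


@njit(cache=True, fastmath=True, inline="always")
def _add_W_d(W, d, out):
    # out += W @ d
    for i in range(W.shape[0]):
        s = 0.0
        for j in range(W.shape[1]):
            s += W[i, j] * d[j]
        out[i] += s


@njit(cache=True, fastmath=True, inline="always")
def _sgd_outer(W, x, d, lr):
    # W -= lr * outer(x, d)
    for i in range(x.shape[0]):
        c = lr * x[i]
        if c != 0.0:
            for j in range(d.shape[0]):
                W[i, j] -= c * d[j]


@njit(cache=True, fastmath=True, inline="always")
def _acc_outer(G, x, d):
    # G += outer(x, d)
    for i in range(x.shape[0]):
        xi = x[i]
        if xi != 0.0:
            for j in range(d.shape[0]):
                G[i, j] += xi * d[j]


@njit(cache=True, fastmath=True)
def forward(
    W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
    orth, has_orth, clamp, has_clamp, ctx,
    T, clamp_steps, target_steps, a_init, target, scale, margin,
    P, C, h,
):
    """Settle for T steps, filling trajectories P (T+1, n_p), C (T+1, n_c)
    and the constant hidden vector h; returns the scaled cross-entropy
    summed over the last `target_steps` steps.

    Units within `margin` of their target contribute no loss (the error
    radius of the training objective); margin 0 gives plain
    cross-entropy."""
    n_p = b_p.shape[0]
    n_c = b_c.shape[0]
    n_h = b_h.shape[0]

    # the reading pathway is engaged only when print is present: speech
    # trials leave the hidden layer silent, so spoken-word learning shapes
    # the phonological attractor, not the orthography->phonology route
    if has_orth:
        for j in range(n_h):
            h[j] = b_h[j]
        _add_Wt_x(W_oh, orth, h)
        _add_Wt_x(W_ch, ctx, h)
        for j in range(n_h):
            h[j] = _sigmoid(h[j])
    else:
        for j in range(n_h):
            h[j] = 0.0

    # per-step-constant phonological input: hidden + context + bias
    base_p = np.empty(n_p)
    for j in range(n_p):
        base_p[j] = b_p[j]
    if has_orth:
        _add_Wt_x(W_hp, h, base_p)
    _add_Wt_x(W_xp, ctx, base_p)

    if has_clamp:
        for j in range(n_p):
            P[0, j] = clamp[j]
    else:
        for j in range(n_p):
            P[0, j] = a_init
    for k in range(n_c):
        C[0, k] = a_init

    loss = 0.0
    cs = clamp_steps if has_clamp else 0
    for t in range(1, T + 1):
        for k in range(n_c):
            C[t, k] = b_c[k]
        _add_Wt_x(W_pc, P[t - 1], C[t])
        for k in range(n_c):
            C[t, k] = _sigmoid(C[t, k])
        if t <= cs:
            for j in range(n_p):
                P[t, j] = clamp[j]
        else:
            for j in range(n_p):
                P[t, j] = base_p[j]
            _add_Wt_x(W_pp, P[t - 1], P[t])
            _add_Wt_x(W_cp, C[t - 1], P[t])
            for j in range(n_p):
                P[t, j] = _sigmoid(P[t, j])
        if t > T - target_steps:
            for j in range(n_p):
                a = P[t, j]
                diff = a - target[j]
                if -margin <= diff <= margin:
                    continue
                if a < EPS:
                    a = EPS
                elif a > 1.0 - EPS:
                    a = 1.0 - EPS
                if target[j] > 0.5:
                    loss -= np.log(a)
                else:
                    loss -= np.log(1.0 - a)
    return loss * scale


@njit(cache=True, fastmath=True)
def backward_deltas(
    W_pp, W_cp, W_pc, W_hp,
    has_clamp, T, clamp_steps, target_steps, target, scale, margin,
    P, C, h, has_orth,
    Dp, Dc, dh,
):
    """Backpropagate through the unrolled settling steps.

    Fills Dp/Dc with the per-step gradients w.r.t. net inputs of the
    phonological and cleanup layers, and dh with the gradient w.r.t. the
    hidden net input.  Clamped steps are inputs, so no gradient flows
    into them.

    `margin` implements an error radius: an output unit within `margin`
    of its target contributes no error gradient, so mastered patterns
    stop driving weight growth (margin 0 recovers the exact
    cross-entropy gradient).
    """
    n_p = Dp.shape[1]
    n_c = Dc.shape[1]
    n_h = dh.shape[0]
    dp = np.zeros(n_p)
    dc = np.zeros(n_c)
    dh_acc = np.zeros(n_h)
    cs = clamp_steps if has_clamp else 0

    for t in range(T, 0, -1):
        if t <= cs:
            for j in range(n_p):
                Dp[t, j] = 0.0
        else:
            for j in range(n_p):
                g = dp[j] * P[t, j] * (1.0 - P[t, j])
                if t > T - target_steps:
                    diff = P[t, j] - target[j]
                    if diff > margin or diff < -margin:
                        g += scale * diff
                Dp[t, j] = g
        for k in range(n_c):
            Dc[t, k] = dc[k] * C[t, k] * (1.0 - C[t, k])
        for j in range(n_p):
            dp[j] = 0.0
        for k in range(n_c):
            dc[k] = 0.0
        _add_W_d(W_pp, Dp[t], dp)
        _add_W_d(W_pc, Dc[t], dp)
        _add_W_d(W_cp, Dp[t], dc)
        if has_orth:
            _add_W_d(W_hp, Dp[t], dh_acc)

    for j in range(n_h):
        dh[j] = dh_acc[j] * h[j] * (1.0 - h[j]) if has_orth else 0.0


@njit(cache=True, fastmath=True)
def apply_update(
    W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
    orth, has_orth, ctx, T, lr, delta_clip,
    P, C, h, Dp, Dc, dh,
):
    """One online gradient-descent step from the BPTT deltas.

    When `delta_clip` > 0, the joint norm of the per-step deltas is
    capped by rescaling the learning rate for this trial, which bounds
    the update size of high-error high-frequency trials and keeps the
    attractor weights out of runaway regions.
    """
    n_p = b_p.shape[0]
    n_c = b_c.shape[0]
    if delta_clip > 0.0:
        sq = 0.0
        for t in range(1, T + 1):
            for j in range(n_p):
                sq += Dp[t, j] * Dp[t, j]
            for k in range(n_c):
                sq += Dc[t, k] * Dc[t, k]
        for j in range(dh.shape[0]):
            sq += dh[j] * dh[j]
        norm = np.sqrt(sq)
        if norm > delta_clip:
            lr = lr * delta_clip / norm
    sum_dp = np.zeros(n_p)
    for t in range(1, T + 1):
        allzero = True
        for j in range(n_p):
            if Dp[t, j] != 0.0:
                allzero = False
                break
        if not allzero:
            _sgd_outer(W_pp, P[t - 1], Dp[t], lr)
            _sgd_outer(W_cp, C[t - 1], Dp[t], lr)
            for j in range(n_p):
                sum_dp[j] += Dp[t, j]
        _sgd_outer(W_pc, P[t - 1], Dc[t], lr)
        for k in range(n_c):
            b_c[k] -= lr * Dc[t, k]
    for j in range(n_p):
        b_p[j] -= lr * sum_dp[j]
    if has_orth:
        _sgd_outer(W_hp, h, sum_dp, lr)
        _sgd_outer(W_oh, orth, dh, lr)
        _sgd_outer(W_ch, ctx, dh, lr)
        for j in range(b_h.shape[0]):
            b_h[j] -= lr * dh[j]
    _sgd_outer(W_xp, ctx, sum_dp, lr)
    # phonological units have no self-connections
    for j in range(n_p):
        W_pp[j, j] = 0.0


@njit(cache=True, fastmath=True)
def accumulate_grads(
    orth, has_orth, ctx, T,
    P, C, h, Dp, Dc, dh,
    gW_oh, gW_ch, gb_h, gW_hp, gW_pp, gW_cp, gW_xp, gb_p, gW_pc, gb_c,
):
    """Materialize full gradient arrays (for train_trial and gradient checks)."""
    n_p = gb_p.shape[0]
    n_c = gb_c.shape[0]
    sum_dp = np.zeros(n_p)
    for t in range(1, T + 1):
        _acc_outer(gW_pp, P[t - 1], Dp[t])
        _acc_outer(gW_cp, C[t - 1], Dp[t])
        _acc_outer(gW_pc, P[t - 1], Dc[t])
        for j in range(n_p):
            sum_dp[j] += Dp[t, j]
        for k in range(n_c):
            gb_c[k] += Dc[t, k]
    for j in range(n_p):
        gb_p[j] += sum_dp[j]
    _acc_outer(gW_xp, ctx, sum_dp)
    if has_orth:
        _acc_outer(gW_hp, h, sum_dp)
        _acc_outer(gW_oh, orth, dh)
        _acc_outer(gW_ch, ctx, dh)
        for j in range(gb_h.shape[0]):
            gb_h[j] += dh[j]
    for j in range(n_p):
        gW_pp[j, j] = 0.0


@njit(cache=True, fastmath=True)
def run_trials(
    W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
    orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat, scales,
    T, clamp_steps, target_steps, a_init, lr, margin, delta_clip,
    losses,
):
    """Sequential online training over a packed trial block.

    Weights are updated in place after each trial; per-trial losses are
    written into `losses` (computed with the pre-update weights).
    """
    n_trials = tgt_mat.shape[0]
    n_p = b_p.shape[0]
    n_c = b_c.shape[0]
    n_h = b_h.shape[0]
    P = np.empty((T + 1, n_p))
    C = np.empty((T + 1, n_c))
    h = np.empty(n_h)
    Dp = np.zeros((T + 1, n_p))
    Dc = np.zeros((T + 1, n_c))
    dh = np.zeros(n_h)
    for n in range(n_trials):
        losses[n] = forward(
            W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
            orth_mat[n], has_orth[n], clamp_mat[n], has_clamp[n], ctx_mat[n],
            T, clamp_steps, target_steps, a_init, tgt_mat[n], scales[n], margin,
            P, C, h,
        )
        backward_deltas(
            W_pp, W_cp, W_pc, W_hp,
            has_clamp[n], T, clamp_steps, target_steps, tgt_mat[n], scales[n],
            margin,
            P, C, h, has_orth[n],
            Dp, Dc, dh,
        )
        apply_update(
            W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
            orth_mat[n], has_orth[n], ctx_mat[n], T, lr, delta_clip,
            P, C, h, Dp, Dc, dh,
        )


@njit(cache=True, fastmath=True)
def settle_batch(
    W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
    orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat,
    T, clamp_steps, target_steps, a_init, margin,
    final_phon, losses,
):
    """Forward-only pass over a trial block (evaluation).

    Writes the final-step phonological activations per trial and the
    unscaled cross-entropy over the target window.
    """
    n_trials = tgt_mat.shape[0]
    n_p = b_p.shape[0]
    P = np.empty((T + 1, n_p))
    C = np.empty((T + 1, b_c.shape[0]))
    h = np.empty(b_h.shape[0])
    for n in range(n_trials):
        losses[n] = forward(
            W_oh, W_ch, b_h, W_hp, W_pp, W_cp, W_xp, b_p, W_pc, b_c,
            orth_mat[n], has_orth[n], clamp_mat[n], has_clamp[n], ctx_mat[n],
            T, clamp_steps, target_steps, a_init, tgt_mat[n], 1.0, margin,
            P, C, h,
        )
        for j in range(n_p):
            final_phon[n, j] = P[T, j]
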