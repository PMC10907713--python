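"""Numba kernels: recurrent forward rollouts and backpropagation through time.

These are the numerical cores of the bond-graph network and the GRU
baseline.  Gradients are hand-derived (there is no autograd dependency)
and verified against central finite differences in the test suite.
Activation flag: 1 = tanh, 0 = identity.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# Bond-graph network: per output block b, three state-update MLPs
# f_{b,k}(q_b, u) -> dq_{b,k} and one readout MLP g_b(q_b, u) -> y_b,
# each input -> H hidden -> scalar.  Euler state update q' = q + dt * f.
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def nbg_rollout(w1f, b1f, w2f, b2f, w1g, b1g, w2g, b2g, u, q0, dt, act):
    """Sequential rollout.  Returns (y, q_traj, hf, hg) with caches for BPTT.

    Shapes: w1f (nb, ns, H, d), b1f (nb, ns, H), w2f (nb, ns, H), b2f (nb, ns),
    w1g (nb, H, d), b1g (nb, H), w2g (nb, H), b2g (nb,), u (m, T), q0 (nb, ns)
    with d = ns + m (the last axis of the first-layer weights runs over the
    MLP input [q_b, u], kept contiguous for vectorization).  q_traj is
    (T+1, nb, ns); hf, hg store post-activation hidden units.
    """
    nb, ns, nh, d = w1f.shape
    m, t_len = u.shape
    q = np.empty((t_len + 1, nb, ns))
    q[0] = q0
    hf = np.empty((t_len, nb, ns, nh))
    hg = np.empty((t_len, nb, nh))
    y = np.empty((nb, t_len))
    z = np.empty(d)
    for t in range(t_len):
        for b in range(nb):
            for j in range(ns):
                z[j] = q[t, b, j]
            for j in range(m):
                z[ns + j] = u[j, t]
            # state-update MLPs
            for k in range(ns):
                dq = b2f[b, k]
                for h in range(nh):
                    pre = b1f[b, k, h]
                    row = w1f[b, k, h]
                    for j in range(d):
                        pre += z[j] * row[j]
                    hv = np.tanh(pre) if act == 1 else pre
                    hf[t, b, k, h] = hv
                    dq += hv * w2f[b, k, h]
                q[t + 1, b, k] = q[t, b, k] + dt * dq
            # readout MLP
            yv = b2g[b]
            for h in range(nh):
                pre = b1g[b, h]
                row = w1g[b, h]
                for j in range(d):
                    pre += z[j] * row[j]
                hv = np.tanh(pre) if act == 1 else pre
                hg[t, b, h] = hv
                yv += hv * w2g[b, h]
            y[b, t] = yv
    return y, q, hf, hg


@njit(cache=True, fastmath=True)
def nbg_bptt(w1f, b1f, w2f, b2f, w1g, b1g, w2g, b2g, u, q, hf, hg, dy, dt, act):
    """Backward pass of :func:`nbg_rollout` for loss gradient ``dy`` = dL/dY.

    Returns gradients for the eight parameter tensors.
    """
    nb, ns, nh, d = w1f.shape
    m, t_len = u.shape
    gw1f = np.zeros_like(w1f)
    gb1f = np.zeros_like(b1f)
    gw2f = np.zeros_like(w2f)
    gb2f = np.zeros_like(b2f)
    gw1g = np.zeros_like(w1g)
    gb1g = np.zeros_like(b1g)
    gw2g = np.zeros_like(w2g)
    gb2g = np.zeros_like(b2g)
    gq = np.zeros((nb, ns))  # dL/dq_{t+1} entering each step
    z = np.empty(d)
    gz = np.empty(d)
    for t in range(t_len - 1, -1, -1):
        for b in range(nb):
            for j in range(ns):
                z[j] = q[t, b, j]
            for j in range(m):
                z[ns + j] = u[j, t]
            for j in range(d):
                gz[j] = 0.0
            # readout backward
            dyv = dy[b, t]
            gb2g[b] += dyv
            for h in range(nh):
                hv = hg[t, b, h]
                gw2g[b, h] += dyv * hv
                dpre = dyv * w2g[b, h]
                if act == 1:
                    dpre *= 1.0 - hv * hv
                gb1g[b, h] += dpre
                grow = gw1g[b, h]
                row = w1g[b, h]
                for j in range(d):
                    grow[j] += dpre * z[j]
                    gz[j] += dpre * row[j]
            # state-update backward; gq[b] currently holds dL/dq_{t+1,b}
            for k in range(ns):
                ddq = dt * gq[b, k]
                gb2f[b, k] += ddq
                for h in range(nh):
                    hv = hf[t, b, k, h]
                    gw2f[b, k, h] += ddq * hv
                    dpre = ddq * w2f[b, k, h]
                    if act == 1:
                        dpre *= 1.0 - hv * hv
                    gb1f[b, k, h] += dpre
                    grow = gw1f[b, k, h]
                    row = w1f[b, k, h]
                    for j in range(d):
                        grow[j] += dpre * z[j]
                        gz[j] += dpre * row[j]
            # dL/dq_t = identity path + MLP input paths
            for k in range(ns):
                gq[b, k] = gq[b, k] + gz[k]
    return gw1f, gb1f, gw2f, gb2f, gw1g, gb1g, gw2g, gb2g


# --------------------------------------------------------------------------
# GRU baseline: two GRU layers then two tanh dense layers and a linear output.
# Gate convention: z = sig(Wz x + Uz h + bz), r = sig(Wr x + Ur h + br),
# n = tanh(Wn x + r*(Un h) + bn), h' = (1-z)*n + z*h.
# --------------------------------------------------------------------------


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def gru_layer_forward(wz, uz, bz, wr, ur, br, wn, un, bn, x):
    """One GRU layer over x (m, T).  Returns (h_seq (H, T), caches)."""
    hdim = wz.shape[0]
    t_len = x.shape[1]
    h = np.zeros(hdim)
    h_seq = np.empty((hdim, t_len))
    zc = np.empty((hdim, t_len))
    rc = np.empty((hdim, t_len))
    nc = np.empty((hdim, t_len))
    unh = np.empty((hdim, t_len))  # Un @ h_prev, needed for dr
    for t in range(t_len):
        xt = x[:, t].copy()
        zt = _sigmoid(np.dot(wz, xt) + np.dot(uz, h) + bz)
        rt = _sigmoid(np.dot(wr, xt) + np.dot(ur, h) + br)
        uh = np.dot(un, h)
        nt = np.tanh(np.dot(wn, xt) + rt * uh + bn)
        h = (1.0 - zt) * nt + zt * h
        h_seq[:, t] = h
        zc[:, t] = zt
        rc[:, t] = rt
        nc[:, t] = nt
        unh[:, t] = uh
    return h_seq, zc, rc, nc, unh


@njit(cache=True)
def gru_layer_backward(wz, uz, bz, wr, ur, br, wn, un, bn, x, h_seq, zc, rc, nc, unh, dh_seq):
    """BPTT through one GRU layer.  dh_seq is dL/dh[:, t] (upstream, per step).

    Returns (dx_seq, and gradients of the nine parameter arrays).
    """
    hdim, t_len = h_seq.shape
    m = x.shape[0]
    gwz = np.zeros_like(wz)
    guz = np.zeros_like(uz)
    gbz = np.zeros_like(bz)
    gwr = np.zeros_like(wr)
    gur = np.zeros_like(ur)
    gbr = np.zeros_like(br)
    gwn = np.zeros_like(wn)
    gun = np.zeros_like(un)
    gbn = np.zeros_like(bn)
    dx_seq = np.zeros((m, t_len))
    dh = np.zeros(hdim)
    for t in range(t_len - 1, -1, -1):
        dh = dh + dh_seq[:, t]
        if t > 0:
            h_prev = h_seq[:, t - 1].copy()
        else:
            h_prev = np.zeros(hdim)
        zt = zc[:, t]
        rt = rc[:, t]
        nt = nc[:, t]
        uh = unh[:, t]
        xt = x[:, t].copy()
        dz = dh * (h_prev - nt)
        dn = dh * (1.0 - zt)
        dh_prev = dh * zt
        dn_pre = dn * (1.0 - nt * nt)
        dr = dn_pre * uh
        dh_prev = dh_prev + np.dot(un.T, dn_pre * rt)
        dz_pre = dz * zt * (1.0 - zt)
        dr_pre = dr * rt * (1.0 - rt)
        dh_prev = dh_prev + np.dot(uz.T, dz_pre) + np.dot(ur.T, dr_pre)
        gbz += dz_pre
        gbr += dr_pre
        gbn += dn_pre
        gwz += np.outer(dz_pre, xt)
        gwr += np.outer(dr_pre, xt)
        gwn += np.outer(dn_pre, xt)
        guz += np.outer(dz_pre, h_prev)
        gur += np.outer(dr_pre, h_prev)
        gun += np.outer(dn_pre * rt, h_prev)
        dx_seq[:, t] = np.dot(wz.T, dz_pre) + np.dot(wr.T, dr_pre) + np.dot(wn.T, dn_pre)
        dh = dh_prev
    return dx_seq, gwz, guz, gbz, gwr, gur, gbr, gwn, gun, gbn


@njit(cache=True)
def dense_forward(w1, c1, w2, c2, wo, co, x):
    """tanh(w1 x) -> tanh(w2 .) -> linear wo: applied columnwise to x (m, T)."""
    t_len = x.shape[1]
    a1 = np.empty((w1.shape[0], t_len))
    a2 = np.empty((w2.shape[0], t_len))
    y = np.empty((wo.shape[0], t_len))
    for t in range(t_len):
        v1 = np.tanh(np.dot(w1, x[:, t].copy()) + c1)
        v2 = np.tanh(np.dot(w2, v1) + c2)
        a1[:, t] = v1
        a2[:, t] = v2
        y[:, t] = np.dot(wo, v2) + co
    return y, a1, a2


@njit(cache=True)
def dense_backward(w1, c1, w2, c2, wo, co, x, a1, a2, dy):
    t_len = x.shape[1]
    gw1 = np.zeros_like(w1)
    gc1 = np.zeros_like(c1)
    gw2 = np.zeros_like(w2)
    gc2 = np.zeros_like(c2)
    gwo = np.zeros_like(wo)
    gco = np.zeros_like(co)
    dx = np.zeros_like(x)
    for t in range(t_len):
        dyt = dy[:, t].copy()
        gco += dyt
        gwo += np.outer(dyt, a2[:, t])
        da2 = np.dot(wo.T, dyt) * (1.0 - a2[:, t] * a2[:, t])
        gc2 += da2
        gw2 += np.outer(da2, a1[:, t])
        da1 = np.dot(w2.T, da2) * (1.0 - a1[:, t] * a1[:, t])
        gc1 += da1
        gw1 += np.outer(da1, x[:, t].copy())
        dx[:, t] = np.dot(w1.T, da1)
    return dx, gw1, gc1, gw2, gc2, gwo, gco
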