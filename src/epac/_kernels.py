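"""Numba-compiled inner loops for the settling dynamics.

The public dynamics live in :mod:`epac.actor` as plain numpy (one Euler
step at a time); these kernels run the same update for a whole phase in
compiled code.  Tests assert that stepping the numpy reference reproduces
the kernel output.
"""

import numpy as np
from numba import njit

# hidden-activation variant codes shared with epac.actor
HARD_SIGMOID_A = 0  # p(u) = clip(u, 0, 1)
HARD_SIGMOID_B = 1  # p(u) = clip((u + 1) / 2, 0, 1)


@njit(cache=False)
def settle_kernel(x_hid, x_out, s, w_in_hid, w_hid_out, w_out_hid,
                  b_hid, b_out, h, gamma_fb, nudge, anchor, iters,
                  variant, tol):
    """Iterate the coupled hidden/output Euler updates for ``iters`` steps.

    Parameters are batched: ``x_hid`` is (B, H), ``x_out`` is (B, O),
    ``s`` is (B, I).  ``nudge`` is the per-row nudging coefficient
    (beta * A(s); all zeros for the free phase) and ``anchor`` the (B, O)
    state the output is pulled toward (the one-hot action, or a supervised
    target).  Both layers read previous-iteration values on the right-hand
    side.  ``tol`` > 0 enables early stopping on max |delta x|.

    Returns ``(x_hid, x_out, iterations_run, last_max_delta, diverged_at)``
    where ``diverged_at`` is -1 unless a non-finite state appeared.
    """
    B, H = x_hid.shape
    O = x_out.shape[1]
    maxdiff = np.inf
    it = 0
    for t in range(iters):
        pre_hid = s @ w_in_hid + gamma_fb * (x_out @ w_out_hid)
        logits = x_hid @ w_hid_out
        new_hid = np.empty_like(x_hid)
        new_out = np.empty_like(x_out)
        maxdiff = 0.0
        for b in range(B):
            for j in range(H):
                u = pre_hid[b, j] + b_hid[j]
                if variant == 1:
                    u = (u + 1.0) / 2.0
                if u < 0.0:
                    u = 0.0
                elif u > 1.0:
                    u = 1.0
                v = x_hid[b, j] + h * (-x_hid[b, j] + u)
                new_hid[b, j] = v
                d = v - x_hid[b, j]
                if d < 0.0:
                    d = -d
                if d > maxdiff:
                    maxdiff = d
            m = -np.inf
            for o in range(O):
                z = logits[b, o] + b_out[o]
                new_out[b, o] = z
                if z > m:
                    m = z
            zsum = 0.0
            for o in range(O):
                e = np.exp(new_out[b, o] - m)
                new_out[b, o] = e
                zsum += e
            for o in range(O):
                sm = new_out[b, o] / zsum
                v = x_out[b, o] + h * (-x_out[b, o] + sm
                                       + nudge[b] * (anchor[b, o] - x_out[b, o]))
                new_out[b, o] = v
                d = v - x_out[b, o]
                if d < 0.0:
                    d = -d
                if d > maxdiff:
                    maxdiff = d
        x_hid = new_hid
        x_out = new_out
        it = t + 1
        if not np.isfinite(maxdiff):
            return x_hid, x_out, it, maxdiff, it
        if tol > 0.0 and maxdiff < tol:
            break
    return x_hid, x_out, it, maxdiff, -1
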