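"""Independent numerical oracle used across the test suite.

The operators under test are proximal maps of f(x) = t2*||x||_2 +
t1*||x . m||_1.  By Moreau's decomposition, prox_f(v) = v - proj_C(v)
where C is the Minkowski sum of the L2 ball of radius t2 and the box
{|w_i| <= t1*m_i} (the conjugate of a sum of norms is the indicator of
the sum of their dual balls).  The projection onto C is computed
numerically: minimise h(w) = 0.5*dist(v - w, t2*B2)^2 over the box by
accelerated projected gradient (h is convex with 1-Lipschitz gradient),
using only elementary ball/box projections.  Nothing here shares code
with the closed forms under test.
"""

import numpy as np


def _ball_proj(y, r):
    n = np.linalg.norm(y)
    return y if n <= r else y * (r / n)


def numeric_prox(v, t_l2=0.0, t_l1=0.0, mask=None, max_iter=200_000, tol=1e-12):
    """argmin_x 0.5||x - v||^2 + t_l2 ||x||_2 + t_l1 ||x * mask||_1."""
    v = np.asarray(v, dtype=float)
    d = v.size
    m = np.ones(d) if mask is None else np.asarray(mask, dtype=float)
    hi = t_l1 * m

    def grad(w):
        y = v - w
        return -(y - _ball_proj(y, t_l2))

    w = np.clip(v, -hi, hi)
    z = w.copy()
    t_mom = 1.0
    for _ in range(max_iter):
        w_new = np.clip(z - grad(z), -hi, hi)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        z = w_new + ((t_mom - 1.0) / t_new) * (w_new - w)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w, t_mom = w_new, t_new
    proj = w + _ball_proj(v - w, t_l2)
    return v - proj
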