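"""Time-stepping kernel for the compartmental cable equation.

The membrane system is tridiagonal (unbranched chain), so each implicit
step is a Thomas solve.  Synaptic conductances make the diagonal
time-dependent; everything else is assembled once.  The loop is jitted
with numba when available and falls back to the identical pure-Python
implementation otherwise (slow but exact).
"""

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _integrate(V, C_dt, gL, a, E_leak,
               syn_idx, syn_g, syn_tau, syn_onset, syn_erev,
               cl_idx, cl_amp, cl_onset, cl_end,
               dt, n_settle, n_main, theta, rec_every, out):
    """theta-method step of C·dV/dt = −A(t)·V + b(t) on a chain.

    Time runs from −n_settle·dt to n_main·dt; t = 0 is the first recorded
    sample (the baseline).  Events with negative onsets are active during
    the settle phase.  Returns −1 on success or the step index at which
    the state became non-finite.
    """
    n = V.shape[0]
    nsyn = syn_idx.shape[0]
    ncl = cl_idx.shape[0]

    # constant part of the operator diagonal: leak + axial neighbor sum
    base = np.empty(n)
    for i in range(n):
        s = gL[i]
        if i > 0:
            s += a[i - 1]
        if i < n - 1:
            s += a[i]
        base[i] = s

    rhs = np.empty(n)
    diag = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)

    rec_i = 0
    total = n_settle + n_main
    for k in range(total):
        # both endpoints as single products of dt so that comparisons with
        # grid-snapped event onsets (also multiples of dt) are exact
        t0 = (k - n_settle) * dt
        t1 = (k - n_settle + 1) * dt

        if k >= n_settle and (k - n_settle) % rec_every == 0:
            ok = True
            for i in range(n):
                out[rec_i, i] = V[i]
                if not np.isfinite(V[i]):
                    ok = False
            if not ok:
                return k
            rec_i += 1

        # rhs = C/dt·V − (1−θ)(A(t0)V − b(t0)) + θ·b(t1)
        om = 1.0 - theta
        for i in range(n):
            av = base[i] * V[i]
            if i > 0:
                av -= a[i - 1] * V[i - 1]
            if i < n - 1:
                av -= a[i] * V[i + 1]
            rhs[i] = C_dt[i] * V[i] - om * av + gL[i] * E_leak
            diag[i] = C_dt[i] + theta * base[i]

        # events are right-continuous at their onset: the implicit endpoint
        # of the step that lands exactly on the onset must not see them,
        # otherwise the event leaks one step backward in time (and would
        # contaminate the baseline sample for onset = 0)
        for s in range(nsyn):
            i = syn_idx[s]
            g0 = 0.0
            g1 = 0.0
            if t0 >= syn_onset[s]:
                g0 = syn_g[s] * np.exp(-(t0 - syn_onset[s]) / syn_tau[s])
            if t1 > syn_onset[s]:
                g1 = syn_g[s] * np.exp(-(t1 - syn_onset[s]) / syn_tau[s])
            rhs[i] += om * g0 * (syn_erev[s] - V[i]) + theta * g1 * syn_erev[s]
            diag[i] += theta * g1

        for c in range(ncl):
            i = cl_idx[c]
            i0 = cl_amp[c] if (cl_onset[c] <= t0 < cl_end[c]) else 0.0
            i1 = cl_amp[c] if (cl_onset[c] < t1 < cl_end[c]) else 0.0
            rhs[i] += om * i0 + theta * i1

        # Thomas solve: (C/dt + θA(t1)) V_new = rhs
        cp[0] = -theta * a[0] / diag[0] if n > 1 else 0.0
        dp[0] = rhs[0] / diag[0]
        for i in range(1, n):
            low = -theta * a[i - 1]
            m = diag[i] - low * cp[i - 1]
            cp[i] = (-theta * a[i] / m) if i < n - 1 else 0.0
            dp[i] = (rhs[i] - low * dp[i - 1]) / m
        V[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            V[i] = dp[i] - cp[i] * V[i + 1]

    for i in range(n):
        out[rec_i, i] = V[i]
        if not np.isfinite(V[i]):
            return total
    return -1
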