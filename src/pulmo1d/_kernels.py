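"""Low-level time-stepping kernel for the 1D network solver.

The kernel advances conservative variables (A, Q) on a flattened network
with the two-step (Richtmyer) Lax-Wendroff scheme in the interior and
characteristic-based Newton closures at the inlet, junctions, and
Windkessel outlets.  Everything is written in numba-compatible style; when
numba is unavailable the same code runs as plain Python (slow but exact).

Flattened layout (built by :mod:`pulmo1d.solver`):
  off[s]..off[s+1]-1 : global node indices of segment s (x increasing,
                       proximal -> distal)
  dx, fwall, adia, pdia : per-segment grid spacing, wall stiffness Eh/r0,
                          reference area, reference pressure
  junc[j]            : (parent_seg, child1_seg, child2_seg)
  term[m], wk[m]     : terminal segment index and its (Rp, Rd, C, Pout)

Status codes returned by :func:`run_cycle`:
  0 ok, 1 CFL violation, 2 nonpositive area, 3 junction Newton failure,
  4 inlet/outlet Newton failure.
"""

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


NEWTON_MAXIT = 30
NEWTON_TOL = 1e-14  # scaled residual target; bottoms out near machine eps


@njit(cache=True)
def _cw(a, c2, ad):
    """Wave speed c = sqrt(c2 * sqrt(A/Adia)) with c2 = 2*(Eh/r0)/(3*rho)."""
    return math.sqrt(c2 * math.sqrt(a / ad))


@njit(cache=True)
def _ptube(a, fwall, ad, pd):
    return (4.0 / 3.0) * fwall * (math.sqrt(a / ad) - 1.0) + pd


@njit(cache=True)
def _w_minus(A, Q, i0, h, dt, c2, ad, fric):
    """Outgoing (left-running) invariant u - 4c at a segment inlet.

    Evaluated at the foot of the characteristic that reaches the boundary
    node after dt (linearly interpolated between the first two nodes) and
    advanced by the friction source -fric*Q/A^2 acting on u along the path.
    """
    u0 = Q[i0] / A[i0]
    c0 = _cw(A[i0], c2, ad)
    th = (c0 - u0) * dt / h
    if th < 0.0:
        th = 0.0
    elif th > 1.0:
        th = 1.0
    af = (1.0 - th) * A[i0] + th * A[i0 + 1]
    qf = (1.0 - th) * Q[i0] + th * Q[i0 + 1]
    return qf / af - 4.0 * _cw(af, c2, ad) - dt * fric * qf / (af * af)


@njit(cache=True)
def _w_plus(A, Q, ie, h, dt, c2, ad, fric):
    """Outgoing (right-running) invariant u + 4c at a segment outlet."""
    u0 = Q[ie] / A[ie]
    c0 = _cw(A[ie], c2, ad)
    th = (u0 + c0) * dt / h
    if th < 0.0:
        th = 0.0
    elif th > 1.0:
        th = 1.0
    af = (1.0 - th) * A[ie] + th * A[ie - 1]
    qf = (1.0 - th) * Q[ie] + th * Q[ie - 1]
    return qf / af + 4.0 * _cw(af, c2, ad) - dt * fric * qf / (af * af)


@njit(cache=True)
def _solve_inlet(qb, wminus, a_guess, c2, ad):
    """Area at the inlet from prescribed Q and the outgoing invariant."""
    a = a_guess
    g = 0.0
    for _ in range(NEWTON_MAXIT):
        c = _cw(a, c2, ad)
        g = qb / a - 4.0 * c - wminus
        if abs(g) <= NEWTON_TOL * (1.0 + abs(wminus)):
            return a, 0
        dg = -qb / (a * a) - c / a
        a_new = a - g / dg
        if a_new <= 0.0:
            a_new = 0.5 * a
        a = a_new
    if abs(g) <= 1e-8 * (1.0 + abs(wminus)):
        return a, 0
    return a, 4


@njit(cache=True)
def _solve_junction(
    X, J, R, wp, w1, w2,
    fp, c2p, adp, pdp,
    f1, c21, ad1, pd1,
    f2, c22, ad2, pd2,
):
    """Newton solve of the six-equation bifurcation system.

    Unknowns X = (Qp, Ap, Q1, A1, Q2, A2).  Equations: parent forward
    invariant, two daughter backward invariants, flow conservation
    Qp = Q1 + Q2, and pressure continuity Pp = P1 = P2.  ``f*`` are the
    wall stiffnesses Eh/r0 and ``c2*`` the 2*(Eh/r0)/(3*rho) factors.
    Returns (status, scaled_flow_res, scaled_pressure_res).
    """
    status = 3
    fres = 0.0
    pres = 0.0
    for _ in range(NEWTON_MAXIT):
        qp, ap, q1, a1, q2, a2 = X[0], X[1], X[2], X[3], X[4], X[5]
        cp = _cw(ap, c2p, adp)
        c1 = _cw(a1, c21, ad1)
        c2_ = _cw(a2, c22, ad2)
        pp = _ptube(ap, fp, adp, pdp)
        p1 = _ptube(a1, f1, ad1, pd1)
        p2 = _ptube(a2, f2, ad2, pd2)
        R[0] = qp / ap + 4.0 * cp - wp
        R[1] = q1 / a1 - 4.0 * c1 - w1
        R[2] = q2 / a2 - 4.0 * c2_ - w2
        R[3] = qp - q1 - q2
        R[4] = pp - p1
        R[5] = pp - p2
        wscale = 1.0 + abs(wp)
        pscale = 1.0 + abs(pp)
        qsc = 1.0 + abs(qp)
        fres = abs(R[3]) / qsc
        pres = max(abs(R[4]), abs(R[5])) / pscale
        res = max(
            abs(R[0]) / wscale, abs(R[1]) / wscale, abs(R[2]) / wscale, fres, pres
        )
        if res <= NEWTON_TOL:
            status = 0
            break
        for i in range(6):
            for j in range(6):
                J[i, j] = 0.0
        dpdap = (2.0 / 3.0) * fp / math.sqrt(ap * adp)
        dpda1 = (2.0 / 3.0) * f1 / math.sqrt(a1 * ad1)
        dpda2 = (2.0 / 3.0) * f2 / math.sqrt(a2 * ad2)
        J[0, 0] = 1.0 / ap
        J[0, 1] = -qp / (ap * ap) + cp / ap
        J[1, 2] = 1.0 / a1
        J[1, 3] = -q1 / (a1 * a1) - c1 / a1
        J[2, 4] = 1.0 / a2
        J[2, 5] = -q2 / (a2 * a2) - c2_ / a2
        J[3, 0] = 1.0
        J[3, 2] = -1.0
        J[3, 4] = -1.0
        J[4, 1] = dpdap
        J[4, 3] = -dpda1
        J[5, 1] = dpdap
        J[5, 5] = -dpda2
        dX = np.linalg.solve(J, R)
        for i in range(6):
            X[i] = X[i] - dX[i]
        for i in (1, 3, 5):
            if X[i] <= 0.0:
                X[i] = 0.25 * (X[i] + dX[i])
    if status != 0 and max(fres, pres) <= 1e-8:
        status = 0
    return status, fres, pres


@njit(cache=True)
def _solve_outlet(wplus, q0, a0, pc_prev, rp, rd, cwk, pout, dt, fwall, c2, ad, pd):
    """Windkessel outlet: solve (Q, A) against the forward invariant and the
    implicit-Euler RCR relation.  Returns (q, a, pc_next, status)."""
    q = q0
    a = a0
    den = 1.0 + dt / (rd * cwk)
    status = 4
    r0 = 0.0
    r1 = 0.0
    p = pd
    for _ in range(NEWTON_MAXIT):
        c = _cw(a, c2, ad)
        pc_next = (pc_prev + dt / cwk * (q + pout / rd)) / den
        p = _ptube(a, fwall, ad, pd)
        r0 = q / a + 4.0 * c - wplus
        r1 = p - rp * q - pc_next
        if abs(r0) <= NEWTON_TOL * (1.0 + abs(wplus)) and abs(r1) <= NEWTON_TOL * (
            1.0 + abs(p)
        ):
            status = 0
            break
        j00 = 1.0 / a
        j01 = -q / (a * a) + c / a
        j10 = -rp - (dt / cwk) / den
        j11 = (2.0 / 3.0) * fwall / math.sqrt(a * ad)
        det = j00 * j11 - j01 * j10
        dq = (r0 * j11 - r1 * j01) / det
        da = (j00 * r1 - j10 * r0) / det
        q -= dq
        a_new = a - da
        if a_new <= 0.0:
            a_new = 0.5 * a
        a = a_new
    pc_next = (pc_prev + dt / cwk * (q + pout / rd)) / den
    if status != 0 and abs(r0) <= 1e-8 * (1.0 + abs(wplus)) and abs(r1) <= 1e-8 * (
        1.0 + abs(p)
    ):
        status = 0
    return q, a, pc_next, status


@njit(cache=True)
def run_cycle(
    A,
    Q,
    Pc,
    A_hist,
    Q_hist,
    off,
    dx,
    fwall,
    adia,
    pdia,
    junc,
    term,
    wk,
    root,
    qin,
    dt,
    gamma,
    rho,
    mu,
):
    """Advance one cardiac cycle (len(qin)-1 steps) in place.

    Returns (status, max_flow_residual, max_pressure_residual, max_cfl_ratio)
    where the residuals are the junction Newton residuals scaled by local
    flow/pressure magnitude and max_cfl_ratio is max (|u|+c)*dt/dx.
    """
    nseg = dx.shape[0]
    njunc = junc.shape[0]
    nterm = term.shape[0]
    ntot = A.shape[0]
    n_steps = qin.shape[0] - 1
    alpha = (gamma + 2.0) / (gamma + 1.0)
    fric = 2.0 * math.pi * mu * (gamma + 2.0) / rho

    An = np.empty(ntot)
    Qn = np.empty(ntot)
    Ah = np.empty(ntot)
    Qh = np.empty(ntot)
    X = np.empty(6)
    J = np.empty((6, 6))
    R = np.empty(6)
    c2 = np.empty(nseg)
    cB = np.empty(nseg)
    for s in range(nseg):
        c2[s] = 2.0 * fwall[s] / (3.0 * rho)
        cB[s] = 4.0 * fwall[s] / (9.0 * rho * math.sqrt(adia[s]))

    A_hist[0, :] = A
    Q_hist[0, :] = Q

    max_fres = 0.0
    max_pres = 0.0
    max_cfl = 0.0

    for k in range(n_steps):
        # --- interior Richtmyer update ---------------------------------
        for s in range(nseg):
            i0 = off[s]
            i1 = off[s + 1]
            h = dx[s]
            cb = cB[s]
            for j in range(i0, i1 - 1):
                a0 = A[j]
                a1 = A[j + 1]
                q0 = Q[j]
                q1 = Q[j + 1]
                f2_0 = alpha * q0 * q0 / a0 + cb * a0 * math.sqrt(a0)
                f2_1 = alpha * q1 * q1 / a1 + cb * a1 * math.sqrt(a1)
                s2_0 = -fric * q0 / a0
                s2_1 = -fric * q1 / a1
                Ah[j] = 0.5 * (a0 + a1) - 0.5 * dt / h * (q1 - q0)
                Qh[j] = (
                    0.5 * (q0 + q1)
                    - 0.5 * dt / h * (f2_1 - f2_0)
                    + 0.25 * dt * (s2_0 + s2_1)
                )
            for j in range(i0 + 1, i1 - 1):
                al = Ah[j - 1]
                ar = Ah[j]
                ql = Qh[j - 1]
                qr = Qh[j]
                if al <= 0.0 or ar <= 0.0:
                    return 2, max_fres, max_pres, max_cfl
                f2l = alpha * ql * ql / al + cb * al * math.sqrt(al)
                f2r = alpha * qr * qr / ar + cb * ar * math.sqrt(ar)
                s2l = -fric * ql / al
                s2r = -fric * qr / ar
                An[j] = A[j] - dt / h * (qr - ql)
                Qn[j] = Q[j] - dt / h * (f2r - f2l) + 0.5 * dt * (s2l + s2r)

        # --- inlet: prescribed flow + outgoing invariant ----------------
        i0 = off[root]
        wm = _w_minus(A, Q, i0, dx[root], dt, c2[root], adia[root], fric)
        qb = qin[k + 1]
        ab, st = _solve_inlet(qb, wm, A[i0], c2[root], adia[root])
        if st != 0:
            return 4, max_fres, max_pres, max_cfl
        An[i0] = ab
        Qn[i0] = qb

        # --- junctions --------------------------------------------------
        for jj in range(njunc):
            p = junc[jj, 0]
            d1 = junc[jj, 1]
            d2 = junc[jj, 2]
            ip = off[p + 1] - 1
            j1 = off[d1]
            j2 = off[d2]
            wp = _w_plus(A, Q, ip, dx[p], dt, c2[p], adia[p], fric)
            w1 = _w_minus(A, Q, j1, dx[d1], dt, c2[d1], adia[d1], fric)
            w2 = _w_minus(A, Q, j2, dx[d2], dt, c2[d2], adia[d2], fric)
            X[0] = Q[ip]
            X[1] = A[ip]
            X[2] = Q[j1]
            X[3] = A[j1]
            X[4] = Q[j2]
            X[5] = A[j2]
            st, fres, pres = _solve_junction(
                X, J, R, wp, w1, w2,
                fwall[p], c2[p], adia[p], pdia[p],
                fwall[d1], c2[d1], adia[d1], pdia[d1],
                fwall[d2], c2[d2], adia[d2], pdia[d2],
            )
            if st != 0:
                return 3, max_fres, max_pres, max_cfl
            if fres > max_fres:
                max_fres = fres
            if pres > max_pres:
                max_pres = pres
            Qn[ip] = X[0]
            An[ip] = X[1]
            Qn[j1] = X[2]
            An[j1] = X[3]
            Qn[j2] = X[4]
            An[j2] = X[5]

        # --- Windkessel outlets ----------------------------------------
        for m in range(nterm):
            s = term[m]
            ie = off[s + 1] - 1
            wpl = _w_plus(A, Q, ie, dx[s], dt, c2[s], adia[s], fric)
            q, a, pc_next, st = _solve_outlet(
                wpl,
                Q[ie],
                A[ie],
                Pc[m],
                wk[m, 0],
                wk[m, 1],
                wk[m, 2],
                wk[m, 3],
                dt,
                fwall[s],
                c2[s],
                adia[s],
                pdia[s],
            )
            if st != 0:
                return 4, max_fres, max_pres, max_cfl
            Qn[ie] = q
            An[ie] = a
            Pc[m] = pc_next

        # --- commit, check positivity and CFL ---------------------------
        for s in range(nseg):
            i0 = off[s]
            i1 = off[s + 1]
            h = dx[s]
            for j in range(i0, i1):
                a = An[j]
                if a <= 0.0 or not math.isfinite(a):
                    return 2, max_fres, max_pres, max_cfl
                sp = abs(Qn[j] / a) + _cw(a, c2[s], adia[s])
                ratio = sp * dt / h
                if ratio > max_cfl:
                    max_cfl = ratio
                A[j] = a
                Q[j] = Qn[j]
        if max_cfl > 1.0:
            return 1, max_fres, max_pres, max_cfl
        A_hist[k + 1, :] = A
        Q_hist[k + 1, :] = Q

    return 0, max_fres, max_pres, max_cfl
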