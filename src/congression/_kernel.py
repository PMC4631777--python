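"""Compiled inner loop of the overdamped force-balance spindle model.

Everything here operates on plain float64 / int8 arrays so that a single
metaphase-to-anaphase simulation (about 18 000 Euler steps) runs in a few
milliseconds and ensembles of several hundred runs stay cheap.

State layout (1-D spindle axis, microns):

* ``x_poles``   shape (2,)        -- left / right spindle pole body.
* ``x_cen``     shape (N, 2)      -- sister centromeres of each chromosome.
* ``x_site``    shape (N, 2, M)   -- microtubule attachment sites.
* ``att``       shape (N, 2, M)   -- attached pole: -1 detached, 0 left, 1 right.
* ``pi``        shape (N, 2, M)   -- attachment state: +1 correct, -1 erroneous,
                                     0 detached.

The attachment state ``pi`` is pure bookkeeping (a site is always pulled
toward the pole it is attached to); its sign records whether the pole was on
the site's own side of the sister-pair midpoint at the moment of attachment.
"""

import numpy as np
from numba import njit

__all__ = ["advance_positions", "attachment_events", "simulate_core"]


@njit(cache=True)
def advance_positions(
    x_poles, x_cen, x_site, att, v_cen, v_site, v_poles,
    F_k, V_k, K_c, d_0, K_k, mu_k, mu_site, mu_ch, mu_spb,
    F_mz, V_mz, alpha, d_mean, ldep_on, cohesin_on, dt,
):
    """One explicit overdamped Euler step for all mechanical elements.

    Sites are solved first (their force-velocity term is handled implicitly
    in their own velocity, which keeps the scheme stable at dt = 0.05 s),
    then centromeres, then poles, which receive the reaction of the pulling
    forces plus the midzone pushing force.  Damper cross-terms use the
    velocities of the previous step (stored in ``v_cen`` / ``v_site``).
    """
    N, S, M = x_site.shape
    pole_force = np.zeros(2)
    new_v_site = np.empty((N, S, M))
    new_v_cen = np.empty((N, S))

    for c in range(N):
        for s in range(S):
            xc = x_cen[c, s]
            for m in range(M):
                xs = x_site[c, s, m]
                p = att[c, s, m]
                num = K_k * (xc - xs) + mu_k * v_cen[c, s]
                drag = mu_site + mu_k
                if p >= 0:
                    xp = x_poles[p]
                    e = 1.0 if xp >= xs else -1.0
                    if ldep_on:
                        L = 1.0 + alpha * (abs(xp - xs) / d_mean - 1.0)
                        if L < 0.0:
                            L = 0.0
                    else:
                        L = 1.0
                    num += e * L * F_k
                    drag += L * F_k / V_k
                vs = num / drag
                new_v_site[c, s, m] = vs
                if p >= 0:
                    # Newton's third law: the kinetochore MT pulls the pole
                    # toward the site with the same (velocity-reduced) force.
                    f_site = e * L * F_k * (1.0 - e * vs / V_k)
                    pole_force[p] -= f_site

    for c in range(N):
        for s in range(S):
            num = 0.0
            for m in range(M):
                num += K_k * (x_site[c, s, m] - x_cen[c, s])
                num += mu_k * new_v_site[c, s, m]
            if cohesin_on:
                o = 1 - s
                dvec = x_cen[c, o] - x_cen[c, s]
                dist = abs(dvec)
                if dist > 0.0:
                    u = 1.0 if dvec > 0.0 else -1.0
                else:
                    # coincident sisters: push them apart deterministically
                    u = 1.0 if s == 0 else -1.0
                num += K_c * (dist - d_0) * u
            new_v_cen[c, s] = num / (mu_ch + M * mu_k)

    for p in range(2):
        e_out = -1.0 if p == 0 else 1.0
        v_poles[p] = (e_out * F_mz + pole_force[p]) / (mu_spb + F_mz / V_mz)

    x_poles[0] += v_poles[0] * dt
    x_poles[1] += v_poles[1] * dt
    for c in range(N):
        for s in range(S):
            x_cen[c, s] += new_v_cen[c, s] * dt
            v_cen[c, s] = new_v_cen[c, s]
            for m in range(M):
                x_site[c, s, m] += new_v_site[c, s, m] * dt
                v_site[c, s, m] = new_v_site[c, s, m]


@njit(cache=True)
def attachment_events(
    x_cen, x_site, att, pi,
    k_a, k_d, d_alpha, d_floor, beta, dt, u_evt, u_pole,
):
    """Stochastic attachment / detachment update for every site.

    ``u_evt`` and ``u_pole`` are uniform(0,1) draws of shape (N, 2, M); one
    pair is consumed per site per step so random streams stay aligned no
    matter which events fire.

    * detached site: attaches with probability min(k_a*dt, 1); the target
      pole is biased toward the "correct" pole (the pole on the sister's own
      side of the pair midpoint) with probability (1+beta)/2 whenever the
      pair already holds at least one attachment, and is equiprobable for a
      fully unattached pair.
    * attached site: detaches with probability min(rate*dt, 1) where
      rate = k_d * d_alpha / max(d_site_center, d_floor) -- the Aurora-B-like
      destabilisation of low-tension attachments near the pair centre.
    """
    N, S, M = x_site.shape
    for c in range(N):
        mid = 0.5 * (x_cen[c, 0] + x_cen[c, 1])
        left_att = False
        right_att = False
        for s in range(S):
            for m in range(M):
                if att[c, s, m] == 0:
                    left_att = True
                elif att[c, s, m] == 1:
                    right_att = True
        for s in range(S):
            for m in range(M):
                p = att[c, s, m]
                if p < 0:
                    p_att = k_a * dt
                    if p_att > 1.0:
                        p_att = 1.0
                    if u_evt[c, s, m] < p_att:
                        side = x_cen[c, s] - mid
                        if side < 0.0 or (side == 0.0 and s == 0):
                            cor = 0
                        else:
                            cor = 1
                        if left_att or right_att:
                            if u_pole[c, s, m] < 0.5 * (1.0 + beta):
                                newp = cor
                            else:
                                newp = 1 - cor
                        else:
                            newp = 0 if u_pole[c, s, m] < 0.5 else 1
                        att[c, s, m] = newp
                        pi[c, s, m] = 1 if newp == cor else -1
                else:
                    d = abs(x_site[c, s, m] - mid)
                    if d < d_floor:
                        d = d_floor
                    p_det = k_d * d_alpha / d * dt
                    if p_det > 1.0:
                        p_det = 1.0
                    if u_evt[c, s, m] < p_det:
                        att[c, s, m] = -1
                        pi[c, s, m] = 0


@njit(cache=True)
def simulate_core(
    seed,
    N, M,
    F_k, V_k, k_a, k_d, d_alpha, d_floor, beta,
    K_c, d_0, K_k, mu_k, mu_site, mu_ch, mu_spb,
    F_mz, V_mz, alpha, d_mean, ldep_enabled,
    dt, n_steps_meta, n_steps_total, rec_every, L0,
):
    """Full metaphase + anaphase-A simulation, recording every ``rec_every``
    steps.  During anaphase the cohesin spring is released and the
    length-dependent prefactor is forced to 1."""
    np.random.seed(seed)

    x_poles = np.empty(2)
    x_poles[0] = -0.5 * L0
    x_poles[1] = 0.5 * L0
    x_cen = np.empty((N, 2))
    x_site = np.empty((N, 2, M))
    for c in range(N):
        x_cen[c, 0] = -0.5 * d_0
        x_cen[c, 1] = 0.5 * d_0
        for m in range(M):
            x_site[c, 0, m] = x_cen[c, 0]
            x_site[c, 1, m] = x_cen[c, 1]
    att = -np.ones((N, 2, M), dtype=np.int8)
    pi = np.zeros((N, 2, M), dtype=np.int8)
    v_cen = np.zeros((N, 2))
    v_site = np.zeros((N, 2, M))
    v_poles = np.zeros(2)
    u_evt = np.empty((N, 2, M))
    u_pole = np.empty((N, 2, M))

    n_rec = n_steps_total // rec_every + 1
    rec_t = np.empty(n_rec)
    rec_poles = np.empty((n_rec, 2))
    rec_cen = np.empty((n_rec, N, 2))
    rec_site = np.empty((n_rec, N, 2, M))
    rec_att = np.empty((n_rec, N, 2, M), dtype=np.int8)
    rec_pi = np.empty((n_rec, N, 2, M), dtype=np.int8)
    rec_ana = np.zeros(n_rec, dtype=np.bool_)

    k = 0
    rec_t[k] = 0.0
    rec_poles[k] = x_poles
    rec_cen[k] = x_cen
    rec_site[k] = x_site
    rec_att[k] = att
    rec_pi[k] = pi
    k += 1

    for i in range(1, n_steps_total + 1):
        metaphase = i <= n_steps_meta
        ldep_on = ldep_enabled and metaphase
        advance_positions(
            x_poles, x_cen, x_site, att, v_cen, v_site, v_poles,
            F_k, V_k, K_c, d_0, K_k, mu_k, mu_site, mu_ch, mu_spb,
            F_mz, V_mz, alpha, d_mean, ldep_on, metaphase, dt,
        )
        for c in range(N):
            for s in range(2):
                for m in range(M):
                    u_evt[c, s, m] = np.random.random()
                    u_pole[c, s, m] = np.random.random()
        attachment_events(
            x_cen, x_site, att, pi,
            k_a, k_d, d_alpha, d_floor, beta, dt, u_evt, u_pole,
        )
        if i % rec_every == 0:
            rec_t[k] = i * dt
            rec_poles[k] = x_poles
            rec_cen[k] = x_cen
            rec_site[k] = x_site
            rec_att[k] = att
            rec_pi[k] = pi
            rec_ana[k] = not metaphase
            k += 1

    return rec_t, rec_poles, rec_cen, rec_site, rec_att, rec_pi, rec_ana
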