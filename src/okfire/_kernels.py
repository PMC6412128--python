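"""Compiled inner loops of the reversible-jump MCMC sampler.

One chain keeps, per cell, the licenced set and firing times, plus a per-box
tally of cells whose forward-strand profile bit is 1 (the incremental form of
``M * F_ave``).  A sweep comprises:

(1) Metropolis random walks on firing times for a fraction of cells (the
    likelihood change is evaluated only on boxes whose bit flipped);
(2) reversible-jump licencing toggles: a death removes an origin's licencing
    and firing time in a cell, a birth adds them with the time proposed from
    its conditional prior N(mu_i, sigma_i^2), so the acceptance ratio is the
    likelihood ratio times q/(1-q) (unit Jacobian); proposals creating
    prohibited cells are rejected;
(3) per-origin hyperparameter draws given the latent population: mu and
    sigma^2 by conjugate Gibbs (Gaussian / inverse-gamma posteriors), q by
    an exact draw of its Beta conditional tilted by the admissibility
    factor Z(q)^-M (see the q block below);
(4) joint group moves that decouple the hyperparameters from the slowly
    moving latent times: a translation move shifts mu_i and every licenced
    t_i together (acceptance = likelihood ratio times the mu prior ratio;
    the latent prior is shift-invariant), and a scale move multiplies
    sigma_i and the centred times (t_i - mu_i) by a common log-normal
    factor c, for which the latent-prior and Jacobian terms collapse to
    c^(-2 a0) exp(-(b0/sigma^2)(c^-2 - 1)).  Without these the sigma Gibbs
    draws are pinned to the current latent dispersion and mix very slowly;
(5) Metropolis updates of the noise precision tau (log-scale walk, gamma
    prior) and the background weight b (logit-scale walk, uniform prior).

Absolute firing times are unobservable (the likelihood depends only on time
differences), so mu carries a proper weakly informative N(0, A^2) prior that
pins the common offset; the conventional sum(mu) = 0 normalization is applied
to reported samples, not inside the chain.

Proposal scales adapt toward a target acceptance rate during burn-in only
(Robbins-Monro with 1/sqrt(block) gain), frozen afterwards so the sampled
chain has the exact stationary distribution.

The kernel uses numba's global RNG; call :func:`seed_rng` once per chain.
Layout of the packed arrays:

* ``theta``: mu[0:3], sigma[3:6], q[6:9], b[9], tau[10]
* ``step``:  per-origin time steps [0:3], log-tau [3], logit-b [4],
  per-origin translation [5:8], log-scale [8]
* ``upd``:   int8 flags [times, mu, sigma, b, tau]
* ``pri``:   [sigma_a0, sigma_b0, q_a, q_b, tau_a, tau_b, mu_prior_var]
* ``acc``:   accept/attempt pairs [time, rj, tau, b, shift, scale]
"""

import numpy as np
from numba import njit

_Q_EPS = 1e-12


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _box_ll(lcf, lcr, tally, M, b, tau):
    # log-normal log-density of both strands in one box, dropping the
    # parameter-free -log(x) terms (constant in every Metropolis ratio)
    F = tally / M
    mf = (1.0 - b) * F + 0.5 * b
    mr = 1.0 - mf
    h = 0.5 / tau
    ef = lcf - np.log(mf) + h
    er = lcr - np.log(mr) + h
    return np.log(tau / (2.0 * np.pi)) - 0.5 * tau * (ef * ef + er * er)


@njit(cache=True)
def total_ll(lcf, lcr, tallies, M, b, tau):
    s = 0.0
    for m in range(lcf.shape[0]):
        s += _box_ll(lcf[m], lcr[m], tallies[m], M, b, tau)
    return s


@njit(cache=True)
def _realized_row(lic, t, x, real):
    n = 0
    for i in range(3):
        r = False
        if lic[i]:
            a = np.inf
            for j in range(3):
                if j != i and lic[j]:
                    v = t[j] + abs(x[i] - x[j])
                    if v < a:
                        a = v
            if t[i] < a:
                r = True
        real[i] = r
        if r:
            n += 1
    return n


@njit(cache=True, inline="always")
def _admissible(real, nreal):
    if nreal == 0:
        return False
    if nreal == 1 and not real[1]:
        return False
    return True


@njit(cache=True)
def _bits_row(real, t, x, xm, bits):
    for m in range(xm.shape[0]):
        best = np.inf
        bj = 0
        for j in range(3):
            if real[j]:
                v = t[j] + abs(xm[m] - x[j])
                if v < best:
                    best = v
                    bj = j
        bits[m] = 1 if x[bj] <= xm[m] else 0


@njit(cache=True)
def recompute_tallies(lic, times, x, xm, tallies):
    nb = xm.shape[0]
    for m in range(nb):
        tallies[m] = 0
    real = np.empty(3, np.bool_)
    bits = np.empty(nb, np.int64)
    for c in range(lic.shape[0]):
        _realized_row(lic[c], times[c], x, real)
        _bits_row(real, times[c], x, xm, bits)
        for m in range(nb):
            tallies[m] += bits[m]


@njit(cache=True)
def _tallies_if_admissible(lic, times, x, xm, out):
    """Recompute tallies from scratch; returns False if any cell is prohibited."""
    nb = xm.shape[0]
    for m in range(nb):
        out[m] = 0
    real = np.empty(3, np.bool_)
    bits = np.empty(nb, np.int64)
    for c in range(lic.shape[0]):
        nr = _realized_row(lic[c], times[c], x, real)
        if not _admissible(real, nr):
            return False
        _bits_row(real, times[c], x, xm, bits)
        for m in range(nb):
            out[m] += bits[m]
    return True


@njit(cache=True)
def _delta_and_maybe_apply(lcf, lcr, tallies, bits_old, bits_new, M, b, tau):
    d = 0.0
    for m in range(bits_old.shape[0]):
        if bits_new[m] != bits_old[m]:
            tn = tallies[m] - bits_old[m] + bits_new[m]
            d += _box_ll(lcf[m], lcr[m], tn, M, b, tau) - _box_ll(
                lcf[m], lcr[m], tallies[m], M, b, tau
            )
    return d


@njit(cache=True)
def _apply_bits(tallies, bits_old, bits_new):
    for m in range(bits_old.shape[0]):
        if bits_new[m] != bits_old[m]:
            tallies[m] += bits_new[m] - bits_old[m]
            bits_old[m] = bits_new[m]


_Q_GRID = 4096


@njit(cache=True)
def _draw_q_conditional(A, B, za, zb, M, qgrid, lgq, lgq1, w):
    """Draw from p(q) ~ q^(A-1) (1-q)^(B-1) (za + zb q)^(-M) on (0, 1).

    Inverse-CDF on a fixed midpoint grid; the grid spacing (1/4096) is far
    below the conditional's scale (s.d. >= ~1/sqrt(M_cells) in practice).
    """
    G = qgrid.shape[0]
    mx = -np.inf
    for k in range(G):
        z = za + zb * qgrid[k]
        if z < 1e-300:
            z = 1e-300
        v = (A - 1.0) * lgq[k] + (B - 1.0) * lgq1[k] - M * np.log(z)
        w[k] = v
        if v > mx:
            mx = v
    total = 0.0
    for k in range(G):
        w[k] = np.exp(w[k] - mx)
        total += w[k]
    u = np.random.random() * total
    acc_w = 0.0
    for k in range(G):
        acc_w += w[k]
        if acc_w >= u:
            return qgrid[k]
    return qgrid[G - 1]


@njit(cache=True)
def run_chain(
    lcf,
    lcr,
    x,
    xm,
    lic,
    times,
    tallies,
    theta,
    n_sweeps,
    n_update,
    step,
    adapt,
    target,
    upd,
    updq,
    lic_idx,
    pri,
    record_every,
    out_theta,
    out_rfrac,
    out_obsc,
    out_pairfrac,
    out_sub_lic,
    out_sub_t,
    out_sub_coll,
    out_sub_pair,
    acc,
):
    M = lic.shape[0]
    nb = xm.shape[0]
    real = np.empty(3, np.bool_)
    bits_old = np.empty(nb, np.int64)
    bits_new = np.empty(nb, np.int64)
    tallies_new = np.empty(nb, np.int64)
    tcol = np.empty(M)
    qgrid = (np.arange(_Q_GRID) + 0.5) / _Q_GRID
    lgq = np.log(qgrid)
    lgq1 = np.log(1.0 - qgrid)
    wgrid = np.empty(_Q_GRID)
    n_sub = out_sub_lic.shape[1]
    nlic_upd = lic_idx.shape[0]
    rec = 0
    # per-block adaptation counters (reset every block); acc[] is cumulative
    at_a = 0.0
    at_t = 0.0
    atau_a = 0.0
    atau_t = 0.0
    ab_a = 0.0
    ab_t = 0.0
    ash_a = 0.0
    ash_t = 0.0
    asc_a = 0.0
    asc_t = 0.0
    block = 0

    for sweep in range(1, n_sweeps + 1):
        b = theta[9]
        tau = theta[10]

        # ---- (1) + (2): per-cell latent moves -------------------------------
        for _u in range(n_update):
            c = np.random.randint(0, M)
            nr = _realized_row(lic[c], times[c], x, real)
            _bits_row(real, times[c], x, xm, bits_old)

            if upd[0] == 1:  # firing-time random walks
                for i in range(3):
                    if lic[c, i]:
                        told = times[c, i]
                        times[c, i] = told + step[i] * np.random.standard_normal()
                        nr2 = _realized_row(lic[c], times[c], x, real)
                        at_t += 1.0
                        acc[1] += 1.0
                        accepted = False
                        if _admissible(real, nr2):
                            _bits_row(real, times[c], x, xm, bits_new)
                            d = _delta_and_maybe_apply(
                                lcf, lcr, tallies, bits_old, bits_new, M, b, tau
                            )
                            dm = times[c, i] - theta[i]
                            dmo = told - theta[i]
                            dprior = (dmo * dmo - dm * dm) / (2.0 * theta[3 + i] * theta[3 + i])
                            if np.log(np.random.random()) < d + dprior:
                                _apply_bits(tallies, bits_old, bits_new)
                                at_a += 1.0
                                acc[0] += 1.0
                                accepted = True
                        if not accepted:
                            times[c, i] = told

            if nlic_upd > 0:  # reversible-jump licencing toggle
                i = lic_idx[np.random.randint(0, nlic_upd)]
                qi = theta[6 + i]
                if qi < _Q_EPS:
                    qi = _Q_EPS
                if qi > 1.0 - _Q_EPS:
                    qi = 1.0 - _Q_EPS
                acc[3] += 1.0
                if lic[c, i]:
                    # death: drop licencing and the firing time
                    told = times[c, i]
                    lic[c, i] = False
                    times[c, i] = 0.0
                    nr2 = _realized_row(lic[c], times[c], x, real)
                    reverted = True
                    if _admissible(real, nr2):
                        _bits_row(real, times[c], x, xm, bits_new)
                        d = _delta_and_maybe_apply(lcf, lcr, tallies, bits_old, bits_new, M, b, tau)
                        if np.log(np.random.random()) < d + np.log((1.0 - qi) / qi):
                            _apply_bits(tallies, bits_old, bits_new)
                            acc[2] += 1.0
                            reverted = False
                    if reverted:
                        lic[c, i] = True
                        times[c, i] = told
                else:
                    # birth: propose the time from its conditional prior
                    lic[c, i] = True
                    times[c, i] = theta[i] + theta[3 + i] * np.random.standard_normal()
                    nr2 = _realized_row(lic[c], times[c], x, real)
                    reverted = True
                    if _admissible(real, nr2):
                        _bits_row(real, times[c], x, xm, bits_new)
                        d = _delta_and_maybe_apply(lcf, lcr, tallies, bits_old, bits_new, M, b, tau)
                        if np.log(np.random.random()) < d + np.log(qi / (1.0 - qi)):
                            _apply_bits(tallies, bits_old, bits_new)
                            acc[2] += 1.0
                            reverted = False
                    if reverted:
                        lic[c, i] = False
                        times[c, i] = 0.0

        # ---- (3) conjugate Gibbs -------------------------------------------
        if upd[1] == 1:  # mu | times  (Gaussian N(0, A^2) prior)
            for i in range(3):
                n = 0
                s1 = 0.0
                for c in range(M):
                    if lic[c, i]:
                        n += 1
                        s1 += times[c, i]
                v_i = theta[3 + i] * theta[3 + i]
                prec = n / v_i + 1.0 / pri[6]
                mean = (s1 / v_i) / prec
                theta[i] = mean + np.random.standard_normal() / np.sqrt(prec)
        if upd[2] == 1:  # sigma^2 | times, mu  (inverse gamma)
            for i in range(3):
                n = 0
                s2 = 0.0
                for c in range(M):
                    if lic[c, i]:
                        dlt = times[c, i] - theta[i]
                        n += 1
                        s2 += dlt * dlt
                shape = pri[0] + 0.5 * n
                rate = pri[1] + 0.5 * s2
                g = np.random.gamma(shape, 1.0)
                if g > 0.0:
                    v = rate / g
                    if v < 1e-8:
                        v = 1e-8
                    if v > 1e10:
                        v = 1e10
                    theta[3 + i] = np.sqrt(v)
        # q | licencing counts.  The latent cells are conditioned on
        # admissibility, so the exact conditional is the conjugate Beta form
        # times Z(q)^-M with Z the admissible-state probability; in the
        # licencing-only closed form Z = 1 - (1 - q2)(1 - q1 q3) = a + b q_i
        # is linear in each q_i, so the 1-D conditional is drawn exactly by
        # inverse-CDF on a fine grid (obscuring-induced prohibitions are
        # negligible and neglected in Z).
        for i in range(3):
            if updq[i] == 1:
                n = 0
                for c in range(M):
                    if lic[c, i]:
                        n += 1
                q1 = theta[6]
                q2 = theta[7]
                q3 = theta[8]
                if i == 0:
                    za = q2
                    zb = (1.0 - q2) * q3
                elif i == 1:
                    za = q1 * q3
                    zb = 1.0 - q1 * q3
                else:
                    za = q2
                    zb = (1.0 - q2) * q1
                theta[6 + i] = _draw_q_conditional(
                    pri[2] + n, pri[3] + (M - n), za, zb, M, qgrid, lgq, lgq1, wgrid
                )

        # ---- (4) joint hyperparameter/latent group moves -------------------
        if upd[0] == 1 and upd[1] == 1:  # translate (mu_i, all licenced t_i)
            for i in range(3):
                delta = step[5 + i] * np.random.standard_normal()
                for c in range(M):
                    tcol[c] = times[c, i]
                    if lic[c, i]:
                        times[c, i] += delta
                ash_t += 1.0
                acc[9] += 1.0
                accepted = False
                if _tallies_if_admissible(lic, times, x, xm, tallies_new):
                    cur = total_ll(lcf, lcr, tallies, M, b, tau)
                    new = total_ll(lcf, lcr, tallies_new, M, b, tau)
                    mu_new = theta[i] + delta
                    dpri = (theta[i] * theta[i] - mu_new * mu_new) / (2.0 * pri[6])
                    if np.log(np.random.random()) < new - cur + dpri:
                        for m in range(nb):
                            tallies[m] = tallies_new[m]
                        theta[i] += delta
                        ash_a += 1.0
                        acc[8] += 1.0
                        accepted = True
                if not accepted:
                    for c in range(M):
                        times[c, i] = tcol[c]
        if upd[0] == 1 and upd[2] == 1:  # scale (sigma_i, centred licenced t_i)
            for i in range(3):
                z = step[8] * np.random.standard_normal()
                cfac = np.exp(z)
                mu_i = theta[i]
                v = theta[3 + i] * theta[3 + i]
                vp = cfac * cfac * v
                for c in range(M):
                    tcol[c] = times[c, i]
                    if lic[c, i]:
                        times[c, i] = mu_i + cfac * (times[c, i] - mu_i)
                asc_t += 1.0
                acc[11] += 1.0
                accepted = False
                if 1e-8 < vp < 1e10 and _tallies_if_admissible(lic, times, x, xm, tallies_new):
                    cur = total_ll(lcf, lcr, tallies, M, b, tau)
                    new = total_ll(lcf, lcr, tallies_new, M, b, tau)
                    lr = new - cur - 2.0 * pri[0] * z - (pri[1] / v) * (1.0 / (cfac * cfac) - 1.0)
                    if np.log(np.random.random()) < lr:
                        for m in range(nb):
                            tallies[m] = tallies_new[m]
                        theta[3 + i] = np.sqrt(vp)
                        asc_a += 1.0
                        acc[10] += 1.0
                        accepted = True
                if not accepted:
                    for c in range(M):
                        times[c, i] = tcol[c]

        # ---- (5) noise parameters ------------------------------------------
        if upd[4] == 1:  # tau, log-scale walk, Gamma(a, b) prior
            atau_t += 1.0
            acc[5] += 1.0
            cur = total_ll(lcf, lcr, tallies, M, b, tau)
            taup = np.exp(np.log(tau) + step[3] * np.random.standard_normal())
            if 1e-8 < taup < 1e12:
                new = total_ll(lcf, lcr, tallies, M, b, taup)
                lr = new - cur + pri[4] * (np.log(taup) - np.log(tau)) - pri[5] * (taup - tau)
                if np.log(np.random.random()) < lr:
                    tau = taup
                    theta[10] = tau
                    atau_a += 1.0
                    acc[4] += 1.0
        if upd[3] == 1:  # b, logit-scale walk, Uniform(0, 1) prior
            ab_t += 1.0
            acc[7] += 1.0
            cur = total_ll(lcf, lcr, tallies, M, b, tau)
            lb = np.log(b / (1.0 - b)) + step[4] * np.random.standard_normal()
            bp = 1.0 / (1.0 + np.exp(-lb))
            if 1e-12 < bp < 1.0 - 1e-12:
                new = total_ll(lcf, lcr, tallies, M, bp, tau)
                lr = new - cur + np.log(bp * (1.0 - bp)) - np.log(b * (1.0 - b))
                if np.log(np.random.random()) < lr:
                    b = bp
                    theta[9] = b
                    ab_a += 1.0
                    acc[6] += 1.0

        # ---- burn-in adaptation --------------------------------------------
        if adapt == 1 and sweep % 50 == 0:
            block += 1
            g = 1.0 / np.sqrt(block)
            if at_t > 0:
                f = np.exp(g * (at_a / at_t - target))
                step[0] *= f
                step[1] *= f
                step[2] *= f
            if atau_t > 0:
                step[3] *= np.exp(g * (atau_a / atau_t - target))
            if ab_t > 0:
                step[4] *= np.exp(g * (ab_a / ab_t - target))
            if ash_t > 0:
                f = np.exp(g * (ash_a / ash_t - target))
                step[5] *= f
                step[6] *= f
                step[7] *= f
            if asc_t > 0:
                step[8] *= np.exp(g * (asc_a / asc_t - target))
            at_a = at_t = atau_a = atau_t = ab_a = ab_t = 0.0
            ash_a = ash_t = asc_a = asc_t = 0.0

        # ---- recording ------------------------------------------------------
        if record_every > 0 and sweep % record_every == 0 and rec < out_theta.shape[0]:
            # reported firing-time means follow the sum-to-zero convention
            mbar = (theta[0] + theta[1] + theta[2]) / 3.0
            for k in range(11):
                out_theta[rec, k] = theta[k]
            for k in range(3):
                out_theta[rec, k] -= mbar
            for i in range(3):
                out_rfrac[rec, i] = 0.0
                out_pairfrac[rec, i] = 0.0
                for j in range(3):
                    out_obsc[rec, i, j] = 0.0
            for c in range(M):
                _realized_row(lic[c], times[c], x, real)
                for i in range(3):
                    if real[i]:
                        out_rfrac[rec, i] += 1.0
                if real[0] and real[1]:
                    out_pairfrac[rec, 0] += 1.0
                if real[1] and real[2]:
                    out_pairfrac[rec, 1] += 1.0
                if real[0] and real[2] and not real[1]:
                    out_pairfrac[rec, 2] += 1.0
                for i in range(3):
                    if lic[c, i] and not real[i]:
                        best = np.inf
                        js = -1
                        for j in range(3):
                            if real[j] and j != i:
                                v = times[c, j] + abs(x[i] - x[j])
                                if v < best:
                                    best = v
                                    js = j
                        if js >= 0:
                            out_obsc[rec, i, js] += 1.0
            for i in range(3):
                out_rfrac[rec, i] /= M
                out_pairfrac[rec, i] /= M
                for j in range(3):
                    out_obsc[rec, i, j] /= M
            for s in range(n_sub):
                c = np.random.randint(0, M)
                _realized_row(lic[c], times[c], x, real)
                for i in range(3):
                    out_sub_lic[rec, s, i] = lic[c, i]
                    out_sub_t[rec, s, i] = times[c, i] - mbar
                out_sub_coll[rec, s, 0] = np.nan
                out_sub_coll[rec, s, 1] = np.nan
                out_sub_pair[rec, s, 0] = -1
                out_sub_pair[rec, s, 1] = -1
                kk = 0
                prev = -1
                for j in range(3):
                    if real[j]:
                        if prev >= 0:
                            out_sub_coll[rec, s, kk] = 0.5 * (
                                x[prev] + x[j] + times[c, j] - times[c, prev]
                            )
                            if prev == 0 and j == 1:
                                out_sub_pair[rec, s, kk] = 0
                            elif prev == 1 and j == 2:
                                out_sub_pair[rec, s, kk] = 1
                            else:
                                out_sub_pair[rec, s, kk] = 2
                            kk += 1
                        prev = j
            rec += 1
    return rec
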