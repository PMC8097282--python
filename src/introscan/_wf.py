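"""Numba kernels for the forward Wright-Fisher admixture simulator.

Chromosomes are stored as ancestry-junction lists: a start ancestry plus the
sorted positions (Morgans) where ancestry flips.  Meiosis walks the two
parental junction lists between Poisson-placed crossovers, so local ancestry
is maintained exactly.  Selected-locus alleles are carried separately per
chromosome so that scenarios where the adaptive allele segregates in the
donor population (start frequency < 1) remain representable.
"""

import numpy as np
from numba import njit

# fitness_mode values
ADDITIVE = 0          # per-locus (possibly dominant/recessive) selection
DMI_DOMINANT = 1      # any cross-population combination at the two loci is penalised
DMI_ONE_DIRECTIONAL = 2  # only the A0+B1 combination is penalised


@njit(cache=True)
def _gamete(junc, nj, start, i1, i2, xs, nxs, first, out_junc, cap):
    """Build one gamete from parental chromosomes i1, i2 with crossovers xs.

    Returns (n_junctions, start_ancestry); n_junctions = -1 on overflow.
    """
    p = 0
    prev = 0.0
    gstart = np.uint8(0)
    cur = np.uint8(0)
    big = 1e30
    for seg in range(nxs + 1):
        hi = xs[seg] if seg < nxs else big
        tmpl = i1 if (seg + first) % 2 == 0 else i2
        c = np.searchsorted(junc[tmpl, : nj[tmpl]], prev, side="right")
        anc_lo = start[tmpl] ^ np.uint8(c & 1)
        if seg == 0:
            gstart = anc_lo
            cur = anc_lo
        elif anc_lo != cur:
            if p >= cap:
                return -1, gstart
            out_junc[p] = prev
            p += 1
            cur = anc_lo
        j = c
        while j < nj[tmpl] and junc[tmpl, j] < hi:
            if p >= cap:
                return -1, gstart
            out_junc[p] = junc[tmpl, j]
            p += 1
            cur = cur ^ np.uint8(1)
            j += 1
        prev = hi
    return p, gstart


@njit(cache=True)
def _fitness(allele, n_ind, n_loci, loci_s, loci_h, fitness_mode, dmi_s, w):
    for i in range(n_ind):
        a = 2 * i
        b = 2 * i + 1
        if fitness_mode == ADDITIVE:
            wi = 1.0
            for l in range(n_loci):
                d = allele[a, l] + allele[b, l]
                if d == 1:
                    wi *= 1.0 + 2.0 * loci_s[l] * loci_h[l]
                elif d == 2:
                    wi *= 1.0 + 2.0 * loci_s[l]
            w[i] = wi if wi > 1e-12 else 1e-12
        else:
            hasA0 = allele[a, 0] == 0 or allele[b, 0] == 0
            hasA1 = allele[a, 0] == 1 or allele[b, 0] == 1
            hasB0 = allele[a, 1] == 0 or allele[b, 1] == 0
            hasB1 = allele[a, 1] == 1 or allele[b, 1] == 1
            bad = (hasA0 and hasB1) or (
                fitness_mode == DMI_DOMINANT and hasA1 and hasB0
            )
            wi = 1.0 + dmi_s if bad else 1.0
            w[i] = wi if wi > 1e-12 else 1e-12


@njit(cache=True)
def simulate_wf_kernel(
    seed,
    n_ind,
    t,
    L_M,
    cap,
    loci_pos,
    loci_s,
    loci_h,
    start_freq,
    fitness_mode,
    dmi_s,
    mig_rate,
    mig_dur,
    stop_freq,
    m,
):
    """Run the forward simulation; returns the final generation's chromosomes,
    the per-generation allele-frequency trajectory, the generation actually
    reached, and an overflow flag."""
    np.random.seed(seed)
    n_chrom = 2 * n_ind
    n_loci = len(loci_pos)

    junc = np.zeros((n_chrom, cap))
    nj = np.zeros(n_chrom, np.int64)
    start = np.zeros(n_chrom, np.uint8)
    allele = np.zeros((n_chrom, n_loci), np.uint8)
    junc2 = np.zeros((n_chrom, cap))
    nj2 = np.zeros(n_chrom, np.int64)
    start2 = np.zeros(n_chrom, np.uint8)
    allele2 = np.zeros((n_chrom, n_loci), np.uint8)

    # admixture pulse: a fraction m of individuals is replaced by donors
    n_donor = int(round(m * n_ind))
    for i in range(n_donor):
        start[2 * i] = 1
        start[2 * i + 1] = 1
        for l in range(n_loci):
            if np.random.random() < start_freq[l]:
                allele[2 * i, l] = 1
            if np.random.random() < start_freq[l]:
                allele[2 * i + 1, l] = 1

    traj = np.zeros((t + 1, n_loci))
    for l in range(n_loci):
        traj[0, l] = allele[:, l].sum() / n_chrom

    w = np.ones(n_ind)
    xs_buf = np.zeros(64)
    gen_reached = t
    for g in range(1, t + 1):
        _fitness(allele, n_ind, n_loci, loci_s, loci_h, fitness_mode, dmi_s, w)
        cum = np.cumsum(w)
        tot = cum[n_ind - 1]
        for c in range(n_chrom):
            u = np.random.random() * tot
            par = np.searchsorted(cum, u)
            if par >= n_ind:
                par = n_ind - 1
            nxs = np.random.poisson(L_M)
            while nxs > 64:
                nxs = np.random.poisson(L_M)
            for k in range(nxs):
                xs_buf[k] = np.random.random() * L_M
            xs = np.sort(xs_buf[:nxs])
            first = np.random.randint(0, 2)
            i1 = 2 * par
            i2 = 2 * par + 1
            n_out, gstart = _gamete(junc, nj, start, i1, i2, xs, nxs, first, junc2[c], cap)
            if n_out < 0:
                return junc, nj, start, allele, traj, g, 1
            nj2[c] = n_out
            start2[c] = gstart
            for l in range(n_loci):
                cc = np.searchsorted(xs, loci_pos[l], side="right")
                tmpl = i1 if (cc + first) % 2 == 0 else i2
                allele2[c, l] = allele[tmpl, l]
        # continuous gene flow after the initial pulse
        if mig_rate > 0.0 and g <= mig_dur:
            n_mig = int(round(mig_rate * n_ind))
            perm = np.random.permutation(n_ind)
            for k in range(n_mig):
                i = perm[k]
                for cc in (2 * i, 2 * i + 1):
                    nj2[cc] = 0
                    start2[cc] = 1
                    for l in range(n_loci):
                        allele2[cc, l] = 1 if np.random.random() < start_freq[l] else 0
        junc, junc2 = junc2, junc
        nj, nj2 = nj2, nj
        start, start2 = start2, start
        allele, allele2 = allele2, allele
        for l in range(n_loci):
            traj[g, l] = allele[:, l].sum() / n_chrom
        if stop_freq > 0.0 and traj[g, 0] >= stop_freq:
            gen_reached = g
            for gg in range(g + 1, t + 1):
                for l in range(n_loci):
                    traj[gg, l] = traj[g, l]
            break
    return junc, nj, start, allele, traj, gen_reached, 0


@njit(cache=True)
def ancestry_at_positions(junc, nj, start, chrom_idx, pos):
    """Local ancestry of selected chromosomes at given map positions."""
    out = np.zeros((len(chrom_idx), len(pos)), np.uint8)
    for ii in range(len(chrom_idx)):
        i = chrom_idx[ii]
        for jj in range(len(pos)):
            c = np.searchsorted(junc[i, : nj[i]], pos[jj], side="right")
            out[ii, jj] = start[i] ^ np.uint8(c & 1)
    return out
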