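"""Independent test oracles, deliberately written with plain loops and
dictionaries rather than the package's precomputed tables."""

import math
from itertools import permutations

import numpy as np

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, a in enumerate(_BASES):
    for _j, b in enumerate(_BASES):
        for _k, c in enumerate(_BASES):
            GENETIC_CODE[a + b + c] = _AA[16 * _i + 4 * _j + _k]

STOPS = {codon for codon, aa in GENETIC_CODE.items() if aa == "*"}


def ng86_oracle(seq1, seq2):
    """Textbook NG86: site fractions, pathway averaging, JC correction."""

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOPS:
                    continue  # counts as nonsynonymous
                if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                    s += 1 / 3
        return s

    def pair_diffs(c1, c2):
        positions = [p for p in range(3) if c1[p] != c2[p]]
        total_s, total_n, n_paths = 0.0, 0.0, 0
        for order in permutations(positions):
            current = c1
            s = n = 0
            blocked = False
            for p in order:
                nxt = current[:p] + c2[p] + current[p + 1 :]
                if nxt in STOPS:
                    blocked = True
                    break
                if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                    s += 1
                else:
                    n += 1
                current = nxt
            if not blocked:
                total_s += s
                total_n += n
                n_paths += 1
        if n_paths == 0:  # every path runs through a stop: keep stop steps
            for order in permutations(positions):
                current = c1
                s = n = 0
                for p in order:
                    nxt = current[:p] + c2[p] + current[p + 1 :]
                    aa1 = GENETIC_CODE[current]
                    aa2 = GENETIC_CODE[nxt]
                    if aa1 == aa2:
                        s += 1
                    else:
                        n += 1
                    current = nxt
                total_s += s
                total_n += n
                n_paths += 1
        return total_s / n_paths, total_n / n_paths

    codons1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]
    s_sites = sum(syn_sites(c) for c in codons1) / 2 + sum(syn_sites(c) for c in codons2) / 2
    n_sites = 3 * len(codons1) - s_sites
    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        if c1 != c2:
            s, n = pair_diffs(c1, c2)
            sd += s
            nd += n
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ds = -0.75 * math.log(1 - 4 * ps / 3)
    dn = -0.75 * math.log(1 - 4 * pn / 3)
    return dn, ds, sd, nd


def grid_search_lnl(seq_a, seq_b, codon_freq_mode="F3x4", rounds=4,
                    nt=13, nk=11, nw=11):
    """Brute-force refinement grid over (t, kappa, omega); returns the best
    log-likelihood found and the grid point achieving it."""
    from poolsel import omega as m  # model evaluation is shared; search is not

    ii, jj, cc = m._site_patterns(seq_a, seq_b)
    pi = m.codon_frequencies([seq_a, seq_b], codon_freq_mode)
    lo = np.log(np.array([0.001, 0.1, 0.05]))
    hi = np.log(np.array([1.0, 30.0, 99.0]))
    best_lnl, best_point = -np.inf, None
    for _round in range(rounds):
        ts = np.exp(np.linspace(lo[0], hi[0], nt))
        ks = np.exp(np.linspace(lo[1], hi[1], nk))
        ws = np.exp(np.linspace(lo[2], hi[2], nw))
        for kappa in ks:
            for w in ws:
                q, _, _ = m.build_rate_matrix(kappa, w, pi)
                sq = np.sqrt(pi)
                sym = q * sq[:, None] / sq[None, :]
                sym = 0.5 * (sym + sym.T)
                ev, u = np.linalg.eigh(sym)
                for t in ts:
                    p = (u * np.exp(ev * t)) @ u.T
                    p = p / sq[:, None] * sq[None, :]
                    p = np.maximum(p, 1e-300)
                    lnl = float((cc * (np.log(pi[ii]) + np.log(p[ii, jj]))).sum())
                    if lnl > best_lnl:
                        best_lnl, best_point = lnl, (t, kappa, w)
        center = np.log(np.array(best_point))
        width = (hi - lo) * 0.3
        lo = np.maximum(center - width / 2, np.log([1e-6, 0.01, 1e-4]))
        hi = np.minimum(center + width / 2, np.log([50.0, 100.0, 99.0]))
    return best_lnl, best_point
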