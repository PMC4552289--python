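"""Pairwise dN/dS estimation on codon alignments.

Two routes to the same quantity are provided:

* :func:`gy94_pairwise_ml` — maximum likelihood under a 61-state codon
  substitution model with parameters ``t`` (expected substitutions per
  codon), ``kappa`` (transition/transversion rate ratio) and ``omega``
  (nonsynonymous/synonymous rate ratio), with F3x4 or equal codon
  frequencies.
* :func:`ng86` — the classic counting estimator (pathway-averaged
  difference counts, Jukes–Cantor correction), used as an independent
  cross-check at low divergence.

:func:`lrt_neutral` compares the free-``omega`` fit against the nested
``omega = 1`` fit with a one-degree-of-freedom chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import optimize
from scipy.stats import chi2
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "MlFit",
    "LrtResult",
    "Ng86Result",
    "OmegaResult",
    "codon_frequencies",
    "build_rate_matrix",
    "transition_matrix",
    "log_likelihood",
    "gy94_pairwise_ml",
    "lrt_neutral",
    "ng86",
    "simulate_pair",
    "fit_gene",
    "omega_table",
]

_TABLE = unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_N = len(SENSE_CODONS)  # 61
_NUC_INDEX = {b: i for i, b in enumerate("ACGT")}
_PURINES = frozenset("AG")

# Single-nucleotide-change structure of the sense-codon space, computed once.
_SINGLE = np.zeros((_N, _N), dtype=bool)
_IS_TS = np.zeros((_N, _N), dtype=bool)
_IS_SYN = np.zeros((_N, _N), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diffs) != 1:
            continue
        k = diffs[0]
        _SINGLE[_i, _j] = True
        _IS_TS[_i, _j] = (_ci[k] in _PURINES) == (_cj[k] in _PURINES)
        _IS_SYN[_i, _j] = AMINO_ACIDS[_i] == AMINO_ACIDS[_j]

T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (1e-4, 99.0)


# ---------------------------------------------------------------------------
# model machinery
# ---------------------------------------------------------------------------

def codon_frequencies(seqs, mode: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies over the 61 sense codons.

    ``F3x4`` uses the observed nucleotide frequencies at each codon
    position (floored at 1e-6 so every sense codon keeps positive mass);
    ``equal`` returns the uniform distribution.
    """
    if mode == "equal":
        return np.full(_N, 1.0 / _N)
    if mode.upper() != "F3X4":
        raise ValueError(f"unknown codon frequency mode: {mode!r}")
    counts = np.zeros((3, 4))
    for seq in seqs:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        for pos, base in enumerate(seq):
            counts[pos % 3, _NUC_INDEX[base]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, 1e-6)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.empty(_N)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = (
            freqs[0, _NUC_INDEX[codon[0]]]
            * freqs[1, _NUC_INDEX[codon[1]]]
            * freqs[2, _NUC_INDEX[codon[2]]]
        )
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray):
    """Scaled reversible codon rate matrix.

    Off-diagonal rates are ``pi_j`` times ``kappa`` for transitions and
    ``omega`` for nonsynonymous changes; multi-position changes have rate
    zero.  The matrix is scaled so the expected flux is one substitution
    per codon per unit time.

    Returns
    -------
    (Q, rho_nonsyn, rho_syn)
        Generator matrix plus the fractions of total flux that are
        nonsynonymous and synonymous (summing to 1).
    """
    rate = np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, omega)
    q = np.where(_SINGLE, rate, 0.0) * pi[None, :]
    flux = pi[:, None] * q
    total = flux.sum()
    q /= total
    rho_syn = flux[_IS_SYN & _SINGLE].sum() / total
    np.fill_diagonal(q, -q.sum(axis=1))
    return q, 1.0 - rho_syn, rho_syn


def transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """``expm(Q t)`` via eigendecomposition of the symmetrized generator."""
    sq = np.sqrt(pi)
    sym = q * sq[:, None] / sq[None, :]
    sym = 0.5 * (sym + sym.T)
    w, u = np.linalg.eigh(sym)
    p = (u * np.exp(w * t)) @ u.T
    p = p / sq[:, None] * sq[None, :]
    return p


def _codon_indices(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide {k + 1}")
        try:
            idx[k // 3] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at nucleotide {k + 1}") from None
    return idx


def _site_patterns(seq_a: str, seq_b: str):
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ia, ib = _codon_indices(seq_a), _codon_indices(seq_b)
    pairs, counts = np.unique(np.stack([ia, ib]), axis=1, return_counts=True)
    return pairs[0], pairs[1], counts.astype(float)


def log_likelihood(t, kappa, omega, pi, ii, jj, counts) -> float:
    """Pairwise log-likelihood ``sum_sites log(pi_i P_ij(t))``."""
    q, _, _ = build_rate_matrix(kappa, omega, pi)
    p = transition_matrix(q, pi, t)
    p = np.maximum(p, 1e-300)
    return float((counts * (np.log(pi[ii]) + np.log(p[ii, jj]))).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class MlFit:
    """Result of a pairwise codon-model maximum-likelihood fit."""

    t: float
    kappa: float
    omega: float
    lnl: float
    dn: float
    ds: float
    converged: bool
    n_codons: int


_STARTS = ((0.05, 2.0, 0.4), (0.2, 1.0, 1.0), (0.01, 5.0, 3.0))


def _derive_dn_ds(t, kappa, omega, pi):
    # dN = t * rho_N / (3 rho_N^1): omega-weighted flux over the neutral
    # (omega = 1) site opportunity; the ratio dn/ds then equals omega exactly.
    _, rho_n, rho_s = build_rate_matrix(kappa, omega, pi)
    _, rho_n1, rho_s1 = build_rate_matrix(kappa, 1.0, pi)
    dn = t * rho_n / (3.0 * rho_n1)
    ds = t * rho_s / (3.0 * rho_s1)
    return dn, ds


def gy94_pairwise_ml(
    seq_a: str,
    seq_b: str,
    codon_freq_mode: str = "F3x4",
    fix_omega: float | None = None,
    extra_starts: tuple = (),
) -> MlFit:
    """Jointly estimate ``(t, kappa, omega)`` by maximum likelihood.

    Parameters are optimized on log scale with bounded quasi-Newton from
    three fixed starting points (plus any ``extra_starts``), which avoids
    ridge pathologies at tiny divergence.  With ``fix_omega`` the ratio is
    held constant (the null model of :func:`lrt_neutral`).
    """
    ii, jj, counts = _site_patterns(seq_a, seq_b)
    pi = codon_frequencies([seq_a, seq_b], codon_freq_mode)
    n_codons = int(counts.sum())
    n_diff = int(counts[ii != jj].sum())

    if n_diff == 0:
        # Likelihood is decreasing in t: the optimum sits at the lower bound.
        omega = fix_omega if fix_omega is not None else float("nan")
        lnl = log_likelihood(T_BOUNDS[0], 1.0, 1.0, pi, ii, jj, counts)
        return MlFit(T_BOUNDS[0], 1.0, omega, lnl, 0.0, 0.0, True, n_codons)

    free = fix_omega is None
    if free:
        bounds = [np.log(T_BOUNDS), np.log(KAPPA_BOUNDS), np.log(OMEGA_BOUNDS)]
    else:
        bounds = [np.log(T_BOUNDS), np.log(KAPPA_BOUNDS)]

    def nll(x):
        t, kappa = math.exp(x[0]), math.exp(x[1])
        omega = math.exp(x[2]) if free else fix_omega
        return -log_likelihood(t, kappa, omega, pi, ii, jj, counts)

    best = None
    starts = _STARTS + tuple(extra_starts)
    for start in starts:
        x0 = np.log(start[:3] if free else start[:2])
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxfun": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # simplex polish: L-BFGS-B's finite-difference gradients can stall on
    # the flat ridge that appears when omega runs to a bound
    polish = optimize.minimize(
        nll, best.x, method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if polish.fun < best.fun:
        best = polish
    t, kappa = math.exp(best.x[0]), math.exp(best.x[1])
    omega = math.exp(best.x[2]) if free else float(fix_omega)
    dn, ds = _derive_dn_ds(t, kappa, omega, pi)
    return MlFit(t, kappa, omega, -best.fun, dn, ds, bool(best.success), n_codons)


@dataclass
class LrtResult:
    """Likelihood-ratio test of the free fit against ``omega = 1``."""

    delta: float
    p: float
    free: MlFit
    null: MlFit


def lrt_neutral(seq_a: str, seq_b: str, codon_freq_mode: str = "F3x4") -> LrtResult:
    """``delta = 2 (lnL_free - lnL_null)`` against chi-square with 1 df."""
    null = gy94_pairwise_ml(seq_a, seq_b, codon_freq_mode, fix_omega=1.0)
    # Seeding the free fit from the null optimum guarantees nesting.
    free = gy94_pairwise_ml(
        seq_a, seq_b, codon_freq_mode,
        extra_starts=((null.t, null.kappa, 1.0),),
    )
    delta = 2.0 * (free.lnl - null.lnl)
    if delta < -1e-6:
        raise RuntimeError(f"LRT nesting violated: delta = {delta}")
    delta = max(delta, 0.0)
    return LrtResult(delta, float(chi2.sf(delta, df=1)), free, null)


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------

_SYN_SITES = np.zeros(_N)
for _i, _codon in enumerate(SENSE_CODONS):
    s = 0.0
    for _pos in range(3):
        for _alt in "ACGT":
            if _alt == _codon[_pos]:
                continue
            mut = _codon[:_pos] + _alt + _codon[_pos + 1 :]
            # changes to stop codons count as nonsynonymous
            if mut not in STOP_CODONS and _TABLE.forward_table[mut] == AMINO_ACIDS[_i]:
                s += 1.0 / 3.0
    _SYN_SITES[_i] = s


@lru_cache(maxsize=None)
def _pathway_counts(i: int, j: int):
    """Average syn/nonsyn step counts over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked (possible only for 2- and 3-fold differences) the stop
    steps are retained and counted as nonsynonymous.
    """
    ca, cb = SENSE_CODONS[i], SENSE_CODONS[j]
    diffs = tuple(k for k in range(3) if ca[k] != cb[k])

    def walk(allow_stops):
        syn = nonsyn = 0.0
        n_valid = 0
        for path in permutations(diffs):
            cur = ca
            s = n = 0
            ok = True
            for pos in path:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not allow_stops:
                    ok = False
                    break
                aa_cur = "*" if cur in STOP_CODONS else _TABLE.forward_table[cur]
                aa_nxt = "*" if nxt in STOP_CODONS else _TABLE.forward_table[nxt]
                if aa_cur == aa_nxt:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                n_valid += 1
                syn += s
                nonsyn += n
        return syn, nonsyn, n_valid

    syn, nonsyn, n_valid = walk(allow_stops=False)
    if n_valid == 0:
        syn, nonsyn, n_valid = walk(allow_stops=True)
    return syn / n_valid, nonsyn / n_valid


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class Ng86Result:
    dn: float
    ds: float
    omega: float  # inf when ds == 0 < dn, nan when both are 0
    nd: float
    sd: float
    n_sites: float
    s_sites: float


def ng86(seq_a: str, seq_b: str) -> Ng86Result:
    """Nei–Gojobori (1986) counting estimate of dN and dS.

    Synonymous/nonsynonymous site fractions are averaged over both
    sequences; difference counts are averaged over minimal mutational
    pathways; proportions are Jukes–Cantor corrected.
    """
    ia, ib = _codon_indices(seq_a), _codon_indices(seq_b)
    if len(ia) != len(ib):
        raise ValueError("sequences differ in length")
    s_sites = 0.5 * (_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum())
    n_sites = 3.0 * len(ia) - s_sites
    sd = nd = 0.0
    for i, j in zip(ia, ib):
        if i == j:
            continue
        s, n = _pathway_counts(int(i), int(j))
        sd += s
        nd += n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if ds == 0.0:
        omega = float("inf") if dn > 0 else float("nan")
    else:
        omega = dn / ds
    return Ng86Result(dn, ds, omega, nd, sd, n_sites, s_sites)


# ---------------------------------------------------------------------------
# simulation under the model (used by tests and calibration checks)
# ---------------------------------------------------------------------------

def simulate_pair(
    n_codons: int,
    t: float,
    kappa: float,
    omega: float,
    pi: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Simulate an in-frame codon sequence pair at divergence ``t``.

    The ancestor is drawn from ``pi`` (uniform by default) and the second
    sequence evolved with the transition matrix ``P(t)``; reversibility
    makes this equivalent to evolving both from a midpoint ancestor.
    """
    rng = np.random.default_rng(rng)
    if pi is None:
        pi = np.full(_N, 1.0 / _N)
    q, _, _ = build_rate_matrix(kappa, omega, pi)
    p = np.maximum(transition_matrix(q, pi, t), 0.0)
    p /= p.sum(axis=1, keepdims=True)
    anc = rng.choice(_N, size=n_codons, p=pi)
    cum = np.cumsum(p, axis=1)
    u = rng.random(n_codons)
    der = (u[:, None] > cum[anc]).sum(axis=1)
    seq_a = "".join(SENSE_CODONS[k] for k in anc)
    seq_b = "".join(SENSE_CODONS[k] for k in der)
    return seq_a, seq_b


# ---------------------------------------------------------------------------
# per-gene driver and reporting
# ---------------------------------------------------------------------------

@dataclass
class OmegaResult:
    """Full per-gene divergence summary (ML fit, LRT, counting estimate)."""

    gene_id: str
    t: float
    kappa: float
    omega: float
    lnl_free: float
    lnl_null: float
    delta: float
    p: float
    dn: float
    ds: float
    ng86_dn: float
    ng86_ds: float
    ng86_omega: float
    omega_infinite: bool
    converged: bool = True

    @property
    def omega_display(self) -> str:
        return "inf" if self.omega_infinite else f"{self.omega:.4f}"


def fit_gene(gene_id: str, seq_a: str, seq_b: str, codon_freq_mode: str = "F3x4",
             compute_lrt: bool = True) -> OmegaResult:
    """Run the ML fit, the neutrality LRT and the NG86 cross-check."""
    counting = ng86(seq_a, seq_b)
    if compute_lrt:
        lrt = lrt_neutral(seq_a, seq_b, codon_freq_mode)
        free, null = lrt.free, lrt.null
        delta, p = lrt.delta, lrt.p
    else:
        free = gy94_pairwise_ml(seq_a, seq_b, codon_freq_mode)
        null = free
        delta, p = float("nan"), float("nan")
    infinite = counting.sd == 0 and counting.nd > 0
    return OmegaResult(
        gene_id=gene_id,
        t=free.t,
        kappa=free.kappa,
        omega=free.omega,
        lnl_free=free.lnl,
        lnl_null=null.lnl if compute_lrt else float("nan"),
        delta=delta,
        p=p,
        dn=free.dn,
        ds=free.ds,
        ng86_dn=counting.dn,
        ng86_ds=counting.ds,
        ng86_omega=counting.omega,
        omega_infinite=infinite,
        converged=free.converged,
    )


def omega_table(results, variations=None, low_support_below: int = 3):
    """Assemble the per-gene report, sorted by fixed nonsynonymous count.

    ``variations`` is an optional iterable of site-count records (anything
    with ``gene_id``, ``n_fixed_syn``, ``n_fixed_nonsyn``, ``n_poly_syn``,
    ``n_poly_nonsyn`` attributes).  Genes with fewer than
    ``low_support_below`` fixed substitutions are flagged, and ``omega``
    renders as ``inf`` when there are nonsynonymous but no synonymous
    fixed differences.
    """
    import pandas as pd

    var_by_gene = {}
    if variations is not None:
        for v in variations:
            var_by_gene[v.gene_id] = v
    rows = []
    for r in results:
        v = var_by_gene.get(r.gene_id)
        n_fixed = (v.n_fixed_syn + v.n_fixed_nonsyn) if v is not None else None
        row = {
            "gene_id": r.gene_id,
            "n_fixed_nonsyn": v.n_fixed_nonsyn if v else None,
            "n_fixed_syn": v.n_fixed_syn if v else None,
            "n_poly_nonsyn": v.n_poly_nonsyn if v else None,
            "n_poly_syn": v.n_poly_syn if v else None,
            "t": r.t,
            "kappa": r.kappa,
            "omega": r.omega,
            "omega_display": r.omega_display,
            "dn": r.dn,
            "ds": r.ds,
            "lnl_free": r.lnl_free,
            "lnl_null": r.lnl_null,
            "delta": r.delta,
            "p": r.p,
            "low_support": bool(n_fixed is not None and n_fixed < low_support_below),
        }
        rows.append(row)
    columns = ["gene_id", "n_fixed_nonsyn", "n_fixed_syn", "n_poly_nonsyn",
               "n_poly_syn", "t", "kappa", "omega", "omega_display", "dn", "ds",
               "lnl_free", "lnl_null", "delta", "p", "low_support"]
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        frame = frame.sort_values(
            ["n_fixed_nonsyn", "gene_id"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return frame
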