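"""Synthetic species-pair data with known ground truth.

Emulates the study design downstream of read mapping: two pools of
haploid individuals per species, orthologous equal-length ORFs carrying
fixed interspecific differences and within-species polymorphisms at
configurable rates, negative-binomial per-site read depth with uniform
per-base sequencing error, and three noisy membrane-topology predictors
around a true 7-TM architecture.

All randomness flows from a single integer seed; the same config always
produces byte-identical sequences, truth tables and pileups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .topodomains import TopologyAnnotation, _fill_topology

__all__ = [
    "SimulationConfig",
    "FixedSiteTruth",
    "PolySiteTruth",
    "GroundTruth",
    "SpeciesPool",
    "generate_ancestral_cds",
    "evolve_species_pair",
    "simulate_pileups",
    "synth_topologies",
]

_BASES = np.array(list("ACGT"))
_STOPS = frozenset({"TAA", "TAG", "TGA"})

_CODON_AA = {}
_aa = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _a in enumerate("TCAG"):
    for _j, _b in enumerate("TCAG"):
        for _k, _c in enumerate("TCAG"):
            _CODON_AA[_a + _b + _c] = _aa[16 * _i + 4 * _j + _k]

_SENSE = sorted(c for c, aa in _CODON_AA.items() if aa != "*")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic gene set.

    Rates are expected events per nucleotide site; ``length_range`` is in
    codons (inclusive, including the start and stop codon).
    """

    n_genes: int = 20
    length_range: tuple = (100, 200)
    n_haploids_per_pool: int = 40
    mean_depth: float = 50.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.003
    fixed_syn_rate: float = 0.0039
    fixed_nonsyn_rate: float = 0.0035
    poly_rate: float = 0.002
    minor_allele_freq_range: tuple = (0.1, 0.5)
    seed: int = 1

    def __post_init__(self):
        for name in ("error_rate", "fixed_syn_rate", "fixed_nonsyn_rate", "poly_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.length_range
        if lo < 100 or hi < lo:
            raise ValueError("length_range minimum is 100 codons")
        if self.n_haploids_per_pool < 2:
            raise ValueError("need at least 2 haploids per pool")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        flo, fhi = self.minor_allele_freq_range
        if not (0.0 < flo <= fhi < 1.0):
            raise ValueError("minor_allele_freq_range must lie inside (0, 1)")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")


@dataclass(frozen=True)
class FixedSiteTruth:
    gene_id: str
    pos: int  # 1-based along the ORF
    allele_a: str
    allele_b: str
    effect: str  # syn | nonsyn


@dataclass(frozen=True)
class PolySiteTruth:
    gene_id: str
    species: str  # A | B
    pos: int
    major: str
    minor: str
    minor_freq: float  # realized fraction of the pool
    effect: str


@dataclass
class GroundTruth:
    """Every change introduced by :func:`evolve_species_pair`."""

    fixed: list = field(default_factory=list)
    poly: list = field(default_factory=list)

    def fixed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [asdict(t) for t in self.fixed],
            columns=["gene_id", "pos", "allele_a", "allele_b", "effect"],
        )

    def poly_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [asdict(t) for t in self.poly],
            columns=["gene_id", "species", "pos", "major", "minor", "minor_freq", "effect"],
        )


@dataclass
class SpeciesPool:
    """One species' haplotype pool: gene -> (n_haploids, length) base array."""

    species: str
    haplotypes: dict

    def consensus(self, gene_id: str) -> str:
        haps = self.haplotypes[gene_id]
        out = []
        for col in haps.T:
            bases, counts = np.unique(col, return_counts=True)
            out.append(bases[np.argmax(counts)])
        return "".join(out)

    def fasta_records(self):
        for gene_id in sorted(self.haplotypes):
            for k, hap in enumerate(self.haplotypes[gene_id]):
                yield f"{gene_id}|{self.species}|hap{k}", "".join(hap)


def _translate(codon: str) -> str:
    return _CODON_AA[codon]


def generate_ancestral_cds(config: SimulationConfig) -> dict:
    """Random in-frame coding sequences: ATG + sense codons + stop."""
    rng = np.random.default_rng([config.seed, 0])
    out = {}
    lo, hi = config.length_range
    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        middle = rng.choice(len(_SENSE), size=n_codons - 2)
        stop = rng.choice(("TAA", "TAG", "TGA"))
        out[f"g{g:04d}"] = "ATG" + "".join(_SENSE[i] for i in middle) + str(stop)
    return out


def _mutate_site(seq: list, pos: int, alt: str) -> tuple[str, str]:
    """(old codon, new codon) for substituting ``alt`` at 0-based ``pos``."""
    ci = pos // 3
    codon = "".join(seq[3 * ci : 3 * ci + 3])
    off = pos % 3
    new = codon[:off] + alt + codon[off + 1 :]
    return codon, new


def _draw_substitution(rng, seq, used, desired_effect, max_tries=100):
    """A (pos, alt, effect) with the desired effect that creates no stop.

    Start and stop codons are left untouched.  Raises after
    ``max_tries`` failed proposals.
    """
    length = len(seq)
    for _ in range(max_tries):
        pos = int(rng.integers(3, length - 3))
        if pos in used:
            continue
        current = seq[pos]
        alt = str(rng.choice(_BASES[_BASES != current]))
        old_codon, new_codon = _mutate_site(seq, pos, alt)
        if new_codon in _STOPS:
            continue
        effect = "syn" if _translate(old_codon) == _translate(new_codon) else "nonsyn"
        if effect == desired_effect:
            return pos, alt, effect
    raise RuntimeError(
        f"could not place a {desired_effect} substitution after {max_tries} tries"
    )


def evolve_species_pair(ancestral: dict, config: SimulationConfig):
    """Introduce fixed differences and polymorphisms into two pools.

    Returns ``(pool_a, pool_b, truth)``.  Fixed differences are carried
    by every haplotype of exactly one species; polymorphic sites
    segregate one minor allele at a drawn frequency within one species.
    Counts per gene are Poisson with mean ``rate * ORF length``.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_hap = config.n_haploids_per_pool
    truth = GroundTruth()
    pools = {"A": {}, "B": {}}

    for gene_id in sorted(ancestral):
        cds = ancestral[gene_id]
        length = len(cds)
        seq_a = list(cds)
        seq_b = list(cds)
        used: set[int] = set()

        n_syn = rng.poisson(config.fixed_syn_rate * length)
        n_nonsyn = rng.poisson(config.fixed_nonsyn_rate * length)
        gene_fixed = []
        for effect in ["syn"] * n_syn + ["nonsyn"] * n_nonsyn:
            target = str(rng.choice(["A", "B"]))
            seq = seq_a if target == "A" else seq_b
            pos, alt, _eff = _draw_substitution(rng, seq, used, effect)
            seq[pos] = alt
            used.add(pos)
            gene_fixed.append((pos, effect))
            truth.fixed.append(
                FixedSiteTruth(gene_id, pos + 1, seq_a[pos], seq_b[pos], effect)
            )

        haps_a = np.tile(np.array(seq_a), (n_hap, 1))
        haps_b = np.tile(np.array(seq_b), (n_hap, 1))
        for species, haps, seq in (("A", haps_a, seq_a), ("B", haps_b, seq_b)):
            n_poly = rng.poisson(config.poly_rate * length)
            for _ in range(n_poly):
                for _try in range(100):
                    pos = int(rng.integers(3, length - 3))
                    if pos in used:
                        continue
                    major = seq[pos]
                    alt = str(rng.choice(_BASES[_BASES != major]))
                    old_codon, new_codon = _mutate_site(seq, pos, alt)
                    if new_codon in _STOPS:
                        continue
                    break
                else:
                    raise RuntimeError("could not place a polymorphic site")
                effect = "syn" if _translate(old_codon) == _translate(new_codon) else "nonsyn"
                freq = rng.uniform(*config.minor_allele_freq_range)
                k = int(round(freq * n_hap))
                k = max(1, min(k, n_hap - 1))
                carriers = rng.choice(n_hap, size=k, replace=False)
                haps[carriers, pos] = alt
                used.add(pos)
                truth.poly.append(
                    PolySiteTruth(gene_id, species, pos + 1, major, alt, k / n_hap, effect)
                )
        pools["A"][gene_id] = haps_a
        pools["B"][gene_id] = haps_b

    return SpeciesPool("A", pools["A"]), SpeciesPool("B", pools["B"]), truth


def simulate_pileups(pool: SpeciesPool, config: SimulationConfig) -> pd.DataFrame:
    """Per-site base counts for one pool's read pile.

    Depth is negative-binomial per site (mean ``mean_depth``, dispersion
    ``depth_dispersion``), each read samples a random haplotype's base
    and is flipped to a uniform alternative base with probability
    ``error_rate``.  Columns: gene_id, pos, species, A, C, G, T.
    """
    species_code = {"A": 2, "B": 3}[pool.species]
    rng = np.random.default_rng([config.seed, species_code])
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)
    err = config.error_rate

    frames = []
    for gene_id in sorted(pool.haplotypes):
        haps = pool.haplotypes[gene_id]
        length = haps.shape[1]
        # per-site haplotype base fractions
        frac = np.zeros((length, 4))
        for bi, base in enumerate("ACGT"):
            frac[:, bi] = (haps == base).mean(axis=0)
        probs = frac * (1.0 - err) + (1.0 - frac) * (err / 3.0)
        depth = rng.negative_binomial(r, p_nb, size=length)
        counts = rng.multinomial(depth, probs)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "pos": np.arange(1, length + 1),
                    "species": pool.species,
                    "A": counts[:, 0],
                    "C": counts[:, 1],
                    "G": counts[:, 2],
                    "T": counts[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def synth_topologies(
    protein_length: int,
    n_tm: int = 7,
    jitter_sd: float = 2.0,
    seed: int = 1,
    protein_id: str = "protein",
    tm_len: int = 21,
    n_predictors: int = 3,
):
    """True n-TM topology plus noisy predictor variants.

    The truth alternates IN / TM / loop segments with evenly distributed
    loop lengths; each predictor shifts every TM boundary by an integer
    normal jitter while keeping intervals ordered and non-overlapping.

    Returns ``(truth, [predictor annotations])``.
    """
    min_needed = n_tm * 5 + (n_tm + 1)  # shrunk TMs and 1-residue loops
    if protein_length < n_tm * tm_len + (n_tm + 1) * 2 or protein_length < min_needed:
        raise ValueError(
            f"protein of {protein_length} residues cannot hold {n_tm} TM domains"
        )
    rng = np.random.default_rng([seed, 4])
    total_loop = protein_length - n_tm * tm_len
    base, rem = divmod(total_loop, n_tm + 1)
    loops = [base + (1 if i < rem else 0) for i in range(n_tm + 1)]
    tm_true = []
    cursor = 0
    for k in range(n_tm):
        cursor += loops[k]
        tm_true.append((cursor + 1, cursor + tm_len))
        cursor += tm_len
    truth = _fill_topology(protein_id, protein_length, tm_true, "truth")

    variants = []
    for v in range(n_predictors):
        tms = []
        prev_end = 0
        for k, (start, end) in enumerate(tm_true):
            s = start + int(round(rng.normal(0.0, jitter_sd)))
            e = end + int(round(rng.normal(0.0, jitter_sd)))
            s = max(s, prev_end + 2)  # keep a 1-residue gap between TMs
            e = max(e, s + 4)  # TM length floor of 5 residues
            e = min(e, protein_length - 2 * (n_tm - k - 1) - 1)
            s = min(s, e - 4)
            tms.append((s, e))
            prev_end = e
        variants.append(
            _fill_topology(protein_id, protein_length, tms, f"predictor{v + 1}")
        )
    return truth, variants
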