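"""Statistical tests and gene-set contingency accounting.

Thin, convention-pinning wrappers around scipy: two-sided Fisher's exact
test with the minimum-likelihood convention, Mann–Whitney U with the
tie-corrected normal approximation, a two-bin goodness-of-fit chi-square
without continuity correction, and Pearson correlation — plus the
construction of the standard gene-set contingency tables from per-gene
variation and dN/dS tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "GeneSetTallies",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "chisq_gof",
    "pearson_r",
    "build_contingencies",
    "gene_set_contingencies",
    "tally_gene_sets",
]

CHEMOSENSORY_FAMILIES = frozenset({"OR", "GR", "IR", "OBP", "CSP"})
RECEPTOR_FAMILIES = frozenset({"OR", "GR", "IR"})


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("negative count in contingency table")
        if not any(counts):
            raise ValueError("all-zero contingency table")

    def values(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple = ()
    extra: dict = field(default_factory=dict)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test (minimum-likelihood convention).

    The p-value sums hypergeometric point probabilities no larger than
    that of the observed table over all tables with the same margins.
    The reported statistic is the sample odds ratio ``(a/b)/(c/d)``.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return TestResult(float(odds), float(p), "fisher_exact", (a + b, c + d))


def mann_whitney_u(x, y) -> TestResult:
    """Mann–Whitney U with midranks, tie and continuity corrections.

    Uses the normal approximation; when the pooled sample is constant the
    test is degenerate and ``U = n1 n2 / 2, p = 1`` is returned.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(len(x) * len(y) / 2.0, 1.0, "mann_whitney_u", (len(x), len(y)))
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return TestResult(float(u), float(p), "mann_whitney_u", (len(x), len(y)))


def chisq_gof(observed_in: int, total: int, expected_fraction: float) -> TestResult:
    """Two-bin Pearson chi-square (df = 1, no continuity correction)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if observed_in > total or observed_in < 0:
        raise ValueError("observed count outside [0, total]")
    if not (0.0 < expected_fraction < 1.0):
        raise ValueError("expected_fraction must lie in (0, 1)")
    observed = np.array([observed_in, total - observed_in], dtype=float)
    expected = np.array([total * expected_fraction, total * (1 - expected_fraction)])
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic, p, "chisq_gof", (total,),
                      {"expected_fraction": expected_fraction})


def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("samples differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson_r", (len(x),))


# ---------------------------------------------------------------------------
# gene-set accounting
# ---------------------------------------------------------------------------

@dataclass
class GeneSetTallies:
    """Site and gene tallies for one gene set."""

    name: str
    n_genes: int
    n_fixed: int
    n_polymorphic: int
    n_fixed_syn: int
    n_fixed_nonsyn: int
    n_omega_gt1: int
    dn_values: tuple = ()
    ds_values: tuple = ()


def tally_gene_sets(gene_frame: pd.DataFrame, omega_frame: pd.DataFrame,
                    chemosensory_families=CHEMOSENSORY_FAMILIES) -> dict:
    """Split per-gene records into chemosensory vs NC tallies.

    ``gene_frame`` follows the gene-variation schema; only genes passing
    the coverage filter are counted.  ``omega_frame`` follows the dN/dS
    report schema; ``omega > 1`` includes genes whose ratio is infinite
    (nonsynonymous but no synonymous fixed differences).
    """
    genes = gene_frame[gene_frame["passes_coverage"]].copy()
    genes["chemo"] = genes["family_tag"].isin(chemosensory_families)
    rates = omega_frame[["gene_id", "omega", "dn", "ds"]].copy()
    for column in ("omega", "dn", "ds"):
        rates[column] = pd.to_numeric(rates[column], errors="coerce")
    merged = genes.merge(rates, on="gene_id", how="left")
    out = {}
    for name, sub in (("chemosensory", merged[merged["chemo"]]),
                      ("NC", merged[~merged["chemo"]])):
        if len(sub) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        fixed = sub["n_fixed_syn"] + sub["n_fixed_nonsyn"]
        poly = sub["n_poly_syn"] + sub["n_poly_nonsyn"]
        omega = sub["omega"]
        gt1 = int(((omega > 1) & np.isfinite(omega)).sum() + np.isinf(omega).sum())
        with_fixed = sub[fixed > 0]
        out[name] = GeneSetTallies(
            name=name,
            n_genes=len(sub),
            n_fixed=int(fixed.sum()),
            n_polymorphic=int(poly.sum()),
            n_fixed_syn=int(sub["n_fixed_syn"].sum()),
            n_fixed_nonsyn=int(sub["n_fixed_nonsyn"].sum()),
            n_omega_gt1=gt1,
            dn_values=tuple(with_fixed["dn"].dropna()),
            ds_values=tuple(with_fixed["ds"].dropna()),
        )
    return out


def build_contingencies(chemo: GeneSetTallies, nc: GeneSetTallies,
                        receptor_gt1: int | None = None,
                        receptor_le1: int | None = None,
                        nonreceptor_gt1: int | None = None,
                        nonreceptor_le1: int | None = None) -> dict:
    """The four gene-set tests from two sets of tallies.

    1. fixed vs polymorphic variable sites, by gene set;
    2. nonsynonymous vs synonymous fixed sites, by gene set;
    3. genes with dN/dS > 1 against the full gene-set sizes (the second
       column holds the set totals, not their complements — this is the
       construction that reproduces the published p-value);
    4. receptor vs non-receptor genes among dN/dS > 1 vs <= 1 (only when
       receptor tallies are supplied).
    """
    results = {}

    def add(name, a, b, c, d, rows, cols):
        if not any((a, b, c, d)):
            return  # degenerate (e.g. zero-divergence run): test skipped
        table = ContingencyTable2x2(a, b, c, d, rows, cols)
        results[name] = (table, fisher_exact_2x2(table))

    add("fixed_vs_polymorphic",
        chemo.n_fixed, chemo.n_polymorphic, nc.n_fixed, nc.n_polymorphic,
        (chemo.name, nc.name), ("fixed", "polymorphic"))
    add("fixed_nonsyn_vs_syn",
        chemo.n_fixed_nonsyn, chemo.n_fixed_syn, nc.n_fixed_nonsyn, nc.n_fixed_syn,
        (chemo.name, nc.name), ("fixed_nonsyn", "fixed_syn"))
    add("omega_gt1_enrichment",
        chemo.n_omega_gt1, chemo.n_genes, nc.n_omega_gt1, nc.n_genes,
        (chemo.name, nc.name), ("omega_gt1", "genes"))
    if receptor_gt1 is not None:
        add("receptor_enrichment",
            receptor_gt1, receptor_le1, nonreceptor_gt1, nonreceptor_le1,
            ("receptor", "non-receptor"), ("omega_gt1", "omega_le1"))
    return results


def gene_set_contingencies(gene_frame: pd.DataFrame, omega_frame: pd.DataFrame) -> dict:
    """Run the full gene-set test battery from pipeline tables.

    Emits the contingency tests of :func:`build_contingencies` plus
    Mann–Whitney comparisons of per-gene dN and dS between the sets
    (restricted to genes with fixed differences, where the rates are
    defined).
    """
    tallies = tally_gene_sets(gene_frame, omega_frame)
    chemo, nc = tallies["chemosensory"], tallies["NC"]

    genes = gene_frame[gene_frame["passes_coverage"]].copy()
    genes["receptor"] = genes["family_tag"].isin(RECEPTOR_FAMILIES)
    rates = omega_frame[["gene_id", "omega"]].copy()
    rates["omega"] = pd.to_numeric(rates["omega"], errors="coerce")
    merged = genes.merge(rates, on="gene_id", how="left")
    gt1 = (merged["omega"] > 1) | np.isinf(merged["omega"])
    gt1 = gt1.fillna(False)
    results = build_contingencies(
        chemo, nc,
        receptor_gt1=int((gt1 & merged["receptor"]).sum()),
        receptor_le1=int((~gt1 & merged["receptor"]).sum()),
        nonreceptor_gt1=int((gt1 & ~merged["receptor"]).sum()),
        nonreceptor_le1=int((~gt1 & ~merged["receptor"]).sum()),
    )
    if chemo.dn_values and nc.dn_values:
        results["dn_mann_whitney"] = (None, mann_whitney_u(chemo.dn_values, nc.dn_values))
    if chemo.ds_values and nc.ds_values:
        results["ds_mann_whitney"] = (None, mann_whitney_u(chemo.ds_values, nc.ds_values))
    results["tallies"] = tallies
    return results
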