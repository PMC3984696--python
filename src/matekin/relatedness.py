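"""Within-individual diversity and between-individual similarity statistics.

Three statistics drive the mate-choice analysis:

* **Internal relatedness (IR)** — a frequency-weighted multilocus
  homozygosity index: IR = (2H - sum f_i) / (2N - sum f_i), where H is the
  number of homozygous typed loci, N the number of typed loci, and the sum
  runs over the reference frequency of every one of the 2N allele copies in
  the genotype.  IR = 1 iff fully homozygous; rare-allele heterozygotes go
  negative.  Offspring of related parents have elevated IR.

* **Pairwise relatedness (r)** — the symmetric Queller-Goodnight estimator
  with ratio-of-sums multilocus weighting and, for unbiasedness, reference
  allele frequencies computed with the focal dyad excluded.  Expectation 0.5
  for parent-offspring, 0 for unrelated dyads.

* **MHC allele-sharing (D)** — D = 2|a n b| / (|a| + |b|) on allele-presence
  sets; 1 for identical profiles, 0 for disjoint ones.

Per-locus summaries (k, N, Hobs, unbiased Hexp, Monte Carlo exact
Hardy-Weinberg p) are exported in a table shaped like a standard
microsatellite marker-panel summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._codes import (
    CodedPopulation,
    count_matrix,
    encode_population,
    qg_relatedness,
)
from .genotype_io import MISSING, Individual, MicrosatGenotype, Population


@dataclass
class AlleleFrequencyTable:
    """Per-locus relative allele frequencies of a reference sample.

    ``freqs[locus][allele]`` in [0,1], summing to 1 per locus; only alleles
    with positive frequency are present.  ``sample_sizes[locus]`` counts the
    typed gene copies behind the estimate.
    """

    freqs: dict[str, dict[int, float]]
    sample_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for locus, fs in self.freqs.items():
            if MISSING in fs:
                raise ValueError(f"{locus}: MISSING in frequency table")
            s = sum(fs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {s}, not 1")

    def freq(self, locus: str, allele: int) -> float:
        try:
            return self.freqs[locus][allele]
        except KeyError:
            raise KeyError(
                f"allele {allele} at locus {locus} absent from frequency table; "
                f"frequencies must come from a sample containing the individual"
            ) from None

    def matrix_for(self, coded: CodedPopulation) -> np.ndarray:
        """(L, A) frequency matrix aligned with a coded population's labels."""
        out = np.zeros((coded.n_loci, max(coded.max_alleles, 1)))
        for l, locus in enumerate(coded.locus_names):
            fs = self.freqs.get(locus, {})
            for j, lab in enumerate(coded.allele_labels[l]):
                out[l, j] = fs.get(int(lab), 0.0)
        return out


@dataclass
class LocusSummary:
    locus: str
    k: int
    N: int
    Hobs: float
    Hexp: float
    hwe_p: float


def allele_frequencies(
    pop: Population,
    reference: list[str] | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> AlleleFrequencyTable:
    """Count-based allele frequencies over a reference sample.

    Default reference: all genotyped adults, pooled across years (matching
    how the marker panel is summarised).  ``exclude`` drops individuals, e.g.
    the focal dyad.  A locus with zero typed copies raises.
    """
    if reference is None:
        reference = [i.id for i in pop.adults() if i.genotype.n_typed > 0]
    ids = [i for i in reference if i not in exclude]
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    for locus in pop.locus_names:
        counts: dict[int, int] = {}
        for ind_id in ids:
            a, b = pop[ind_id].genotype.calls.get(locus, (MISSING, MISSING))
            if a != MISSING:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus}: no typed gene copies in reference")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        sizes[locus] = total
    return AlleleFrequencyTable(freqs, sizes)


def internal_relatedness(g: MicrosatGenotype, freqs: AlleleFrequencyTable) -> float:
    """IR of one genotype against a reference frequency table.

    Missing loci contribute nothing; a fully missing genotype raises; an
    allele absent from the table raises (the table must come from a sample
    containing the individual, or a superset).
    """
    H = N = 0
    S = 0.0
    for locus, (a, b) in g.calls.items():
        if a == MISSING:
            continue
        N += 1
        H += a == b
        S += freqs.freq(locus, a) + freqs.freq(locus, b)
    if N == 0:
        raise ValueError("genotype entirely missing: IR undefined")
    return (2.0 * H - S) / (2.0 * N - S)


def pairwise_relatedness(
    x: Individual,
    y: Individual,
    pop: Population,
    reference: list[str] | None = None,
) -> float:
    """Queller-Goodnight r between two individuals.

    Reference frequencies come from ``reference`` (default: genotyped
    adults) with the focal dyad excluded.  Raises if no locus is typed in
    both members or every locus is dropped (estimator undefined).
    """
    if x.id == y.id:
        # algebraic identity: per-locus numerator equals denominator
        if x.genotype.n_typed == 0:
            raise ValueError("estimator undefined: no typed loci")
        return 1.0
    if reference is None:
        reference = [i.id for i in pop.adults() if i.genotype.n_typed > 0]
    ref = list(dict.fromkeys(reference))
    for ind in (x.id, y.id):
        if ind not in ref:
            ref.append(ind)
    coded = encode_population(pop, ref)
    counts = count_matrix(coded)
    xi = coded.codes[coded.index[x.id]][None]
    yi = coded.codes[coded.index[y.id]][None]
    r = float(qg_relatedness(xi, yi, counts, exclude_dyad=True)[0])
    if np.isnan(r):
        raise ValueError("estimator undefined: all loci dropped")
    return r


def mhc_allele_sharing(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """D = 2|a n b| / (|a| + |b|); symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("allele-sharing undefined for an empty MHC profile")
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def hwe_exact_test(
    codes: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte Carlo exact Hardy-Weinberg test for one locus.

    ``codes``: (n, 2) integer allele codes of typed individuals.  The test
    statistic is the conditional probability of the genotype table given the
    allele counts (up to constants, h*ln 2 - sum ln n_g!); the p-value is the
    fraction of allele permutations with a table at most as probable,
    with the add-one correction so p is never 0.  Monomorphic loci return 1.
    """
    codes = np.asarray(codes)
    n = codes.shape[0]
    if n == 0:
        return 1.0
    k = int(codes.max()) + 1
    if k <= 1 or len(np.unique(codes)) <= 1:
        return 1.0
    rng = rng or np.random.default_rng()

    def _log_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        code = lo * k + hi
        h = (a != b).sum(axis=-1)
        if code.ndim == 1:
            cnt = np.bincount(code, minlength=k * k)
            table_term = gammaln(cnt + 1.0).sum()
        else:
            m = code.shape[0]
            cnt = np.zeros((m, k * k), dtype=np.float64)
            np.add.at(cnt, (np.repeat(np.arange(m), code.shape[1]), code.ravel()), 1.0)
            table_term = gammaln(cnt + 1.0).sum(axis=1)
        return h * np.log(2.0) - table_term

    obs = _log_t(codes[:, 0], codes[:, 1])
    pool = codes.ravel()
    idx = np.argsort(rng.random((n_perm, pool.size)), axis=1)
    perm = pool[idx]
    stats = _log_t(perm[:, ::2], perm[:, 1::2])
    return float((1 + np.sum(stats <= obs + 1e-12)) / (n_perm + 1))


def locus_summaries(
    pop: Population,
    reference: list[str] | None = None,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> list[LocusSummary]:
    """Marker-panel summary per locus over the reference adults.

    Hexp is the unbiased gene diversity 2n/(2n-1) * (1 - sum p^2); the HWE
    p-value comes from :func:`hwe_exact_test`.
    """
    if reference is None:
        reference = [i.id for i in pop.adults() if i.genotype.n_typed > 0]
    rng = rng or np.random.default_rng()
    coded = encode_population(pop, reference)
    out: list[LocusSummary] = []
    for l, locus in enumerate(coded.locus_names):
        col = coded.codes[:, l, :]
        typed = col[col[:, 0] >= 0]
        n = typed.shape[0]
        if n == 0:
            out.append(LocusSummary(locus, 0, 0, 0.0, 0.0, 1.0))
            continue
        labels, flat = np.unique(typed, return_inverse=True)
        typed = flat.reshape(typed.shape)
        k = len(labels)
        hobs = float((typed[:, 0] != typed[:, 1]).mean())
        p = np.bincount(typed.ravel(), minlength=k) / (2.0 * n)
        hexp = 0.0 if k == 1 else float(2 * n / (2 * n - 1) * (1.0 - np.sum(p**2)))
        hwe_p = 1.0 if k == 1 else hwe_exact_test(typed, n_perm=n_perm, rng=rng)
        out.append(LocusSummary(locus, k, n, hobs, hexp, hwe_p))
    return out


def locus_summary_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.locus, s.k, s.N, s.Hobs, s.Hexp, s.hwe_p) for s in summaries],
        columns=["locus", "k", "N", "Hobs", "Hexp", "HW_p"],
    )
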