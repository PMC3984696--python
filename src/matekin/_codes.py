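"""Dense array encoding of genotypes for the vectorised numeric kernels.

Allele labels are recoded per locus to contiguous indices 0..k_l-1 into a
per-locus frequency/count row; -1 marks a missing locus.  The encoding is a
private implementation detail: public APIs speak in loci and allele labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, MicrosatGenotype, Population


@dataclass
class CodedPopulation:
    ids: list[str]
    index: dict[str, int]
    codes: np.ndarray            # (n, L, 2) int32, -1 = missing
    locus_names: list[str]
    allele_labels: list[np.ndarray]   # per-locus sorted label arrays

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def max_alleles(self) -> int:
        return max((len(a) for a in self.allele_labels), default=0)

    def rows(self, ids) -> np.ndarray:
        return self.codes[[self.index[i] for i in ids]]

    def decode(self, row: np.ndarray) -> MicrosatGenotype:
        calls = {}
        for l, locus in enumerate(self.locus_names):
            a, b = row[l]
            if a < 0:
                calls[locus] = (MISSING, MISSING)
            else:
                calls[locus] = (
                    int(self.allele_labels[l][a]),
                    int(self.allele_labels[l][b]),
                )
        return MicrosatGenotype(calls)


def encode_population(pop: Population, ids: list[str] | None = None) -> CodedPopulation:
    """Recode every individual's genotype; allele space is the union observed."""
    if ids is None:
        ids = list(pop.individuals)
    loci = pop.locus_names
    label_sets: list[set[int]] = [set() for _ in loci]
    for ind_id in ids:
        g = pop[ind_id].genotype
        for l, locus in enumerate(loci):
            a, b = g.calls.get(locus, (MISSING, MISSING))
            if a != MISSING:
                label_sets[l].update((a, b))
    labels = [np.array(sorted(s), dtype=np.int64) for s in label_sets]
    lookup = [{int(a): j for j, a in enumerate(arr)} for arr in labels]
    codes = np.full((len(ids), len(loci), 2), -1, dtype=np.int32)
    for i, ind_id in enumerate(ids):
        g = pop[ind_id].genotype
        for l, locus in enumerate(loci):
            a, b = g.calls.get(locus, (MISSING, MISSING))
            if a != MISSING:
                codes[i, l, 0] = lookup[l][a]
                codes[i, l, 1] = lookup[l][b]
    return CodedPopulation(list(ids), {v: i for i, v in enumerate(ids)}, codes, list(loci), labels)


def count_matrix(coded: CodedPopulation, rows: np.ndarray | None = None) -> np.ndarray:
    """(L, A) matrix of typed gene-copy counts over the given row subset."""
    codes = coded.codes if rows is None else coded.codes[rows]
    L, A = coded.n_loci, max(coded.max_alleles, 1)
    out = np.zeros((L, A), dtype=np.float64)
    for l in range(L):
        c = codes[:, l, :].ravel()
        c = c[c >= 0]
        if len(c):
            out[l, : len(coded.allele_labels[l])] = np.bincount(
                c, minlength=len(coded.allele_labels[l])
            )[: len(coded.allele_labels[l])]
    return out


def freq_matrix_from_counts(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        f = counts / totals
    return np.nan_to_num(f)


def ir_values(codes: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """Internal relatedness for each row of ``codes`` against ``freq`` (L, A).

    IR = (2H - sum f_i) / (2N - sum f_i) over typed loci, where the sum runs
    over all 2N allele copies of the genotype.
    """
    n, L, _ = codes.shape
    typed = codes[:, :, 0] >= 0
    safe = np.clip(codes, 0, None)
    f = freq[np.arange(L)[None, :, None], safe]        # (n, L, 2)
    f = np.where(typed[:, :, None], f, 0.0)
    S = f.sum(axis=(1, 2))
    H = ((codes[:, :, 0] == codes[:, :, 1]) & typed).sum(axis=1)
    N = typed.sum(axis=1)
    if np.any(N == 0):
        raise ValueError("genotype with no typed loci")
    return (2.0 * H - S) / (2.0 * N - S)


def ir_values_loo(codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Leave-one-out internal relatedness: each row's own two gene copies per
    locus are removed from the reference counts before its frequencies are
    taken, so in-sample individuals are scored as if out-of-sample (the same
    footing as freshly simulated genotypes)."""
    n, L, _ = codes.shape
    typed = codes[:, :, 0] >= 0
    safe = np.clip(codes, 0, None)
    li = np.arange(L)[None, :]
    tot = counts.sum(axis=1)[None, :]
    c_a = counts[li, safe[:, :, 0]]
    c_b = counts[li, safe[:, :, 1]]
    hom = codes[:, :, 0] == codes[:, :, 1]
    own = np.where(hom, 2.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a = (c_a - own) / (tot - 2.0)
        f_b = (c_b - own) / (tot - 2.0)
    S = (np.where(typed, f_a + f_b, 0.0)).sum(axis=1)
    H = (hom & typed).sum(axis=1)
    N = typed.sum(axis=1)
    if np.any(N == 0):
        raise ValueError("genotype with no typed loci")
    return (2.0 * H - S) / (2.0 * N - S)


def qg_relatedness(
    x: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    exclude_dyad: bool = True,
) -> np.ndarray:
    """Symmetric Queller-Goodnight relatedness for paired rows of codes.

    ``x``, ``y``: (m, L, 2) coded genotypes; ``counts``: (L, A) gene-copy
    counts of the reference sample.  When ``exclude_dyad`` the four copies of
    the dyad itself are subtracted from the counts before computing the
    reference frequencies ("unbiased" estimator); the reference sample must
    then contain both members.  Multilocus weighting is ratio-of-sums; loci
    missing in either member, or with both per-direction denominators zero,
    are dropped.  Returns NaN where no locus survives.
    """
    m, L, _ = x.shape
    a, b = x[:, :, 0], x[:, :, 1]
    c, d = y[:, :, 0], y[:, :, 1]
    typed = (a >= 0) & (c >= 0)
    sa, sb = np.clip(a, 0, None), np.clip(b, 0, None)
    sc, sd = np.clip(c, 0, None), np.clip(d, 0, None)
    li = np.arange(L)[None, :]

    def _p(al_safe, al):
        cnt = counts[li, al_safe].astype(np.float64)
        tot = counts.sum(axis=1)[None, :] * np.ones((m, 1))
        if exclude_dyad:
            # remove the dyad's own copies of this allele and its 4 typed copies
            own = (
                (al == a).astype(np.float64)
                + (al == b)
                + (al == c)
                + (al == d)
            )
            cnt = cnt - own
            tot = tot - 4.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = cnt / tot
        return np.where(typed, p, 0.0)

    p_a, p_b = _p(sa, a), _p(sb, b)
    p_c, p_d = _p(sc, c), _p(sd, d)

    I = lambda u, v: (u == v).astype(np.float64)  # noqa: E731
    cross = 0.5 * (I(a, c) + I(a, d) + I(b, c) + I(b, d))
    num_x = cross - p_a - p_b
    den_x = 1.0 + I(a, b) - p_a - p_b
    num_y = cross - p_c - p_d
    den_y = 1.0 + I(c, d) - p_c - p_d

    keep = typed & ~((den_x == 0.0) & (den_y == 0.0))
    zero = np.zeros_like(num_x)
    sum_ = lambda v: np.where(keep, v, zero).sum(axis=1)  # noqa: E731
    nx, dx, ny, dy = sum_(num_x), sum_(den_x), sum_(num_y), sum_(den_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 0.5 * (nx / dx + ny / dy)
    r = np.where(keep.any(axis=1), r, np.nan)
    return r


def mendelian_offspring_codes(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Mendelian child per row: one uniform allele from each parent,
    independently across loci; a locus missing in either parent is missing
    in the child."""
    n, L, _ = mothers.shape
    pm = rng.integers(0, 2, size=(n, L))
    pf = rng.integers(0, 2, size=(n, L))
    child = np.stack(
        [
            np.take_along_axis(mothers, pm[:, :, None], axis=2)[:, :, 0],
            np.take_along_axis(fathers, pf[:, :, None], axis=2)[:, :, 0],
        ],
        axis=2,
    ).astype(np.int32)
    miss = (mothers[:, :, 0] < 0) | (fathers[:, :, 0] < 0)
    child[miss] = -1
    return child


def hwe_genotypes(freq_rows: list[np.ndarray], n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n individuals at Hardy-Weinberg equilibrium from per-locus freqs."""
    L = len(freq_rows)
    out = np.empty((n, L, 2), dtype=np.int32)
    for l, p in enumerate(freq_rows):
        out[:, l, :] = rng.choice(len(p), size=(n, 2), p=p)
    return out
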