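"""Likelihood-based paternity assignment with simulation-calibrated confidence.

For each chick the LOD score of a candidate sire is the summed per-locus log
likelihood ratio of "candidate is the father" against "the father is a random
male from the population":

    LOD = sum_l  ln[(1-e) T(g_c | g_m, g_f) + e P(g_c)]
        - sum_l  ln[(1-e) T(g_c | g_m)      + e P(g_c)]

where T are Mendelian transition probabilities (paternal allele from the
candidate vs from population frequencies), P(g_c) the Hardy-Weinberg genotype
probability, and e a per-locus genotyping-error rate under a simple mixture
model: with probability e the observed genotype is a random HWE draw.  When
the mother is untyped at a locus (or incompatible with the chick there) the
motherless forms are used, marginalising the dam over population frequencies.

Confidence follows the classic simulation-calibration recipe: simulate
offspring of known sires, score the full candidate pool, record
Delta = LOD(best) - LOD(second best), and find the smallest Delta threshold
at which the requested fraction (default 95%) of above-threshold best
candidates are the true sire.  A chick is assigned when its best male clears
the strict threshold; an assigned sire differing from the brood's social
father makes the chick extra-pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codes import (
    CodedPopulation,
    encode_population,
    hwe_genotypes,
    mendelian_offspring_codes,
)
from .genotype_io import Population, _mother_mismatch_loci
from .relatedness import AlleleFrequencyTable, allele_frequencies


@dataclass
class PaternityConfig:
    error_rate: float = 0.01
    confidence_level: float = 0.95          # strict class
    relaxed_level: float = 0.80             # relaxed class (label only)
    n_calibration_offspring: int = 10_000
    prop_candidates_sampled: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must be in (0, 1)")
        if not (0.0 < self.prop_candidates_sampled <= 1.0):
            raise ValueError("prop_candidates_sampled must be in (0, 1]")


@dataclass
class PaternityAssignment:
    chick_id: str
    best_male_id: str | None
    lod: float
    delta: float
    confidence: str                          # strict | relaxed | unassigned
    mismatch_loci: int
    status: str                              # within-pair | extra-pair | unassigned
    brood_id: str = ""
    year: int = 0
    reason: str = ""


@dataclass
class DeltaCalibration:
    strict: float
    relaxed: float
    n_simulated: int
    success_rate_at_strict: float


# ---------------------------------------------------------------------------
# LOD kernel
# ---------------------------------------------------------------------------

def lod_matrix(
    chicks: np.ndarray,
    mothers: np.ndarray | None,
    candidates: np.ndarray,
    freq: np.ndarray,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD and mismatch counts for every chick x candidate pair.

    ``chicks`` (nc, L, 2), ``mothers`` (nc, L, 2) or None, ``candidates``
    (nm, L, 2) coded genotypes; ``freq`` (L, A).  Loci untyped in the chick
    or the candidate are skipped; loci where the recorded mother is untyped
    or Mendelian-incompatible with the chick fall back to the motherless
    form.  Returns (lod (nc, nm), mismatches (nc, nm)); with error_rate = 0 a
    Mendelian exclusion gives lod = -inf rather than an exception.
    """
    nc, L, _ = chicks.shape
    nm = candidates.shape[0]
    li = np.arange(L)[None, :]

    a, b = chicks[:, :, 0], chicks[:, :, 1]          # (nc, L)
    ch_typed = a >= 0
    sa, sb = np.clip(a, 0, None), np.clip(b, 0, None)
    p_a = freq[li, sa]
    p_b = freq[li, sb]
    homo = a == b
    # HWE genotype probability P(g_c)
    pgc = np.where(homo, p_a * p_a, 2.0 * p_a * p_b)  # (nc, L)

    f = candidates                                    # (nm, L, 2)
    cd_typed = f[:, :, 0] >= 0                        # (nm, L)
    # candidate allele-match counts against each chick allele: (nc, nm, L)
    cFa = (f[None, :, :, 0] == a[:, None, :]).astype(np.float64) + (
        f[None, :, :, 1] == a[:, None, :]
    )
    cFb = (f[None, :, :, 0] == b[:, None, :]).astype(np.float64) + (
        f[None, :, :, 1] == b[:, None, :]
    )
    cFab = np.where(homo[:, None, :], cFa, 0.0)       # both == a and == b only if a == b

    if mothers is not None:
        m = mothers
        mo_typed = m[:, :, 0] >= 0                    # (nc, L)
        cMa = (m[:, :, 0] == a).astype(np.float64) + (m[:, :, 1] == a)
        cMb = (m[:, :, 0] == b).astype(np.float64) + (m[:, :, 1] == b)
        cMab = np.where(homo, cMa, 0.0)
        mo_compat = (cMa + cMb) > 0
        use_mother = mo_typed & mo_compat & ch_typed  # (nc, L)
    else:
        cMa = cMb = cMab = None
        use_mother = np.zeros((nc, L), dtype=bool)

    # motherless forms
    t_num_nm = 0.5 * np.where(
        homo[:, None, :], cFa * p_a[:, None, :], cFa * p_b[:, None, :] + cFb * p_a[:, None, :]
    )
    t_den_nm = np.broadcast_to(pgc[:, None, :], t_num_nm.shape)

    if mothers is not None:
        t_num_m = 0.25 * (
            cMa[:, None, :] * cFb + cMb[:, None, :] * cFa - cMab[:, None, :] * cFab
        )
        t_den_m = 0.5 * np.where(homo, cMa * p_a, cMa * p_b + cMb * p_a)  # (nc, L)
        t_num = np.where(use_mother[:, None, :], t_num_m, t_num_nm)
        t_den = np.where(use_mother[:, None, :], t_den_m[:, None, :], t_den_nm)
    else:
        t_num, t_den = t_num_nm, t_den_nm

    mask = ch_typed[:, None, :] & cd_typed[None, :, :]
    e = error_rate
    pgc3 = pgc[:, None, :]
    with np.errstate(divide="ignore"):
        num = np.log((1.0 - e) * t_num + e * pgc3)
        den = np.log((1.0 - e) * t_den + e * pgc3)
    contrib = np.where(mask, num - den, 0.0)
    # -inf - (-inf) would be nan; an excluded locus with e = 0 stays -inf
    contrib = np.where(mask & np.isneginf(num) & ~np.isneginf(den), -np.inf, contrib)
    lod = contrib.sum(axis=2)
    mismatches = (mask & (t_num == 0.0)).sum(axis=2)
    return lod, mismatches


def transition_lod(
    chick,
    mother,
    candidate,
    freqs: AlleleFrequencyTable,
    error_rate: float = 0.0,
    locus_names: list[str] | None = None,
) -> tuple[float, int]:
    """LOD and mismatch count for one chick/mother/candidate trio.

    ``chick``, ``mother`` (may be None), ``candidate`` are
    :class:`MicrosatGenotype`; convenience wrapper over the vectorised
    kernel.  Requires at least one locus typed jointly in chick and
    candidate.
    """
    from .genotype_io import MISSING

    if locus_names is None:
        locus_names = [l for l in chick.calls]
    joint = [
        l
        for l in locus_names
        if chick.is_typed(l) and candidate.is_typed(l)
    ]
    if not joint:
        raise ValueError("no locus typed jointly in chick and candidate")

    # build a tiny coded universe over just these genotypes
    labels: list[np.ndarray] = []
    for l in locus_names:
        s: set[int] = set()
        for g in (chick, mother, candidate):
            if g is None:
                continue
            a, bb = g.calls.get(l, (MISSING, MISSING))
            if a != MISSING:
                s.update((a, bb))
        s.update(freqs.freqs.get(l, {}))
        labels.append(np.array(sorted(s), dtype=np.int64))
    A = max((len(x) for x in labels), default=1)
    freq = np.zeros((len(locus_names), A))
    for i, l in enumerate(locus_names):
        fs = freqs.freqs.get(l, {})
        for j, lab in enumerate(labels[i]):
            freq[i, j] = fs.get(int(lab), 0.0)

    def code(g) -> np.ndarray:
        row = np.full((len(locus_names), 2), -1, dtype=np.int32)
        if g is None:
            return row
        for i, l in enumerate(locus_names):
            a, bb = g.calls.get(l, (MISSING, MISSING))
            if a != MISSING:
                lk = {int(v): j for j, v in enumerate(labels[i])}
                row[i] = (lk[a], lk[bb])
        return row

    lod, mm = lod_matrix(
        code(chick)[None],
        None if mother is None else code(mother)[None],
        code(candidate)[None],
        freq,
        error_rate,
    )
    return float(lod[0, 0]), int(mm[0, 0])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_delta(
    cfg: PaternityConfig,
    freqs: AlleleFrequencyTable,
    candidate_codes: np.ndarray,
    coded: CodedPopulation,
    rng: np.random.Generator | None = None,
) -> DeltaCalibration:
    """Simulate offspring of known sires and locate the Delta threshold.

    True sires are drawn from the candidate pool with probability
    ``prop_candidates_sampled`` (else an unsampled HWE male); mothers are HWE
    draws; chicks are Mendelian with per-locus error applied at
    ``error_rate``.  The strict threshold is the smallest Delta at which at
    least ``confidence_level`` of above-threshold best candidates are the
    true sire; deterministic given the RNG.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_pool = candidate_codes.shape[0]
    if n_pool == 0:
        raise ValueError("empty candidate pool")
    if n_pool == 1:
        warnings.warn("degenerate candidate pool of 1 male: Delta uses second-best LOD = 0")
    n_sim = cfg.n_calibration_offspring
    freq = freqs.matrix_for(coded)
    freq_rows = [
        freq[l, : max(len(coded.allele_labels[l]), 1)] for l in range(coded.n_loci)
    ]
    # guard: rows must each sum to 1
    freq_rows = [r / r.sum() if r.sum() > 0 else np.ones(1) for r in freq_rows]

    deltas = np.empty(n_sim)
    correct = np.empty(n_sim, dtype=bool)
    chunk = 2000
    for start in range(0, n_sim, chunk):
        nb = min(chunk, n_sim - start)
        mothers = hwe_genotypes(freq_rows, nb, rng)
        sampled = rng.random(nb) < cfg.prop_candidates_sampled
        sire_idx = rng.integers(0, n_pool, nb)
        sires = candidate_codes[sire_idx].copy()
        if (~sampled).any():
            sires[~sampled] = hwe_genotypes(freq_rows, int((~sampled).sum()), rng)
        chicks = mendelian_offspring_codes(mothers, sires, rng)
        if cfg.error_rate > 0:
            err = rng.random(chicks.shape[:2]) < cfg.error_rate
            if err.any():
                rand = hwe_genotypes(freq_rows, nb, rng)
                chicks = np.where(err[:, :, None], rand, chicks)
        lod, _ = lod_matrix(chicks, mothers, candidate_codes, freq, cfg.error_rate)
        order = np.argsort(lod, axis=1)
        best = order[:, -1]
        best_lod = lod[np.arange(nb), best]
        if n_pool >= 2:
            second_lod = lod[np.arange(nb), order[:, -2]]
        else:
            second_lod = np.zeros(nb)
        second_lod = np.where(np.isneginf(second_lod), np.nan, second_lod)
        d = best_lod - np.where(np.isnan(second_lod), 0.0, second_lod)
        d = np.where(np.isneginf(best_lod), 0.0, d)
        deltas[start : start + nb] = d
        correct[start : start + nb] = sampled & (best == sire_idx)

    strict = _smallest_threshold(deltas, correct, cfg.confidence_level)
    relaxed = _smallest_threshold(deltas, correct, cfg.relaxed_level)
    above = deltas >= strict
    rate = float(correct[above].mean()) if above.any() else float("nan")
    return DeltaCalibration(strict, min(relaxed, strict), n_sim, rate)


def _smallest_threshold(deltas: np.ndarray, correct: np.ndarray, level: float) -> float:
    """Smallest d such that mean(correct | delta >= d) >= level."""
    order = np.argsort(deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order].astype(np.float64)
    # suffix means
    suffix_sum = np.cumsum(c_sorted[::-1])[::-1]
    n_suffix = np.arange(len(deltas), 0, -1)
    rate = suffix_sum / n_suffix
    ok = rate >= level
    if not ok.any():
        return float(d_sorted[-1]) + 1e-9  # nothing assignable at this level
    i = int(np.argmax(ok))
    if i == 0:
        # every simulated assignment already meets the level
        return 0.0
    return float(d_sorted[i])


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_paternity(
    pop: Population,
    cfg: PaternityConfig,
    freqs: AlleleFrequencyTable | None = None,
) -> tuple[list[PaternityAssignment], dict[int, DeltaCalibration]]:
    """Assign a sire to every chick from the per-year candidate pools.

    The candidate pool for a year is every genotyped adult male on that
    year's roster; the Delta threshold is calibrated per year (pool
    composition differs).  Returns the assignments plus the per-year
    calibrations.
    """
    adult_ids = [i.id for i in pop.adults() if i.genotype.n_typed > 0]
    chick_ids = [c.id for c in pop.chicks()]
    if freqs is None:
        # include chicks so every observed allele has positive frequency
        typed_chicks = [c for c in chick_ids if pop[c].genotype.n_typed > 0]
        freqs = allele_frequencies(pop, reference=adult_ids + typed_chicks)
    coded = encode_population(pop, adult_ids + chick_ids)
    freq = freqs.matrix_for(coded)
    master = np.random.default_rng(cfg.seed)

    assignments: list[PaternityAssignment] = []
    calibrations: dict[int, DeltaCalibration] = {}
    brood_of = pop.brood_of()
    years = sorted({b.year for b in pop.broods})
    for year in years:
        males, _ = pop.rosters.get(year, ([], []))
        pool = [m for m in males if m in coded.index and pop[m].genotype.n_typed > 0]
        year_chicks = [
            c for c in chick_ids
            if c in brood_of and brood_of[c].year == year
        ]
        if not year_chicks:
            continue
        if not pool:
            for c in year_chicks:
                assignments.append(
                    PaternityAssignment(c, None, float("nan"), float("nan"),
                                        "unassigned", 0, "unassigned",
                                        brood_of[c].brood_id, year,
                                        reason="no candidate males"))
            continue
        cand = coded.rows(pool)
        rng = np.random.default_rng(master.integers(0, 2**31))
        cal = calibrate_delta(cfg, freqs, cand, coded, rng)
        calibrations[year] = cal

        typed = [c for c in year_chicks if pop[c].genotype.n_typed > 0]
        for c in year_chicks:
            if c not in typed:
                assignments.append(
                    PaternityAssignment(c, None, float("nan"), float("nan"),
                                        "unassigned", 0, "unassigned",
                                        brood_of[c].brood_id, year,
                                        reason="chick has no typed loci"))
        if not typed:
            continue
        ch = coded.rows(typed)
        mo = np.stack([
            coded.codes[coded.index[brood_of[c].social_mother]]
            if brood_of[c].social_mother in coded.index
            else np.full((coded.n_loci, 2), -1, dtype=np.int32)
            for c in typed
        ])
        lod, mism = lod_matrix(ch, mo, cand, freq, cfg.error_rate)
        order = np.argsort(lod, axis=1)
        nb = len(typed)
        best = order[:, -1]
        best_lod = lod[np.arange(nb), best]
        second = lod[np.arange(nb), order[:, -2]] if len(pool) >= 2 else np.zeros(nb)
        delta = best_lod - np.where(np.isneginf(second), 0.0, second)
        delta = np.where(np.isneginf(best_lod), 0.0, delta)
        best_mism = mism[np.arange(nb), best]
        for i, c in enumerate(typed):
            b = brood_of[c]
            male = pool[int(best[i])]
            if np.isneginf(best_lod[i]):
                conf, status, assigned = "unassigned", "unassigned", None
                reason = "all candidates excluded"
            elif delta[i] >= cal.strict:
                conf, status, assigned = "strict", "", male
                reason = ""
            elif delta[i] >= cal.relaxed:
                conf, status, assigned = "relaxed", "unassigned", None
                reason = "below strict Delta threshold"
            else:
                conf, status, assigned = "unassigned", "unassigned", None
                reason = "below Delta threshold"
            if assigned is not None:
                status = "within-pair" if assigned == b.social_father else "extra-pair"
            assignments.append(
                PaternityAssignment(
                    c, assigned, float(best_lod[i]), float(delta[i]), conf,
                    int(best_mism[i]), status, b.brood_id, year,
                    reason,
                )
            )
    return assignments, calibrations


def assignment_frame(assignments: list[PaternityAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.chick_id, a.brood_id, a.year, a.best_male_id, a.lod, a.delta,
             a.confidence, a.status, a.mismatch_loci, a.reason)
            for a in assignments
        ],
        columns=["chick_id", "brood_id", "year", "best_male", "lod", "delta",
                 "confidence", "status", "mismatch_loci", "reason"],
    )


def maternal_mismatch_check(
    pop: Population,
    threshold: int = 2,
) -> list[tuple[str, int, bool]]:
    """Screen broods for chicks incompatible with the recorded mother.

    Flags chicks sharing no allele with the social mother at more than
    ``threshold`` loci.  Returns one record per affected brood:
    (brood_id, max mismatch loci among flagged chicks, whole_brood) —
    ``whole_brood=True`` (every chick mismatches) points to a band misread
    rather than brood parasitism.
    """
    out: list[tuple[str, int, bool]] = []
    for b in pop.broods:
        mother = pop.individuals.get(b.social_mother)
        if mother is None or mother.genotype.n_typed == 0 or not b.chick_ids:
            continue
        counts = []
        for c in b.chick_ids:
            chick = pop.individuals.get(c)
            if chick is None or chick.genotype.n_typed == 0:
                continue
            counts.append(_mother_mismatch_loci(mother.genotype, chick.genotype))
        if not counts:
            continue
        flagged = [n for n in counts if n > threshold]
        if flagged:
            out.append((b.brood_id, max(flagged), len(flagged) == len(counts)))
    return out
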