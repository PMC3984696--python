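"""Randomization test of random mating.

The null hypothesis is that pair formation is random with respect to
genotype.  Each iteration re-pairs the year's reproductive males and females
(females without replacement — a female holds one nest; males with
replacement — a male can sire several females' young), regenerates the
observed number of chicks per breeding unit by Mendelian sampling, and
recomputes the statistic of interest.  Iterations are stratified by year and
pooled across years, so a three-year study yields one null distribution per
statistic.  Empirical p-values use the add-one correction
p_high = (1 + #{null >= observed}) / (B + 1), and both tails are always
reported.

Three statistics share one pairing code path:

* ``mean_offspring_IR`` — mean internal relatedness of (re)generated chicks;
* ``mean_pair_r``       — mean Queller-Goodnight relatedness of the pairs;
* ``mean_pair_D``       — mean MHC allele-sharing of the pairs.

Scopes select which observed entities define the comparison: all chicks,
within-pair or extra-pair chicks (paternity assignments required), social
pairs, or genetic pairs (female x assigned sire(s), averaged per breeding
event when a female had several extra-pair sires).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codes import (
    count_matrix,
    encode_population,
    ir_values,
    ir_values_loo,
    mendelian_offspring_codes,
    qg_relatedness,
)
from .genotype_io import MISSING, MicrosatGenotype, Population
from .relatedness import AlleleFrequencyTable, allele_frequencies

STATISTICS = ("mean_offspring_IR", "mean_pair_r", "mean_pair_D")
CHICK_SCOPES = ("all_chicks", "within_pair", "extra_pair")
PAIR_SCOPES = ("social_pairs", "genetic_pairs")


@dataclass
class NullDistribution:
    statistic: str
    scope: str
    B: int
    values: np.ndarray
    observed: float
    p_high: float
    p_low: float
    seed: int
    n_observed: int = 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.B > 1 else 0.0


def mendelian_offspring(
    mother: MicrosatGenotype, father: MicrosatGenotype, rng: np.random.Generator
) -> MicrosatGenotype:
    """One Mendelian child: at each locus typed in both parents, one allele
    drawn uniformly from each parent, independently across loci; a locus
    missing in either parent is missing in the child."""
    calls: dict[str, tuple[int, int]] = {}
    loci = set(mother.calls) | set(father.calls)
    for locus in sorted(loci):
        ma, mb = mother.calls.get(locus, (MISSING, MISSING))
        fa, fb = father.calls.get(locus, (MISSING, MISSING))
        if ma == MISSING or fa == MISSING:
            calls[locus] = (MISSING, MISSING)
        else:
            calls[locus] = (
                (ma, mb)[rng.integers(0, 2)],
                (fa, fb)[rng.integers(0, 2)],
            )
    return MicrosatGenotype(calls)


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------

@dataclass
class _YearPlan:
    year: int
    male_rows: np.ndarray          # rows into the coded universe
    female_rows: np.ndarray
    male_ids: list[str]
    female_ids: list[str]
    n_units: int = 0               # pair units to simulate
    chick_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    # chick-level structure (chick statistics only)
    unit_of_chick: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    ep_flag: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def _sample_pairs(
    plan: _YearPlan,
    rng: np.random.Generator,
    males_with_replacement: bool = True,
    females_with_replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Random (female_idx, male_idx) local index vectors for one iteration."""
    k = plan.n_units
    n_f, n_m = len(plan.female_ids), len(plan.male_ids)
    if n_f == 0 or n_m == 0:
        raise ValueError(f"year {plan.year}: empty roster")
    if females_with_replacement:
        f = rng.integers(0, n_f, k)
    else:
        if k > n_f:
            raise ValueError(
                f"year {plan.year}: {k} pairs requested but only {n_f} females"
            )
        f = rng.permutation(n_f)[:k]
    if males_with_replacement:
        m = rng.integers(0, n_m, k)
    else:
        if k > n_m:
            raise ValueError(
                f"year {plan.year}: {k} pairs requested but only {n_m} males"
            )
        m = rng.permutation(n_m)[:k]
    return f, m


def _pair_units(pop: Population, year: int) -> list[tuple[str, str, int]]:
    """Distinct (mother, father) social pairs of a year with chick totals."""
    agg: dict[tuple[str, str], int] = {}
    for b in pop.broods:
        if b.year == year:
            key = (b.social_mother, b.social_father)
            agg[key] = agg.get(key, 0) + len(b.chick_ids)
    return [(m, f, n) for (m, f), n in agg.items()]


def simulate_iteration(
    pop: Population,
    year: int,
    rng: np.random.Generator,
    males_with_replacement: bool = True,
    females_with_replacement: bool = False,
) -> tuple[list[tuple[str, str]], list[tuple[int, MicrosatGenotype]]]:
    """One randomized re-pairing of a year's roster.

    Returns ``(pairs, chicks)``: pairs as (female_id, male_id) matching the
    observed pair count, and chicks as (pair_index, genotype) regenerating
    each observed pair's chick total on the corresponding random pair.
    """
    males, females = pop.rosters.get(year, ([], []))
    units = _pair_units(pop, year)
    plan = _YearPlan(
        year,
        np.zeros(len(males), int), np.zeros(len(females), int),
        list(males), list(females),
        n_units=len(units),
        chick_counts=np.array([n for _, _, n in units], dtype=int),
    )
    f_idx, m_idx = _sample_pairs(
        plan, rng, males_with_replacement, females_with_replacement
    )
    pairs = [(females[f], males[m]) for f, m in zip(f_idx, m_idx)]
    chicks: list[tuple[int, MicrosatGenotype]] = []
    for j, (fid, mid) in enumerate(pairs):
        for _ in range(int(plan.chick_counts[j])):
            chicks.append(
                (j, mendelian_offspring(pop[fid].genotype, pop[mid].genotype, rng))
            )
    return pairs, chicks


def _scope_chicks(pop: Population, scope: str, assignments) -> list[str]:
    brood_of = pop.brood_of()
    all_chicks = [
        c.id for c in pop.chicks() if c.id in brood_of and c.genotype.n_typed > 0
    ]
    if scope == "all_chicks":
        return all_chicks
    if assignments is None:
        raise ValueError(f"scope {scope!r} requires paternity assignments")
    status = {a.chick_id: a.status for a in assignments}
    want = "within-pair" if scope == "within_pair" else "extra-pair"
    return [c for c in all_chicks if status.get(c) == want]


def _scope_events(pop: Population, scope: str, assignments):
    """Breeding events: list of (year, female_id, [male_id, ...])."""
    events = []
    if scope == "social_pairs":
        for year in sorted({b.year for b in pop.broods}):
            for mother, father, _ in _pair_units(pop, year):
                events.append((year, mother, [father]))
    else:  # genetic_pairs
        if assignments is None:
            raise ValueError("scope 'genetic_pairs' requires paternity assignments")
        sire_of = {
            a.chick_id: a.best_male_id
            for a in assignments
            if a.best_male_id is not None and a.status != "unassigned"
        }
        for b in pop.broods:
            sires = sorted({sire_of[c] for c in b.chick_ids if c in sire_of})
            if sires:
                events.append((b.year, b.social_mother, sires))
    return events


def null_test(
    pop: Population,
    statistic: str,
    scope: str,
    B: int = 1000,
    seed: int = 0,
    assignments=None,
    freqs: AlleleFrequencyTable | None = None,
    males_with_replacement: bool = True,
    females_with_replacement: bool = False,
) -> NullDistribution:
    """Observed statistic vs its year-stratified random-mating null.

    ``B`` iterations each re-pair every year's roster and pool the simulated
    entities across years; the observed value is computed on the real data
    with identical estimator settings (same reference frequencies, same
    dyad-excluded relatedness).  Raises if the scope is empty.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "mean_offspring_IR":
        if scope not in CHICK_SCOPES:
            raise ValueError(f"scope {scope!r} invalid for {statistic}")
    elif scope not in PAIR_SCOPES:
        raise ValueError(f"scope {scope!r} invalid for {statistic}")

    adult_ids = [i.id for i in pop.adults() if i.genotype.n_typed > 0]
    chick_ids = [c.id for c in pop.chicks() if c.genotype.n_typed > 0]
    coded = encode_population(pop, adult_ids + chick_ids)
    adult_rows = np.arange(len(adult_ids))
    counts = count_matrix(coded, adult_rows)
    loo_observed = freqs is None
    if freqs is None:
        # include genotyped chicks so every observed allele has positive
        # frequency (a chick can carry an allele its only adult carrier
        # happens to be missing-typed at); observed chicks are then scored
        # leave-one-out so they sit on the same footing as null chicks
        freqs = allele_frequencies(pop, reference=adult_ids + chick_ids)
    freq = freqs.matrix_for(coded)
    counts_ref = count_matrix(coded)

    # MHC bitmask matrix over the coded universe
    mhc_alleles = sorted({a for i in pop.individuals.values() if i.mhc for a in i.mhc})
    mhc_idx = {a: j for j, a in enumerate(mhc_alleles)}
    mhc = np.zeros((coded.n, max(len(mhc_alleles), 1)), dtype=bool)
    for ind_id in coded.ids:
        prof = pop[ind_id].mhc
        if prof:
            mhc[coded.index[ind_id], [mhc_idx[a] for a in prof]] = True

    years = sorted({b.year for b in pop.broods})
    plans: list[_YearPlan] = []
    rng = np.random.default_rng(seed)

    # ------------------------------------------------------------------ observed
    if statistic == "mean_offspring_IR":
        scope_chicks = _scope_chicks(pop, scope, assignments)
        if not scope_chicks:
            raise ValueError(f"scope {scope!r} contains no chicks")
        rows = np.array([coded.index[c] for c in scope_chicks])
        _check_freq_cover(coded.codes[rows], freq, statistic)
        if loo_observed:
            observed = float(np.mean(ir_values_loo(coded.codes[rows], counts_ref)))
        else:
            observed = float(np.mean(ir_values(coded.codes[rows], freq)))
        n_observed = len(scope_chicks)
        brood_of = pop.brood_of()
        in_scope = set(scope_chicks)
        status = {a.chick_id: a.status for a in assignments} if assignments else {}
        for year in years:
            # one unit per social pair; each chick keeps its observed
            # extra-pair status so the null regenerates the same number of
            # chicks AND mating pairs (extra-pair chicks get an independent
            # random sire)
            unit_key: dict[tuple[str, str], int] = {}
            unit_of: list[int] = []
            ep: list[bool] = []
            for b in pop.broods:
                if b.year != year:
                    continue
                key = (b.social_mother, b.social_father)
                for c in b.chick_ids:
                    if c not in in_scope:
                        continue
                    if key not in unit_key:
                        unit_key[key] = len(unit_key)
                    unit_of.append(unit_key[key])
                    ep.append(status.get(c) == "extra-pair")
            if not unit_of:
                continue
            plan = _roster_plan(pop, coded, year)
            plan.n_units = len(unit_key)
            plan.unit_of_chick = np.array(unit_of, dtype=int)
            plan.ep_flag = np.array(ep, dtype=bool)
            plans.append(plan)
    else:
        events = [e for e in _scope_events(pop, scope, assignments)]
        if statistic == "mean_pair_D":
            events = [
                (y, f, [m for m in ms if pop[m].mhc])
                for y, f, ms in events
                if pop[f].mhc
            ]
            events = [e for e in events if e[2]]
        if not events:
            raise ValueError(f"scope {scope!r} contains no pairs")
        per_event = []
        for _, fem, males in events:
            frow = coded.codes[coded.index[fem]][None]
            vals = []
            for m in males:
                if statistic == "mean_pair_r":
                    mrow = coded.codes[coded.index[m]][None]
                    vals.append(float(qg_relatedness(frow, mrow, counts)[0]))
                else:
                    fa = mhc[coded.index[fem]]
                    ma = mhc[coded.index[m]]
                    vals.append(2.0 * (fa & ma).sum() / (fa.sum() + ma.sum()))
            per_event.append(float(np.mean(vals)))
        observed = float(np.mean(per_event))
        n_observed = len(events)
        for year in years:
            k = sum(1 for y, _, _ in events if y == year)
            if k:
                plan = _roster_plan(pop, coded, year)
                plan.n_units = k
                plans.append(plan)

    # ---------------------------------------------------------------------- null
    values = np.empty(B)
    for it in range(B):
        parts: list[np.ndarray] = []
        for plan in plans:
            f_idx, m_idx = _sample_pairs(
                plan, rng, males_with_replacement, females_with_replacement
            )
            frows = plan.female_rows[f_idx]
            mrows = plan.male_rows[m_idx]
            if statistic == "mean_offspring_IR":
                u = plan.unit_of_chick
                mo = coded.codes[frows[u]]
                sire_rows = plan.male_rows[m_idx[u]].copy()
                ep = plan.ep_flag
                n_m = len(plan.male_ids)
                n_ep = int(ep.sum())
                if n_ep and n_m > 1:
                    # extra-pair chicks: independent sire, not the social male
                    j = rng.integers(0, n_m - 1, n_ep)
                    soc = m_idx[u][ep]
                    j = j + (j >= soc)
                    sire_rows[ep] = plan.male_rows[j]
                fa = coded.codes[sire_rows]
                kids = mendelian_offspring_codes(mo, fa, rng)
                parts.append(ir_values(kids, freq))
            elif statistic == "mean_pair_r":
                parts.append(
                    qg_relatedness(coded.codes[frows], coded.codes[mrows], counts)
                )
            else:
                fa, ma = mhc[frows], mhc[mrows]
                na, nb = fa.sum(axis=1), ma.sum(axis=1)
                ok = (na > 0) & (nb > 0)
                inter = (fa & ma).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    d = 2.0 * inter / (na + nb)
                parts.append(d[ok])
        pooled = np.concatenate(parts)
        values[it] = np.nanmean(pooled)

    p_high = float((1 + np.sum(values >= observed)) / (B + 1))
    p_low = float((1 + np.sum(values <= observed)) / (B + 1))
    return NullDistribution(
        statistic, scope, B, values, observed, p_high, p_low, seed, n_observed
    )


def _roster_plan(pop: Population, coded, year: int) -> _YearPlan:
    males, females = pop.rosters.get(year, ([], []))
    males = [m for m in males if m in coded.index]
    females = [f for f in females if f in coded.index]
    return _YearPlan(
        year,
        np.array([coded.index[m] for m in males], dtype=int),
        np.array([coded.index[f] for f in females], dtype=int),
        males,
        females,
    )


def _check_freq_cover(codes: np.ndarray, freq: np.ndarray, what: str) -> None:
    typed = codes[:, :, 0] >= 0
    L = codes.shape[1]
    f = freq[np.arange(L)[None, :, None], np.clip(codes, 0, None)]
    bad = typed[:, :, None] & (f <= 0.0)
    if bad.any():
        raise ValueError(
            f"{what}: some observed alleles have zero reference frequency; "
            f"compute frequencies on a sample containing these individuals"
        )
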