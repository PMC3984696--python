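"""Data model and input/output for microsatellite, MHC and brood data.

Genotypes are diploid microsatellite calls at named loci; allele labels are
positive integers (size classes), with ``MISSING = 0`` as the sentinel for an
untyped locus.  A locus is either fully typed (both calls > 0) or fully
missing — half genotypes are rejected at parse time because no downstream
statistic can use them.

Two input routes are supported:

* a GenePop file (2- or 3-digit diploid coding, auto-detected; ``00``/``000``
  encodes missing) carrying genotypes only, and
* a trio of delimited tables (``genotypes.csv`` long form, ``mhc.csv``,
  ``broods.csv``) carrying genotypes plus sex/stage, MHC allele-presence
  profiles and brood/field records, which assemble into a fully cross-linked
  :class:`Population`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

MISSING = 0

SEXES = ("male", "female", "unknown")
STAGES = ("adult", "chick")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Cross-reference or invariant violation in assembled data."""


@dataclass
class MicrosatGenotype:
    """Unordered diploid calls per locus: ``calls[locus] = (a, b)``.

    Invariant: at every locus either both calls are MISSING or neither.
    """

    calls: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, (a, b) in self.calls.items():
            if (a == MISSING) != (b == MISSING):
                raise ValidationError(
                    f"half-missing genotype at locus {locus!r}: {(a, b)}"
                )
            if a < 0 or b < 0:
                raise ValidationError(f"negative allele label at {locus!r}")

    def is_typed(self, locus: str) -> bool:
        a, b = self.calls.get(locus, (MISSING, MISSING))
        return a != MISSING

    def typed_loci(self) -> list[str]:
        return [l for l in self.calls if self.is_typed(l)]

    @property
    def n_typed(self) -> int:
        return len(self.typed_loci())


@dataclass
class Individual:
    id: str
    sex: str = "unknown"
    stage: str = "adult"
    years_present: set[int] = field(default_factory=set)
    genotype: MicrosatGenotype = field(default_factory=MicrosatGenotype)
    mhc: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"{self.id}: bad sex {self.sex!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"{self.id}: bad stage {self.stage!r}")


@dataclass
class BroodRecord:
    brood_id: str
    year: int
    social_mother: str
    social_father: str
    chick_ids: list[str]
    eggs_laid: int
    hatched: int
    fledged_by_chick: dict[str, bool] = field(default_factory=dict)


@dataclass
class Population:
    """Validated container linking individuals, loci, broods and year rosters.

    ``rosters[year] = (male_ids, female_ids)`` lists the reproductive adults
    of that year (see :func:`derive_rosters` for the definition used).
    """

    individuals: dict[str, Individual] = field(default_factory=dict)
    locus_names: list[str] = field(default_factory=list)
    broods: list[BroodRecord] = field(default_factory=list)
    rosters: dict[int, tuple[list[str], list[str]]] = field(default_factory=dict)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def adults(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.stage == "adult"]

    def chicks(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.stage == "chick"]

    def years(self) -> list[int]:
        return sorted({b.year for b in self.broods} | set(self.rosters))

    def natal_brood(self, chick_id: str) -> BroodRecord | None:
        for b in self.broods:
            if chick_id in b.chick_ids:
                return b
        return None

    def brood_of(self) -> dict[str, BroodRecord]:
        """Map chick id -> natal brood (first wins; validate() flags dupes)."""
        out: dict[str, BroodRecord] = {}
        for b in self.broods:
            for c in b.chick_ids:
                out.setdefault(c, b)
        return out


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class PopulationFragment:
    """Genotypes-only result of reading a GenePop file."""

    locus_names: list[str]
    individuals: list[tuple[str, MicrosatGenotype]]
    groups: list[list[str]]  # ids per "pop" block, order preserved
    title: str = ""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path) -> PopulationFragment:
    """Parse a GenePop file with diploid 2- or 3-digit allele coding.

    The digit width is auto-detected from the first genotype token; ``0000``
    (or ``000000``) encodes a missing locus.  Raises :class:`ParseError`
    naming the line for malformed headers, ragged locus counts or
    odd-length allele codes.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (line 1)")
    title = lines[0].strip()
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no 'pop' line found (header ends line {i})")
    if not locus_names:
        raise ParseError(f"{path}: no locus names before first 'pop' (line {i + 1})")

    individuals: list[tuple[str, MicrosatGenotype]] = []
    groups: list[list[str]] = []
    width: int | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            groups.append([])
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {lineno + 1}: missing ',' after id")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"{path}: line {lineno + 1}: {len(tokens)} genotype fields, "
                f"expected {len(locus_names)}"
            )
        calls: dict[str, tuple[int, int]] = {}
        for locus, tok in zip(locus_names, tokens):
            if len(tok) % 2 != 0 or len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}: line {lineno + 1}: bad allele code {tok!r} "
                    f"at locus {locus}"
                )
            if width is None:
                width = len(tok) // 2
            elif len(tok) // 2 != width:
                raise ParseError(
                    f"{path}: line {lineno + 1}: mixed allele-code widths"
                )
            a, b = int(tok[:width]), int(tok[width:])
            if (a == 0) != (b == 0):
                raise ParseError(
                    f"{path}: line {lineno + 1}: half-missing genotype {tok!r} "
                    f"at locus {locus}"
                )
            calls[locus] = (a, b)
        individuals.append((ind_id, MicrosatGenotype(calls)))
        groups[-1].append(ind_id)
    return PopulationFragment(locus_names, individuals, groups, title)


def write_genepop(fragment: PopulationFragment, path) -> None:
    """Write a GenePop file in 3-digit coding (the emitted dialect)."""
    buf = io.StringIO()
    buf.write((fragment.title or "matekin genotype export") + "\n")
    for locus in fragment.locus_names:
        buf.write(locus + "\n")
    by_id = dict(fragment.individuals)
    groups = fragment.groups or [[i for i, _ in fragment.individuals]]
    for group in groups:
        buf.write("Pop\n")
        for ind_id in group:
            g = by_id[ind_id]
            toks = []
            for locus in fragment.locus_names:
                a, b = g.calls.get(locus, (MISSING, MISSING))
                if max(a, b) > 999:
                    raise ValueError(f"allele label {max(a, b)} exceeds 3 digits")
                toks.append(f"{a:03d}{b:03d}")
            buf.write(f"{ind_id} ,  " + " ".join(toks) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def fragment_of(pop: Population, ids: list[str] | None = None) -> PopulationFragment:
    """Genotype-only view of a Population, adults then chicks by default."""
    if ids is None:
        ids = [i.id for i in pop.adults()] + [c.id for c in pop.chicks()]
    inds = [(i, pop[i].genotype) for i in ids]
    return PopulationFragment(list(pop.locus_names), inds, [list(ids)])


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_tables(genotypes, mhc, broods) -> Population:
    """Assemble a Population from the three delimited input tables.

    ``genotypes.csv``: id,sex,stage,year,locus,allele1,allele2 (long form;
    one row per individual x locus, year rows may repeat per presence year).
    ``mhc.csv``: id,allele.  ``broods.csv``: brood_id,year,mother_id,
    father_id,eggs_laid,hatched,chick_id,fledged (one row per chick).

    Raises :class:`ValidationError` listing dangling ids, duplicate
    conflicting rows, or sex conflicts.
    """
    gdf = pd.read_csv(genotypes, dtype={"id": str, "locus": str})
    mdf = pd.read_csv(mhc, dtype={"id": str}) if mhc is not None else None
    bdf = pd.read_csv(
        broods,
        dtype={"brood_id": str, "mother_id": str, "father_id": str, "chick_id": str},
    )

    required = {"id", "sex", "stage", "year", "locus", "allele1", "allele2"}
    if not required.issubset(gdf.columns):
        raise ParseError(f"genotypes table missing columns {required - set(gdf.columns)}")

    locus_names = list(dict.fromkeys(gdf["locus"]))
    individuals: dict[str, Individual] = {}
    errors: list[str] = []

    for ind_id, sub in gdf.groupby("id", sort=False):
        sexes = set(sub["sex"])
        stages = set(sub["stage"])
        if len(sexes) > 1:
            errors.append(f"{ind_id}: conflicting sex values {sorted(sexes)}")
        if len(stages) > 1:
            errors.append(f"{ind_id}: conflicting stage values {sorted(stages)}")
        calls: dict[str, tuple[int, int]] = {}
        for row in sub.itertuples():
            pair = (int(row.allele1), int(row.allele2))
            if row.locus in calls and calls[row.locus] != pair:
                errors.append(f"{ind_id}: duplicate conflicting rows at {row.locus}")
            calls[row.locus] = pair
        try:
            geno = MicrosatGenotype(
                {l: calls.get(l, (MISSING, MISSING)) for l in locus_names}
            )
        except ValidationError as e:
            errors.append(str(e))
            continue
        individuals[str(ind_id)] = Individual(
            id=str(ind_id),
            sex=next(iter(sexes)),
            stage=next(iter(stages)),
            years_present=set(int(y) for y in sub["year"]),
            genotype=geno,
        )

    if mdf is not None and len(mdf):
        for ind_id, sub in mdf.groupby("id", sort=False):
            if str(ind_id) not in individuals:
                errors.append(f"mhc.csv: unknown id {ind_id}")
                continue
            individuals[str(ind_id)].mhc = frozenset(int(a) for a in sub["allele"])

    brood_map: dict[str, BroodRecord] = {}
    for row in bdf.itertuples():
        bid = str(row.brood_id)
        rec = brood_map.get(bid)
        if rec is None:
            rec = BroodRecord(
                brood_id=bid,
                year=int(row.year),
                social_mother=str(row.mother_id),
                social_father=str(row.father_id),
                chick_ids=[],
                eggs_laid=int(row.eggs_laid),
                hatched=int(row.hatched),
            )
            brood_map[bid] = rec
        chick = str(row.chick_id)
        if chick and chick.lower() != "nan":
            rec.chick_ids.append(chick)
            rec.fledged_by_chick[chick] = bool(row.fledged)
            if chick not in individuals:
                errors.append(f"broods.csv: chick {chick} absent from genotype table")
    for rec in brood_map.values():
        for pid, want_sex in ((rec.social_mother, "female"), (rec.social_father, "male")):
            ind = individuals.get(pid)
            if ind is None:
                errors.append(f"brood {rec.brood_id}: unknown parent id {pid}")
            elif ind.sex != want_sex:
                errors.append(
                    f"brood {rec.brood_id}: parent {pid} has sex {ind.sex}, "
                    f"expected {want_sex}"
                )

    if errors:
        raise ValidationError("; ".join(errors))

    pop = Population(
        individuals=individuals,
        locus_names=locus_names,
        broods=list(brood_map.values()),
    )
    pop.rosters = derive_rosters(pop)
    return pop


def write_tables(pop: Population, genotypes, mhc, broods) -> None:
    """Write the three delimited tables (inverse of :func:`read_tables`)."""
    grows = []
    for ind in pop.individuals.values():
        years = sorted(ind.years_present) or [min(pop.years(), default=0)]
        for y in years:  # one block per presence year (long form allows repeats)
            for locus in pop.locus_names:
                a, b = ind.genotype.calls.get(locus, (MISSING, MISSING))
                grows.append((ind.id, ind.sex, ind.stage, y, locus, a, b))
    pd.DataFrame(
        grows, columns=["id", "sex", "stage", "year", "locus", "allele1", "allele2"]
    ).to_csv(genotypes, index=False)

    mrows = [
        (ind.id, a)
        for ind in pop.individuals.values()
        if ind.mhc
        for a in sorted(ind.mhc)
    ]
    pd.DataFrame(mrows, columns=["id", "allele"]).to_csv(mhc, index=False)

    brows = []
    for b in pop.broods:
        for c in b.chick_ids:
            brows.append(
                (b.brood_id, b.year, b.social_mother, b.social_father,
                 b.eggs_laid, b.hatched, c, int(b.fledged_by_chick.get(c, False)))
            )
    pd.DataFrame(
        brows,
        columns=["brood_id", "year", "mother_id", "father_id",
                 "eggs_laid", "hatched", "chick_id", "fledged"],
    ).to_csv(broods, index=False)


def derive_rosters(
    pop: Population,
    genetic_sires: dict[str, str] | None = None,
    include_all_adults: bool = False,
) -> dict[int, tuple[list[str], list[str]]]:
    """Year -> (reproductive males, reproductive females).

    "Reproductive" means: appears as a social parent of a brood that year,
    or (when known) as an assigned genetic sire of a chick hatched that year.
    ``include_all_adults=True`` widens the roster to every adult flagged
    present that year.
    """
    rosters: dict[int, tuple[list[str], list[str]]] = {}
    years = sorted({b.year for b in pop.broods})
    brood_of = pop.brood_of()
    for year in years:
        males: dict[str, None] = {}
        females: dict[str, None] = {}
        for b in pop.broods:
            if b.year != year:
                continue
            females.setdefault(b.social_mother)
            males.setdefault(b.social_father)
        if genetic_sires:
            for chick, sire in genetic_sires.items():
                b = brood_of.get(chick)
                if b is not None and b.year == year and sire in pop.individuals:
                    males.setdefault(sire)
        if include_all_adults:
            for ind in pop.adults():
                if year in ind.years_present:
                    (males if ind.sex == "male" else females).setdefault(ind.id)
        rosters[year] = (list(males), list(females))
    return rosters


def validate(pop: Population) -> list[Finding]:
    """Consistency report: errors block downstream stages, warnings do not."""
    findings: list[Finding] = []
    err = lambda m: findings.append(Finding("error", m))  # noqa: E731
    warn = lambda m: findings.append(Finding("warning", m))  # noqa: E731

    seen_natal: dict[str, str] = {}
    for b in pop.broods:
        if b.hatched > b.eggs_laid:
            err(f"brood {b.brood_id}: hatched {b.hatched} > eggs laid {b.eggs_laid}")
        if len(b.chick_ids) > b.hatched:
            err(
                f"brood {b.brood_id}: {len(b.chick_ids)} chicks listed but only "
                f"{b.hatched} hatched"
            )
        for pid, want in ((b.social_mother, "female"), (b.social_father, "male")):
            ind = pop.individuals.get(pid)
            if ind is None:
                err(f"brood {b.brood_id}: dangling parent id {pid}")
            elif ind.sex != want:
                err(f"brood {b.brood_id}: parent {pid} is {ind.sex}, expected {want}")
            elif ind.stage != "adult":
                err(f"brood {b.brood_id}: parent {pid} is not an adult")
        for c in b.chick_ids:
            if c not in pop.individuals:
                err(f"brood {b.brood_id}: dangling chick id {c}")
            elif c in seen_natal:
                err(f"chick {c} appears in broods {seen_natal[c]} and {b.brood_id}")
            else:
                seen_natal[c] = b.brood_id

    for ind in pop.individuals.values():
        if ind.stage == "chick" and ind.id not in seen_natal:
            err(f"chick {ind.id} has no natal brood")
        if ind.mhc is not None and len(ind.mhc) > 6:
            warn(f"{ind.id}: {len(ind.mhc)} MHC alleles (more than the usual 1-6)")

    # mother incompatible with all her chicks at >=2 loci: likely band misread
    # or brood parasitism; mirror of the maternal-mismatch screen.
    for b in pop.broods:
        mother = pop.individuals.get(b.social_mother)
        if mother is None or not b.chick_ids:
            continue
        if all(c in pop.individuals for c in b.chick_ids):
            n_bad = sum(
                _mother_mismatch_loci(mother.genotype, pop[c].genotype) >= 2
                for c in b.chick_ids
            )
            if n_bad == len(b.chick_ids):
                warn(
                    f"brood {b.brood_id}: mother {b.social_mother} mismatches every "
                    f"chick at >=2 loci — possible band-misread / parasitism"
                )

    for year, (males, females) in pop.rosters.items():
        for mid in males + females:
            ind = pop.individuals.get(mid)
            if ind is None:
                err(f"roster {year}: dangling id {mid}")
            elif ind.stage != "adult":
                err(f"roster {year}: {mid} is not an adult")
    return findings


def _mother_mismatch_loci(mother: MicrosatGenotype, chick: MicrosatGenotype) -> int:
    """Loci where the chick shares no allele with the putative mother."""
    n = 0
    for locus, (a, b) in chick.calls.items():
        if a == MISSING or not mother.is_typed(locus):
            continue
        ma, mb = mother.calls[locus]
        if a not in (ma, mb) and b not in (ma, mb):
            n += 1
    return n


def errors_of(findings: list[Finding]) -> list[Finding]:
    return [f for f in findings if f.level == "error"]
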