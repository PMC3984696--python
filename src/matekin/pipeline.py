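"""End-to-end orchestration: validate -> locus summaries -> paternity ->
observed statistics -> randomization tests -> report bundle.

The pipeline is a pure function of (inputs, config, seed): every random
stage draws from a named substream spawned off one master seed, so reruns
with the same configuration reproduce byte-identical CSV outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from .genotype_io import Population, derive_rosters
from .paternity import (
    PaternityConfig,
    assign_paternity,
    assignment_frame,
    maternal_mismatch_check,
)
from .random_mating import NullDistribution, null_test
from .relatedness import (
    allele_frequencies,
    internal_relatedness,
    locus_summaries,
    locus_summary_frame,
    mhc_allele_sharing,
    pairwise_relatedness,
)
from .synthetic import SimulationConfig, Truth, generate

DEFAULT_TESTS: list[tuple[str, str]] = [
    ("mean_offspring_IR", "all_chicks"),
    ("mean_offspring_IR", "within_pair"),
    ("mean_offspring_IR", "extra_pair"),
    ("mean_pair_r", "social_pairs"),
    ("mean_pair_r", "genetic_pairs"),
    ("mean_pair_D", "social_pairs"),
    ("mean_pair_D", "genetic_pairs"),
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "matekin_out"
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None   # genotypes / mhc / broods paths
    paternity: PaternityConfig = field(default_factory=PaternityConfig)
    B: int = 1000
    tests: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_TESTS))
    histograms: bool = True
    roster_all_adults: bool = False
    hwe_permutations: int = 10_000

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' / 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        pat = raw.pop("paternity", {})
        tests = raw.pop("tests", None)
        cfg = cls(
            simulate=SimulationConfig(**sim) if sim is not None else None,
            paternity=PaternityConfig(**pat),
            **raw,
        )
        if tests is not None:
            cfg.tests = [(t["statistic"], t["scope"]) for t in tests]
        return cfg


@dataclass
class RunResult:
    outdir: Path
    population: Population
    truth: Truth | None
    nulls: list[NullDistribution]
    files: dict[str, Path]


def load_population(inputs: dict[str, str], roster_all_adults: bool = False) -> Population:
    pop = gio.read_tables(inputs["genotypes"], inputs.get("mhc"), inputs["broods"])
    if roster_all_adults:
        pop.rosters = derive_rosters(pop, include_all_adults=True)
    return pop


def run(cfg: RunConfig, log=sys.stderr) -> RunResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    sub = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("simulate", "loci", "paternity", "nulltest"), master.spawn(4)
        )
    }
    files: dict[str, Path] = {}
    loglines = [f"matekin run  seed={cfg.seed}  numpy={np.__version__}"]

    def stage(name):
        loglines.append(f"stage: {name}")
        if log:
            print(f"[matekin] {name}", file=log)

    try:
        stage("load")
        truth = None
        if cfg.simulate is not None:
            pop, truth = generate(cfg.simulate, sub["simulate"])
        else:
            pop = load_population(cfg.inputs, cfg.roster_all_adults)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    try:
        stage("validate")
        findings = gio.validate(pop)
        errors = gio.errors_of(findings)
        if errors:
            raise ValueError("; ".join(f.message for f in errors))
        for f in findings:
            loglines.append(f"  {f.level}: {f.message}")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("validate", e) from e

    try:
        stage("locus_summaries")
        summ = locus_summaries(pop, n_perm=cfg.hwe_permutations, rng=sub["loci"])
        df = locus_summary_frame(summ)
        files["locus_summaries"] = out / "locus_summaries.csv"
        df.to_csv(files["locus_summaries"], index=False, float_format="%.6g")
    except Exception as e:  # noqa: BLE001
        raise StageError("locus_summaries", e) from e

    try:
        stage("paternity")
        pcfg = cfg.paternity
        pcfg.seed = int(sub["paternity"].integers(0, 2**31))
        assignments, calibrations = assign_paternity(pop, pcfg)
        adf = assignment_frame(assignments)
        files["assignments"] = out / "assignments.csv"
        adf.to_csv(files["assignments"], index=False, float_format="%.6g")
        for year, cal in calibrations.items():
            loglines.append(
                f"  year {year}: strict Delta={cal.strict:.4g} "
                f"(success {cal.success_rate_at_strict:.3f} on {cal.n_simulated} sims)"
            )
        for bid, nmm, whole in maternal_mismatch_check(pop):
            loglines.append(
                f"  maternal mismatch: brood {bid} ({nmm} loci, whole_brood={whole})"
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("paternity", e) from e

    try:
        stage("nulltest")
        nulls: list[NullDistribution] = []
        rows = []
        nt_seed_rng = sub["nulltest"]
        for statistic, scope in cfg.tests:
            s = int(nt_seed_rng.integers(0, 2**31))
            try:
                nd = null_test(
                    pop, statistic, scope, B=cfg.B, seed=s, assignments=assignments
                )
            except ValueError as e:
                loglines.append(f"  skipped {statistic}/{scope}: {e}")
                continue
            nulls.append(nd)
            rows.append(
                (statistic, scope, nd.B, nd.n_observed, nd.observed,
                 nd.null_mean, nd.null_sd, nd.p_high, nd.p_low, nd.seed)
            )
        ndf = pd.DataFrame(
            rows,
            columns=["statistic", "scope", "B", "n_observed", "observed",
                     "null_mean", "null_sd", "p_high", "p_low", "seed"],
        )
        files["nulltest"] = out / "nulltest.csv"
        ndf.to_csv(files["nulltest"], index=False, float_format="%.6g")
        if cfg.histograms:
            for nd in nulls:
                p = out / f"null_{nd.statistic}_{nd.scope}.svg"
                plot_null(nd, p)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("nulltest", e) from e

    try:
        stage("descriptive")
        ddf = descriptive_table(pop, assignments)
        files["descriptive"] = out / "descriptive.csv"
        ddf.to_csv(files["descriptive"], index=False, float_format="%.6g")
    except Exception as e:  # noqa: BLE001
        raise StageError("descriptive", e) from e

    files["log"] = out / "run.log"
    files["log"].write_text("\n".join(loglines) + "\n")
    return RunResult(out, pop, truth, nulls, files)


def summarize_epp(
    pop: Population,
    assignments,
    denominator: str = "assigned",
) -> pd.DataFrame:
    """Per-year extra-pair summary.

    Chick-level EPP % uses assigned chicks as denominator by default
    (``denominator='all'`` switches to every genotyped chick); brood-level
    % counts broods with at least one confidently extra-pair chick.
    """
    status = {a.chick_id: a.status for a in assignments}
    rows = []
    for year in sorted({b.year for b in pop.broods}):
        broods = [b for b in pop.broods if b.year == year]
        chicks = [c for b in broods for c in b.chick_ids]
        ep = sum(status.get(c) == "extra-pair" for c in chicks)
        wp = sum(status.get(c) == "within-pair" for c in chicks)
        un = len(chicks) - ep - wp
        denom = (ep + wp) if denominator == "assigned" else len(chicks)
        chick_pct = 100.0 * ep / denom if denom else float("nan")
        with_brood = [b for b in broods if b.chick_ids]
        b_ep = sum(
            any(status.get(c) == "extra-pair" for c in b.chick_ids) for b in with_brood
        )
        brood_pct = 100.0 * b_ep / len(with_brood) if with_brood else float("nan")
        rows.append((year, len(chicks), ep, wp, un, chick_pct, brood_pct))
    return pd.DataFrame(
        rows,
        columns=["year", "n_chicks", "extra_pair", "within_pair", "unassigned",
                 "chick_epp_pct", "brood_epp_pct"],
    )


def descriptive_table(pop: Population, assignments) -> pd.DataFrame:
    """Long-form descriptive summary (per-year EPP plus pooled means)."""
    epp = summarize_epp(pop, assignments)
    rows = [
        (f"chick_epp_pct_year{int(r.year)}", r.chick_epp_pct)
        for r in epp.itertuples()
    ] + [
        (f"brood_epp_pct_year{int(r.year)}", r.brood_epp_pct)
        for r in epp.itertuples()
    ] + [
        ("n_chicks_total", float(epp["n_chicks"].sum())),
        ("n_unassigned_total", float(epp["unassigned"].sum())),
    ]

    # mean distinct microsatellite alleles carried per adult
    adults = [a for a in pop.adults() if a.genotype.n_typed > 0]
    if adults:
        n_alleles = [
            sum(
                len({a, b})
                for a, b in ind.genotype.calls.values()
                if a != gio.MISSING
            )
            for ind in adults
        ]
        rows.append(("mean_microsat_alleles_per_adult", float(np.mean(n_alleles))))
    mhc_sizes = [len(i.mhc) for i in pop.individuals.values() if i.mhc]
    if mhc_sizes:
        rows.append(("mean_mhc_alleles_per_bird", float(np.mean(mhc_sizes))))

    typed_ids = [i.id for i in pop.individuals.values() if i.genotype.n_typed > 0]
    freqs = allele_frequencies(pop, reference=typed_ids)
    chicks = [c for c in pop.chicks() if c.genotype.n_typed > 0]
    if chicks:
        irs = [internal_relatedness(c.genotype, freqs) for c in chicks]
        rows.append(("mean_chick_IR", float(np.mean(irs))))
    pairs = {(b.social_mother, b.social_father) for b in pop.broods}
    rs = []
    ds = []
    for mom, dad in sorted(pairs):
        try:
            rs.append(pairwise_relatedness(pop[mom], pop[dad], pop))
        except (ValueError, KeyError):
            pass
        if pop[mom].mhc and pop[dad].mhc:
            ds.append(mhc_allele_sharing(pop[mom].mhc, pop[dad].mhc))
    if rs:
        rows.append(("mean_social_pair_r", float(np.mean(rs))))
    if ds:
        rows.append(("mean_social_pair_D", float(np.mean(ds))))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def plot_null(nd: NullDistribution, path) -> None:
    """Histogram of the null distribution with the observed value marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "matekin"}):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(nd.values, bins=40, color="#8aa9c9", edgecolor="white")
        ax.axvline(nd.observed, color="#c0392b", lw=2)
        ax.set_xlabel(nd.statistic)
        ax.set_ylabel("null count")
        ax.set_title(
            f"{nd.statistic} / {nd.scope}  (B={nd.B}, "
            f"p_high={nd.p_high:.3g}, p_low={nd.p_low:.3g})",
            fontsize=9,
        )
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)
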