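"""Synthetic MA experiments with known ground truth.

The generator mirrors the study design: a founder full-sib pair preceded by
~20 burn-in generations of sib mating, a 3-generation expansion
establishing 55 lines, then full-sib MA breeding with up to 3 matings per
line for 21 generations in total, a control branch cryopreserved at
generation 3 and revived when the MA lines reach generation 16, and
phenotypes generated under the animal-model variance structure (litter,
maternal, base-additive, mutational and residual components) with a shared
environmental time trend applied by calendar date.

Base-additive values are produced by gene-dropping founder haplotype
effects (exact A-structured covariance, inbreeding included); mutational
values by per-individual new-mutation bundles of variance ``v_m``
transmitted Mendelianly as discrete loci.  Every phenotype decomposes
exactly into stored parts (fixed + litter + maternal + additive +
mutational + residual), so simulations are reconstructible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from musema.pedigree import (FEMALE, MALE, IndividualRecord, Pedigree,
                             prepend_burnin)

MORPHOMETRIC_TRAITS = ("weight3wk", "weight6wk", "tail_length")
FITNESS_TRAITS = ("litter_size_trait", "surviving_offspring")


@dataclass
class TraitSpec:
    """Generative settings for one morphometric trait."""

    mean: float
    sex_effect: float            # added to males
    trend_per_gen: float         # shared environmental drift, units/gen
    dimension: str = "other"     # volume | length | other


def _default_traits() -> dict[str, TraitSpec]:
    # grams for weights, cm for tail; means near the study's strain
    return {
        "weight3wk": TraitSpec(mean=12.0, sex_effect=0.6,
                               trend_per_gen=-0.03, dimension="volume"),
        "weight6wk": TraitSpec(mean=22.0, sex_effect=2.0,
                               trend_per_gen=-0.05, dimension="volume"),
        "tail_length": TraitSpec(mean=8.0, sex_effect=0.15,
                                 trend_per_gen=-0.02, dimension="length"),
    }


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the MA study: 55 lines, 21 generations in total (the
    first 3 an expansion phase), up to 3 matings per line, a 20-generation
    burn-in, and a control branch frozen at generation 3, revived at MA
    generation 16, expanded 2 generations and bred for 3 more as 20 control
    lines.
    """

    n_lines: int = 55
    n_generations: int = 21            # last generation index
    expansion_generations: int = 3
    matings_per_line: int = 3
    burnin: int = 20
    control_branch_generation: int = 3
    control_revival_generation: int = 16
    n_control_lines: int = 20
    control_generations: int = 5       # incl. 2-generation expansion

    # variance components (trait units^2) shared across morphometric traits
    v_litter: float = 0.2
    v_maternal: float = 0.2
    v_a: float = 0.0                   # founders near-isogenic
    v_m: float = 0.005
    v_e: float = 1.0

    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    litter_mean: float = 6.5
    litter_max: int = 12
    mating_failure_prob: float = 0.10
    cross_family_prob: float = 0.13
    sex_ratio: float = 0.5
    survival_prob: float = 0.99
    ma_deficit_percent: float = 0.0    # genetic deficit of MA vs control
    seed_burnin_mutations: bool = True # founders at mutation-drift balance
    generation_days: int = 91          # ~13 weeks
    anchor_generation: int = 19        # MA generation born at anchor_date
    anchor_date: date = date(2022, 7, 20)
    seed: int = 0

    def date_of_generation(self, g: int) -> date:
        return (self.anchor_date
                + timedelta(days=(g - self.anchor_generation)
                            * self.generation_days))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    variance_components: dict[str, float]
    genetic_values: pd.DataFrame       # per individual x trait: a and m
    mutations: pd.DataFrame            # origin individual, trait, effect
    parts: dict[str, pd.DataFrame]     # per-trait exact phenotype parts

    def reconstruct(self, trait: str) -> np.ndarray:
        p = self.parts[trait]
        return (p["fixed"] + p["litter"] + p["maternal"] + p["additive"]
                + p["mutational"] + p["residual"]).to_numpy()


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, mean: float,
                       high: int) -> int:
    for _ in range(100):
        k = rng.poisson(mean)
        if 1 <= k <= high:
            return int(k)
    return max(1, min(high, int(round(mean))))


class _Breeder:
    """Shared litter-production machinery for MA and control branches."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator,
                 prefix: str = ""):
        self.cfg = cfg
        self.rng = rng
        self.counter = 0
        self.prefix = prefix
        self.records: list[IndividualRecord] = []
        self.litter_sizes: dict[str, int] = {}   # litter key -> pups born

    def new_id(self) -> str:
        self.counter += 1
        return f"{self.prefix}i{self.counter}"

    def spawn_litter(self, sire: str, dam: str, gen: int,
                     line: str | None, birth: date | None,
                     can_fail: bool = True) -> list[IndividualRecord]:
        if can_fail and self.rng.random() < self.cfg.mating_failure_prob:
            return []
        size = _truncated_poisson(self.rng, self.cfg.litter_mean,
                                  self.cfg.litter_max)
        pups = []
        for _ in range(size):
            sex = MALE if self.rng.random() < self.cfg.sex_ratio else FEMALE
            pups.append(IndividualRecord(
                id=self.new_id(), sire_id=sire, dam_id=dam, sex=sex,
                line_id=line, generation=gen, birth_date=birth))
        self.litter_sizes[f"{sire}x{dam}"] = size
        self.records.extend(pups)
        return pups

    def jittered_date(self, gen: int) -> date:
        base = self.cfg.date_of_generation(gen)
        return base + timedelta(days=int(self.rng.integers(-21, 22)))

    def next_pairs(self, litters: list[list[IndividualRecord]],
                   n_pairs: int) -> list[tuple[str, str]]:
        """Breeding-pair selection: fill pairs from one randomly picked
        litter, substituting from further litters, then falling back to
        cross-family (cross-litter) matings within the line.  A configured
        fraction of pairs is made cross-family outright."""
        litters = [l for l in litters if l]
        if not litters:
            return []
        order = list(self.rng.permutation(len(litters)))
        males = [[p.id for p in litters[i] if p.sex == MALE] for i in order]
        females = [[p.id for p in litters[i] if p.sex == FEMALE]
                   for i in order]
        for ms in males:
            self.rng.shuffle(ms)
        for fs in females:
            self.rng.shuffle(fs)
        pairs: list[tuple[str, str]] = []
        # within-litter pairs, first litter preferred
        for li in range(len(order)):
            while (len(pairs) < n_pairs and males[li] and females[li]
                   and not (self.rng.random() < self.cfg.cross_family_prob
                            and len(order) > 1)):
                pairs.append((males[li].pop(), females[li].pop()))
            if len(pairs) >= n_pairs:
                return pairs
        # cross-family fallback
        flat_m = [m for ms in males for m in ms]
        flat_f = [f for fs in females for f in fs]
        while len(pairs) < n_pairs and flat_m and flat_f:
            pairs.append((flat_m.pop(), flat_f.pop()))
        return pairs


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Simulate the MA pedigree: founder pair, expansion, line breeding.

    Burn-in generations are prepended afterwards (``cfg.burnin``).  Line
    extinction occurs when no breeding pair can be formed.  Fixed seeds
    give identical pedigrees.
    """
    rng = np.random.default_rng(cfg.seed)
    br = _Breeder(cfg, rng)
    fm = IndividualRecord(id="founder_m", sex=MALE, generation=0,
                          birth_date=br.jittered_date(0))
    ff = IndividualRecord(id="founder_f", sex=FEMALE, generation=0,
                          birth_date=br.jittered_date(0))
    br.records.extend([fm, ff])

    # expansion: each pair may produce two litters; pair off sibs freely
    pairs = [(fm.id, ff.id)]
    litters_by_pair: dict[tuple[str, str], list[IndividualRecord]] = {}
    for g in range(1, cfg.expansion_generations + 1):
        new_pairs: list[tuple[str, str]] = []
        for sire, dam in pairs:
            pups: list[IndividualRecord] = []
            for _ in range(2):
                pups.extend(br.spawn_litter(sire, dam, g, None,
                                            br.jittered_date(g),
                                            can_fail=False))
            males = [p.id for p in pups if p.sex == MALE]
            females = [p.id for p in pups if p.sex == FEMALE]
            rng.shuffle(males)
            rng.shuffle(females)
            new_pairs.extend(zip(males, females))
        pairs = new_pairs

    # line establishment: first n_lines expansion pairs found the lines
    rng.shuffle(pairs)
    line_pairs = pairs[: cfg.n_lines]
    line_of: dict[str, str] = {}
    for k, (m, f) in enumerate(line_pairs, start=1):
        line_of[m] = line_of[f] = f"L{k:02d}"
    br.records = [replace(r, line_id=line_of[r.id]) if r.id in line_of else r
                  for r in br.records]

    # MA line breeding
    alive: dict[str, list[tuple[str, str]]] = {
        line_of[m]: [(m, f)] for m, f in line_pairs}
    first_line_gen = cfg.expansion_generations + 1
    for g in range(first_line_gen, cfg.n_generations + 1):
        for line in list(alive):
            cur = alive[line]
            litters = []
            bdate = br.jittered_date(g)
            n_litters_per_pair = 2 if len(cur) == 1 else 1
            for sire, dam in cur:
                for _ in range(n_litters_per_pair):
                    litters.append(br.spawn_litter(sire, dam, g, line, bdate))
            nxt = br.next_pairs(litters, cfg.matings_per_line)
            if nxt:
                alive[line] = nxt
            else:
                del alive[line]   # line extinct
    ped = Pedigree(br.records)
    if cfg.burnin:
        ped = prepend_burnin(ped, cfg.burnin)
    return ped


# ---------------------------------------------------------------------------
# Genetic values
# ---------------------------------------------------------------------------

def _drop_additive(ped: Pedigree, v_a: float,
                   rng: np.random.Generator) -> np.ndarray:
    """A-structured base-additive values by founder-haplotype gene drop."""
    n = len(ped)
    parents = ped.parent_positions()
    hap = np.zeros((n, 2))
    sd = np.sqrt(v_a / 2.0)
    for i in range(n):
        s, d = parents[i]
        if s < 0:
            hap[i] = rng.normal(0.0, sd, size=2)
        else:
            hap[i, 0] = hap[s, rng.integers(0, 2)]
            hap[i, 1] = hap[d, rng.integers(0, 2)]
    return hap.sum(axis=1)


def _drop_mutational(ped: Pedigree, v_m: float, rng: np.random.Generator,
                     from_generation: int = 0
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-individual new-mutation bundles of variance v_m, transmitted
    Mendelianly as single heterozygous loci.

    Individuals born before ``from_generation`` receive no new bundle
    (burn-in mutations are part of founder variation, covered by v_a).
    Returns genotypic values and the mutation list (origin, effect).
    """
    n = len(ped)
    parents = ped.parent_positions()
    gens = ped.generations()
    pos = {i: p for p, i in enumerate(ped.ids)}
    child_pos: list[list[int]] = [[] for _ in range(n)]
    for cid, plist in ped.children_map().items():
        for ch in plist:
            child_pos[pos[cid]].append(pos[ch])

    values = np.zeros(n)
    sd = np.sqrt(v_m)
    muts = []
    for o in range(n):
        if gens[o] < from_generation or v_m == 0:
            continue
        eff = rng.normal(0.0, sd)
        muts.append((ped.ids[o], eff))
        desc = {o}
        stack = [o]
        while stack:
            for ch in child_pos[stack.pop()]:
                if ch not in desc:
                    desc.add(ch)
                    stack.append(ch)
        order = sorted(desc)
        copies = {o: 1}
        values[o] += eff
        for i in order[1:]:
            s, d = parents[i]
            c = 0
            for par in (s, d):
                pc = copies.get(par, 0)
                if pc:
                    c += int(rng.binomial(pc, 0.5))
            if c:
                copies[i] = c
                values[i] += c * eff
    mut_df = pd.DataFrame(muts, columns=["origin", "effect"])
    return values, mut_df


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(ped: Pedigree, cfg: SimConfig,
                        experiment: str = "MA") -> tuple[pd.DataFrame,
                                                         SimulationTruth]:
    """Generate the trait table and its exact decomposition.

    Morphometric traits attach to every line individual; fitness traits
    (litter size at birth, surviving offspring) attach to mothers only.
    Each morphometric trait gets independent genetic and environmental
    draws with the configured variance components; the environmental time
    trend is linear in generation.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    phen_recs = [r for r in ped.records if r.line_id is not None]
    if not phen_recs:
        phen_recs = [r for r in ped.records if (r.generation or 0) >= 0]
    litter_key = {r.id: f"{r.sire_id}x{r.dam_id}" for r in phen_recs
                  if r.sire_id is not None}
    litter_size_of: dict[str, int] = {}
    for r in ped.records:
        if r.sire_id is not None:
            k = f"{r.sire_id}x{r.dam_id}"
            litter_size_of[k] = litter_size_of.get(k, 0) + 1

    base = pd.DataFrame({
        "individual_id": [r.id for r in phen_recs],
        "experiment": experiment,
        "line": [r.line_id for r in phen_recs],
        "generation": [r.generation for r in phen_recs],
        "birth_date": [r.birth_date for r in phen_recs],
        "sex": [r.sex for r in phen_recs],
        "litter_id": [litter_key.get(r.id) for r in phen_recs],
        "mother_id": [r.dam_id for r in phen_recs],
    })
    base["litter_size"] = base["litter_id"].map(litter_size_of)

    gv_rows = {}
    parts: dict[str, pd.DataFrame] = {}
    mut_frames = []
    keep = np.array([ped.position(i) for i in base["individual_id"]])
    mut_from = (int(ped.generations().min()) if cfg.seed_burnin_mutations
                else 0)
    for trait, spec in cfg.traits.items():
        a = _drop_additive(ped, cfg.v_a, rng)
        m, mut_df = _drop_mutational(ped, cfg.v_m, rng,
                                     from_generation=mut_from)
        mut_df["trait"] = trait
        mut_frames.append(mut_df)
        litters = base["litter_id"].fillna("<none>")
        l_eff = {k: rng.normal(0, np.sqrt(cfg.v_litter))
                 for k in litters.unique()}
        mothers = base["mother_id"].fillna("<none>")
        m_eff = {k: rng.normal(0, np.sqrt(cfg.v_maternal))
                 for k in mothers.unique()}
        fixed = (spec.mean
                 + spec.sex_effect * (base["sex"] == MALE).to_numpy()
                 + spec.trend_per_gen * base["generation"].to_numpy(float))
        p = pd.DataFrame({
            "fixed": fixed,
            "litter": litters.map(l_eff).to_numpy(),
            "maternal": mothers.map(m_eff).to_numpy(),
            "additive": a[keep],
            "mutational": m[keep],
            "residual": rng.normal(0, np.sqrt(cfg.v_e), size=len(base)),
        })
        parts[trait] = p
        base[trait] = (p["fixed"] + p["litter"] + p["maternal"]
                       + p["additive"] + p["mutational"] + p["residual"])
        gv_rows[trait] = pd.DataFrame({
            "individual_id": base["individual_id"],
            "trait": trait, "additive": a[keep], "mutational": m[keep]})

    # fitness traits: structural litter sizes, assigned to mothers
    fitness = []
    for key, size in litter_size_of.items():
        dam = key.split("x", 1)[1]
        if dam not in ped:
            continue
        rec = ped[dam]
        if rec.line_id is None:
            continue
        surviving = int(rng.binomial(size, cfg.survival_prob))
        fitness.append({"individual_id": dam, "line": rec.line_id,
                        "generation": rec.generation,
                        "litter_size_trait": size,
                        "surviving_offspring": surviving})
    fit_df = pd.DataFrame(fitness)
    if not fit_df.empty:
        base = base.merge(fit_df, on=["individual_id", "line", "generation"],
                          how="left")
    else:
        base["litter_size_trait"] = np.nan
        base["surviving_offspring"] = np.nan

    truth = SimulationTruth(
        config=cfg,
        variance_components={"v_litter": cfg.v_litter,
                             "v_maternal": cfg.v_maternal,
                             "v_a": cfg.v_a, "v_m": cfg.v_m,
                             "v_e": cfg.v_e},
        genetic_values=pd.concat(gv_rows.values(), ignore_index=True),
        mutations=pd.concat(mut_frames, ignore_index=True),
        parts=parts,
    )
    return base, truth


# ---------------------------------------------------------------------------
# Control branch
# ---------------------------------------------------------------------------

def simulate_control_branch(ped: Pedigree, cfg: SimConfig
                            ) -> tuple[pd.DataFrame, Pedigree]:
    """Cryopreserved control lineage plus the combined MA+control table.

    Control embryos descend from the generation-3 branch point, undergo no
    mutation accumulation during storage, are revived at MA generation 16,
    expanded for 2 generations, and bred as ``n_control_lines`` lines for
    the remaining generations alongside the MA lines.  The shared
    environmental time trend is applied by calendar date (via the MA
    generation whose window a record falls in), so the MA-control contrast
    isolates the configured genetic deficit (``cfg.ma_deficit_percent``,
    applied to MA records as a mean shift).
    """
    bg = cfg.control_branch_generation
    branch_parents = sorted({(r.sire_id, r.dam_id) for r in ped.records
                             if r.generation == bg and r.sire_id is not None})
    if not branch_parents:
        raise ValueError(f"pedigree lacks a generation-{bg} branch point")
    rng = np.random.default_rng(cfg.seed + 202)
    br = _Breeder(cfg, rng, prefix="c")

    # revived embryos: litters of the branch-point pairs, born (revived)
    # when the MA lines are at the revival generation
    revival_gen = cfg.control_revival_generation
    revived: list[IndividualRecord] = []
    for sire, dam in branch_parents[:6]:
        revived.extend(br.spawn_litter(sire, dam, revival_gen, None,
                                       br.jittered_date(revival_gen),
                                       can_fail=False))
        if len(revived) >= 18:
            break

    # 2-generation expansion of the control cohort
    pairs = []
    males = [p.id for p in revived if p.sex == MALE]
    females = [p.id for p in revived if p.sex == FEMALE]
    rng.shuffle(males)
    rng.shuffle(females)
    pairs = list(zip(males, females))
    n_expansion = cfg.control_generations - 3
    for cg in range(1, n_expansion + 1):
        g = revival_gen + cg
        new_pairs = []
        for sire, dam in pairs:
            pups = []
            for _ in range(2):
                pups.extend(br.spawn_litter(sire, dam, g, None,
                                            br.jittered_date(g),
                                            can_fail=False))
            ms = [p.id for p in pups if p.sex == MALE]
            fs = [p.id for p in pups if p.sex == FEMALE]
            rng.shuffle(ms)
            rng.shuffle(fs)
            new_pairs.extend(zip(ms, fs))
        pairs = new_pairs
    rng.shuffle(pairs)
    line_pairs = pairs[: cfg.n_control_lines]
    line_of = {}
    for k, (m, f) in enumerate(line_pairs, start=1):
        line_of[m] = line_of[f] = f"C{k:02d}"
    br.records = [replace(r, line_id=line_of[r.id]) if r.id in line_of else r
                  for r in br.records]

    alive = {line_of[m]: [(m, f)] for m, f in line_pairs}
    first = revival_gen + n_expansion + 1
    for g in range(first, cfg.n_generations + 1):
        for line in list(alive):
            cur = alive[line]
            litters = []
            bdate = br.jittered_date(g)
            n_lit = 2 if len(cur) == 1 else 1
            for sire, dam in cur:
                for _ in range(n_lit):
                    litters.append(br.spawn_litter(sire, dam, g, line, bdate))
            nxt = br.next_pairs(litters, cfg.matings_per_line)
            if nxt:
                alive[line] = nxt
            else:
                del alive[line]

    combined_ped = Pedigree(list(ped.records) + br.records,
                            burnin_depth=ped.burnin_depth)
    ma_table, _ = simulate_phenotypes(ped, cfg, experiment="MA")
    ctrl_cfg = replace(cfg, seed=cfg.seed + 303)
    ctrl_table, _ = simulate_phenotypes(combined_ped, ctrl_cfg,
                                        experiment="control")
    ctrl_table = ctrl_table[
        ctrl_table["line"].astype(str).str.startswith("C")].copy()

    combined = pd.concat([ma_table, ctrl_table], ignore_index=True)
    # genetic deficit of the MA lines (accumulated mutational load),
    # expressed relative to the realized control mean so the window
    # contrast recovers the configured percentage
    if cfg.ma_deficit_percent:
        is_ma = combined["experiment"] == "MA"
        for trait in (*cfg.traits, *FITNESS_TRAITS):
            mean = combined.loc[~is_ma, trait].mean()
            combined.loc[is_ma, trait] += (cfg.ma_deficit_percent / 100.0
                                           * mean)
    return combined, combined_ped


# ---------------------------------------------------------------------------
# Toy VCF fixture generator
# ---------------------------------------------------------------------------

_ARTIFACT_CLASSES = ("clean", "shared", "founder", "low_qual", "low_depth",
                     "high_depth", "bad_balance", "impure", "phased",
                     "sexchrom_het", "triallelic", "crossmate")

# criterion expected to reject each artifact class (None: never a candidate)
ARTIFACT_EXPECTED_CRITERION = {
    "clean": None, "shared": None, "founder": None,
    "low_qual": 1, "low_depth": 2, "high_depth": 3, "bad_balance": 4,
    "impure": 5, "phased": 6, "sexchrom_het": 7, "triallelic": 8,
    "crossmate": 9,
}


def simulate_vcf(ped: Pedigree | None, sequenced: Sequence[str],
                 artifact_spec: dict[str, int], seed: int, path: str,
                 founders: Sequence[str] = ("founder_m", "founder_f"),
                 n_invariant: int = 100, invariant_pass: int = 80
                 ) -> pd.DataFrame:
    """Write a multi-sample VCF with planted de novos and artifact classes.

    ``artifact_spec`` maps class names (``clean``, ``shared``, ``founder``,
    ``low_qual``, ``low_depth``, ``high_depth``, ``bad_balance``,
    ``impure``, ``phased``, ``sexchrom_het``, ``triallelic``,
    ``crossmate``) to counts.  Also emits ``n_invariant`` per-base
    invariant records on chr1 of which ``invariant_pass`` meet the callable
    criteria, plus a handful of Y-chromosome records.  Returns the sidecar
    truth table; the written VCF is byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sequenced = list(sequenced)
    founders = list(founders)
    samples = founders + sequenced
    unknown = set(artifact_spec) - set(_ARTIFACT_CLASSES)
    if unknown:
        raise ValueError(f"unknown artifact classes: {sorted(unknown)}")

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=PH,Number=1,Type=Integer,Description='
        '"Variant in phase with a neighbouring variant">',
        '##INFO=<ID=XC,Number=1,Type=Integer,Description='
        '"Reads with mate aligned to another chromosome">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths">',
        "##contig=<ID=chr1,length=2000000>",
        "##contig=<ID=chr2,length=2000000>",
        "##contig=<ID=X,length=2000000>",
        "##contig=<ID=Y,length=2000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]

    def fmt(gt, dp, ad):
        return f"{gt}:{dp}:{','.join(map(str, ad))}"

    def clean_sample(dp):
        return fmt("0/0", dp, [dp, 0])

    def het_sample(dp, alt=None):
        alt = dp // 2 if alt is None else alt
        return fmt("0/1", dp, [dp - alt, alt])

    truth_rows = []
    pos_counter = {"chr1": 1000, "chr2": 1000, "X": 1000, "Y": 1000}
    bases = "ACGT"

    def next_pos(chrom):
        pos_counter[chrom] += int(rng.integers(50, 150))
        return pos_counter[chrom]

    def depth():
        return int(rng.integers(25, 40))

    records = []
    for cls in _ARTIFACT_CLASSES:
        for _ in range(artifact_spec.get(cls, 0)):
            chrom = "X" if cls == "sexchrom_het" else \
                rng.choice(["chr1", "chr2"])
            pos = next_pos(chrom)
            ref = bases[rng.integers(0, 4)]
            alt = bases[(bases.index(ref) + 1 + rng.integers(0, 3)) % 4]
            carrier = sequenced[rng.integers(0, len(sequenced))]
            qual = 100.0
            info = "."
            alt_field = alt
            cols = {}
            for s in samples:
                cols[s] = clean_sample(depth())
            if cls == "clean":
                cols[carrier] = het_sample(depth())
            elif cls == "shared":
                other = sequenced[(sequenced.index(carrier) + 1)
                                  % len(sequenced)]
                cols[carrier] = het_sample(depth())
                cols[other] = het_sample(depth())
            elif cls == "founder":
                cols[founders[0]] = het_sample(depth())
                cols[carrier] = het_sample(depth())
            elif cls == "low_qual":
                qual = 20.0
                cols[carrier] = het_sample(depth())
            elif cls == "low_depth":
                cols[carrier] = het_sample(depth())
                victim = samples[rng.integers(0, len(samples))]
                d = 5
                cols[victim] = (het_sample(d, 2) if victim == carrier
                                else fmt("0/0", d, [d, 0]))
            elif cls == "high_depth":
                cols[carrier] = het_sample(80)
            elif cls == "bad_balance":
                cols[carrier] = het_sample(30, 3)
            elif cls == "impure":
                cols[carrier] = het_sample(depth())
                others = [s for s in sequenced if s != carrier]
                spread = np.zeros(len(others), dtype=int)
                need = 26
                for k in range(len(spread)):
                    if need <= 0:
                        break
                    take = min(int(rng.integers(1, 8)), need)
                    spread[k] = take
                    need -= take
                if need > 0:
                    spread[0] += need
                for s, extra in zip(others, spread):
                    d = depth()
                    cols[s] = fmt("0/0", d, [d - int(extra), int(extra)])
            elif cls == "phased":
                info = "PH=1"
                cols[carrier] = het_sample(depth())
            elif cls == "sexchrom_het":
                cols[carrier] = het_sample(depth())
            elif cls == "triallelic":
                alt2 = bases[(bases.index(alt) + 1) % 4]
                if alt2 == ref:
                    alt2 = bases[(bases.index(alt) + 2) % 4]
                alt_field = f"{alt},{alt2}"
                d = depth()
                cols[carrier] = fmt("0/1", d, [d - d // 2, d // 2, 0])
                for s in samples:
                    if s != carrier:
                        d2 = depth()
                        cols[s] = fmt("0/0", d2, [d2, 0, 0])
            elif cls == "crossmate":
                info = "XC=2"
                cols[carrier] = het_sample(depth())
            records.append((chrom, pos, ref, alt_field, qual, info,
                            [cols[s] for s in samples]))
            truth_rows.append({
                "chrom": chrom, "pos": pos, "class": cls,
                "carrier": carrier,
                "is_candidate": cls not in ("shared", "founder"),
                "is_true_mutation": cls == "clean",
                "expected_criterion": ARTIFACT_EXPECTED_CRITERION[cls],
            })

    # invariant sites for callable accounting
    for k in range(n_invariant):
        chrom = "chr1"
        pos = next_pos(chrom)
        ref = bases[rng.integers(0, 4)]
        if k < invariant_pass:
            qual, d = 50.0, depth()
        else:
            # alternate between the two failure modes
            qual, d = (20.0, depth()) if k % 2 == 0 else (50.0, 5)
        cols = [fmt("0/0", d, [d, 0]) for _ in samples]
        records.append((chrom, pos, ref, ".", qual, ".", cols))
    for _ in range(5):
        pos = next_pos("Y")
        d = depth()
        records.append(("Y", pos, "A", ".", 50.0, ".",
                        [fmt("0/0", d, [d, 0]) for _ in samples]))

    chrom_order = {"chr1": 0, "chr2": 1, "X": 2, "Y": 3}
    records.sort(key=lambda r: (chrom_order[r[0]], r[1]))
    for chrom, pos, ref, alt, qual, info, cols in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\t.\t"
                     f"{info}\tGT:DP:AD\t" + "\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return pd.DataFrame(truth_rows)
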