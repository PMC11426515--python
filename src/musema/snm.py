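"""De novo single-nucleotide mutation (SNM) detection and rate estimation.

Candidates come from a multi-sample VCF holding the two MA-line founders
and one sequenced mouse per MA line: a candidate is a single-nucleotide
site where exactly one line sample carries a non-reference genotype and
both founders are homozygous reference.  Candidates are then filtered by
nine criteria:

1. site quality (QUAL) >= 30;
2. read depth of every sample >= 10;
3. read depth of every sample < 60;
4. a heterozygous call has an alt-read fraction in [0.25, 0.75];
5. alt reads summed over non-mutated MA samples <= an impurity threshold
   (default 25, chosen by the threshold search);
6. the variant is not in phase with neighbouring variants;
7. variants on sex chromosomes are homozygous;
8. the site has at most 2 alleles;
9. at most 1 read has its mate aligned to another chromosome.

Criteria 3 and 6-9 target misaligned paralogous reads.  The callable
genome applies criteria 1-3 to every site (invariant sites included) on
the autosomes and the X; the Y is excluded.  The per-site per-generation
rate divides the mutation count by 2 x callable sites x generations x
mice, and a pedigree-aware gene-dropping correction accounts for mutations
lost by segregation or filtered out because an expansion-phase origin made
them non-unique across lines.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from musema.pedigree import Pedigree

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

DEPTH_MIN = 10       # criterion 2 (inclusive)
DEPTH_MAX = 60       # criterion 3 (exclusive)
QUAL_MIN = 30.0      # criterion 1
ALT_FRAC = (0.25, 0.75)   # criterion 4, inclusive bounds
IMPURITY_DEFAULT = 25     # criterion 5


@dataclass
class SampleEvidence:
    depth: int | None
    genotype: str          # "hom_ref", "het", "hom_alt", "missing"
    alt_reads: int | None


@dataclass
class CandidateVariant:
    """One putative de novo SNM with per-sample evidence and verdicts."""

    chrom: str
    pos: int               # 1-based, VCF convention
    ref: str
    alt: str
    qual: float | None
    carrier: str           # the single line sample with a non-ref genotype
    samples: dict[str, SampleEvidence]
    line_samples: tuple[str, ...]
    founder_samples: tuple[str, ...]
    n_alleles: int = 2
    in_phase: bool = False
    cross_chrom_mate_reads: int = 0
    failed_criteria: list[int] = field(default_factory=list)
    incomplete_evidence: bool = False

    @property
    def passed(self) -> bool:
        return not self.failed_criteria and not self.incomplete_evidence

    def impurity_reads(self) -> int | None:
        """Alt reads summed over non-mutated MA samples."""
        total = 0
        for s in self.line_samples:
            if s == self.carrier:
                continue
            ev = self.samples[s]
            if ev.alt_reads is None:
                return None
            total += ev.alt_reads
        return total


def _gt_label(gt_type: int) -> str:
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    return {0: "hom_ref", 1: "het", 3: "hom_alt"}.get(gt_type, "missing")


def identify_candidates(vcf, founder_samples: Sequence[str],
                        line_samples: Sequence[str],
                        counters: dict | None = None
                        ) -> Iterator[CandidateVariant]:
    """Stream candidate de novo SNMs from a cyvcf2 VCF (or path).

    Emits biallelic-record single-nucleotide sites where both founders are
    homozygous reference and exactly one line sample is non-reference.
    Non-SNV records are skipped and counted in ``counters['non_snv']``.
    """
    if isinstance(vcf, str):
        from cyvcf2 import VCF
        vcf = VCF(vcf)
    names = list(vcf.samples)
    missing = [s for s in (*founder_samples, *line_samples)
               if s not in names]
    if missing:
        raise KeyError(f"samples absent from VCF: {missing}")
    sidx = {s: names.index(s) for s in names}
    if counters is None:
        counters = {}
    counters.setdefault("non_snv", 0)
    counters.setdefault("records", 0)

    for v in vcf:
        counters["records"] += 1
        if not v.ALT:          # invariant site
            continue
        if len(v.REF) != 1 or any(len(a) != 1 for a in v.ALT):
            counters["non_snv"] += 1
            continue
        gts = v.gt_types
        if any(gts[sidx[f]] != 0 for f in founder_samples):
            continue
        carriers = [s for s in line_samples
                    if gts[sidx[s]] in (1, 3)]
        if len(carriers) != 1:
            continue
        depths = v.gt_depths
        alts = v.gt_alt_depths
        samples = {}
        for s in (*founder_samples, *line_samples):
            i = sidx[s]
            samples[s] = SampleEvidence(
                depth=None if depths[i] < 0 else int(depths[i]),
                genotype=_gt_label(int(gts[i])),
                alt_reads=None if alts[i] < 0 else int(alts[i]),
            )
        info = dict(v.INFO)
        yield CandidateVariant(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
            qual=v.QUAL, carrier=carriers[0], samples=samples,
            line_samples=tuple(line_samples),
            founder_samples=tuple(founder_samples),
            n_alleles=1 + len(v.ALT),
            in_phase=bool(info.get("PH", 0)),
            cross_chrom_mate_reads=int(info.get("XC", 0)),
        )


def apply_site_filters(c: CandidateVariant,
                       impurity_threshold: int = IMPURITY_DEFAULT
                       ) -> list[int]:
    """Criteria 1-5 (quality, depth window, allele balance, impurity).

    Appends every failed criterion to ``c.failed_criteria`` and returns the
    list of criteria failed by this call.  Missing evidence fails with the
    ``incomplete_evidence`` flag set.
    """
    failed: list[int] = []
    if c.qual is None:
        c.incomplete_evidence = True
        failed.append(1)
    elif c.qual < QUAL_MIN:
        failed.append(1)
    for crit, bad in ((2, lambda d: d < DEPTH_MIN),
                      (3, lambda d: d >= DEPTH_MAX)):
        for ev in c.samples.values():
            if ev.depth is None:
                c.incomplete_evidence = True
                failed.append(crit)
                break
            if bad(ev.depth):
                failed.append(crit)
                break
    carrier = c.samples[c.carrier]
    if carrier.genotype == "het":
        if carrier.alt_reads is None or carrier.depth in (None, 0):
            c.incomplete_evidence = True
            failed.append(4)
        else:
            frac = carrier.alt_reads / carrier.depth
            if not (ALT_FRAC[0] <= frac <= ALT_FRAC[1]):
                failed.append(4)
    imp = c.impurity_reads()
    if imp is None:
        c.incomplete_evidence = True
        failed.append(5)
    elif imp > impurity_threshold:
        failed.append(5)
    c.failed_criteria.extend(f for f in failed if f not in c.failed_criteria)
    return failed


def apply_paralog_filters(c: CandidateVariant,
                          sex_chroms: set[str] = SEX_CHROMS) -> list[int]:
    """Criteria 6-9 (phase, sex-chromosome zygosity, allele count,
    cross-chromosome mate pairs)."""
    failed: list[int] = []
    if c.in_phase:
        failed.append(6)
    if c.chrom in sex_chroms and c.samples[c.carrier].genotype == "het":
        failed.append(7)
    if c.n_alleles > 2:
        failed.append(8)
    if c.cross_chrom_mate_reads > 1:
        failed.append(9)
    c.failed_criteria.extend(f for f in failed if f not in c.failed_criteria)
    return failed


def impurity_threshold_search(candidates: Sequence[tuple[int, bool]]) -> int:
    """Impurity threshold: raise the allowance from zero until no new true
    positives are included.

    ``candidates`` are (impurity_read_count, is_true_positive) pairs.
    Returns the smallest threshold at which the true-positive count has
    reached its maximum (i.e., the largest impurity count among true
    positives, found by upward scan).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    tp_counts = sorted(imp for imp, truth in candidates if truth)
    if not tp_counts:
        return 0
    total = len(tp_counts)
    t = 0
    while sum(1 for i in tp_counts if i <= t) < total:
        t += 1
    return t


@dataclass
class CallableMask:
    """Per-chromosome counts of sites meeting the detection-quality
    criteria (1-3); autosomes and X only, Y excluded."""

    per_chrom: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_chrom.values())


def callable_sites(vcf, included_chroms: set[str] | None = None
                   ) -> CallableMask:
    """Count sites (invariant included) passing criteria 1-3.

    The stream must carry per-base records with QUAL and per-sample depths.
    The Y chromosome never contributes; ``included_chroms`` restricts
    further when given.
    """
    if isinstance(vcf, str):
        from cyvcf2 import VCF
        vcf = VCF(vcf)
    counts: dict[str, int] = defaultdict(int)
    for v in vcf:
        chrom = v.CHROM
        if chrom in ("Y", "chrY"):
            continue
        if included_chroms is not None and chrom not in included_chroms:
            continue
        if v.QUAL is None or v.QUAL < QUAL_MIN:
            continue
        depths = v.gt_depths
        if (depths < DEPTH_MIN).any() or (depths >= DEPTH_MAX).any():
            continue
        counts[chrom] += 1
    return CallableMask(dict(counts))


# ---------------------------------------------------------------------------
# Gene-dropping correction for the rate estimate
# ---------------------------------------------------------------------------

def _eligible_origins(ped: Pedigree, sequenced: Sequence[str]) -> list[int]:
    """Origins that can contribute germline mutations to the sequenced
    samples: non-burn-in individuals born no later than the sequencing
    generation.  Burn-in mutations are founder variation, removed by the
    founder-genotype filter."""
    gens = ped.generations()
    seq_gen = max(ped[s].generation for s in sequenced)
    return [i for i in range(len(ped))
            if 0 <= gens[i] <= seq_gen]


@dataclass
class CorrectionEstimate:
    correction_factor: float
    p_detected: float      # carried by exactly one sequenced sample
    p_lost: float          # carried by no sequenced sample
    p_shared: float        # carried by >= 2 sequenced samples (non-unique)
    n_iter: int


def gene_drop_correction(ped: Pedigree, sequenced: Sequence[str],
                         n_iter: int = 1_000_000, seed: int = 0,
                         eligible: Sequence[str] | None = None
                         ) -> CorrectionEstimate:
    """Monte-Carlo correction factor for the mutation-rate estimate.

    Each iteration plants one heterozygous mutation in a uniformly chosen
    eligible individual and transmits it by random Mendelian segregation.
    It is *detected* when exactly one sequenced sample carries it
    (mirroring the uniqueness filter that removes expansion-phase
    mutations shared across lines); the correction factor is
    1 / P(detected) >= 1, with loss and sharing components reported.
    """
    if not sequenced:
        raise ValueError("no sequenced individuals given")
    for s in sequenced:
        if s not in ped:
            raise KeyError(f"sequenced individual {s!r} not in pedigree")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    if eligible is None:
        origin_pos = _eligible_origins(ped, sequenced)
    else:
        origin_pos = [ped.position(s) for s in eligible]

    parents = ped.parent_positions()
    pos = {i: p for p, i in enumerate(ped.ids)}
    child_pos: list[list[int]] = [[] for _ in range(len(ped))]
    for cid, plist in ped.children_map().items():
        for ch in plist:
            child_pos[pos[cid]].append(pos[ch])
    seq_pos = np.array(sorted(pos[s] for s in sequenced))

    # allocate iterations across origins (uniform origin choice)
    alloc = np.bincount(rng.integers(0, len(origin_pos), size=n_iter),
                        minlength=len(origin_pos))
    detected = lost = shared = 0
    for o, m in zip(origin_pos, alloc):
        m = int(m)
        if m == 0:
            continue
        desc = {o}
        stack = [o]
        while stack:
            for ch in child_pos[stack.pop()]:
                if ch not in desc:
                    desc.add(ch)
                    stack.append(ch)
        order = sorted(desc)
        copies: dict[int, np.ndarray] = {o: np.ones(m, dtype=np.int64)}
        for i in order[1:]:
            s, d = parents[i]
            cs = copies.get(s)
            cd = copies.get(d)
            if cs is None and cd is None:
                continue
            c = np.zeros(m, dtype=np.int64)
            if cs is not None:
                c += rng.binomial(cs, 0.5)
            if cd is not None:
                c += rng.binomial(cd, 0.5)
            copies[i] = c
        n_carrier = np.zeros(m, dtype=np.int64)
        for sp in seq_pos:
            c = copies.get(int(sp))
            if c is not None:
                n_carrier += (c > 0)
        detected += int((n_carrier == 1).sum())
        lost += int((n_carrier == 0).sum())
        shared += int((n_carrier >= 2).sum())

    p_det = detected / n_iter
    if p_det == 0:
        raise RuntimeError("no simulated mutation was detected; "
                           "correction factor undefined")
    return CorrectionEstimate(
        correction_factor=1.0 / p_det,
        p_detected=p_det,
        p_lost=lost / n_iter,
        p_shared=shared / n_iter,
        n_iter=n_iter,
    )


def enumerate_correction(ped: Pedigree, sequenced: Sequence[str],
                         eligible: Sequence[str] | None = None
                         ) -> CorrectionEstimate:
    """Exact correction factor by exhaustive enumeration of Mendelian
    transmission outcomes (frontier dynamic programme over copy-number
    states; practical for pedigrees up to a few tens of individuals)."""
    if not sequenced:
        raise ValueError("no sequenced individuals given")
    pos = {i: p for p, i in enumerate(ped.ids)}
    parents = ped.parent_positions()
    n = len(ped)
    if eligible is None:
        origin_pos = _eligible_origins(ped, sequenced)
    else:
        origin_pos = [pos[s] for s in eligible]
    seq_set = {pos[s] for s in sequenced}
    children = ped.children_map()
    last_use = np.full(n, -1)
    for p, ind in enumerate(ped.ids):
        for ch in children[ind]:
            last_use[p] = max(last_use[p], pos[ch])

    # transmission kernel: P(child copies from one parent | parent copies)
    trans = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}

    p_det = p_lost = p_shared = 0.0
    for o in origin_pos:
        # state: (frozen {position: copies} over individuals that still
        # have unprocessed children, carriers among sequenced so far)
        init_carr = 1 if o in seq_set else 0
        work: dict[tuple[tuple[tuple[int, int], ...], int], float] = {
            (((o, 1),), init_carr): 1.0}
        for i in range(o + 1, n):
            s, d = parents[i]
            new_work: dict[tuple[tuple[tuple[int, int], ...], int], float] = {}
            for (state, carr), prob in work.items():
                sd = dict(state)
                cs = sd.get(s, 0) if s >= 0 else 0
                cd = sd.get(d, 0) if s >= 0 else 0
                if cs or cd:
                    outcomes: dict[int, float] = {}
                    for a, pa in trans[cs].items():
                        for b, pb in trans[cd].items():
                            outcomes[a + b] = outcomes.get(a + b, 0) + pa * pb
                else:
                    outcomes = {0: 1.0}
                for c, pc in outcomes.items():
                    nd = dict(sd)
                    if c:
                        nd[i] = c
                    ncarr = carr + (1 if (c and i in seq_set) else 0)
                    pruned = tuple(sorted(
                        (k, v) for k, v in nd.items() if last_use[k] > i))
                    key = (pruned, ncarr)
                    new_work[key] = new_work.get(key, 0.0) + prob * pc
            work = new_work
        for (_, carr), prob in work.items():
            if carr == 1:
                p_det += prob
            elif carr == 0:
                p_lost += prob
            else:
                p_shared += prob
    k = len(origin_pos)
    p_det, p_lost, p_shared = p_det / k, p_lost / k, p_shared / k
    if p_det == 0:
        raise RuntimeError("detection probability is zero")
    return CorrectionEstimate(
        correction_factor=1.0 / p_det,
        p_detected=p_det, p_lost=p_lost, p_shared=p_shared, n_iter=0,
    )


@dataclass
class RateEstimate:
    """Per-site per-generation SNM rate with pedigree-aware correction."""

    n_mutations: int
    callable_sites: int
    n_generations: float
    n_mice: int
    correction_factor: float
    raw_rate: float
    corrected_rate: float


def mutation_rate(n_mutations: int, callable_sites: int,
                  n_generations: float, n_mice: int,
                  correction_factor: float = 1.0) -> RateEstimate:
    """Rate = mutations / (2 x callable sites x generations x mice), times
    the gene-dropping correction factor.

    ``n_generations`` is the mean pedigree depth from the founders to the
    sequenced individuals, so mice x generations equals the per-mouse sum
    of transmission opportunities.
    """
    if callable_sites <= 0:
        raise ValueError("callable sites must be positive")
    if n_generations <= 0 or n_mice <= 0:
        raise ValueError("generations and mice must be positive")
    if correction_factor < 1.0:
        raise ValueError("correction factor must be >= 1")
    raw = n_mutations / (2.0 * callable_sites * n_generations * n_mice)
    return RateEstimate(
        n_mutations=n_mutations, callable_sites=callable_sites,
        n_generations=n_generations, n_mice=n_mice,
        correction_factor=correction_factor,
        raw_rate=raw, corrected_rate=raw * correction_factor,
    )
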