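"""Shared fixtures: tiny hand-built pedigrees, a small simulated MA
experiment, and a toy VCF with planted truth."""

import numpy as np
import pytest

from musema.pedigree import FEMALE, MALE, IndividualRecord, Pedigree
from musema.simulate import (ARTIFACT_EXPECTED_CRITERION, SimConfig,
                             TraitSpec, simulate_pedigree,
                             simulate_phenotypes, simulate_vcf)


def make_chain_pedigree(n_gen: int = 3) -> Pedigree:
    """Founder pair plus n_gen successive full-sib generations."""
    recs = [IndividualRecord("f0m", sex=MALE, generation=0),
            IndividualRecord("f0f", sex=FEMALE, generation=0)]
    prev = ("f0m", "f0f")
    for g in range(1, n_gen + 1):
        m = IndividualRecord(f"g{g}m", prev[0], prev[1], MALE, generation=g)
        f = IndividualRecord(f"g{g}f", prev[0], prev[1], FEMALE, generation=g)
        recs.extend([m, f])
        prev = (m.id, f.id)
    return Pedigree(recs)


def make_random_pedigree(seed: int, n_max: int = 60) -> Pedigree:
    """Random mating structure: founder cohort plus random-parent
    generations, at most n_max individuals."""
    rng = np.random.default_rng(seed)
    n_founders = int(rng.integers(2, 6))
    recs = []
    males, females = [], []
    for i in range(n_founders):
        sex = MALE if i % 2 == 0 else FEMALE
        r = IndividualRecord(f"F{i}", sex=sex, generation=0)
        recs.append(r)
        (males if sex == MALE else females).append(r.id)
    g = 0
    while len(recs) < n_max:
        g += 1
        n_kids = int(rng.integers(2, 9))
        new_m, new_f = [], []
        for k in range(n_kids):
            if len(recs) >= n_max:
                break
            sire = males[rng.integers(0, len(males))]
            dam = females[rng.integers(0, len(females))]
            sex = MALE if rng.random() < 0.5 else FEMALE
            r = IndividualRecord(f"I{g}_{k}", sire, dam, sex, generation=g)
            recs.append(r)
            (new_m if sex == MALE else new_f).append(r.id)
        males = new_m or males
        females = new_f or females
        if g > 6:
            break
    return Pedigree(recs)


def make_line_pedigree(n_lines: int, n_gen: int, line_size: int) -> Pedigree:
    """Deterministic balanced pedigree: each line is a full-sib chain with
    exactly ``line_size`` individuals per generation (first two are the
    next breeding pair)."""
    recs = [IndividualRecord("fm", sex=MALE, generation=0),
            IndividualRecord("ff", sex=FEMALE, generation=0)]
    for l in range(1, n_lines + 1):
        prev = ("fm", "ff")
        for g in range(1, n_gen + 1):
            ids = []
            for k in range(line_size):
                sex = MALE if k % 2 == 0 else FEMALE
                r = IndividualRecord(f"L{l}g{g}i{k}", prev[0], prev[1], sex,
                                     line_id=f"L{l}", generation=g)
                recs.append(r)
                ids.append(r.id)
            prev = (ids[0], ids[1])
    return Pedigree(recs)


@pytest.fixture(scope="session")
def small_cfg():
    traits = {"trait": TraitSpec(mean=10.0, sex_effect=0.5,
                                 trend_per_gen=0.0)}
    return SimConfig(n_lines=12, n_generations=9, burnin=10, litter_mean=4.5,
                     seed=42, v_m=0.01, v_a=0.0, v_litter=0.1,
                     v_maternal=0.1, v_e=1.0, traits=traits)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    ped = simulate_pedigree(small_cfg)
    phen, truth = simulate_phenotypes(ped, small_cfg)
    return ped, phen, truth


@pytest.fixture(scope="session")
def vcf_fixture(tmp_path_factory):
    path = str(tmp_path_factory.mktemp("vcf") / "toy.vcf")
    sequenced = [f"line{i}" for i in range(1, 6)]
    spec = {c: (50 if c == "clean" else 10)
            for c in ARTIFACT_EXPECTED_CRITERION}
    truth = simulate_vcf(None, sequenced, spec, seed=9, path=path)
    return path, sequenced, truth
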