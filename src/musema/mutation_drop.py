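"""Between-line estimator of mutational heritability by mutation dropping.

The estimator uses only the variation among MA-line means.  A large number
of effect-tagged mutations (10^6 by default) is dropped into the complete
pedigree -- including the full-sib burn-in generations leading up to the
founder pair -- under diploid autosomal Mendelian inheritance.  Each of the
n pedigree members is seeded with an average of b = n_mutations/n new
mutations of effect -a or +a with equal probability, with a = sqrt(2/b) so
the per-individual mutational variance V_M = b a^2 / 2 is exactly 1.  Line
means of genotypic values give the expected between-line genetic variance
trajectory g (per unit V_M); standard-normal environmental draws averaged
over replicates give the environmental trajectory e (per unit V_E).  The
observed between-line phenotypic variance trajectory z is then fitted as

    z ~ x * g + y * e      (least squares),

and the mutational heritability is h2_M = x / y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from musema.pedigree import FEMALE, MALE, Pedigree


@dataclass
class DropConfig:
    """Configuration of the mutation-dropping simulation.

    ``effect`` is derived from the mutation count and pedigree size so the
    seeded mutational variance is exactly one unit; it is not user-set.
    """

    n_mutations_total: int = 1_000_000
    n_env_replicates: int = 100
    seed: int = 0

    def effect(self, n_individuals: int) -> float:
        b = self.n_mutations_total / n_individuals
        return float(np.sqrt(2.0 / b))

    def per_individual_variance(self, n_individuals: int) -> float:
        """b * a^2 / 2 with a = sqrt(2/b); equals 1 exactly by
        construction (evaluated in rational arithmetic so the identity is
        not blurred by the float sqrt round trip)."""
        from fractions import Fraction
        b = Fraction(self.n_mutations_total, n_individuals)
        a_sq = 2 / b
        return float(b * a_sq / 2)


@dataclass
class VarianceSeries:
    """Aligned per-generation between-line variance trajectories.

    ``z`` observed phenotypic, ``g`` expected genetic (per unit V_M),
    ``e_env`` expected environmental (per unit V_E).  The generation range
    runs from t1, the first generation with >= 2 independent lines with
    data, to t2, the last generation of the experiment.
    """

    generations: np.ndarray
    z: np.ndarray | None = None
    g: np.ndarray | None = None
    e_env: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        for name in ("z", "g", "e_env"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.generations.shape:
                    raise ValueError(f"{name} misaligned with generations")
                setattr(self, name, v)

    def merged(self, other: "VarianceSeries") -> "VarianceSeries":
        """Combine filled channels of two series over the intersection of
        their generation ranges."""
        common = np.intersect1d(self.generations, other.generations)
        out = VarianceSeries(common)
        for name in ("z", "g", "e_env"):
            for src in (self, other):
                v = getattr(src, name)
                if v is not None:
                    sel = np.isin(src.generations, common)
                    setattr(out, name, np.asarray(v)[sel])
        return out


@dataclass
class H2MEstimate:
    """Least-squares fit of z on (g, e_env)."""

    x_coef: float     # weight on g, in units of V_M
    y_coef: float     # weight on e_env, in units of V_E
    h2m: float        # x / y
    ci_low: float | None = None
    ci_high: float | None = None


# ---------------------------------------------------------------------------
# Observed trajectory z
# ---------------------------------------------------------------------------

def _sex_corrected(values: np.ndarray, sex: np.ndarray,
                   per_generation: bool = False,
                   generation: np.ndarray | None = None) -> np.ndarray:
    """Subtract per-sex grand means (default) or per-generation-sex means."""
    out = np.asarray(values, dtype=float).copy()
    if per_generation:
        df = pd.DataFrame({"v": out, "s": sex, "g": generation})
        out -= df.groupby(["s", "g"])["v"].transform("mean").to_numpy()
    else:
        for s in np.unique(sex):
            m = sex == s
            out[m] -= out[m].mean()
    return out


def observed_between_line_variances(
        phenotypes: pd.DataFrame, ped: Pedigree, trait: str,
        sex_correction: str = "grand") -> VarianceSeries:
    """Between-MA-line variance of sex-corrected line means, per generation.

    ``phenotypes`` needs columns ``individual_id``, ``line``, ``generation``,
    ``sex`` and the trait.  Generations with fewer than 2 lines are dropped
    from the front (defining t1); a data-free generation inside [t1, t2] is
    an error.
    """
    if trait not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    df = phenotypes.dropna(subset=[trait]).copy()
    df["_corr"] = _sex_corrected(
        df[trait].to_numpy(), df["sex"].to_numpy(),
        per_generation=(sex_correction == "per_generation"),
        generation=df["generation"].to_numpy())
    line_means = (df.groupby(["generation", "line"])["_corr"].mean()
                    .unstack("line"))
    n_lines = line_means.notna().sum(axis=1)
    usable = n_lines[n_lines >= 2]
    if usable.empty:
        raise ValueError("no generation has >= 2 lines with data")
    t1 = int(usable.index.min())
    t2 = int(line_means.index.max())
    gens = np.arange(t1, t2 + 1)
    missing = [g for g in gens if g not in line_means.index
               or n_lines.get(g, 0) < 2]
    if missing:
        raise ValueError(f"generations {missing} inside [{t1}, {t2}] lack "
                         "data from >= 2 lines")
    z = line_means.loc[gens].var(axis=1, ddof=1).to_numpy()
    return VarianceSeries(gens, z=z)


# ---------------------------------------------------------------------------
# Simulated trajectories g and e
# ---------------------------------------------------------------------------

def _line_assignment(ped: Pedigree):
    lines = sorted({r.line_id for r in ped.records if r.line_id is not None})
    line_pos = {l: i for i, l in enumerate(lines)}
    idx = np.array([line_pos.get(r.line_id, -1) for r in ped.records])
    return lines, idx


def _between_line_variance_by_generation(values: np.ndarray, ped: Pedigree,
                                         gens_wanted: np.ndarray) -> np.ndarray:
    """Variance across line means of ``values`` for each requested
    generation (NaN when < 2 lines present)."""
    lines, line_idx = _line_assignment(ped)
    gens = ped.generations()
    out = np.full(len(gens_wanted), np.nan)
    for j, t in enumerate(gens_wanted):
        sel = (gens == t) & (line_idx >= 0)
        if not sel.any():
            continue
        df = pd.DataFrame({"line": line_idx[sel], "v": values[sel]})
        means = df.groupby("line")["v"].mean()
        if len(means) >= 2:
            out[j] = means.var(ddof=1)
    return out


def drop_genotypic_values(ped: Pedigree, cfg: DropConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Drop ``cfg.n_mutations_total`` effect-tagged mutations through the
    pedigree and return each individual's genotypic value (sum of carried
    effects).

    Mutations are allocated round-robin so the total is exact: with
    b = total/n, each individual receives floor(b) or ceil(b) mutations.
    Each mutation starts as a single copy on one haplotype of its origin
    individual and every transmission passes each carried copy with
    probability 1/2.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(ped)
    a = cfg.effect(n)
    counts = np.full(n, cfg.n_mutations_total // n, dtype=np.int64)
    counts[: cfg.n_mutations_total % n] += 1

    parents = ped.parent_positions()
    pos = {i: p for p, i in enumerate(ped.ids)}
    child_pos: list[list[int]] = [[] for _ in range(n)]
    for cid, plist in ped.children_map().items():
        for ch in plist:
            child_pos[pos[cid]].append(pos[ch])

    # per-origin descendant subtrees, walked in global topological order
    values = np.zeros(n)
    for o in range(n):
        m = int(counts[o])
        if m == 0:
            continue
        effects = rng.choice([-a, a], size=m)
        desc = {o}
        stack = [o]
        while stack:
            for ch in child_pos[stack.pop()]:
                if ch not in desc:
                    desc.add(ch)
                    stack.append(ch)
        order = sorted(desc)
        # copies[i] = per-mutation copy count carried by individual i
        copies: dict[int, np.ndarray] = {o: np.ones(m, dtype=np.int64)}
        values[o] += effects.sum()
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
            if c.any():
                copies[i] = c
                values[i] += float(c @ effects)
    return values


def simulate_mutation_drop(ped: Pedigree, cfg: DropConfig,
                           generations: Sequence[int] | None = None
                           ) -> VarianceSeries:
    """Expected between-line genetic variance trajectory g per unit V_M,
    from a single drop of ``cfg.n_mutations_total`` mutations."""
    rng = np.random.default_rng(cfg.seed)
    values = drop_genotypic_values(ped, cfg, rng)
    gens_wanted = _wanted_generations(ped, generations)
    g = _between_line_variance_by_generation(values, ped, gens_wanted)
    return VarianceSeries(gens_wanted, g=g)


def _wanted_generations(ped: Pedigree, generations) -> np.ndarray:
    if generations is not None:
        return np.asarray(generations, dtype=int)
    gens = ped.generations()
    lined = np.array([r.line_id is not None for r in ped.records])
    if not lined.any():
        raise ValueError("pedigree has no line assignments")
    return np.arange(int(gens[lined].min()), int(gens.max()) + 1)


def simulate_env_between_line(ped: Pedigree, cfg: DropConfig,
                              generations: Sequence[int] | None = None
                              ) -> VarianceSeries:
    """Expected between-line environmental variance trajectory per unit
    V_E: mean over ``cfg.n_env_replicates`` of the between-line variance of
    line means of iid standard-normal individual effects."""
    rng = np.random.default_rng(cfg.seed + 1)
    gens_wanted = _wanted_generations(ped, generations)
    acc = np.zeros(len(gens_wanted))
    for _ in range(cfg.n_env_replicates):
        e = rng.normal(size=len(ped))
        acc += _between_line_variance_by_generation(e, ped, gens_wanted)
    return VarianceSeries(gens_wanted, e_env=acc / cfg.n_env_replicates)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_h2m(series: VarianceSeries) -> H2MEstimate:
    """Minimise ||x g + y e - z||^2 via the 2x2 normal equations.

    Coefficients are unconstrained in sign; h2_M = x / y may be negative.
    """
    for name in ("z", "g", "e_env"):
        if getattr(series, name) is None:
            raise ValueError(f"series channel {name} not filled")
    G = np.column_stack([series.g, series.e_env])
    gram = G.T @ G
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            "g and e_env are collinear; normal equations singular")
    x, y = np.linalg.solve(gram, G.T @ series.z)
    return H2MEstimate(x_coef=float(x), y_coef=float(y), h2m=float(x / y))


def bootstrap_h2m(phenotypes: pd.DataFrame, ped: Pedigree, trait: str,
                  cfg: DropConfig, n_boot: int = 1000,
                  series: VarianceSeries | None = None,
                  sex_correction: str = "grand") -> H2MEstimate:
    """Point estimate with a percentile bootstrap CI over MA lines.

    Lines are resampled with replacement; z is recomputed and refitted per
    replicate while g and e_env are held fixed (they describe the pedigree
    design, not the phenotypes).  Returns the full-data estimate with the
    empirical 2.5/97.5 percentile bounds attached.
    """
    if series is None:
        zs = observed_between_line_variances(phenotypes, ped, trait,
                                             sex_correction)
        g = simulate_mutation_drop(ped, cfg, generations=zs.generations)
        e = simulate_env_between_line(ped, cfg, generations=zs.generations)
        series = zs.merged(g).merged(e)
    est = fit_h2m(series)

    # per-line, per-generation means of sex-corrected values
    df = phenotypes.dropna(subset=[trait]).copy()
    df["_corr"] = _sex_corrected(
        df[trait].to_numpy(), df["sex"].to_numpy(),
        per_generation=(sex_correction == "per_generation"),
        generation=df["generation"].to_numpy())
    lm = (df.groupby(["generation", "line"])["_corr"].mean()
            .unstack("line").reindex(series.generations))
    L = lm.shape[1]
    rng = np.random.default_rng(cfg.seed + 2)
    G = np.column_stack([series.g, series.e_env])
    vals = lm.to_numpy()   # (n_gen, L)
    h2ms = []
    for b in range(n_boot):
        take = rng.integers(0, L, size=L)
        sub = vals[:, take]
        n_fin = np.isfinite(sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = np.nanvar(sub, axis=1, ddof=1)
        ok = (n_fin >= 2) & np.isfinite(zb)
        if ok.sum() < 2:
            continue   # resample left too few informative generations
        Gk = G[ok]
        x, y = np.linalg.solve(Gk.T @ Gk, Gk.T @ zb[ok])
        h2ms.append(x / y)
    if not h2ms:
        raise RuntimeError("no bootstrap replicate had enough data")
    est.ci_low, est.ci_high = np.percentile(h2ms, [2.5, 97.5])
    return est
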