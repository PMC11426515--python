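"""Animal model with a mutational random effect, fitted by REML.

The mixed model for a trait vector y is

    y = X beta + Z1 u_litter + Z2 u_maternal + Za a + Zm m + e,

with fixed effects (sex, generation, litter size), two environmental random
effects shared by pups (the litter of rearing and the non-genetic effect of
the mother), a base-population additive effect a with covariance
A sigma^2_a, and a mutational effect m with covariance M sigma^2_m that
captures additive variance contributed by new mutations over the pedigree's
generations.  Variance components are estimated by restricted maximum
likelihood on the phenotypic covariance representation

    V = sum_i sigma^2_i B_i + sigma^2_e I,

where each B_i is the record-level covariance scaler of one random effect
(for a and m, the A and M submatrices over phenotyped individuals).
Updates use average-information steps with step-halving, falling back to EM
steps, so the restricted log-likelihood never decreases; components are
clamped at a small nonnegative floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from musema.relatedness import RelationshipMatrix

RANDOM_EFFECTS = ("litter", "maternal", "additive", "mutational")


@dataclass
class VarianceComponents:
    """REML variance-component estimates (trait units squared)."""

    v_litter: float
    v_maternal: float
    v_a: float
    v_m: float
    v_e: float
    logL: float
    n_iter: int = 0
    converged: bool = False
    fitted_effects: tuple[str, ...] = RANDOM_EFFECTS
    logL_path: list[float] = field(default_factory=list, repr=False)

    @property
    def total(self) -> float:
        return self.v_litter + self.v_maternal + self.v_a + self.v_m + self.v_e

    @property
    def h2m(self) -> float:
        return self.v_m / self.total


@dataclass
class EvolvabilityMetrics:
    """Mean- and variance-standardised measures of mutational input."""

    h2m: float
    cv_m: float
    cv_m_rescaled: float
    i_m: float
    dimension_divisor: float


_DIM_DIVISOR = {"volume": 3.0, "length": 2.0, "other": 1.0}


def evolvability_metrics(v_m: float, trait_mean: float, total_variance: float,
                         dimension: str = "other") -> EvolvabilityMetrics:
    """Mutational heritability, CV_M, rescaled CV_M and I_M.

    CV_M = sqrt(V_M)/mean; I_M = V_M/mean^2 = CV_M^2; the rescaled CV_M
    divides by 3 for volumes (weights), 2 for lengths, 1 otherwise, to
    correct for positive correlations among dimensions of multidimensional
    traits.
    """
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive")
    if total_variance <= 0:
        raise ValueError("total variance must be positive")
    div = _DIM_DIVISOR[dimension]
    cv = np.sqrt(v_m) / trait_mean
    return EvolvabilityMetrics(
        h2m=v_m / total_variance,
        cv_m=float(cv),
        cv_m_rescaled=float(cv / div),
        i_m=float(v_m / trait_mean**2),
        dimension_divisor=div,
    )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _fixed_design(data: pd.DataFrame, fixed_effects: Sequence[str],
                  generation_as: str) -> np.ndarray:
    cols = [np.ones(len(data))]
    for f in fixed_effects:
        if f not in data.columns:
            raise KeyError(f"fixed effect column {f!r} missing")
        v = data[f]
        if f == "generation" and generation_as == "linear":
            cols.append(v.to_numpy(dtype=float))
        elif f in ("sex", "generation") or v.dtype == object:
            d = pd.get_dummies(v, drop_first=True, dtype=float)
            cols.extend(d[c].to_numpy() for c in d.columns)
        else:
            cols.append(v.to_numpy(dtype=float))
    X = np.column_stack(cols)
    # drop aliased columns via pivoted QR
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep = piv[diag > 1e-8 * max(diag.max(), 1.0)]
    return X[:, np.sort(keep)]


def _grouping_structure(labels: pd.Series) -> np.ndarray:
    codes = pd.factorize(labels)[0]
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z @ Z.T


def _genetic_structure(data: pd.DataFrame, rel: RelationshipMatrix
                       ) -> np.ndarray:
    pos = {ind: i for i, ind in enumerate(rel.individual_ids)}
    try:
        idx = np.array([pos[i] for i in data["individual_id"]])
    except KeyError as e:
        raise KeyError(f"individual {e.args[0]!r} not indexed in the "
                       f"{rel.role} relationship matrix") from None
    return rel.values[np.ix_(idx, idx)]


def _build_structures(data: pd.DataFrame, A: RelationshipMatrix | None,
                      M: RelationshipMatrix | None,
                      model_spec: Sequence[str]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for eff in model_spec:
        if eff == "litter":
            out[eff] = _grouping_structure(data["litter_id"])
        elif eff == "maternal":
            out[eff] = _grouping_structure(data["mother_id"])
        elif eff == "additive":
            if A is None:
                raise ValueError("model includes 'additive' but A not given")
            out[eff] = _genetic_structure(data, A)
        elif eff == "mutational":
            if M is None:
                raise ValueError("model includes 'mutational' but M not given")
            out[eff] = _genetic_structure(data, M)
        else:
            raise ValueError(f"unknown random effect {eff!r}")
        w = linalg.eigvalsh(out[eff])
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise ValueError(f"covariance scaler for {eff!r} is not PSD")
    return out


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _restricted_loglik(theta: np.ndarray, Bs: list[np.ndarray],
                       X: np.ndarray, y: np.ndarray):
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, B in zip(theta[:-1], Bs):
        V += t * B
    c, low = linalg.cho_factor(V, check_finite=False)
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    XtViX = X.T @ Vi @ X
    sign, logdetX = np.linalg.slogdet(XtViX)
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    logL = -0.5 * (logdetV + logdetX + float(y @ Py))
    return logL, P, Py


def fit_reml(data: pd.DataFrame, A: RelationshipMatrix | None,
             M: RelationshipMatrix | None, trait: str,
             model_spec: Sequence[str] = RANDOM_EFFECTS,
             fixed_effects: Sequence[str] | None = None,
             generation_as: str = "categorical",
             max_iter: int = 2000, tol: float = 1e-6,
             verbose: bool = False) -> VarianceComponents:
    """REML fit of the animal model for one trait.

    ``data`` needs ``individual_id``, the trait column, the fixed-effect
    columns, and ``litter_id``/``mother_id`` for the corresponding random
    effects.  ``model_spec`` selects the fitted random effects (residual is
    always included).  When ``fixed_effects`` is None, morphometric-style
    defaults (sex, generation, litter_size) are used, restricted to the
    columns present.
    """
    df = data.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 records")
    if fixed_effects is None:
        fixed_effects = [f for f in ("sex", "generation", "litter_size")
                         if f in df.columns]
    X = _fixed_design(df, fixed_effects, generation_as)
    structures = _build_structures(df, A, M, model_spec)
    names = list(structures)
    Bs = [structures[k] for k in names]
    qs = [np.linalg.matrix_rank(B) if B.shape[0] < 200 else B.shape[0]
          for B in Bs]
    vy = float(np.var(y, ddof=1))
    floor = 1e-10 * vy

    k = len(Bs)
    theta = np.full(k + 1, vy / (k + 1))
    logL, P, Py = _restricted_loglik(theta, Bs, X, y)
    logL_path = [float(logL)]

    def em_step(theta, P, Py):
        new = theta.copy()
        for i, (B, q) in enumerate(zip(Bs, qs)):
            # tr(P B) = sum(P * B) for symmetric P, B
            grad = (B @ Py) @ Py - np.sum(P * B)
            new[i] = theta[i] + theta[i]**2 / q * grad
        new[-1] = theta[-1] + theta[-1]**2 / n * (Py @ Py - np.trace(P))
        return np.maximum(new, floor)

    def ai_step(theta, P, Py, lam):
        """Average-information step with Levenberg-Marquardt damping
        (lam -> 0: Newton-like; lam large: scaled gradient ascent)."""
        Bys = [B @ Py for B in Bs] + [Py]
        score = np.empty(k + 1)
        for i in range(k + 1):
            trPB = np.sum(P * Bs[i]) if i < k else np.trace(P)
            score[i] = -0.5 * (trPB - Bys[i] @ Py)
        AI = np.empty((k + 1, k + 1))
        PBys = [P @ By for By in Bys]
        for i in range(k + 1):
            for j in range(i, k + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(Bys[i] @ PBys[j])
        damp = lam * np.maximum(np.diag(AI), 1e-12)
        try:
            delta = np.linalg.solve(AI + np.diag(damp), score)
        except np.linalg.LinAlgError:
            return None
        return np.maximum(theta + delta, floor)

    n_iter = 0
    converged = False
    n_flat = 0
    lam = 1e-6
    for n_iter in range(1, max_iter + 1):
        accepted = False
        if n_iter > 2:
            # damped AI with adaptive lambda: reject -> raise damping
            for _ in range(8):
                cand = ai_step(theta, P, Py, lam)
                if cand is None:
                    lam = min(lam * 10, 1e8)
                    continue
                try:
                    cl, cP, cPy = _restricted_loglik(cand, Bs, X, y)
                except linalg.LinAlgError:
                    lam = min(lam * 10, 1e8)
                    continue
                if cl >= logL - 1e-10:
                    accepted = True
                    lam = max(lam / 3, 1e-8)
                    break
                lam = min(lam * 10, 1e8)
        if not accepted:
            cand = em_step(theta, P, Py)
            for _ in range(12):  # step-halving toward the current point
                try:
                    cl, cP, cPy = _restricted_loglik(cand, Bs, X, y)
                except linalg.LinAlgError:
                    cand = 0.5 * (cand + theta)
                    continue
                if cl >= logL - 1e-10:
                    accepted = True
                    break
                cand = 0.5 * (cand + theta)
        if accepted:
            rel = np.max(np.abs(cand - theta) / np.maximum(theta, 1e-3 * vy))
            n_flat = n_flat + 1 if cl - logL < 1e-10 * (1 + abs(cl)) else 0
            theta, logL, P, Py = cand, cl, cP, cPy
            logL_path.append(float(logL))
            if rel < tol or n_flat >= 3:
                converged = True
        if verbose:
            print(f"iter {n_iter}: logL={logL:.6f} lam={lam:.1e} "
                  f"theta={theta}")
        if converged or not accepted:
            converged = converged or not accepted
            break

    comp = dict.fromkeys(RANDOM_EFFECTS, 0.0)
    for nm, t in zip(names, theta[:-1]):
        comp[nm] = float(t)
    return VarianceComponents(
        v_litter=comp["litter"], v_maternal=comp["maternal"],
        v_a=comp["additive"], v_m=comp["mutational"], v_e=float(theta[-1]),
        logL=float(logL), n_iter=n_iter, converged=converged,
        fitted_effects=tuple(names), logL_path=logL_path,
    )


def model_compare(data: pd.DataFrame, A: RelationshipMatrix | None,
                  M: RelationshipMatrix | None, trait: str,
                  model_spec: Sequence[str] = RANDOM_EFFECTS,
                  **fit_kwargs) -> pd.DataFrame:
    """Restricted log-likelihoods for the full model and each model with
    one random effect removed.  The full model is flagged best when its
    logL is highest."""
    rows = []
    full = fit_reml(data, A, M, trait, model_spec, **fit_kwargs)
    rows.append({"model": "full", "dropped": None, "logL": full.logL,
                 "converged": full.converged})
    for eff in model_spec:
        spec = tuple(e for e in model_spec if e != eff)
        try:
            sub = fit_reml(data, A, M, trait, spec, **fit_kwargs)
            rows.append({"model": f"-{eff}", "dropped": eff,
                         "logL": sub.logL, "converged": sub.converged})
        except Exception as err:  # propagate per-sub-model failures as rows
            rows.append({"model": f"-{eff}", "dropped": eff,
                         "logL": np.nan, "converged": False,
                         "error": str(err)})
    out = pd.DataFrame(rows)
    out["full_is_best"] = out.loc[0, "logL"] >= out["logL"].max() - 1e-9
    return out


def bootstrap_components(data: pd.DataFrame, A: RelationshipMatrix | None,
                         M: RelationshipMatrix | None, trait: str,
                         n_boot: int = 1000, seed: int = 0,
                         trait_mean: float | None = None,
                         dimension: str = "other",
                         model_spec: Sequence[str] = RANDOM_EFFECTS,
                         **fit_kwargs) -> dict:
    """Percentile bootstrap over MA lines for h2_M and CV_M.

    Lines are resampled with replacement; litter and mother groupings are
    relabelled per resampled copy (two copies of a line are independent
    environmental replicates) while genetic structures follow the shared
    pedigree entries.  Failed replicate fits are skipped and counted.
    """
    if "line" not in data.columns:
        raise KeyError("bootstrap over lines needs a 'line' column")
    lines = data["line"].dropna().unique()
    rng = np.random.default_rng(seed)
    if trait_mean is None:
        trait_mean = float(data[trait].mean())
    h2ms, cvms = [], []
    n_failed = 0
    for _ in range(n_boot):
        take = rng.choice(lines, size=len(lines), replace=True)
        parts = []
        for copy, ln in enumerate(take):
            sub = data[data["line"] == ln].copy()
            for col in ("litter_id", "mother_id"):
                if col in sub.columns:
                    sub[col] = sub[col].astype(str) + f"#b{copy}"
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_reml(boot, A, M, trait, model_spec, **fit_kwargs)
        except Exception:
            n_failed += 1
            continue
        h2ms.append(fit.h2m)
        cvms.append(np.sqrt(fit.v_m) / trait_mean)
    if not h2ms:
        raise RuntimeError("all bootstrap replicates failed")
    lo_h, hi_h = np.percentile(h2ms, [2.5, 97.5])
    lo_c, hi_c = np.percentile(cvms, [2.5, 97.5])
    return {
        "h2m_ci": (float(lo_h), float(hi_h)),
        "cv_m_ci": (float(lo_c), float(hi_c)),
        "n_failed": n_failed,
        "n_used": len(h2ms),
        "h2m_samples": np.array(h2ms),
    }
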