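"""Pedigree data model, I/O, validation and inbreeding.

A :class:`Pedigree` is an ordered list of individual records in topological
order (parents precede offspring).  Founders have neither parent; every
non-founder has both.  Generation indices follow the MA-experiment
convention: the experimental founder pair is generation 0, burn-in
generations (full-sib matings preceding the founders, with no trait data)
are negative, and descendants count upward.

Missing parents are encoded in delimited files as an empty field or ``"0"``;
``"0"`` is never a legal individual id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "": UNKNOWN, "u": UNKNOWN, "unknown": UNKNOWN, "na": UNKNOWN, "0": UNKNOWN,
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicate ids, dangling
    parents, cycles, sex inconsistencies)."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    Parents are both present or both absent (founder).  ``generation`` may
    be negative for burn-in individuals; ``line_id`` is absent for burn-in
    and expansion-phase individuals.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN
    line_id: str | None = None
    generation: int | None = None
    birth_date: date | None = None

    def __post_init__(self) -> None:
        if (self.sire_id is None) != (self.dam_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: sire and dam must both be present "
                f"or both absent (got sire={self.sire_id!r}, dam={self.dam_id!r})"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise PedigreeError(f"individual {self.id!r}: bad sex {self.sex!r}")

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None


@dataclass
class Pedigree:
    """Ordered, validated pedigree.

    ``burnin_depth`` records how many generations of full-sib burn-in
    matings precede the experimental founder pair (their records are part
    of ``records``, at negative generation indices).
    """

    records: list[IndividualRecord]
    burnin_depth: int = 0
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, ind_id: str) -> IndividualRecord:
        return self.records[self._index[ind_id]]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def position(self, ind_id: str) -> int:
        return self._index[ind_id]

    def founders(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.is_founder]

    def generations(self) -> np.ndarray:
        return np.array([r.generation for r in self.records], dtype=int)

    @property
    def max_generation(self) -> int:
        return int(self.generations().max())

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {r.id: [] for r in self.records}
        for r in self.records:
            if r.sire_id is not None:
                out[r.sire_id].append(r.id)
                out[r.dam_id].append(r.id)
        return out

    def parent_positions(self) -> np.ndarray:
        """(n, 2) array of sire/dam row positions, -1 for founders."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire_id is not None:
                out[i, 0] = self._index[r.sire_id]
                out[i, 1] = self._index[r.dam_id]
        return out

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in index:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            if rec.id == "0":
                raise PedigreeError('"0" is reserved for missing parents')
            for role, pid in (("sire", rec.sire_id), ("dam", rec.dam_id)):
                if pid is None:
                    continue
                if pid not in index:
                    raise PedigreeError(
                        f"individual {rec.id!r}: {role} {pid!r} not defined "
                        "earlier in the pedigree (dangling reference or cycle)"
                    )
                parent = self.records[index[pid]]
                want = MALE if role == "sire" else FEMALE
                if parent.sex not in (want, UNKNOWN):
                    raise PedigreeError(
                        f"individual {rec.id!r}: {role} {pid!r} has sex "
                        f"{parent.sex!r}"
                    )
            index[rec.id] = i
        self._index = index

    def infer_generations(self) -> "Pedigree":
        """Fill missing generation indices as 1 + max(parent generations);
        founders with no stated generation get 0."""
        gen: dict[str, int] = {}
        new = []
        for rec in self.records:
            if rec.generation is not None:
                g = rec.generation
            elif rec.is_founder:
                g = 0
            else:
                g = 1 + max(gen[rec.sire_id], gen[rec.dam_id])
            gen[rec.id] = g
            new.append(replace(rec, generation=g))
        return Pedigree(new, burnin_depth=self.burnin_depth)

    # -- subsetting ---------------------------------------------------------
    def ancestor_closure(self, ind_ids: Iterable[str]) -> "Pedigree":
        """Subset pedigree to ``ind_ids`` plus all their ancestors."""
        keep = set()
        stack = list(ind_ids)
        while stack:
            i = stack.pop()
            if i in keep:
                continue
            keep.add(i)
            rec = self[i]
            if rec.sire_id is not None:
                stack.extend((rec.sire_id, rec.dam_id))
        recs = [r for r in self.records if r.id in keep]
        return Pedigree(recs, burnin_depth=self.burnin_depth)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_DIALECT = {
    "id": "id", "sire": "sire", "dam": "dam", "sex": "sex",
    "line": "line", "generation": "generation", "birth_date": "birth_date",
}


def _parse_parent(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "0", "nan", "NA"):
        return None
    return s


def read_pedigree(source, dialect: Mapping[str, str] | None = None,
                  burnin_depth: int = 0) -> Pedigree:
    """Read a pedigree from a delimited text file (CSV or TSV).

    ``dialect`` maps the canonical column roles (``id``, ``sire``, ``dam``,
    optionally ``sex``, ``line``, ``generation``, ``birth_date``) onto the
    file's column names.  Missing parents may be empty or ``"0"``.
    Generation indices absent from the file are inferred as
    1 + max(parent generations), founders at 0.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    for role in ("id", "sire", "dam"):
        if cols[role] not in df.columns:
            raise PedigreeError(f"missing required column {cols[role]!r}")

    records = []
    for _, row in df.iterrows():
        sex = _SEX_ALIASES.get(str(row.get(cols["sex"], "")).strip().lower())
        if sex is None:
            raise PedigreeError(f"unrecognised sex value {row[cols['sex']]!r}")
        gen_raw = str(row.get(cols["generation"], "")).strip()
        bd_raw = str(row.get(cols["birth_date"], "")).strip()
        line_raw = str(row.get(cols["line"], "")).strip()
        records.append(IndividualRecord(
            id=str(row[cols["id"]]).strip(),
            sire_id=_parse_parent(row[cols["sire"]]),
            dam_id=_parse_parent(row[cols["dam"]]),
            sex=sex,
            line_id=line_raw or None,
            generation=int(gen_raw) if gen_raw else None,
            birth_date=date.fromisoformat(bd_raw) if bd_raw else None,
        ))
    ped = Pedigree(records, burnin_depth=burnin_depth)
    if any(r.generation is None for r in records):
        ped = ped.infer_generations()
    return ped


def write_pedigree(ped: Pedigree, target) -> None:
    """Write a pedigree as header-bearing CSV (ISO-8601 birth dates,
    empty field for missing parents)."""
    rows = []
    for r in ped.records:
        rows.append({
            "id": r.id,
            "sire": r.sire_id or "",
            "dam": r.dam_id or "",
            "sex": r.sex,
            "line": r.line_id or "",
            "generation": "" if r.generation is None else r.generation,
            "birth_date": r.birth_date.isoformat() if r.birth_date else "",
        })
    pd.DataFrame(rows).to_csv(target, index=False)


def pedigree_roundtrip_equal(a: Pedigree, b: Pedigree) -> bool:
    return a.records == b.records and a.burnin_depth == b.burnin_depth


# ---------------------------------------------------------------------------
# Burn-in extension
# ---------------------------------------------------------------------------

def prepend_burnin(ped: Pedigree, n_gen: int) -> Pedigree:
    """Prepend ``n_gen`` generations of full-sib matings ahead of the
    founder pair.

    The experimental founders must be exactly one male-female pair; they
    keep their ids and generation indices but gain parents from the burn-in
    chain (generations -1 down to -(burnin_depth + n_gen)).  Burn-in
    individuals carry no line or birth date.
    """
    if n_gen == 0:
        return ped
    if n_gen < 0:
        raise ValueError("n_gen must be >= 0")
    founders = ped.founders()
    if len(founders) != 2:
        raise PedigreeError(
            f"burn-in requires exactly one founder pair, got {len(founders)}"
        )
    sexes = {f.sex for f in founders}
    if sexes != {MALE, FEMALE}:
        raise PedigreeError("founder pair must be one male and one female")

    base = -ped.burnin_depth          # generation of current earliest pair
    chain: list[IndividualRecord] = []
    prev_m = prev_f = None
    for g in range(base - n_gen, base):
        sire, dam = (prev_m, prev_f) if prev_m else (None, None)
        m = IndividualRecord(id=f"burnin_g{g}_m", sire_id=sire, dam_id=dam,
                             sex=MALE, generation=g)
        f = IndividualRecord(id=f"burnin_g{g}_f", sire_id=sire, dam_id=dam,
                             sex=FEMALE, generation=g)
        chain.extend([m, f])
        prev_m, prev_f = m.id, f.id

    new_records = list(chain)
    for rec in ped.records:
        if rec.is_founder:
            rec = replace(rec, sire_id=prev_m, dam_id=prev_f)
        new_records.append(rec)
    return Pedigree(new_records, burnin_depth=ped.burnin_depth + n_gen)


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship (coancestry) matrix by the tabular method: f_ii = (1+F_i)/2,
    f_ij = (f_{i,sire_j} + f_{i,dam_j})/2."""
    n = len(ped)
    parents = ped.parent_positions()
    K = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        if s < 0:
            K[i, i] = 0.5
        else:
            K[i, :i] = 0.5 * (K[s, :i] + K[d, :i])
            K[:i, i] = K[i, :i]
            K[i, i] = 0.5 * (1.0 + K[s, d])
    return K


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficient F.

    F is the kinship of the individual's parents; founders have F = 0.
    """
    K = kinship_matrix(ped)
    F = 2.0 * np.diag(K) - 1.0
    return pd.Series(F, index=ped.ids, name="F")


def fullsib_inbreeding(n_gen: int) -> float:
    """F after ``n_gen`` generations of repeated full-sib mating, from the
    recursion F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4."""
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(n_gen):
        f_prev2, f_prev1 = f_prev1, 0.25 * (1.0 + 2.0 * f_prev1 + f_prev2)
    return f_prev1
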