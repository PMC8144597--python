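"""Studbook pedigrees: reading, validation, kinship, inbreeding, generations.

A studbook is the registry of a managed captive population: one row per
individual with parentage, sex, dates, birth region, wild/captive origin and
a hybrid flag.  All derived genetic quantities follow the conventions of
pedigree-based captive management:

* wild-born founders are assumed unrelated and non-inbred (f = 0),
* an unknown parent is treated as a unique, unrelated wild founder
  ("set unknown parents to wild"),
* generations in captivity G are 0 for wild-born animals and the parental
  mean plus one for captive-born animals (so G may be non-integer),
* an individual's inbreeding coefficient equals the kinship of its parents.

Dates are ISO-8601 calendar dates and every age or duration is an integer
number of days.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "PedigreeMetrics",
    "StudbookError",
    "Violation",
    "read_studbook",
    "write_studbook",
    "validate_pedigree",
    "kinship",
    "kinship_matrix",
    "write_kinship_matrix",
    "inbreeding",
    "generation",
    "effective_size",
    "gene_drop_kinship",
    "compute_metrics",
]

#: required columns of the studbook CSV dialect (see README)
STUDBOOK_COLUMNS = (
    "id",
    "sire",
    "dam",
    "sex",
    "birth_date",
    "death_date",
    "birth_program",
    "origin",
    "hybrid",
    "species",
)

_UNKNOWN_TOKENS = {"", "unknown", "unk", "wild", "na", "nan", "none"}
_SEXES = {"female", "male", "unknown"}
_ORIGINS = {"wild", "captive"}


class StudbookError(ValueError):
    """Raised for malformed studbook input (bad rows, dangling ids, cycles)."""


@dataclass
class IndividualRecord:
    """One studbook row.

    ``sire_id``/``dam_id`` are ``None`` when the parent is unknown;
    ``death_date`` is ``None`` while the animal is alive; ``release_date``
    (optional column) records release to the wild, used by the exclusion
    filters.
    """

    id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: str
    birth_date: date
    death_date: Optional[date]
    birth_program: str
    origin: str
    hybrid: bool
    species: str
    release_date: Optional[date] = None

    @property
    def alive(self) -> bool:
        return self.death_date is None

    def age_at_death_days(self) -> Optional[int]:
        if self.death_date is None:
            return None
        return (self.death_date - self.birth_date).days


class Pedigree:
    """A validated collection of :class:`IndividualRecord` linked by parentage.

    Parameters
    ----------
    records
        Individual records; ids must be unique.
    wild_ancestry
        ``"truncate"`` (default) treats every wild-born individual as a
        pedigree founder for kinship/inbreeding/generation purposes even if
        parents are recorded; ``"keep"`` follows recorded parents of
        wild-born animals too.
    """

    def __init__(self, records: Iterable[IndividualRecord],
                 wild_ancestry: str = "truncate"):
        if wild_ancestry not in ("truncate", "keep"):
            raise ValueError("wild_ancestry must be 'truncate' or 'keep'")
        self.wild_ancestry = wild_ancestry
        self.records: dict[str, IndividualRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise StudbookError(f"duplicate individual id {rec.id!r}")
            self.records[rec.id] = rec
        self._kinship_memo: dict[tuple[str, str], float] = {}
        self._depth: Optional[dict[str, int]] = None
        self._generation: dict[str, float] = {}

    # -- basic container behaviour -------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self.records

    def __getitem__(self, iid: str) -> IndividualRecord:
        try:
            return self.records[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    @property
    def current_date(self) -> date:
        """Latest birth or death date in the studbook."""
        dates = [r.birth_date for r in self.records.values()]
        dates += [r.death_date for r in self.records.values()
                  if r.death_date is not None]
        if not dates:
            raise ValueError("empty pedigree has no current date")
        return max(dates)

    # -- ancestry -------------------------------------------------------
    def is_ancestry_founder(self, iid: str) -> bool:
        """True if ``iid`` contributes no pedigree paths through parents."""
        rec = self[iid]
        if self.wild_ancestry == "truncate" and rec.origin == "wild":
            return True
        return rec.sire_id is None and rec.dam_id is None

    def parents(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        """Effective (sire, dam) for ancestry traversal (founders -> none)."""
        rec = self[iid]
        if self.wild_ancestry == "truncate" and rec.origin == "wild":
            return (None, None)
        return (rec.sire_id, rec.dam_id)

    def _depths(self) -> dict[str, int]:
        # longest ancestor-chain length; also detects cycles
        if self._depth is not None:
            return self._depth
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 1 = on stack, 2 = done
        for start in self.records:
            if start in depth:
                continue
            stack = [start]
            while stack:
                iid = stack[-1]
                if state.get(iid) == 2:
                    stack.pop()
                    continue
                parents = [p for p in self.parents(iid)
                           if p is not None and p in self.records]
                pending = []
                for p in parents:
                    if state.get(p) == 1:
                        raise StudbookError(
                            f"pedigree cycle involving {iid!r} and {p!r}")
                    if state.get(p) != 2:
                        pending.append(p)
                if pending:
                    state[iid] = 1
                    stack.extend(pending)
                else:
                    depth[iid] = 1 + max(
                        (depth[p] for p in parents), default=-1)
                    state[iid] = 2
                    stack.pop()
        self._depth = depth
        return depth

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-offspring."""
        depth = self._depths()
        return sorted(self.records, key=lambda i: (depth[i], i))


@dataclass
class Violation:
    """A single pedigree-invariant violation (returned, never raised)."""

    rule: str
    ids: tuple[str, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message}"


@dataclass
class PedigreeMetrics:
    """Per-individual derived quantities for one pedigree."""

    f: dict[str, float]
    generation: dict[str, float]
    ne: Optional[float] = None
    kinship: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_date(text: str, row: int, column: str) -> Optional[date]:
    text = text.strip()
    if text == "" or text.lower() in ("alive", "none", "na"):
        return None
    try:
        return date.fromisoformat(text)
    except ValueError:
        raise StudbookError(
            f"row {row}: unparseable {column} {text!r} (expected YYYY-MM-DD)")


def _parse_parent(text: str) -> Optional[str]:
    t = text.strip()
    return None if t.lower() in _UNKNOWN_TOKENS else t


def read_studbook(path, species_label: Optional[str] = None,
                  wild_ancestry: str = "truncate") -> Pedigree:
    """Read a studbook CSV (dialect documented in the README).

    Parameters
    ----------
    path
        CSV file with columns ``id, sire, dam, sex, birth_date, death_date,
        birth_program, origin, hybrid, species`` (optional
        ``release_date``).  UNKNOWN or empty marks a missing parent.
    species_label
        If given, overrides / fills the species column for every record
        (single-species studbooks often omit it).

    Raises
    ------
    StudbookError
        On a missing required column, duplicate id, unparseable date,
        death before birth, or a parent id that resolves to no record.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [c for c in STUDBOOK_COLUMNS if c != "species"]
        missing = [c for c in required if c not in header]
        if species_label is None and "species" not in header:
            missing.append("species")
        if missing:
            raise StudbookError(
                f"missing required column(s): {', '.join(sorted(missing))}")
        has_release = "release_date" in header
        records = []
        for row_no, row in enumerate(reader, start=2):
            iid = row["id"].strip()
            if not iid:
                raise StudbookError(f"row {row_no}: empty id")
            birth = _parse_date(row["birth_date"], row_no, "birth_date")
            if birth is None:
                raise StudbookError(f"row {row_no}: missing birth_date")
            death = _parse_date(row["death_date"], row_no, "death_date")
            if death is not None and death < birth:
                raise StudbookError(
                    f"row {row_no}: death_date {death} precedes "
                    f"birth_date {birth} for id {iid!r}")
            sex = row["sex"].strip().lower() or "unknown"
            if sex not in _SEXES:
                raise StudbookError(f"row {row_no}: invalid sex {sex!r}")
            origin = row["origin"].strip().lower()
            if origin not in _ORIGINS:
                raise StudbookError(
                    f"row {row_no}: invalid origin {origin!r}")
            species = (species_label if species_label is not None
                       else row["species"].strip())
            records.append(IndividualRecord(
                id=iid,
                sire_id=_parse_parent(row["sire"]),
                dam_id=_parse_parent(row["dam"]),
                sex=sex,
                birth_date=birth,
                death_date=death,
                birth_program=row["birth_program"].strip() or "unknown",
                origin=origin,
                hybrid=row["hybrid"].strip().lower() in ("1", "true", "yes"),
                species=species,
                release_date=(_parse_date(row["release_date"], row_no,
                                          "release_date")
                              if has_release else None),
            ))
    ped = Pedigree(records, wild_ancestry=wild_ancestry)
    # referential integrity is a hard error at read time
    for rec in ped.records.values():
        for role, pid in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if pid is not None and pid not in ped.records:
                raise StudbookError(
                    f"{role} id {pid!r} of {rec.id!r} not in studbook")
    ped._depths()  # raises on cycles
    return ped


def write_studbook(ped: Pedigree, path) -> None:
    """Write a pedigree back out in the studbook CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STUDBOOK_COLUMNS + ("release_date",))
        for iid in ped.topological_order():
            r = ped[iid]
            writer.writerow([
                r.id,
                r.sire_id or "UNKNOWN",
                r.dam_id or "UNKNOWN",
                r.sex,
                r.birth_date.isoformat(),
                r.death_date.isoformat() if r.death_date else "",
                r.birth_program,
                r.origin,
                "1" if r.hybrid else "0",
                r.species,
                r.release_date.isoformat() if r.release_date else "",
            ])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check all pedigree invariants; returns violations instead of raising."""
    out: list[Violation] = []
    for rec in ped.records.values():
        for role, pid in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if pid is not None and pid not in ped.records:
                out.append(Violation(
                    "dangling_parent", (rec.id, pid),
                    f"{role} {pid!r} of {rec.id!r} has no record"))
        if rec.death_date is not None and rec.death_date < rec.birth_date:
            out.append(Violation(
                "death_before_birth", (rec.id,),
                f"{rec.id!r} dies {rec.death_date} before birth "
                f"{rec.birth_date}"))
    # chronology: a parent must be born before each offspring
    for rec in ped.records.values():
        for pid in (rec.sire_id, rec.dam_id):
            if pid is not None and pid in ped.records:
                if ped.records[pid].birth_date >= rec.birth_date:
                    out.append(Violation(
                        "parent_born_after_child", (pid, rec.id),
                        f"parent {pid!r} born {ped.records[pid].birth_date} "
                        f"not before offspring {rec.id!r} born "
                        f"{rec.birth_date}"))
    try:
        ped._depths()
    except StudbookError as exc:
        # re-derive the offending pair from the message is brittle; scan
        out.append(Violation("cycle", _cycle_members(ped), str(exc)))
    return out


def _cycle_members(ped: Pedigree) -> tuple[str, ...]:
    # individuals that are their own ancestor
    members = []
    for iid in ped.records:
        seen = set()
        stack = [p for p in ped.parents(iid) if p is not None]
        while stack:
            cur = stack.pop()
            if cur == iid:
                members.append(iid)
                break
            if cur in seen or cur not in ped.records:
                continue
            seen.add(cur)
            stack.extend(p for p in ped.parents(cur) if p is not None)
    return tuple(sorted(members))


# ---------------------------------------------------------------------------
# kinship / inbreeding / generations
# ---------------------------------------------------------------------------

def kinship(ped: Pedigree, i: str, j: str) -> float:
    """Kinship coefficient between individuals ``i`` and ``j``.

    Probability that two alleles, one drawn at random from each individual,
    are identical by descent, under the founder conventions above.  Memoized
    recursion over the pedigree; ``kinship(i, i) = (1 + f(i)) / 2``.
    """
    if i not in ped.records:
        raise KeyError(f"unknown individual id {i!r}")
    if j not in ped.records:
        raise KeyError(f"unknown individual id {j!r}")
    return _kinship(ped, i, j)


def _kinship(ped: Pedigree, i: str, j: str) -> float:
    key = (i, j) if i <= j else (j, i)
    memo = ped._kinship_memo
    if key in memo:
        return memo[key]
    depth = ped._depths()
    if i == j:
        sire, dam = ped.parents(i)
        if sire is None or dam is None:
            val = 0.5
        else:
            val = 0.5 * (1.0 + _kinship(ped, sire, dam))
    else:
        # recurse through the parents of the deeper individual; this never
        # descends into the other's descendants, so it terminates and is
        # exact (Karigl-style recurrence)
        if depth[i] < depth[j]:
            i, j = j, i
        sire, dam = ped.parents(i)
        val = 0.0
        if sire is not None:
            val += 0.5 * _kinship(ped, sire, j)
        if dam is not None:
            val += 0.5 * _kinship(ped, dam, j)
    memo[key] = val
    return val


def inbreeding(ped: Pedigree, i: str) -> float:
    """Inbreeding coefficient f(i) = kinship of i's parents.

    Founders (wild-born, or either parent unknown) have f = 0: an unknown
    parent is a unique unrelated wild founder, so every pedigree path
    through it contributes nothing.
    """
    sire, dam = ped.parents(i) if i in ped.records else (None, None)
    if i not in ped.records:
        raise KeyError(f"unknown individual id {i!r}")
    if sire is None or dam is None:
        return 0.0
    return _kinship(ped, sire, dam)


def generation(ped: Pedigree, i: str) -> float:
    """Generations in captivity: 0 for wild-born, parental mean + 1 otherwise.

    An unknown parent counts as G0 (set-unknown-parents-to-wild), so the
    value can be non-integer, e.g. a G0 x G1 pairing gives (0 + 1)/2 + 1
    = 1.5.
    """
    if i not in ped.records:
        raise KeyError(f"unknown individual id {i!r}")
    if i in ped._generation:
        return ped._generation[i]
    # iterative DP in topological order restricted to ancestors of i
    order = []
    seen = set()
    stack = [i]
    while stack:
        cur = stack.pop()
        if cur in seen or cur in ped._generation:
            continue
        seen.add(cur)
        order.append(cur)
        for p in ped.parents(cur):
            if p is not None:
                stack.append(p)
    depth = ped._depths()
    for cur in sorted(order, key=lambda x: depth[x]):
        rec = ped[cur]
        if rec.origin == "wild":
            g = 0.0
        else:
            sire, dam = ped.parents(cur)
            gs = ped._generation[sire] if sire is not None else 0.0
            gd = ped._generation[dam] if dam is not None else 0.0
            g = 0.5 * (gs + gd) + 1.0
        ped._generation[cur] = g
    return ped._generation[i]


def effective_size(ped: Pedigree) -> float:
    """Wright's unequal-sex-ratio effective population size.

    ``Ne = 4 Nm Nf / (Nm + Nf)`` over distinct breeding males (individuals
    appearing as a sire) and breeding females (appearing as a dam).
    """
    sires = {r.sire_id for r in ped.records.values() if r.sire_id is not None}
    dams = {r.dam_id for r in ped.records.values() if r.dam_id is not None}
    nm, nf = len(sires), len(dams)
    if nm == 0 or nf == 0:
        raise ValueError(
            f"need breeders of both sexes (breeding males={nm}, "
            f"breeding females={nf})")
    return 4.0 * nm * nf / (nm + nf)


def kinship_matrix(ped: Pedigree, ids: Optional[list[str]] = None):
    """Full kinship matrix over ``ids`` (default: every individual).

    Returns ``(ids, matrix)`` with ``matrix[a, b] = kinship(ids[a], ids[b])``.
    """
    if ids is None:
        ids = ped.topological_order()
    n = len(ids)
    mat = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            mat[a, b] = mat[b, a] = _kinship(ped, ids[a], ids[b])
    return ids, mat


def write_kinship_matrix(ped: Pedigree, path,
                         ids: Optional[list[str]] = None) -> None:
    """Write the kinship matrix in long format (id_i, id_j, kinship)."""
    ids, mat = kinship_matrix(ped, ids)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_i", "id_j", "kinship"])
        for a, ia in enumerate(ids):
            for b in range(a, len(ids)):
                writer.writerow([ia, ids[b], repr(mat[a, b])])


def compute_metrics(ped: Pedigree, ne: bool = True) -> PedigreeMetrics:
    """Inbreeding and captive generation for every individual (+ Ne)."""
    f = {i: inbreeding(ped, i) for i in ped.topological_order()}
    g = {i: generation(ped, i) for i in ped.records}
    ne_val = None
    if ne:
        try:
            ne_val = effective_size(ped)
        except ValueError:
            ne_val = None
    return PedigreeMetrics(f=f, generation=g, ne=ne_val)


# ---------------------------------------------------------------------------
# gene dropping (Monte Carlo oracle)
# ---------------------------------------------------------------------------

def gene_drop_kinship(ped: Pedigree, i: str, j: str, replicates: int = 100_000,
                      seed: int = 0) -> tuple[float, float]:
    """Monte Carlo kinship by gene dropping.

    Each founder receives two globally distinct alleles; alleles are
    transmitted Mendelianly down the pedigree.  Per replicate one random
    allele is drawn from each of ``i`` and ``j``; the estimate is the
    proportion of replicates in which the two draws are identical by
    descent, with its binomial standard error.  Unknown parents contribute
    fresh founder alleles.  Deterministic under ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if i not in ped.records:
        raise KeyError(f"unknown individual id {i!r}")
    if j not in ped.records:
        raise KeyError(f"unknown individual id {j!r}")
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    hits = 0
    chunk = 20_000
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        next_allele = 0
        for iid in order:
            sire, dam = ped.parents(iid)
            out = []
            for parent in (sire, dam):
                if parent is None:
                    # fresh phantom-founder allele pair; pick one of the two
                    a = np.full(m, next_allele, dtype=np.int64)
                    b = np.full(m, next_allele + 1, dtype=np.int64)
                    next_allele += 2
                    pick = rng.integers(0, 2, size=m)
                    out.append(np.where(pick == 0, a, b))
                else:
                    pa, pb = alleles[parent]
                    pick = rng.integers(0, 2, size=m)
                    out.append(np.where(pick == 0, pa, pb))
            alleles[iid] = (out[0], out[1])
        ia = np.where(rng.integers(0, 2, size=m) == 0, *alleles[i])
        ja = np.where(rng.integers(0, 2, size=m) == 0, *alleles[j])
        hits += int(np.count_nonzero(ia == ja))
        done += m
    est = hits / replicates
    se = float(np.sqrt(est * (1.0 - est) / replicates))
    return est, se
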