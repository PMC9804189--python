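"""Pedigree parsing, cleaning, and analysis for closed dog-breed populations.

The central object is :class:`Pedigree`, an acyclic parent-link graph over
:class:`PedigreeRecord` entries.  On top of it this module computes

* Wright/Malecot kinship (coancestry) and the pedigree inbreeding
  coefficient F_ped (kinship of an individual's parents),
* pedigree completeness: complete generation equivalents (CGE) and
  per-generation proportions of known ancestors,
* breed-demography summaries: popular sires, yearly top-sire contribution,
  generation interval, litter sizes, and the fraction of pups that breed.

Raw breed-club pedigrees contain typos (five-digit birth years, parents
born after their offspring, parentage loops); :func:`clean_pedigree`
repairs them deterministically and reports every mutation it makes.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN_SEX = "unknown"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "": UNKNOWN_SEX, "u": UNKNOWN_SEX, "unknown": UNKNOWN_SEX, "0": UNKNOWN_SEX,
}


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identifier, parent links, sex, birth information, country.

    ``sire_id``/``dam_id`` are ``None`` when unknown; ``birth_year`` is an
    integer year or ``None``; ``birth_date`` a :class:`datetime.date` or
    ``None``.  ``phantom`` marks records auto-created for parents that were
    referenced but never declared.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN_SEX
    birth_year: int | None = None
    birth_date: _dt.date | None = None
    country: str | None = None
    phantom: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")


@dataclass
class CleaningReport:
    """What :func:`clean_pedigree` changed."""

    n_year_reset: int = 0
    n_dob_reset: int = 0
    removed_links: list[tuple[str, str]] = field(default_factory=list)
    n_phantom_created: int = 0


class Pedigree:
    """Acyclic parent-link graph keyed by animal id.

    Construct via :func:`clean_pedigree` (recommended) or directly from
    records whose parent references are already consistent and acyclic.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self._records: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate id {rec.id!r}")
            self._records[rec.id] = rec
        for rec in self._records.values():
            if rec.sire_id == rec.id or rec.dam_id == rec.id:
                raise ValueError(f"record {rec.id!r} is its own parent")
            for pid in (rec.sire_id, rec.dam_id):
                if pid is not None and pid not in self._records:
                    raise ValueError(
                        f"record {rec.id!r} references missing parent {pid!r}"
                    )
        self._generation: dict[str, int] = {}
        self._compute_generations()
        self._kinship_cache: dict[frozenset, float] = {}

    # -- basic access ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._records

    def __iter__(self):
        return iter(self._records.values())

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def record(self, id_: str) -> PedigreeRecord:
        try:
            return self._records[id_]
        except KeyError:
            raise KeyError(f"unknown id {id_!r}") from None

    def parents(self, id_: str) -> tuple[str | None, str | None]:
        rec = self.record(id_)
        return rec.sire_id, rec.dam_id

    def _compute_generations(self) -> None:
        """Longest path from a founder; also detects cycles (hard error)."""
        state: dict[str, int] = {}  # 0 in-progress, 1 done
        order: list[str] = []

        for start in sorted(self._records):
            if start in state:
                continue
            stack = [(start, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise ValueError(f"pedigree cycle through {node!r}")
                state[node] = 0
                stack.append((node, True))
                rec = self._records[node]
                for pid in (rec.sire_id, rec.dam_id):
                    if pid is not None and state.get(pid) != 1:
                        if state.get(pid) == 0:
                            raise ValueError(f"pedigree cycle through {pid!r}")
                        stack.append((pid, False))
        for node in order:
            rec = self._records[node]
            gens = [
                self._generation[p] + 1
                for p in (rec.sire_id, rec.dam_id)
                if p is not None
            ]
            self._generation[node] = max(gens, default=0)

    def generation(self, id_: str) -> int:
        self.record(id_)
        return self._generation[id_]

    # -- kinship and inbreeding -----------------------------------------
    def kinship(self, a: str, b: str) -> float:
        """Malecot coancestry f(a, b).

        f(x, x) = (1 + F_x) / 2 and f(a, b) = [f(sire_a, b) + f(dam_a, b)] / 2
        recursing on the individual further from the founders; an unknown
        parent contributes zero.  Symmetric and memoised.
        """
        self.record(a), self.record(b)
        return self._kinship(a, b)

    def _kinship(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        if a == b:
            sire, dam = self.parents(a)
            f_a = self._kinship(sire, dam) if sire and dam else 0.0
            val = 0.5 * (1.0 + f_a)
        else:
            # recurse on the individual with the larger generation number:
            # it cannot be an ancestor of the other
            if self._generation[a] < self._generation[b]:
                a, b = b, a
            sire, dam = self.parents(a)
            val = 0.0
            if sire is not None:
                val += 0.5 * self._kinship(sire, b)
            if dam is not None:
                val += 0.5 * self._kinship(dam, b)
        self._kinship_cache[key] = val
        return val

    def inbreeding(self, id_: str) -> float:
        """F_ped: the kinship of the individual's parents (0 if either unknown)."""
        sire, dam = self.parents(id_)
        if sire is None or dam is None:
            return 0.0
        return self._kinship(sire, dam)

    # -- completeness ----------------------------------------------------
    def _is_known(self, id_: str | None) -> bool:
        return id_ is not None and not self._records[id_].phantom

    def complete_generation_equivalent(self, id_: str) -> float:
        """CGE = sum over known ancestor slots of (1/2)^generation."""
        self.record(id_)
        memo: dict[str, float] = {}

        def cge(x: str) -> float:
            if x in memo:
                return memo[x]
            total = 0.0
            for p in self.parents(x):
                if self._is_known(p):
                    total += 0.5 * (1.0 + cge(p))
            memo[x] = total
            return total

        return cge(id_)

    def ancestor_slot_counts(self, id_: str, max_gen: int) -> list[int]:
        """Known ancestor slots filled at generations 1..max_gen (slot-wise:
        an ancestor reached twice counts twice)."""
        self.record(id_)
        counts = [0] * max_gen
        frontier: Counter[str] = Counter({id_: 1})
        for g in range(max_gen):
            nxt: Counter[str] = Counter()
            for node, mult in frontier.items():
                for p in self.parents(node):
                    if self._is_known(p):
                        counts[g] += mult
                        nxt[p] += mult
            frontier = nxt
            if not frontier:
                break
        return counts


# ----------------------------------------------------------------------
# cleaning
# ----------------------------------------------------------------------

def clean_pedigree(
    records: Sequence[PedigreeRecord],
    min_year: int = 1850,
    max_year: int | None = None,
) -> tuple[Pedigree, CleaningReport]:
    """Repair a raw pedigree and build an acyclic :class:`Pedigree`.

    Steps, in order:

    1. duplicate ids are a hard error; self-parent links are cut and reported;
    2. phantom founder records are created for referenced-but-missing parents;
    3. birth years outside ``[min_year, max_year]`` (impossible years such as
       19981 or 201) are set to unknown, together with the full date;
    4. any record whose known parent has a strictly later known birth year
       has its own birth date and year set to unknown (equal years are
       tolerated);
    5. parentage cycles are broken by cutting the link that closes the cycle,
       preferring the dam link, in deterministic sorted-id DFS order.

    The function is idempotent: cleaning its own output changes nothing.
    """
    if max_year is None:
        max_year = _dt.date.today().year
    if min_year >= max_year:
        raise ValueError("min_year must be < max_year")

    report = CleaningReport()

    seen: set[str] = set()
    recs: dict[str, PedigreeRecord] = {}
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
        recs[rec.id] = rec

    # self-parent links: cut and report
    for id_, rec in list(recs.items()):
        if rec.sire_id == id_ or rec.dam_id == id_:
            recs[id_] = replace(
                rec,
                sire_id=None if rec.sire_id == id_ else rec.sire_id,
                dam_id=None if rec.dam_id == id_ else rec.dam_id,
            )
            report.removed_links.append((id_, id_))

    # phantom founders for dangling parent references
    for rec in list(recs.values()):
        for pid in (rec.sire_id, rec.dam_id):
            if pid is not None and pid not in recs:
                recs[pid] = PedigreeRecord(id=pid, phantom=True)
                report.n_phantom_created += 1

    # implausible birth years
    for id_, rec in recs.items():
        if rec.birth_year is not None and not (min_year <= rec.birth_year <= max_year):
            recs[id_] = replace(rec, birth_year=None, birth_date=None)
            report.n_year_reset += 1

    # parent born after child (by year; ties tolerated)
    changed = True
    while changed:
        changed = False
        for id_ in sorted(recs):
            rec = recs[id_]
            if rec.birth_year is None:
                continue
            for pid in (rec.sire_id, rec.dam_id):
                if pid is None:
                    continue
                py = recs[pid].birth_year
                if py is not None and py > rec.birth_year:
                    recs[id_] = replace(rec, birth_year=None, birth_date=None)
                    report.n_dob_reset += 1
                    changed = True
                    break

    # break cycles by DFS in sorted-id order, cutting the link that closes
    # each cycle (dam link preferred -- see parents_of ordering below)
    def cut_link(child: str, parent: str) -> None:
        rec = recs[child]
        if rec.sire_id == parent and rec.dam_id == parent:
            recs[child] = replace(rec, sire_id=None, dam_id=None)
        elif rec.dam_id == parent:
            recs[child] = replace(rec, dam_id=None)
        elif rec.sire_id == parent:
            recs[child] = replace(rec, sire_id=None)
        report.removed_links.append((child, parent))

    WHITE, GREY, BLACK = 0, 1, 2
    colour = {id_: WHITE for id_ in recs}

    def parents_of(id_: str) -> list[str]:
        rec = recs[id_]
        # dam first so that when both links close a cycle the dam link is cut
        out = []
        if rec.dam_id is not None:
            out.append(rec.dam_id)
        if rec.sire_id is not None and rec.sire_id != rec.dam_id:
            out.append(rec.sire_id)
        return out

    def dfs(start: str) -> None:
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(parents_of(start)))]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if colour[p] == GREY:  # back edge: this link closes a cycle
                    cut_link(node, p)
                    continue
                if colour[p] == WHITE:
                    colour[p] = GREY
                    stack.append((p, iter(parents_of(p))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()

    for id_ in sorted(recs):
        if colour[id_] == WHITE:
            dfs(id_)

    return Pedigree(recs.values()), report


# ----------------------------------------------------------------------
# demography and completeness
# ----------------------------------------------------------------------

def completeness_by_generation(
    ped: Pedigree,
    ids: Sequence[str],
    max_gen: int,
    group_by_country: bool = False,
) -> pd.DataFrame:
    """Mean proportion of known ancestors per generation over a cohort.

    For generation g the proportion is (filled ancestor slots) / 2^g,
    averaged over cohort members; with ``group_by_country`` the cohort is
    stratified by each individual's country (unknown country grouped as "").
    Returns a DataFrame with columns generation, group, proportion_known.
    """
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    if len(ids) == 0:
        raise ValueError("empty cohort")

    groups: dict[str, list[str]] = defaultdict(list)
    for id_ in ids:
        key = (ped.record(id_).country or "") if group_by_country else "all"
        groups[key].append(id_)

    rows = []
    for group in sorted(groups):
        members = groups[group]
        sums = [0.0] * max_gen
        for id_ in members:
            counts = ped.ancestor_slot_counts(id_, max_gen)
            for g in range(max_gen):
                sums[g] += counts[g] / (2 ** (g + 1))
        for g in range(max_gen):
            rows.append(
                {"generation": g + 1, "group": group,
                 "proportion_known": sums[g] / len(members)}
            )
    return pd.DataFrame(rows)


def popular_sires(ped: Pedigree, min_offspring: int = 32) -> list[tuple[str, int]]:
    """Sires with at least ``min_offspring`` recorded offspring, most prolific
    first (the breed-club convention: >= 32 pups is about five litters)."""
    counts: Counter[str] = Counter()
    for rec in ped:
        if rec.sire_id is not None:
            counts[rec.sire_id] += 1
    out = [(s, n) for s, n in counts.items() if n >= min_offspring]
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out


def top_sire_contribution(ped: Pedigree, year: int, n_top: int = 10) -> float:
    """Percentage of the year's puppies fathered by that year's top sires.

    The top ``n_top`` sires are ranked by offspring born in the given year
    (not by lifetime offspring).
    """
    counts: Counter[str] = Counter()
    total = 0
    for rec in ped:
        if rec.birth_year != year:
            continue
        total += 1
        if rec.sire_id is not None:
            counts[rec.sire_id] += 1
    if total == 0:
        raise ValueError(f"no recorded births in {year}")
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
    return 100.0 * sum(n for _, n in top) / total


def generation_interval(ped: Pedigree) -> float:
    """Mean parent age at offspring birth in years, pooling sire and dam
    pathways unweighted."""
    ages = []
    for rec in ped:
        if rec.birth_year is None:
            continue
        for pid in (rec.sire_id, rec.dam_id):
            if pid is None:
                continue
            py = ped.record(pid).birth_year
            if py is not None:
                ages.append(rec.birth_year - py)
    if not ages:
        raise ValueError("no parent-offspring pair with both birth years known")
    return sum(ages) / len(ages)


def litter_sizes(ped: Pedigree) -> tuple[list[int], float]:
    """Group offspring into litters and return (sizes, mean size).

    A litter is the set of records sharing (dam, birth date); when the date
    is unknown the key falls back to (dam, sire, birth year).  Records with
    no dam are ignored.  Singleton litters are allowed.
    """
    litters: Counter[tuple] = Counter()
    for rec in ped:
        if rec.dam_id is None:
            continue
        if rec.birth_date is not None:
            key = ("date", rec.dam_id, rec.birth_date)
        elif rec.birth_year is not None:
            key = ("year", rec.dam_id, rec.sire_id, rec.birth_year)
        else:
            continue
        litters[key] += 1
    sizes = sorted(litters.values(), reverse=True)
    mean = sum(sizes) / len(sizes) if sizes else float("nan")
    return sizes, mean


def fraction_of_pups_breeding(ped: Pedigree) -> tuple[float, float]:
    """Percentage of males that ever sired and of females that ever whelped.

    Phantom records are excluded from the denominators.
    """
    sires = {rec.sire_id for rec in ped if rec.sire_id is not None}
    dams = {rec.dam_id for rec in ped if rec.dam_id is not None}
    n_m = n_f = b_m = b_f = 0
    for rec in ped:
        if rec.phantom:
            continue
        if rec.sex == MALE:
            n_m += 1
            b_m += rec.id in sires
        elif rec.sex == FEMALE:
            n_f += 1
            b_f += rec.id in dams
    male = 100.0 * b_m / n_m if n_m else 0.0
    female = 100.0 * b_f / n_f if n_f else 0.0
    return male, female


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_pedigree_csv(path: str | Path) -> list[PedigreeRecord]:
    """Read a pedigree CSV with header id,sire,dam,sex,birth_date,country.

    Empty fields mean unknown.  birth_date accepts YYYY-MM-DD or a bare
    YYYY year.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex", "birth_date", "country"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        date: _dt.date | None = None
        year: int | None = None
        raw = row.birth_date.strip()
        if raw:
            try:
                date = _dt.date.fromisoformat(raw)
                year = date.year
            except ValueError:
                year = int(raw)  # bare year; raises on garbage
        records.append(
            PedigreeRecord(
                id=row.id.strip(),
                sire_id=row.sire.strip() or None,
                dam_id=row.dam.strip() or None,
                sex=_SEX_ALIASES.get(row.sex.strip().lower(), UNKNOWN_SEX),
                birth_year=year,
                birth_date=date,
                country=row.country.strip() or None,
            )
        )
    return records


def write_pedigree_csv(records: Iterable[PedigreeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if rec.birth_date is not None:
            bd = rec.birth_date.isoformat()
        elif rec.birth_year is not None:
            bd = str(rec.birth_year)
        else:
            bd = ""
        rows.append(
            {"id": rec.id, "sire": rec.sire_id or "", "dam": rec.dam_id or "",
             "sex": rec.sex if rec.sex != UNKNOWN_SEX else "",
             "birth_date": bd, "country": rec.country or ""}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
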