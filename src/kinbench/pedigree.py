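"""Pedigree representation, kinship recursion and ordinal degree classification.

A pedigree is a directed acyclic parent-offspring structure.  Every member
either has two recorded parents or none (a *founder*).  From the topology we
derive the kinship coefficient ``phi(i, j)`` -- the probability that two
alleles, one drawn at random from each individual, are identical by descent --
and the coefficient of relationship ``r = 2 * phi``, which is the quantity the
benchmarked relatedness estimators try to recover.

Relationship degrees are ordinal classes on the grid
``r = {0, 0.125, 0.25, 0.5, 1}`` (unrelated, third, second, first degree, and
self/monozygotic twins), with class boundaries at the midpoints between
consecutive grid values.

Monozygotic twins are modelled as verbatim genotype copies of an existing
member ("duplication"): the twin keeps the source's recorded parents, but
kinship between a twin and its source equals the source's self-kinship
``(1 + F) / 2``, not the full-sibling value.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "Individual",
    "DegreeGrid",
    "PairRelationship",
    "Pedigree",
    "PedigreeError",
    "DEFAULT_GRID",
]


class PedigreeError(ValueError):
    """Raised for malformed pedigree definitions or unknown individuals."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are positional slots only -- founder sex is
    not modelled, so "father" and "mother" merely name the two parental
    genome sources.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class DegreeGrid:
    """Ordered relationship classes with their expected r values.

    The default grid is (Unrelated, Third, Second, First, Self) with
    expected r values (0, 0.125, 0.25, 0.5, 1).  Class boundaries sit at the
    midpoints between consecutive r values; a value landing exactly on a
    boundary is assigned to the more-related class, and negative estimates
    map to Unrelated.
    """

    classes: tuple[str, ...] = ("Unrelated", "Third", "Second", "First", "Self")
    r_values: tuple[float, ...] = (0.0, 0.125, 0.25, 0.5, 1.0)
    short_labels: tuple[str, ...] = ("U", "3°", "2°", "1°", "S")

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.r_values):
            raise ValueError("classes and r_values must have equal length")
        if any(b <= a for a, b in zip(self.r_values, self.r_values[1:])):
            raise ValueError("grid r values must be strictly increasing")

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Midpoints between consecutive grid r values."""
        return tuple(
            (a + b) / 2.0 for a, b in zip(self.r_values, self.r_values[1:])
        )

    def classify(self, r: float) -> str:
        """Map an r coefficient to its ordinal degree class.

        Boundary ties go to the more-related class; ``r < 0`` maps to the
        least-related class.
        """
        if r != r:  # NaN
            raise ValueError("cannot classify NaN relatedness")
        k = 0
        for i, boundary in enumerate(self.boundaries):
            if r >= boundary:
                k = i + 1
        return self.classes[k]

    def expected_value(self, cls: str) -> float:
        return self.r_values[self.classes.index(cls)]

    def short_label(self, cls: str) -> str:
        return self.short_labels[self.classes.index(cls)]


DEFAULT_GRID = DegreeGrid()


@dataclass(frozen=True)
class PairRelationship:
    """Ground-truth description of one unordered pair of pedigree members."""

    pair: tuple[str, str]
    kinship: float
    expected_r: float
    ties: tuple[str, ...]
    truth_class: str


class Pedigree:
    """A pedigree with kinship recursion and twin duplication.

    Parameters
    ----------
    members
        Individuals in any order; parents must be resolvable within the
        collection.
    twin_of
        Maps a duplicated member's id to its source member's id.  Twin
        duplicates carry the same parents as their source and must receive
        identical genotypes in downstream simulation.
    """

    def __init__(
        self,
        members: Sequence[Individual],
        twin_of: dict[str, str] | None = None,
    ) -> None:
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id: {ind.id!r}")
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(
                    f"individual {ind.id!r} has exactly one recorded parent; "
                    "zero or two are required"
                )
            self._members[ind.id] = ind
        for ind in members:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self._members:
                    raise PedigreeError(
                        f"unknown parent id {parent!r} for individual {ind.id!r}"
                    )
        self.twin_of = dict(twin_of or {})
        for twin, src in self.twin_of.items():
            if twin not in self._members or src not in self._members:
                raise PedigreeError("twin mapping refers to unknown individual")
        self._topo = self._topological_order()
        self._rank = {i: k for k, i in enumerate(self._topo)}
        self._phi_cache: dict[tuple[str, str], float] = {}

    # ------------------------------------------------------------------ basic

    @classmethod
    def from_text(cls, text: str) -> "Pedigree":
        """Parse a trio-format pedigree table.

        One whitespace-delimited row per individual: ``id father mother``,
        with ``0`` marking a missing parent and ``#`` starting comments.
        Row order is irrelevant.
        """
        members = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise PedigreeError(
                    f"line {lineno}: expected 3 columns (id father mother), "
                    f"got {len(fields)}"
                )
            iid, father, mother = fields
            members.append(
                Individual(
                    iid,
                    None if father == "0" else father,
                    None if mother == "0" else mother,
                )
            )
        if not members:
            raise PedigreeError("empty pedigree definition")
        return cls(members)

    @classmethod
    def from_file(cls, path) -> "Pedigree":
        with open(path) as handle:
            return cls.from_text(handle.read())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual id: {iid!r}") from None

    @property
    def members(self) -> tuple[Individual, ...]:
        """Members in topological order (parents before children)."""
        return tuple(self._members[i] for i in self._topo)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._topo)

    @property
    def founders(self) -> tuple[str, ...]:
        """Founder ids, excluding twin duplicates of founders (copies, not
        fresh founder genotype draws)."""
        return tuple(
            i
            for i in self._topo
            if self._members[i].is_founder and i not in self.twin_of
        )

    def pairs(self) -> Iterator[tuple[str, str]]:
        """All unordered pairs of member ids."""
        return itertools.combinations(self._topo, 2)

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited / 1 in-progress / 2 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise PedigreeError(
                    "pedigree contains a cycle involving "
                    + " -> ".join(stack + [iid])
                )
            state[iid] = 1
            ind = self._members[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 2
            order.append(iid)

        for iid in self._members:
            visit(iid, [])
        return order

    # ---------------------------------------------------------------- kinship

    def _twin_source(self, iid: str) -> str:
        seen = set()
        while iid in self.twin_of:
            if iid in seen:
                raise PedigreeError("circular twin mapping")
            seen.add(iid)
            iid = self.twin_of[iid]
        return iid

    def kinship(self, i: str, j: str) -> float:
        """Classic recursive kinship coefficient phi(i, j), valid under
        inbreeding: phi(i, i) = (1 + F_i) / 2 with F_i = phi(father_i,
        mother_i).  Twin duplicates are genotype copies, so a twin behaves
        exactly as its source (phi(twin, source) = phi(source, source))."""
        self[i], self[j]  # id validation
        i, j = self._twin_source(i), self._twin_source(j)
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> float:
        # Order so that j is never an ancestor of i (later in topo order).
        if self._rank[i] > self._rank[j]:
            i, j = j, i
        key = (i, j)
        cached = self._phi_cache.get(key)
        if cached is not None:
            return cached
        ind_j = self._members[j]
        if i == j:
            if ind_j.is_founder:
                phi = 0.5
            else:
                phi = 0.5 * (1.0 + self._phi(ind_j.father_id, ind_j.mother_id))
        elif ind_j.is_founder:
            phi = 0.0
        else:
            phi = 0.5 * (self._phi(i, ind_j.father_id) + self._phi(i, ind_j.mother_id))
        self._phi_cache[key] = phi
        return phi

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient F_i = phi(father_i, mother_i)."""
        ind = self[self._twin_source(i)]
        if ind.is_founder:
            return 0.0
        return self.kinship(ind.father_id, ind.mother_id)

    def expected_r(self, i: str, j: str) -> float:
        """Expected relatedness coefficient r = 2 * phi(i, j)."""
        return 2.0 * self.kinship(i, j)

    # ------------------------------------------------------------------- ties

    def ancestors(self, iid: str, include_self: bool = True) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            cur = stack.pop()
            ind = self._members[cur]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        if include_self:
            out.add(iid)
        return out

    def _paths_up(self, start: str, apex: str) -> list[tuple[str, ...]]:
        """All ancestral chains start -> ... -> apex following parent links."""
        if start == apex:
            return [(start,)]
        out = []
        ind = self._members[start]
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None:
                for tail in self._paths_up(parent, apex):
                    out.append((start,) + tail)
        return out

    def enumerate_ties(
        self, i: str, j: str, grid: DegreeGrid = DEFAULT_GRID
    ) -> tuple[str, ...]:
        """Decompose a pair's relatedness into per-ancestor-group ties.

        Kinship contributions are grouped by distinct most-recent common
        ancestor *couple* (two mated shared ancestors count as one group) or
        single shared ancestor; each group's ``2 * phi_group`` is mapped to
        the nearest grid value's degree label.  Full siblings yield
        ``("1°",)``; double first cousins yield ``("3°", "3°")`` -- two
        third-degree ties whose compound effect is a second-degree r.

        Returns the multiset of short degree labels, sorted.
        """
        self[i], self[j]
        if i == j:
            raise PedigreeError("enumerate_ties requires two distinct members")
        si, sj = self._twin_source(i), self._twin_source(j)
        if si == sj:
            return (grid.short_labels[-1],)  # a twin pair is one self tie
        anc_i, anc_j = self.ancestors(si), self.ancestors(sj)
        common = anc_i & anc_j
        if not common:
            return ()
        # Most-recent common ancestors: no child also a common ancestor.
        children: dict[str, set[str]] = {a: set() for a in common}
        for ind in self._members.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent in children:
                    children[parent].add(ind.id)
        mrca = {a for a in common if not (children[a] & common)}
        # Wright path counting, apex restricted to the MRCA set; the two
        # branches of a loop may share no individual but the apex, and no
        # intermediate node may itself be a common ancestor.
        contrib: dict[str, float] = {}
        for apex in mrca:
            total = 0.0
            f_apex = self.inbreeding(apex)
            up_i = [
                p
                for p in self._paths_up(si, apex)
                if not (set(p[:-1]) & common)
            ]
            up_j = [
                p
                for p in self._paths_up(sj, apex)
                if not (set(p[:-1]) & common)
            ]
            for p1 in up_i:
                for p2 in up_j:
                    if set(p1[:-1]) & set(p2[:-1]):
                        continue
                    n_edges = (len(p1) - 1) + (len(p2) - 1)
                    total += 0.5 ** (n_edges + 1) * (1.0 + f_apex)
            contrib[apex] = total
        # Group MRCAs into mated couples: two shared ancestors sharing a
        # child that is an ancestor-or-self of either pair member.
        relevant = anc_i | anc_j
        groups: list[set[str]] = []
        assigned: set[str] = set()
        mrca_list = sorted(mrca, key=self._rank.get)
        for a, b in itertools.combinations(mrca_list, 2):
            if a in assigned or b in assigned:
                continue
            kids = children[a] & children[b]
            if any(k in relevant for k in kids):
                groups.append({a, b})
                assigned.update((a, b))
        groups.extend({a} for a in mrca_list if a not in assigned)
        labels = []
        for group in groups:
            r_group = 2.0 * sum(contrib[a] for a in group)
            cls = grid.classify(r_group)
            if cls == grid.classes[0]:
                continue  # contribution too weak to register as a tie
            labels.append(grid.short_label(cls))
        return tuple(sorted(labels))

    # ------------------------------------------------------------------ twins

    def duplicate_individual(self, iid: str, new_id: str | None = None) -> "Pedigree":
        """Return a new pedigree with a monozygotic-twin copy of ``iid``.

        The duplicate keeps the source's recorded parents and must receive
        the source's genotypes verbatim during simulation; for a founder
        source the founder count for genotype-sampling purposes is unchanged.
        """
        src = self[iid]
        if new_id is None:
            new_id = f"{iid}.twin"
            k = 2
            while new_id in self._members:
                new_id = f"{iid}.twin{k}"
                k += 1
        elif new_id in self._members:
            raise PedigreeError(f"duplicate individual id: {new_id!r}")
        members = list(self._members.values()) + [
            Individual(new_id, src.father_id, src.mother_id)
        ]
        twin_of = dict(self.twin_of)
        twin_of[new_id] = iid
        return Pedigree(members, twin_of)

    # -------------------------------------------------------------- summaries

    def relationship(
        self, i: str, j: str, grid: DegreeGrid = DEFAULT_GRID
    ) -> PairRelationship:
        phi = self.kinship(i, j)
        r = 2.0 * phi
        return PairRelationship(
            pair=(i, j),
            kinship=phi,
            expected_r=r,
            ties=self.enumerate_ties(i, j, grid),
            truth_class=grid.classify(r),
        )

    def count_pair_classes(self, grid: DegreeGrid = DEFAULT_GRID) -> dict[str, int]:
        """Classify every unordered pair by expected r; counts sum to
        n(n-1)/2."""
        if len(self) < 2:
            raise PedigreeError("need at least two members to form pairs")
        counts: Counter[str] = Counter()
        for i, j in self.pairs():
            counts[grid.classify(self.expected_r(i, j))] += 1
        return dict(counts)
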