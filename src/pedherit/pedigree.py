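"""Pedigree parsing, validation, kinship coefficients and relative-pair summaries.

A pedigree is a directed family structure of individuals with parent links and
sex; it is the sole source of relatedness information for the polygenic models
in this package. Founders are assumed non-inbred and mutually unrelated, the
standard assumption of the variance-components polygenic model, so kinship is
exactly zero across family blocks and the kinship matrix is block diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: missing-parent marker in LINKAGE / PLINK .fam files
MISSING = "0"


class Sex(IntEnum):
    """LINKAGE sex coding: 1 = male, 2 = female, 0 = unknown."""

    UNKNOWN = 0
    MALE = 1
    FEMALE = 2


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate id, bad parent link, cycle)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member. ``father_id``/``mother_id`` are ``None`` for founders."""

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Validated, topologically ordered collection of :class:`Individual`.

    Validation enforces: globally unique ids; parents either both present
    within the same family or both missing (unless ``pad_single_parent`` adds
    a dummy founder for the absent one); no individual is its own ancestor.
    After construction ``individuals`` is sorted parents-before-offspring.
    """

    def __init__(self, individuals: list[Individual], pad_single_parent: bool = False):
        individuals = list(individuals)
        seen: set[str] = set()
        for ind in individuals:
            if ind.individual_id in seen:
                raise PedigreeError(f"duplicate individual id: {ind.individual_id!r}")
            seen.add(ind.individual_id)

        individuals = self._resolve_parents(individuals, pad_single_parent)

        graph = nx.DiGraph()
        graph.add_nodes_from(ind.individual_id for ind in individuals)
        for ind in individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    graph.add_edge(parent, ind.individual_id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise PedigreeError(f"pedigree contains an ancestry cycle: {cycle}")

        order = list(nx.topological_sort(graph))
        by_id = {ind.individual_id: ind for ind in individuals}
        self.individuals: list[Individual] = [by_id[i] for i in order]
        self.index: dict[str, int] = {i: k for k, i in enumerate(order)}
        self._graph = graph

        for fam, group in self._by_family().items():
            n_founder = sum(ind.is_founder for ind in group)
            logger.debug(
                "family %s: %d founders, %d nonfounders",
                fam, n_founder, len(group) - n_founder,
            )

    @staticmethod
    def _resolve_parents(
        individuals: list[Individual], pad_single_parent: bool
    ) -> list[Individual]:
        ids_by_family: dict[str, set[str]] = {}
        all_ids = {ind.individual_id for ind in individuals}
        for ind in individuals:
            ids_by_family.setdefault(ind.family_id, set()).add(ind.individual_id)
        out: list[Individual] = []
        padded: list[Individual] = []
        n_pad = 0
        for ind in individuals:
            father, mother = ind.father_id, ind.mother_id
            if (father is None) != (mother is None):
                if not pad_single_parent:
                    raise PedigreeError(
                        f"individual {ind.individual_id!r} has a single parent "
                        "(use pad_single_parent to add a dummy founder)"
                    )
                n_pad += 1
                dummy = f"__pad{n_pad}"
                while dummy in all_ids:
                    n_pad += 1
                    dummy = f"__pad{n_pad}"
                all_ids.add(dummy)
                ids_by_family[ind.family_id].add(dummy)
                sex = Sex.MALE if father is None else Sex.FEMALE
                padded.append(Individual(dummy, ind.family_id, None, None, sex))
                if father is None:
                    father = dummy
                else:
                    mother = dummy
                ind = Individual(ind.individual_id, ind.family_id, father, mother, ind.sex)
            for parent in (father, mother):
                if parent is not None and parent not in ids_by_family[ind.family_id]:
                    raise PedigreeError(
                        f"parent {parent!r} of individual {ind.individual_id!r} "
                        f"not found in family {ind.family_id!r}"
                    )
            out.append(ind)
        return padded + out

    def _by_family(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[self.index[individual_id]]

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def founders(self) -> list[str]:
        return [i.individual_id for i in self.individuals if i.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i.individual_id for i in self.individuals if not i.is_founder]

    def children_of(self, individual_id: str) -> list[str]:
        return list(self._graph.successors(individual_id))

    def leaves(self) -> list[str]:
        """Nonfounders with no offspring of their own — the study children."""
        return [
            i.individual_id
            for i in self.individuals
            if not i.is_founder and self._graph.out_degree(i.individual_id) == 0
        ]


def read_pedigree(path, dialect: str = "linkage", pad_single_parent: bool = False) -> Pedigree:
    """Read a whitespace/tab-delimited LINKAGE or PLINK ``.fam`` pedigree file.

    Both dialects share the leading five columns
    ``family id father mother sex``; any further columns (e.g. the phenotype
    column of a ``.fam`` file) are ignored. Missing parents are coded ``"0"``.
    """
    if dialect not in ("linkage", "plink_fam"):
        raise ValueError(f"unknown pedigree dialect: {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 5 columns, got {len(parts)}"
                )
            fam, iid, fat, mot, sex = parts[:5]
            try:
                sex_code = Sex(int(sex))
            except (ValueError, KeyError):
                sex_code = Sex.UNKNOWN
            rows.append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if fat == MISSING else fat,
                    mother_id=None if mot == MISSING else mot,
                    sex=sex_code,
                )
            )
    ped = Pedigree(rows, pad_single_parent=pad_single_parent)
    logger.info(
        "read %d individuals (%d founders) in %d families from %s",
        len(ped), len(ped.founders), len({i.family_id for i in ped.individuals}), path,
    )
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree in PLINK ``.fam`` dialect (6th column written as -9)."""
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{ind.family_id}\t{ind.individual_id}\t"
                f"{ind.father_id or MISSING}\t{ind.mother_id or MISSING}\t"
                f"{int(ind.sex)}\t-9\n"
            )


@dataclass
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients phi_ij over pedigree members.

    ``values[i, i] = (1 + f_i) / 2`` with ``f_i`` the inbreeding coefficient
    (0.5 for non-inbred individuals); ``2 * values`` is the additive genetic
    relationship matrix used by the polygenic models.
    """

    values: np.ndarray
    ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("kinship matrix must be symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def phi(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def subset(self, ids) -> "KinshipMatrix":
        ids = list(ids)
        pos = [self._index[i] for i in ids]
        return KinshipMatrix(self.values[np.ix_(pos, pos)], ids)

    def family_blocks(self) -> list[np.ndarray]:
        """Index arrays of the connected components of the nonzero pattern."""
        adj = csr_matrix(self.values != 0)
        n_comp, labels = connected_components(adj, directed=False)
        return [np.flatnonzero(labels == c) for c in range(n_comp)]

    def to_long(self, include_diagonal: bool = False) -> pd.DataFrame:
        """Long-format table (id1, id2, phi) of nonzero kinship coefficients."""
        iu = np.triu_indices(len(self.ids), k=0 if include_diagonal else 1)
        mask = self.values[iu] != 0
        ids = np.asarray(self.ids, dtype=object)
        return pd.DataFrame(
            {
                "id1": ids[iu[0][mask]],
                "id2": ids[iu[1][mask]],
                "phi": self.values[iu][mask],
            }
        )


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients for a validated pedigree.

    Processing individuals parents-first, a founder has phi_ii = 1/2 and is
    unrelated to every earlier individual; a nonfounder i satisfies
    phi_ij = (phi_{father(i),j} + phi_{mother(i),j}) / 2 for every earlier j
    and phi_ii = (1 + phi_{father(i),mother(i)}) / 2.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for pos, ind in enumerate(ped.individuals):
        if ind.is_founder:
            phi[pos, pos] = 0.5
            continue
        fa = ped.index[ind.father_id]
        mo = ped.index[ind.mother_id]
        row = 0.5 * (phi[fa, :] + phi[mo, :])
        row[pos] = 0.5 * (1.0 + phi[fa, mo])
        phi[pos, :] = row
        phi[:, pos] = row
    return KinshipMatrix(phi, ped.ids)


#: kinship classes reported by :func:`relative_pairs`
PAIR_CLASSES = {
    0.25: "phi=0.25 (parent-offspring / full sibs)",
    0.125: "phi=0.125 (half sibs / avuncular / grandparental)",
    0.0625: "phi=0.0625 (first cousins)",
}


def relative_pairs(
    ped: Pedigree,
    kinship: KinshipMatrix | None = None,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Count pairs of (optionally restricted) individuals by kinship class.

    Returns a table with one row per class (phi = 0.25, 0.125, 0.0625, other
    nonzero) plus a ``total related`` row summing the nonzero classes.
    """
    kin = kinship if kinship is not None else compute_kinship(ped)
    if ids is not None:
        kin = kin.subset(ids)
    m = kin.values
    iu = np.triu_indices(len(kin.ids), k=1)
    phis = m[iu]
    counts: dict[str, int] = {label: 0 for label in PAIR_CLASSES.values()}
    counts["other nonzero phi"] = 0
    for value in phis[phis != 0]:
        for ref, label in PAIR_CLASSES.items():
            if abs(value - ref) < 1e-12:
                counts[label] += 1
                break
        else:
            counts["other nonzero phi"] += 1
    rows = [{"pair_class": k, "count": v} for k, v in counts.items()]
    rows.append({"pair_class": "total related", "count": int((phis != 0).sum())})
    return pd.DataFrame(rows)
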