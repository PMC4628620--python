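"""Family structure, kinship matrices and inbreeding coefficients.

A :class:`Pedigree` is an ordered set of individuals with optional parent
links; both parents are either present or absent (founder).  Kinship is
computed by the exact recursive (Emik–Terrill) algorithm in topological
order: for founders ``phi_ii = 1/2`` and ``phi_ij = 0`` with anyone who is
not a descendant; for a non-founder ``i`` with parents ``f, m``,

    phi_ii = 1/2 * (1 + phi_fm)
    phi_ij = 1/2 * (phi_fj + phi_mj)   for every j processed before i.

The inbreeding coefficient ``F_i`` is the kinship of i's parents.  The
additive-genetic relationship used by the polygenic model is ``2 * phi``;
that doubling happens in :mod:`ecgherit.varcomp`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipResult",
    "PedigreeError",
    "CycleError",
    "MissingParentError",
    "HalfSpecifiedParentError",
    "DuplicateIdError",
    "validate_pedigree",
    "compute_kinship",
    "inbreeding_classes",
]

#: sex codes on file (PLINK convention) -> internal labels
SEX_CODES: Mapping[str, str] = {"1": "male", "2": "female", "0": "unknown"}
_SEX_LABELS = {"male", "female", "unknown"}

#: default missing-parent code (PLINK convention)
MISSING_CODE = "0"


class PedigreeError(ValueError):
    """Base class for structural pedigree problems."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


class MissingParentError(PedigreeError):
    """A named parent does not exist in the pedigree."""


class HalfSpecifiedParentError(PedigreeError):
    """Exactly one parent is named; the model needs both or neither."""


class DuplicateIdError(PedigreeError):
    """The same individual id appears twice."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None  # None for founders
    mother: str | None
    sex: str  # "male" | "female" | "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass(frozen=True)
class Pedigree:
    """Individuals in topological order (every parent precedes its children)."""

    individuals: tuple[Individual, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {ind.id: k for k, ind in enumerate(self.individuals)}
        )

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    def index(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.individuals if ind.is_founder)

    @property
    def n_founders(self) -> int:
        return sum(ind.is_founder for ind in self.individuals)

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of father/mother positions; -1 for founders."""
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for k, ind in enumerate(self.individuals):
            if not ind.is_founder:
                out[k, 0] = self._index[ind.father]
                out[k, 1] = self._index[ind.mother]
        return out


def _normalize_sex(value: object) -> str:
    s = str(value).strip().lower()
    if s in SEX_CODES:
        return SEX_CODES[s]
    if s in _SEX_LABELS:
        return s
    if s in {"m", "f"}:
        return "male" if s == "m" else "female"
    return "unknown"


def validate_pedigree(
    records: Iterable[Sequence | Mapping], missing_code: str = MISSING_CODE
) -> Pedigree:
    """Check raw pedigree rows and return a topologically ordered Pedigree.

    Parameters
    ----------
    records
        Iterable of ``(id, father, mother, sex)`` sequences or mappings with
        those keys.  Missing parents are encoded by ``missing_code``.

    Raises
    ------
    DuplicateIdError, MissingParentError, HalfSpecifiedParentError, CycleError
    """
    rows: list[tuple[str, str | None, str | None, str]] = []
    for rec in records:
        if isinstance(rec, Mapping):
            iid, fa, mo, sex = rec["id"], rec["father"], rec["mother"], rec.get("sex", "0")
        else:
            iid, fa, mo, sex = rec[0], rec[1], rec[2], rec[3] if len(rec) > 3 else "0"
        iid = str(iid).strip()
        fa = None if fa is None or str(fa).strip() == missing_code else str(fa).strip()
        mo = None if mo is None or str(mo).strip() == missing_code else str(mo).strip()
        rows.append((iid, fa, mo, _normalize_sex(sex)))

    seen: set[str] = set()
    for iid, _, _, _ in rows:
        if iid in seen:
            raise DuplicateIdError(f"individual {iid!r} appears more than once")
        seen.add(iid)

    for iid, fa, mo, _ in rows:
        if (fa is None) != (mo is None):
            raise HalfSpecifiedParentError(
                f"individual {iid!r} names only one parent; need both or neither"
            )
        for parent in (fa, mo):
            if parent is not None and parent not in seen:
                raise MissingParentError(
                    f"parent {parent!r} of {iid!r} is not in the pedigree"
                )
        if fa is not None and iid in (fa, mo):
            raise CycleError(f"individual {iid!r} listed as its own parent")

    order_in_file = {iid: k for k, (iid, _, _, _) in enumerate(rows)}
    graph = nx.DiGraph()
    graph.add_nodes_from(order_in_file)
    for iid, fa, mo, _ in rows:
        if fa is not None:
            graph.add_edge(fa, iid)
            graph.add_edge(mo, iid)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CycleError(
            f"pedigree contains a cycle through individual {cycle[0][0]!r}"
        )
    topo = list(nx.lexicographical_topological_sort(graph, key=order_in_file.get))
    by_id = {iid: (fa, mo, sex) for iid, fa, mo, sex in rows}
    individuals = tuple(
        Individual(iid, by_id[iid][0], by_id[iid][1], by_id[iid][2]) for iid in topo
    )
    return Pedigree(individuals)


@dataclass(frozen=True)
class KinshipResult:
    """Kinship matrix phi, inbreeding coefficients F and quartile classes."""

    ids: tuple[str, ...]
    phi: np.ndarray  # (n, n) symmetric kinship coefficients
    F: np.ndarray  # (n,) inbreeding coefficients
    quartile_class: tuple[str, ...]  # over {"C0","Q1","Q2","Q3","Q4"}

    def __len__(self) -> int:
        return len(self.ids)

    def pair(self, a: str, b: str) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.phi[idx[a], idx[b]])


def compute_kinship(ped: Pedigree) -> KinshipResult:
    """Exact recursive kinship and inbreeding for a validated pedigree."""
    n = len(ped)
    parents = ped.parent_indices()
    if np.any(parents.max(axis=1) >= np.arange(n)):
        raise PedigreeError("pedigree is not in topological order (parent after child)")
    phi = np.zeros((n, n))
    F = np.zeros(n)
    for i in range(n):
        f, m = parents[i]
        if f < 0:  # founder: unrelated to everyone processed so far
            phi[i, i] = 0.5
        else:
            row = 0.5 * (phi[f, :i] + phi[m, :i])
            phi[i, :i] = row
            phi[:i, i] = row
            F[i] = phi[f, m]
            phi[i, i] = 0.5 * (1.0 + F[i])
    return KinshipResult(ped.ids, phi, F, tuple(inbreeding_classes(F)))


def inbreeding_classes(F: np.ndarray) -> np.ndarray:
    """Classify inbreeding coefficients: exact zeros are "C0"; positive values
    are split at their 25/50/75th percentiles into Q1..Q4 (boundary ties go to
    the lower class).  The heavy skew of F in an inbred cohort motivates the
    quartile scheme."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("inbreeding coefficients must be nonnegative")
    labels = np.full(F.shape, "C0", dtype=object)
    pos = F > 0
    if pos.any():
        q25, q50, q75 = np.percentile(F[pos], [25, 50, 75])
        vals = F[pos]
        lab = np.full(vals.shape, "Q4", dtype=object)
        lab[vals <= q75] = "Q3"
        lab[vals <= q50] = "Q2"
        lab[vals <= q25] = "Q1"
        labels[pos] = lab
    return labels.astype(str)
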