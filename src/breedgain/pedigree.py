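"""Pedigree handling and additive genetic relationship matrices.

A pedigree records, for each genotype, its female and male parents and a
selfing-generation count ``fgen``.  Selfing is encoded explicitly by listing
the same genotype as both parents; ``fgen`` is only meaningful for base
(founder) genotypes with both parents unknown, where it encodes inbreeding
accumulated before the pedigree starts: a base genotype with ``fgen = g``
gets inbreeding coefficient F = 1 - 0.5**g (the standard selfing-series
limit, so fgen = 5 gives F ~ 0.97 for inbred varieties and fgen = 10 gives
F ~ 0.999 for doubled haploids).

The additive (numerator) relationship matrix A is built by the tabular
method:

    a_ii = 1 + 0.5 * a(sire_i, dam_i)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))   for j earlier than i

with base genotypes seeded at a_ii = 2 - 0.5**fgen.  The inbreeding
coefficient is F_i = a_ii - 1 and the coefficient of coancestry (kinship)
between two genotypes is f_ij = a_ij / 2, the expected inbreeding of their
offspring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "RelationshipMatrix",
    "load_pedigree",
    "sort_pedigree",
    "build_additive_matrix",
    "inbreeding_coefficients",
    "coancestry",
    "invert_relationship",
    "gene_drop_kinship",
]


@dataclass(frozen=True)
class PedigreeRecord:
    """One genotype with its parents and selfing metadata.

    ``female == male`` encodes a selfing; both ``UNKNOWN`` marks a base
    genotype whose accumulated inbreeding is carried by ``fgen``.
    """

    id: str
    female: str = UNKNOWN
    male: str = UNKNOWN
    fgen: int = 0

    @property
    def is_base(self) -> bool:
        return self.female == UNKNOWN and self.male == UNKNOWN


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix over ordered genotypes."""

    ids: list[str]
    a: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        self.index = {g: i for i, g in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        try:
            return float(self.a[self.index[i], self.index[j]])
        except KeyError as exc:
            raise KeyError(f"genotype {exc.args[0]!r} not in relationship matrix") from None

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.index[g] for g in ids]
        return RelationshipMatrix(list(ids), self.a[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.ids, columns=self.ids)


def _as_records(frame: pd.DataFrame) -> list[PedigreeRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PedigreeRecord(
                id=str(row.id),
                female=str(row.female) if not _is_unknown(row.female) else UNKNOWN,
                male=str(row.male) if not _is_unknown(row.male) else UNKNOWN,
                fgen=int(row.fgen) if "fgen" in frame.columns and not pd.isna(row.fgen) else 0,
            )
        )
    return records


def _is_unknown(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return True
    s = str(value).strip()
    return s in ("", UNKNOWN, "nan", "NA", "unknown", "UNKNOWN")


def sort_pedigree(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    """Topologically order records so every parent precedes its offspring.

    Raises ``ValueError`` on duplicate ids, undefined parents, or cycles
    (a genotype that is its own ancestor), naming the offending genotypes.
    """
    by_id: dict[str, PedigreeRecord] = {}
    for rec in records:
        if rec.id in by_id:
            raise ValueError(f"duplicate genotype id {rec.id!r} in pedigree")
        by_id[rec.id] = rec

    graph = nx.DiGraph()
    graph.add_nodes_from(by_id)
    for rec in records:
        for parent in (rec.female, rec.male):
            if parent == UNKNOWN:
                continue
            if parent not in by_id:
                raise ValueError(
                    f"parent {parent!r} of {rec.id!r} is referenced but never defined"
                )
            graph.add_edge(parent, rec.id)

    try:
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(graph)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"cycle in pedigree: {path}") from None

    ordered = []
    for gid in order:
        rec = by_id[gid]
        if not rec.is_base and (rec.female == UNKNOWN or rec.male == UNKNOWN):
            raise ValueError(
                f"genotype {rec.id!r} has exactly one unknown parent; "
                "half-known parentage is not supported"
            )
        if not rec.is_base and rec.fgen != 0:
            warnings.warn(
                f"genotype {rec.id!r} has known parents; fgen={rec.fgen} ignored "
                "(selfing must be encoded by identical parents)",
                stacklevel=2,
            )
            rec = PedigreeRecord(rec.id, rec.female, rec.male, 0)
        ordered.append(rec)
    return ordered


def load_pedigree(path) -> list[PedigreeRecord]:
    """Read a pedigree CSV with columns id, female, male, fgen.

    Unknown parents may be encoded as ``0``, empty, or NA.  Records are
    returned topologically sorted (parents before offspring).
    """
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"id", "female", "male"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"pedigree file missing column(s): {sorted(missing)}")
    if "fgen" not in frame.columns:
        frame["fgen"] = 0
    frame["fgen"] = pd.to_numeric(frame["fgen"]).fillna(0).astype(int)
    return sort_pedigree(_as_records(frame))


def build_additive_matrix(records: list[PedigreeRecord]) -> RelationshipMatrix:
    """Tabular-method A-matrix; records must be topologically ordered."""
    n = len(records)
    ids = [r.id for r in records]
    index = {g: i for i, g in enumerate(ids)}
    a = np.zeros((n, n))
    for i, rec in enumerate(records):
        if rec.is_base:
            if rec.fgen < 0:
                raise ValueError(f"negative fgen for {rec.id!r}")
            a[i, i] = 2.0 - 0.5**rec.fgen
            continue
        s, d = index[rec.female], index[rec.male]
        if s >= i or d >= i:
            raise ValueError("records are not topologically ordered")
        rel = 0.5 * (a[:i, s] + a[:i, d])
        a[i, :i] = rel
        a[:i, i] = rel
        a[i, i] = 1.0 + 0.5 * a[s, d]
    return RelationshipMatrix(ids, a)


def inbreeding_coefficients(rm: RelationshipMatrix) -> pd.Series:
    """Inbreeding coefficient per genotype: F_i = a_ii - 1."""
    return pd.Series(np.diag(rm.a) - 1.0, index=rm.ids, name="F")


def coancestry(rm: RelationshipMatrix, i: str, j: str) -> float:
    """Coefficient of coancestry f = a_ij / 2 (expected offspring F)."""
    return 0.5 * rm.loc(i, j)


def invert_relationship(rm: RelationshipMatrix) -> np.ndarray:
    """Inverse of the relationship matrix via Cholesky.

    If the first factorization fails, a jitter of 1e-10 is added to the
    diagonal once; a second failure (e.g. duplicated genotype rows such as
    clones) raises ``np.linalg.LinAlgError``.
    """
    from scipy.linalg import cho_factor, cho_solve

    n = rm.a.shape[0]
    w = np.linalg.eigvalsh(rm.a)
    if w[0] < 1e-9 * max(w[-1], 1.0):
        raise np.linalg.LinAlgError(
            "relationship matrix is structurally singular "
            "(e.g. clone pair with identical relationship rows)"
        )
    try:
        c = cho_factor(rm.a)
    except np.linalg.LinAlgError:
        try:
            c = cho_factor(rm.a + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "relationship matrix is structurally singular "
                "(e.g. clone pair with identical relationship rows)"
            ) from None
    return cho_solve(c, np.eye(n))


def gene_drop_kinship(
    records: list[PedigreeRecord],
    n_reps: int = 200_000,
    seed: int = 20160101,
) -> RelationshipMatrix:
    """Monte-Carlo estimate of the A-matrix by gene dropping.

    Every base genotype starts with two unique founder alleles and is put
    through ``fgen`` generations of simulated selfing; offspring draw one
    allele from each parent (two independent draws from the same parent for
    a selfing).  The additive relationship is estimated as twice the
    identity-by-descent kinship averaged over replicates.  Serves as an
    independent check of the tabular method.
    """
    records = list(records)
    n = len(records)
    ids = [r.id for r in records]
    index = {g: i for i, g in enumerate(ids)}
    rng = np.random.default_rng(seed)

    # alleles[i] is (n_reps, 2) integer array of allele labels
    alleles: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    next_label = 0
    for i, rec in enumerate(records):
        if rec.is_base:
            pair = np.empty((n_reps, 2), dtype=np.int64)
            pair[:, 0] = next_label
            pair[:, 1] = next_label + 1
            next_label += 2
            for _ in range(rec.fgen):
                picks = rng.integers(0, 2, size=(n_reps, 2))
                pair = np.take_along_axis(pair, picks, axis=1)
            alleles[i] = pair
        else:
            fem = alleles[index[rec.female]]
            mal = alleles[index[rec.male]]
            picks = rng.integers(0, 2, size=(n_reps, 2))
            pair = np.empty((n_reps, 2), dtype=np.int64)
            pair[:, 0] = np.take_along_axis(fem, picks[:, :1], axis=1)[:, 0]
            pair[:, 1] = np.take_along_axis(mal, picks[:, 1:], axis=1)[:, 0]
            alleles[i] = pair

    a = np.empty((n, n))
    for i in range(n):
        ai = alleles[i]
        for j in range(i, n):
            aj = alleles[j]
            if i == j:
                ibd = (ai[:, 0] == ai[:, 1]).mean()
                a[i, i] = 1.0 + ibd
            else:
                match = (
                    (ai[:, 0] == aj[:, 0]).astype(np.int8)
                    + (ai[:, 0] == aj[:, 1])
                    + (ai[:, 1] == aj[:, 0])
                    + (ai[:, 1] == aj[:, 1])
                )
                a[i, j] = a[j, i] = 2.0 * match.mean() / 4.0
    return RelationshipMatrix(ids, a)
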