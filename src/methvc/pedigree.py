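"""Pedigree parsing and expected kinship matrices.

The polygenic component of the mixed model is structured by the expected
kinship matrix Phi computed from the pedigree: phi(i, j) is the probability
that an allele drawn at random from individual i is identical by descent to
one drawn from j.  The additive (numerator) relationship matrix 2*Phi is the
kernel that actually enters the phenotypic covariance.

Kinship is computed with the standard recursive (tabular) method over a
topological ordering of the pedigree: for a non-founder i with parents f, m

    phi(i, i) = 0.5 * (1 + phi(f, m))
    phi(i, j) = 0.5 * (phi(f, j) + phi(m, j))        (j earlier than i)

with phi = 0 between founders and for any missing parent.  The method is
exact and O(n^2) in memory, which is adequate for family-study sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "kinship_matrix",
    "additive_matrix",
    "write_kinship",
]

#: tokens accepted as "no parent recorded"
MISSING_PARENT = {"", "0", "NA", ".", "nan", "None"}

_SEX_CODES = {
    "1": "male", "m": "male", "male": "male",
    "2": "female", "f": "female", "female": "female",
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate or unknown ids)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record.  ``father``/``mother`` are ``None`` for founders."""

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    family: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A validated set of :class:`Individual` records.

    Validation guarantees unique ids, that every named parent is itself a
    record, and that the parent graph is acyclic.  Half-founders (one known
    parent) are allowed; the unknown side contributes zero kinship.
    """

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        if dups:
            raise PedigreeError(f"duplicate individual id(s): {dups}")
        known = set(ids)
        missing = sorted(
            {p for ind in self.individuals for p in (ind.father, ind.mother)
             if p is not None and p not in known}
        )
        if missing:
            raise PedigreeError(f"parent id(s) not present in pedigree: {missing}")
        self.topological_order()  # raises on cycles

    @property
    def ids(self) -> list[str]:
        """Ids in file first-appearance order (the downstream sample ordering)."""
        return [ind.iid for ind in self.individuals]

    @property
    def founders(self) -> list[str]:
        return [ind.iid for ind in self.individuals if ind.is_founder]

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        try:
            return next(ind for ind in self.individuals if ind.iid == iid)
        except StopIteration:
            raise KeyError(iid) from None

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-children; founders first among ties."""
        ts: TopologicalSorter[str] = TopologicalSorter()
        for ind in self.individuals:
            preds = [p for p in (ind.father, ind.mother) if p is not None]
            ts.add(ind.iid, *preds)
        try:
            return list(ts.static_order())
        except CycleError as err:
            cycle = err.args[1]
            raise PedigreeError(
                f"pedigree contains an ancestry cycle: {' -> '.join(cycle)}"
            ) from None


@dataclass
class KinshipMatrix:
    """Expected kinship coefficients for an ordered set of samples."""

    sample_ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError(f"phi shape {self.phi.shape} != ({n}, {n})")

    def reindex(self, sample_ids: list[str]) -> "KinshipMatrix":
        """Return a copy restricted/reordered to ``sample_ids``."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as err:
            raise KeyError(f"sample {err.args[0]!r} not in kinship matrix") from None
        return KinshipMatrix(list(sample_ids), self.phi[np.ix_(idx, idx)])


def _parse_sex(token: str) -> str:
    return _SEX_CODES.get(token.strip().lower(), "unknown")


def _parent(token: str) -> str | None:
    tok = token.strip()
    return None if tok in MISSING_PARENT else tok


def read_pedigree(path: str | Path, dialect: str = "ped") -> Pedigree:
    """Read a pedigree file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"ped"`` — whitespace-delimited, columns either
        ``family id father mother sex [...]`` (5+ columns) or
        ``id father mother [sex]`` (3-4 columns), no header.
        ``"tsv"`` — tab-separated with a header row; columns are matched
        case-insensitively against common names (id/iid/individual_id,
        father/sire/pat, mother/dam/mat, sex/gender, family/fid).

    Missing parents may be coded ``0`` or left empty in either dialect.
    """
    path = Path(path)
    if dialect == "ped":
        individuals = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                tok = line.split()
                if len(tok) >= 5:
                    fam, iid, fa, mo, sex = tok[0], tok[1], tok[2], tok[3], tok[4]
                elif len(tok) == 4:
                    fam, (iid, fa, mo, sex) = None, tok
                elif len(tok) == 3:
                    fam, (iid, fa, mo), sex = None, tok, "0"
                else:
                    raise PedigreeError(f"{path}:{lineno}: expected >= 3 columns")
                individuals.append(
                    Individual(iid, _parent(fa), _parent(mo), _parse_sex(sex), fam)
                )
        return Pedigree(individuals)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        cols = {c.lower(): c for c in df.columns}

        def pick(*names: str, required: bool = True) -> str | None:
            for n in names:
                if n in cols:
                    return cols[n]
            if required:
                raise PedigreeError(f"{path}: none of columns {names} found")
            return None

        c_id = pick("id", "iid", "individual", "individual_id")
        c_fa = pick("father", "father_id", "sire", "pat")
        c_mo = pick("mother", "mother_id", "dam", "mat")
        c_sex = pick("sex", "gender", required=False)
        c_fam = pick("family", "family_id", "fid", required=False)
        individuals = [
            Individual(
                str(row[c_id]).strip(),
                _parent(str(row[c_fa])),
                _parent(str(row[c_mo])),
                _parse_sex(str(row[c_sex])) if c_sex else "unknown",
                str(row[c_fam]).strip() or None if c_fam else None,
            )
            for _, row in df.iterrows()
        ]
        return Pedigree(individuals)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'ped' or 'tsv')")


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute the expected kinship matrix Phi by the recursive tabular method.

    Rows/columns follow the pedigree file's first-appearance order; downstream
    code must align matrices by explicit id matching, never by position.
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    by_id = {ind.iid: ind for ind in ped.individuals}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        ind = by_id[iid]
        fi = pos[ind.father] if ind.father is not None else None
        mi = pos[ind.mother] if ind.mother is not None else None
        for j in range(k):
            pf = phi[fi, j] if fi is not None else 0.0
            pm = phi[mi, j] if mi is not None else 0.0
            phi[k, j] = phi[j, k] = 0.5 * (pf + pm)
        inb = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + inb)
    file_order = ped.ids
    perm = [pos[iid] for iid in file_order]
    return KinshipMatrix(file_order, phi[np.ix_(perm, perm)])


def additive_matrix(k: KinshipMatrix) -> np.ndarray:
    """The additive relationship matrix 2*Phi (unit diagonal for outbred samples)."""
    return 2.0 * k.phi


def write_kinship(k: KinshipMatrix, path: str | Path, square: bool = False) -> None:
    """Write kinship to TSV: long (id1, id2, phi) pairs, or a square matrix."""
    path = Path(path)
    if square:
        pd.DataFrame(k.phi, index=k.sample_ids, columns=k.sample_ids).to_csv(
            path, sep="\t", index_label="id"
        )
        return
    rows = [
        (k.sample_ids[i], k.sample_ids[j], k.phi[i, j])
        for i in range(len(k.sample_ids))
        for j in range(i + 1)
    ]
    pd.DataFrame(rows, columns=["id1", "id2", "phi"]).to_csv(path, sep="\t", index=False)
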