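"""LINKAGE pre-makeped I/O plus Merlin-style map/dat writers.

The ped dialect is the pre-makeped one: whitespace-delimited rows of

    family  id  father  mother  sex  affection  [allele1 allele2] ...

with ``0`` for an absent parent, sex coded 1 = male / 2 = female, affection
0 = unknown / 1 = unaffected / 2 = affected, and marker alleles coded 1/2
(``0 0`` = missing).  The standard format has no genotyped/phenotyped field,
so those flags live in a sidecar whitespace-delimited file with columns
``id  genotyped  phenotyped`` (0/1 each).
"""

from __future__ import annotations

import os

import numpy as np

from .pedigree import UNKNOWN, Individual, Pedigree, PedigreeError

__all__ = [
    "read_pedfile",
    "read_genotypes",
    "write_pedfile",
    "read_flags",
    "write_flags",
    "write_mapfile",
    "write_datfile",
]


def _parse_rows(path: str | os.PathLike) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if tok:
                rows.append(tok)
    return rows


def read_flags(path: str | os.PathLike) -> dict[str, tuple[bool, bool]]:
    """Read the sidecar flags file: id -> (genotyped, phenotyped)."""
    out: dict[str, tuple[bool, bool]] = {}
    for tok in _parse_rows(path):
        if len(tok) != 3:
            raise PedigreeError(f"flags row needs 3 columns, got {tok}")
        out[tok[0]] = (tok[1] != "0", tok[2] != "0")
    return out


def write_flags(pedigree: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(f"{ind.id} {int(ind.genotyped)} {int(ind.phenotyped)}\n")


def read_pedfile(
    path: str | os.PathLike,
    flags_path: str | os.PathLike | None = None,
    dialect: str = "premakeped",
) -> Pedigree:
    """Read a pre-makeped ped file into a validated :class:`Pedigree`.

    Marker columns, if present, are ignored here (see :func:`read_genotypes`).
    Without a sidecar flags file, ``phenotyped`` defaults to ``affection !=
    unknown`` and ``genotyped`` to the same.
    """
    if dialect != "premakeped":
        raise ValueError(f"unsupported dialect {dialect!r}")
    flags = read_flags(flags_path) if flags_path is not None else None
    members: list[Individual] = []
    family = None
    for tok in _parse_rows(path):
        if len(tok) < 6 or (len(tok) - 6) % 2:
            raise PedigreeError(f"ped row has bad column count: {tok}")
        fam, iid, fid, mid, sex, aff = tok[:6]
        family = family or fam
        g, p = (
            flags.get(iid, (False, None))
            if flags is not None
            else (int(aff) != UNKNOWN, None)
        )
        members.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=int(sex),
                affection=int(aff),
                genotyped=bool(g),
                phenotyped=p,
            )
        )
    return Pedigree(members, family_id=family or "F1")


def read_genotypes(path: str | os.PathLike, pedigree: Pedigree) -> np.ndarray:
    """Read marker allele pairs from a ped file as risk-allele counts.

    Returns an ``(n_members, n_loci)`` int8 matrix in the pedigree's sorted
    member order; allele coding 1/2 with allele 2 the counted (risk) allele,
    ``0 0`` = missing = -1.
    """
    rows = _parse_rows(path)
    n_loci = (len(rows[0]) - 6) // 2
    geno = np.full((len(pedigree), n_loci), -1, dtype=np.int8)
    for tok in rows:
        if (len(tok) - 6) // 2 != n_loci:
            raise PedigreeError("inconsistent marker column count")
        iid = tok[1]
        alleles = np.array(tok[6:], dtype=np.int64).reshape(n_loci, 2)
        counts = (alleles == 2).sum(axis=1).astype(np.int8)
        counts[(alleles == 0).any(axis=1)] = -1
        geno[pedigree.index(iid)] = counts
    return geno


_ALLELES = {0: "1 1", 1: "1 2", 2: "2 2", -1: "0 0"}


def write_pedfile(
    pedigree: Pedigree,
    path: str | os.PathLike,
    genotypes: np.ndarray | None = None,
    phenotypes: np.ndarray | None = None,
) -> None:
    """Write pre-makeped rows, one per member, sorted by id.

    ``genotypes`` is an ``(n_members, n_loci)`` risk-allele-count matrix in
    sorted member order (-1 = missing, written as ``0 0``); ``phenotypes``
    optionally overrides the members' affection column (same order).
    """
    n = len(pedigree)
    if genotypes is not None and genotypes.shape[0] != n:
        raise ValueError(
            f"genotype matrix has {genotypes.shape[0]} rows for {n} members"
        )
    if phenotypes is not None and len(phenotypes) != n:
        raise ValueError("phenotype vector length inconsistent with pedigree")
    with open(path, "w") as fh:
        for k, ind in enumerate(pedigree):
            aff = int(phenotypes[k]) if phenotypes is not None else ind.affection
            cols = [
                pedigree.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                str(ind.sex),
                str(aff),
            ]
            if genotypes is not None:
                cols += [_ALLELES[int(g)] for g in genotypes[k]]
            fh.write(" ".join(cols) + "\n")


def write_mapfile(marker_map, path: str | os.PathLike) -> None:
    """Merlin-style map: chromosome, marker name, position (cM)."""
    with open(path, "w") as fh:
        fh.write("CHROMOSOME MARKER POSITION\n")
        for chrom, name, pos in marker_map.loci:
            fh.write(f"{chrom} {name} {pos:.6f}\n")


def write_datfile(marker_map, path: str | os.PathLike) -> None:
    """Merlin-style dat: affection declaration followed by marker names."""
    with open(path, "w") as fh:
        fh.write("A disease\n")
        for _, name, _ in marker_map.loci:
            fh.write(f"M {name}\n")
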