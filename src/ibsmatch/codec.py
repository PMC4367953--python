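"""Genotype storage, 2-bit packing and PLINK-text PED/MAP I/O.

Genotypes are minor-allele dosage codes in {0, 1, 2}; missing genotypes
carry the sentinel :data:`MISSING`.  Internally each genotype occupies two
bits using a unary-weight encoding (0 -> 00, 1 -> 01, 2 -> 11, missing ->
10) so that the population count of the XOR of two packed rows equals the
summed absolute allele-count difference between the two individuals --
the quantity at the heart of the identity-by-state similarity score.
A parallel 2-bit validity mask (11 for observed, 00 for missing) removes
loci missing in either member of a pair before counting.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in unpacked code matrices.
MISSING: int = 3

CONTROL = 0
CASE = 1

# 2-bit payloads per genotype code; index by code 0,1,2,MISSING.
_ENCODE = np.array([0b00, 0b01, 0b11, 0b10], dtype=np.uint8)
_DECODE = {0b00: 0, 0b01: 1, 0b11: 2, 0b10: MISSING}
_DECODE_LUT = np.array([0, 1, MISSING, 2], dtype=np.uint8)


class GenotypeCodeError(ValueError):
    """A code matrix contains a value outside {0, 1, 2, MISSING}."""


class PedFormatError(ValueError):
    """PED/MAP files violate the PLINK text conventions."""


@dataclass(frozen=True)
class Phenotype:
    """Case-control labels with the index sets of controls ``O`` and cases ``A``."""

    labels: np.ndarray  # int8, CONTROL/CASE per phenotyped individual

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(labels, (CONTROL, CASE)).all():
            raise ValueError("phenotype labels must be 0 (control) or 1 (case)")
        object.__setattr__(self, "labels", labels)

    @property
    def controls(self) -> np.ndarray:
        """Indices of controls (the set O)."""
        return np.flatnonzero(self.labels == CONTROL)

    @property
    def cases(self) -> np.ndarray:
        """Indices of cases (the set A)."""
        return np.flatnonzero(self.labels == CASE)

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class PackedGenotypes:
    """2-bit packed genotype matrix for ``n_individuals`` x ``n_snps``.

    ``packed`` holds four genotypes per byte (little-endian within the
    byte: locus ``k`` occupies bits ``2*(k % 4)`` .. ``2*(k % 4) + 1`` of
    byte ``k // 4``).  ``mask`` mirrors the layout with 11 for observed
    and 00 for missing genotypes.
    """

    n_individuals: int
    n_snps: int
    packed: np.ndarray  # (n_individuals, n_bytes) uint8
    mask: np.ndarray  # same shape, uint8
    snp_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.n_snps)]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.n_individuals)]
        if len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length mismatch")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")

    # -- unpacked views ----------------------------------------------------

    def codes(self) -> np.ndarray:
        """Decode to an (n_individuals, n_snps) uint8 matrix in {0,1,2,MISSING}."""
        n_bytes = self.packed.shape[1]
        out = np.empty((self.n_individuals, 4 * n_bytes), dtype=np.uint8)
        b = self.packed
        for k in range(4):
            out[:, k::4] = (b >> (2 * k)) & 0b11
        return _DECODE_LUT[out[:, : self.n_snps]]

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the genotype is observed."""
        return self.codes() != MISSING

    def take_snps(self, index: Sequence[int] | np.ndarray) -> "PackedGenotypes":
        """Subset to the given SNP indices (re-packs)."""
        index = np.asarray(index)
        codes = self.codes()[:, index]
        return pack_genotypes(
            codes,
            snp_ids=[self.snp_ids[j] for j in index],
            individual_ids=list(self.individual_ids),
        )

    def take_individuals(self, index: Sequence[int] | np.ndarray) -> "PackedGenotypes":
        index = np.asarray(index)
        return PackedGenotypes(
            n_individuals=len(index),
            n_snps=self.n_snps,
            packed=self.packed[index].copy(),
            mask=self.mask[index].copy(),
            snp_ids=list(self.snp_ids),
            individual_ids=[self.individual_ids[i] for i in index],
        )


def pack_genotypes(
    codes: np.ndarray,
    snp_ids: Iterable[str] | None = None,
    individual_ids: Iterable[str] | None = None,
    missing: int = MISSING,
) -> PackedGenotypes:
    """Pack an integer code matrix into the 2-bit representation.

    Parameters
    ----------
    codes
        (n, S) integer matrix with values in {0, 1, 2, ``missing``}.
    missing
        The sentinel used for missing genotypes in ``codes``; stored
        internally as :data:`MISSING`.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise GenotypeCodeError("codes must be a 2-D matrix")
    codes = codes.copy()
    is_missing = codes == missing
    codes[is_missing] = MISSING
    if not np.isin(codes, (0, 1, 2, MISSING)).all():
        bad = np.unique(codes[~np.isin(codes, (0, 1, 2, MISSING))])
        raise GenotypeCodeError(f"invalid genotype codes: {bad.tolist()}")
    n, s = codes.shape
    n_bytes = (s + 3) // 4
    payload = _ENCODE[codes.astype(np.uint8)]
    valid = np.where(codes == MISSING, 0b00, 0b11).astype(np.uint8)
    # pad the tail of the last byte with missing loci masked to zero
    pad = 4 * n_bytes - s
    if pad:
        payload = np.pad(payload, ((0, 0), (0, pad)))
        valid = np.pad(valid, ((0, 0), (0, pad)))
    packed = np.zeros((n, n_bytes), dtype=np.uint8)
    maskb = np.zeros((n, n_bytes), dtype=np.uint8)
    for k in range(4):
        packed |= payload[:, k::4] << (2 * k)
        maskb |= valid[:, k::4] << (2 * k)
    return PackedGenotypes(
        n_individuals=n,
        n_snps=s,
        packed=packed,
        mask=maskb,
        snp_ids=list(snp_ids) if snp_ids is not None else [],
        individual_ids=list(individual_ids) if individual_ids is not None else [],
    )


def allele_diff_count(pg: PackedGenotypes, i: int, j: int) -> tuple[int, int]:
    """Popcount-based (sum |g_ik - g_jk|, N shared loci) for one pair.

    Only loci observed in both individuals contribute; ``N`` is their
    count.
    """
    m = pg.mask[i] & pg.mask[j]
    diff = (pg.packed[i] ^ pg.packed[j]) & m
    mismatches = int(np.bitwise_count(diff).sum())
    n_shared = int(np.bitwise_count(m).sum()) // 2
    return mismatches, n_shared


# -- PLINK text PED/MAP ----------------------------------------------------

_MISSING_ALLELE = "0"


def _opener(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[PackedGenotypes, Phenotype]:
    """Read PLINK text PED/MAP into packed minor-allele dosage codes.

    The minor allele of every SNP is determined from the loaded sample
    (ties at 0.5 broken by lexicographic allele order) and genotypes are
    recoded as minor-allele counts.  PED phenotype column: 1 = control,
    2 = case; anything else marks the individual's phenotype as missing
    and the individual is excluded with a warning.
    """
    snp_ids: list[str] = []
    with _opener(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise PedFormatError(f"MAP line has {len(parts)} columns")
            snp_ids.append(parts[1])
    n_snps = len(snp_ids)

    ids: list[str] = []
    phen_raw: list[str] = []
    allele_rows: list[list[str]] = []
    with _opener(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PedFormatError(
                    f"PED line {ln}: expected {6 + 2 * n_snps} columns, got {len(parts)}"
                )
            ids.append(parts[1])
            phen_raw.append(parts[5])
            allele_rows.append(parts[6:])

    n = len(ids)
    alleles = np.array(allele_rows, dtype="U8").reshape(n, n_snps, 2) if n else np.empty(
        (0, n_snps, 2), dtype="U8"
    )

    codes = np.full((n, n_snps), MISSING, dtype=np.uint8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != _MISSING_ALLELE]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise PedFormatError(f"SNP {snp_ids[j]} is not biallelic: {uniq.tolist()}")
        if len(uniq) == 0:
            continue  # fully missing SNP stays MISSING
        obs = (col != _MISSING_ALLELE).all(axis=1)
        if len(uniq) == 1:
            codes[obs, j] = 0  # monomorphic: only allele seen is the major one
            continue
        # minor allele = lower count; lexicographic tie-break
        order = uniq[np.lexsort((uniq, counts))]
        minor = order[0]
        codes[obs, j] = (col[obs] == minor).sum(axis=1)

    phen_codes = np.full(n, -1, dtype=np.int8)
    for i, p in enumerate(phen_raw):
        if p == "1":
            phen_codes[i] = CONTROL
        elif p == "2":
            phen_codes[i] = CASE
    keep = phen_codes >= 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"excluding {len(dropped)} individuals with missing phenotype: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    codes = codes[keep]
    ids = [ids[i] for i in np.flatnonzero(keep)]
    pg = pack_genotypes(codes, snp_ids=snp_ids, individual_ids=ids)
    return pg, Phenotype(phen_codes[keep])


def write_ped_map(
    pg: PackedGenotypes,
    phen: Phenotype,
    ped_path: str | Path,
    map_path: str | Path,
    chromosome: int = 1,
) -> None:
    """Write PLINK text PED/MAP; dosage 0/1/2 becomes A/G letter pairs.

    The minor allele is written as ``G`` so that a read-back recodes to
    the identical dosage matrix (up to allele-letter relabeling).
    """
    codes = pg.codes()
    with _opener(map_path, "wt") as fh:
        for j, sid in enumerate(pg.snp_ids):
            fh.write(f"{chromosome}\t{sid}\t0\t{j + 1}\n")
    geno_strings = {0: "A A", 1: "A G", 2: "G G", MISSING: "0 0"}
    with _opener(ped_path, "wt") as fh:
        for i, iid in enumerate(pg.individual_ids):
            phe = 2 if phen.labels[i] == CASE else 1
            row = " ".join(geno_strings[int(c)] for c in codes[i])
            fh.write(f"FAM{i} {iid} 0 0 0 {phe} {row}\n".rstrip() + "\n")
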