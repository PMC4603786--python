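"""Molecular fingerprints and Tanimoto similarity.

Every score in the screening pipeline bottoms out in the Tanimoto
coefficient of two fixed-length binary fingerprints.  Fingerprints are
1024-bit hashed path (Daylight-style) fingerprints computed with RDKit;
the scheme is recorded on each :class:`Fingerprint` so downstream tables
can state their provenance, and every consumer depends only on the
bit-vector contract, never on particular bit positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

N_BITS = 1024
DEFAULT_SCHEME = "rdkit-path-1024"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary molecular fingerprint.

    Parameters
    ----------
    bits
        Boolean vector of length 1024.
    scheme
        Name of the fingerprinting scheme that produced the bits.
    """

    bits: np.ndarray
    scheme: str = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        if bits.shape != (N_BITS,):
            raise ValueError(
                f"fingerprint must have exactly {N_BITS} bits, got shape {bits.shape}"
            )
        object.__setattr__(self, "bits", bits)
        self.bits.setflags(write=False)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str, scheme: str = DEFAULT_SCHEME) -> "Fingerprint":
        if len(s) != N_BITS or set(s) - {"0", "1"}:
            raise ValueError("bitstring must be 1024 characters of 0/1")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) == ord("1"), scheme)

    @classmethod
    def from_on_bits(cls, on_bits: Iterable[int], scheme: str = DEFAULT_SCHEME) -> "Fingerprint":
        bits = np.zeros(N_BITS, dtype=bool)
        bits[list(on_bits)] = True
        return cls(bits, scheme)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return bool(np.array_equal(self.bits, other.bits))

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class CompoundRecord:
    """A drug or ligand: identifier, optional SMILES, and its fingerprint."""

    compound_id: str
    fingerprint: Fingerprint
    smiles: str | None = None
    name: str | None = None


def compute_fingerprint(smiles: str, scheme: str = DEFAULT_SCHEME) -> Fingerprint:
    """Compute the 1024-bit fingerprint of a molecule given as SMILES.

    The SMILES is parsed and canonicalized first, so any textual variant
    of the same molecule yields an identical fingerprint.  Unparsable
    input raises :class:`SmilesParseError` naming the offending string.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    if scheme != DEFAULT_SCHEME:
        raise ValueError(f"unknown fingerprint scheme: {scheme!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=N_BITS)
    bits = np.zeros(N_BITS, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return Fingerprint(bits, scheme)


def canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two fingerprints.

    Symmetric and bounded in [0, 1].  Two all-zero fingerprints score 0
    by convention so ranking never meets a NaN.
    """
    if a.bits.shape != b.bits.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(a.bits & b.bits))
    return inter / union


# ---------------------------------------------------------------------------
# I/O


def read_smiles_file(path) -> list[CompoundRecord]:
    """Read a SMILES file: one record per line, `SMILES<ws>identifier`.

    Blank lines and `#` comments are skipped.  A line with no identifier
    gets `cmpd<line>` as its id.
    """
    records: list[CompoundRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"cmpd{lineno}"
            try:
                fp = compute_fingerprint(smiles)
            except SmilesParseError as exc:
                raise SmilesParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(CompoundRecord(cid, fp, smiles=canonical_smiles(smiles)))
    return records


def read_sdf(path) -> list[CompoundRecord]:
    """Read compounds from an SDF file, fingerprinting each molecule."""
    from rdkit import Chem

    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise SmilesParseError(f"{path}: unparsable molecule at index {i}")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"cmpd{i + 1}"
        fp = Chem.RDKFingerprint(mol, fpSize=N_BITS)
        bits = np.zeros(N_BITS, dtype=bool)
        bits[list(fp.GetOnBits())] = True
        records.append(
            CompoundRecord(cid, Fingerprint(bits), smiles=Chem.MolToSmiles(mol))
        )
    return records


def write_fingerprint_table(records: Iterable[CompoundRecord], path) -> None:
    """Write a TSV of compound_id and the 1024-char 0/1 bitstring."""
    with open(path, "w") as fh:
        fh.write("compound_id\tfingerprint\n")
        for rec in records:
            fh.write(f"{rec.compound_id}\t{rec.fingerprint.to_bitstring()}\n")


def read_fingerprint_table(path) -> list[CompoundRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("compound_id"):
            raise ValueError(f"{path}: expected header starting with 'compound_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                cid, bitstring = line.split("\t")
                fp = Fingerprint.from_bitstring(bitstring)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(CompoundRecord(cid, fp))
    return records
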