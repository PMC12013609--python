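"""Nine-family concatenated molecular fingerprints.

The target vector concatenates, in fixed order: FP2 (1024), AtomPair
(2048), Avalon (512), MACCS (166), Morgan (2048), RDKitFP (2048), CDK
(1024), PubChem (881) and Klekota-Roth (4860) bits - 14 611 bits total.

AtomPair, Avalon, MACCS, Morgan and RDKitFP come straight from RDKit.
The remaining four families were designed for other toolchains (Open
Babel, CDK); here they are RDKit-computed stand-ins that keep each
family's exact bit length and general character:

* FP2       - linear-path hashed fingerprint (unbranched paths, length <= 7),
* CDK       - hashed path fingerprint, path length <= 8,
* PubChem   - feature-invariant Morgan (FCFP-like), radius 2, folded to 881,
* KlekotaRoth - Morgan radius 3 folded to 4860 (substructure-keyed in the
  original definition; hashed circular substructures here).

Backends are recorded per family in :class:`FingerprintFamilySpec` so the
substitution is visible in any serialized config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")


class StructureError(ValueError):
    """SMILES/InChI string does not parse to a molecule."""


class FingerprintConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FingerprintFamilySpec:
    name: str
    length: int
    backend: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self):
        if self.length <= 0:
            raise FingerprintConfigError(f"family {self.name}: non-positive length")


@dataclass(frozen=True)
class FingerprintConfig:
    """Ordered family layout; bit b of family k lives at offset(k) + b."""

    families: tuple[FingerprintFamilySpec, ...]

    def __post_init__(self):
        if not self.families:
            raise FingerprintConfigError("family list is empty")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise FingerprintConfigError("duplicate family names")

    @property
    def total_length(self) -> int:
        return sum(f.length for f in self.families)

    def offset(self, name: str) -> int:
        off = 0
        for f in self.families:
            if f.name == name:
                return off
            off += f.length
        raise FingerprintConfigError(f"unknown family {name!r}")

    def layout_hash(self) -> str:
        doc = [(f.name, f.length, f.backend, f.params) for f in self.families]
        return hashlib.sha256(json.dumps(doc, default=str).encode()).hexdigest()[:16]


def default_config() -> FingerprintConfig:
    return FingerprintConfig(families=(
        FingerprintFamilySpec("FP2", 1024, "rdkit-surrogate:linear-path",
                              (("maxPath", 7),)),
        FingerprintFamilySpec("AtomPair", 2048, "rdkit"),
        FingerprintFamilySpec("Avalon", 512, "rdkit"),
        FingerprintFamilySpec("MACCS", 166, "rdkit"),
        FingerprintFamilySpec("Morgan", 2048, "rdkit", (("radius", 2),)),
        FingerprintFamilySpec("RDKitFP", 2048, "rdkit", (("maxPath", 7),)),
        FingerprintFamilySpec("CDK", 1024, "rdkit-surrogate:path",
                              (("maxPath", 8),)),
        FingerprintFamilySpec("PubChem", 881, "rdkit-surrogate:fcfp",
                              (("radius", 2),)),
        FingerprintFamilySpec("KlekotaRoth", 4860, "rdkit-surrogate:morgan",
                              (("radius", 3),)),
    ))


@dataclass
class FingerprintVector:
    bits: np.ndarray
    layout: FingerprintConfig

    def __post_init__(self):
        if self.bits.shape != (self.layout.total_length,):
            raise FingerprintConfigError(
                f"bit vector length {self.bits.shape} does not match layout "
                f"({self.layout.total_length},)"
            )


def parse_structure(structure: str) -> Chem.Mol:
    """Parse a SMILES or InChI string (InChI recognized by its prefix)."""
    if structure.startswith("InChI="):
        mol = Chem.MolFromInchi(structure)
    else:
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparsable structure {structure!r}")
    return mol


def _bitvect_to_array(bv, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.int8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


def compute_family_fingerprint(structure: str | Chem.Mol,
                               spec: FingerprintFamilySpec) -> np.ndarray:
    """Binary vector of exactly ``spec.length`` bits for one family."""
    mol = parse_structure(structure) if isinstance(structure, str) else structure
    params = dict(spec.params)
    n = spec.length
    if spec.name == "MACCS":
        # RDKit emits 167 bits with bit 0 unused; drop it for the 166-bit layout.
        full = MACCSkeys.GenMACCSKeys(mol)
        return _bitvect_to_array(full, 167)[1:]
    if spec.name == "Avalon":
        return _bitvect_to_array(pyAvalonTools.GetAvalonFP(mol, nBits=n), n)
    if spec.name == "AtomPair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "Morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=int(params.get("radius", 2)), fpSize=n)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "RDKitFP":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=int(params.get("maxPath", 7)), fpSize=n)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "FP2":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=int(params.get("maxPath", 7)), fpSize=n, branchedPaths=False)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "CDK":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=int(params.get("maxPath", 8)), fpSize=n)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "PubChem":
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=int(params.get("radius", 2)), fpSize=n,
            atomInvariantsGenerator=inv)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    if spec.name == "KlekotaRoth":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=int(params.get("radius", 3)), fpSize=n)
        return _bitvect_to_array(gen.GetFingerprint(mol), n)
    raise FingerprintConfigError(f"unsupported family {spec.name!r}")


def compute_concatenated_fingerprint(structure: str,
                                     config: FingerprintConfig) -> FingerprintVector:
    """Compute all families in config order and concatenate the bits."""
    mol = parse_structure(structure)
    parts = []
    for fam in config.families:
        try:
            parts.append(compute_family_fingerprint(mol, fam))
        except StructureError:
            raise
        except Exception as e:  # pragma: no cover - backend failures
            raise FingerprintConfigError(f"family {fam.name} failed: {e}") from e
    return FingerprintVector(bits=np.concatenate(parts), layout=config)
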