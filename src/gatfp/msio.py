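"""Readers and writers for fragmentation trees, MassBank-style records and
candidate libraries.

The canonical interchange for trees is a JSON document mirroring the
SIRIUS tree output::

    {
      "sampleId": "...",                      # optional, else file stem
      "precursorMass": 180.0634,              # optional, else root m/z
      "precursorFormula": "C6H12O6",          # optional, else root formula
      "adduct": "[M+H]+",                     # optional
      "fragments": [
        {"id": 0, "molecularFormula": "C6H12O6", "mz": 180.06,
         "relativeIntensity": 1.0}, ...
      ],
      "losses": [{"source": 0, "target": 1}, ...]
    }

The reader tolerates SIRIUS-dialect synonyms (``relativeIntensity`` /
``intensity`` / ``relInt``; loss endpoints given either as fragment ids or
as fragment molecular formulas).  Intensities are renormalized so the
maximum over nodes is exactly 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .formulas import DEFAULT_ALPHABET, FormulaError, canonical_formula, parse_formula

logger = logging.getLogger(__name__)


class TreeFormatError(ValueError):
    """A tree document is missing or mistypes a required field."""


class TreeStructureError(ValueError):
    """Tree edges do not form a single rooted tree."""


class MetadataError(ValueError):
    """A compound record lacks required structure metadata."""


class LibraryIntegrityError(ValueError):
    """A candidate library violates uniqueness or range constraints."""


@dataclass
class FragmentNode:
    """One fragment: elemental composition, m/z and relative abundance."""

    node_id: int
    formula: dict[str, int]
    mz: float
    rel_intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise TreeFormatError(f"fragment {self.node_id}: non-positive mz {self.mz}")
        if not (0.0 <= self.rel_intensity <= 1.0):
            raise TreeFormatError(
                f"fragment {self.node_id}: rel_intensity {self.rel_intensity} outside [0,1]"
            )
        if not any(v > 0 for v in self.formula.values()):
            raise TreeFormatError(f"fragment {self.node_id}: empty formula")

    @property
    def formula_str(self) -> str:
        return canonical_formula(self.formula)


@dataclass
class FragmentationTree:
    """A rooted fragmentation tree; edges point parent fragment → child."""

    sample_id: str
    nodes: list[FragmentNode]
    edges: list[tuple[int, int]]
    precursor_mass: float
    precursor_formula: dict[str, int]
    adduct: str | None = None

    def __post_init__(self):
        validate_tree_structure(self.nodes, self.edges)

    @property
    def root_id(self) -> int:
        children = {c for _, c in self.edges}
        (root,) = [n.node_id for n in self.nodes if n.node_id not in children]
        return root

    def node(self, node_id: int) -> FragmentNode:
        return next(n for n in self.nodes if n.node_id == node_id)


@dataclass
class CompoundRecord:
    """Structure metadata for one spectrum's compound."""

    sample_id: str
    formula: dict[str, int]
    monoisotopic_mass: float
    smiles: str | None = None
    inchi: str | None = None

    def __post_init__(self):
        if not self.smiles and not self.inchi:
            raise MetadataError(
                f"record {self.sample_id}: neither SMILES nor InChI present"
            )

    @property
    def structure(self) -> str:
        return self.smiles or self.inchi  # type: ignore[return-value]


@dataclass(frozen=True)
class CandidateRecord:
    """One library entry available for retrieval and scoring."""

    candidate_id: str
    formula: dict[str, int] = field(hash=False)
    monoisotopic_mass: float = 0.0
    smiles: str = ""


def validate_tree_structure(nodes: list[FragmentNode], edges: list[tuple[int, int]]) -> None:
    ids = [n.node_id for n in nodes]
    if len(set(ids)) != len(ids):
        raise TreeStructureError("duplicate node ids")
    idset = set(ids)
    for p, c in edges:
        if p not in idset or c not in idset:
            raise TreeStructureError(f"edge ({p},{c}) references unknown node id")
    if len(edges) != len(nodes) - 1:
        raise TreeStructureError(
            f"{len(nodes)} nodes require {len(nodes) - 1} edges, got {len(edges)}"
        )
    if len(nodes) == 1:
        return
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    if not nx.is_arborescence(g):
        raise TreeStructureError("edges do not form a single rooted tree")


_INTENSITY_KEYS = ("relativeIntensity", "intensity", "relInt")


def _tree_from_doc(doc: dict, sample_id: str,
                   alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> FragmentationTree:
    if "fragments" not in doc:
        raise TreeFormatError("missing field 'fragments'")
    raw_frags = doc["fragments"]
    if not raw_frags:
        raise TreeFormatError("empty 'fragments' array")

    intensities: list[float] = []
    parsed: list[tuple[int, dict[str, int], float]] = []
    formula_to_id: dict[str, int] = {}
    for k, fr in enumerate(raw_frags):
        if "molecularFormula" not in fr:
            raise TreeFormatError(f"fragment {k}: missing field 'molecularFormula'")
        if "mz" not in fr:
            raise TreeFormatError(f"fragment {k}: missing field 'mz'")
        comp = parse_formula(str(fr["molecularFormula"]), alphabet)
        nid = int(fr.get("id", k))
        inten = None
        for key in _INTENSITY_KEYS:
            if key in fr and fr[key] is not None:
                inten = float(fr[key])
                break
        if inten is None:
            logger.warning("%s fragment %d: missing relative intensity, using 0.0",
                           sample_id, nid)
            inten = 0.0
        parsed.append((nid, comp, float(fr["mz"])))
        intensities.append(inten)
        formula_to_id.setdefault(canonical_formula(comp), nid)

    peak = max(intensities)
    if peak <= 0:
        logger.warning("%s: all intensities missing or zero, using uniform 1.0", sample_id)
        intensities = [1.0] * len(intensities)
    else:
        intensities = [v / peak for v in intensities]

    nodes = [FragmentNode(node_id=nid, formula=comp, mz=mz, rel_intensity=iv)
             for (nid, comp, mz), iv in zip(parsed, intensities)]

    def endpoint(v) -> int:
        if isinstance(v, str) and not v.lstrip("-").isdigit():
            key = canonical_formula(parse_formula(v, alphabet))
            if key not in formula_to_id:
                raise TreeFormatError(f"loss endpoint formula {v!r} not among fragments")
            return formula_to_id[key]
        return int(v)

    edges = []
    for k, loss in enumerate(doc.get("losses", [])):
        if "source" not in loss or "target" not in loss:
            raise TreeFormatError(f"loss {k}: missing field 'source' or 'target'")
        edges.append((endpoint(loss["source"]), endpoint(loss["target"])))

    validate_tree_structure(nodes, edges)
    children = {c for _, c in edges}
    root = next(n for n in nodes if n.node_id not in children)
    precursor_mass = float(doc.get("precursorMass", doc.get("ionMass", root.mz)))
    if "precursorFormula" in doc:
        precursor_formula = parse_formula(str(doc["precursorFormula"]), alphabet)
    else:
        precursor_formula = dict(root.formula)
    return FragmentationTree(
        sample_id=str(doc.get("sampleId", sample_id)),
        nodes=nodes,
        edges=edges,
        precursor_mass=precursor_mass,
        precursor_formula=precursor_formula,
        adduct=doc.get("adduct"),
    )


def read_sirius_tree(path: str | Path,
                     alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> FragmentationTree:
    """Read a SIRIUS-style JSON fragmentation tree and validate it."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise TreeFormatError(f"{path}: invalid JSON ({e})") from e
    if not isinstance(doc, dict):
        raise TreeFormatError(f"{path}: top-level JSON must be an object")
    return _tree_from_doc(doc, sample_id=path.stem, alphabet=alphabet)


def tree_to_doc(tree: FragmentationTree) -> dict:
    """Serialize a tree to the canonical JSON document."""
    return {
        "sampleId": tree.sample_id,
        "precursorMass": tree.precursor_mass,
        "precursorFormula": canonical_formula(tree.precursor_formula),
        "adduct": tree.adduct,
        "fragments": [
            {"id": n.node_id, "molecularFormula": n.formula_str,
             "mz": n.mz, "relativeIntensity": n.rel_intensity}
            for n in tree.nodes
        ],
        "losses": [{"source": p, "target": c} for p, c in tree.edges],
    }


def write_tree(tree: FragmentationTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_doc(tree), indent=1))


_MB_FIELDS = ("CH$SMILES", "CH$IUPAC", "CH$FORMULA", "CH$EXACT_MASS")


def read_massbank_record(path: str | Path,
                         alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> CompoundRecord:
    """Parse a MassBank-style plain-text record into a :class:`CompoundRecord`.

    Recognized fields: ``ACCESSION``, ``CH$SMILES``, ``CH$IUPAC`` (InChI),
    ``CH$FORMULA``, ``CH$EXACT_MASS`` and ``MS$FOCUSED_ION: PRECURSOR_M/Z``.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    precursor_mz = None
    for line in path.read_text().splitlines():
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "MS$FOCUSED_ION" and value.startswith("PRECURSOR_M/Z"):
            precursor_mz = float(value.split()[-1])
        elif key not in fields:
            fields[key] = value

    smiles = fields.get("CH$SMILES")
    if smiles in ("N/A", ""):
        smiles = None
    inchi = fields.get("CH$IUPAC")
    if inchi is not None and not inchi.startswith("InChI="):
        inchi = None
    if not smiles and not inchi:
        raise MetadataError(f"{path}: record has neither CH$SMILES nor CH$IUPAC InChI")
    if "CH$FORMULA" not in fields:
        raise TreeFormatError(f"{path}: missing CH$FORMULA")
    if "CH$EXACT_MASS" not in fields:
        raise TreeFormatError(f"{path}: missing CH$EXACT_MASS")
    try:
        formula = parse_formula(fields["CH$FORMULA"], alphabet)
    except FormulaError as e:
        raise TreeFormatError(f"{path}: {e}") from e
    mass = float(fields["CH$EXACT_MASS"])
    sample_id = fields.get("ACCESSION", path.stem)
    rec = CompoundRecord(sample_id=sample_id, formula=formula,
                         monoisotopic_mass=mass, smiles=smiles, inchi=inchi)
    if precursor_mz is not None:
        rec.precursor_mz = precursor_mz  # type: ignore[attr-defined]
    return rec


LIBRARY_COLUMNS = ("id", "formula", "monoisotopic_mass", "smiles")


def read_candidate_library(path: str | Path,
                           alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> list[CandidateRecord]:
    """Read a tab-separated candidate library with header id/formula/monoisotopic_mass/smiles."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "formula": str, "smiles": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryIntegrityError(f"{path}: missing columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise LibraryIntegrityError(f"{path}: duplicate candidate id {dup!r}")
    if (df["monoisotopic_mass"] <= 0).any():
        raise LibraryIntegrityError(f"{path}: non-positive monoisotopic_mass")
    return [
        CandidateRecord(
            candidate_id=row.id,
            formula=parse_formula(row.formula, alphabet),
            monoisotopic_mass=float(row.monoisotopic_mass),
            smiles="" if pd.isna(row.smiles) else str(row.smiles),
        )
        for row in df.itertuples()
    ]


def write_candidate_library(candidates: list[CandidateRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [c.candidate_id for c in candidates],
            "formula": [canonical_formula(c.formula) for c in candidates],
            "monoisotopic_mass": [c.monoisotopic_mass for c in candidates],
            "smiles": [c.smiles for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
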