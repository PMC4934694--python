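"""Protein-RNA complex structures: parsing, interface annotation, dataset filters.

An *interface residue* is a protein residue with at least one atom within a
distance cutoff (default 5 Å) of any atom of a bound RNA molecule.  This module
parses PDB-format complexes, annotates interface residues, and applies the
admission criteria used to assemble structure-derived benchmark sets of
RNA-binding protein chains: resolution better than 3.5 Å, protein chains of at
least 40 residues, an RNA chain of at least 5 nucleotides in the complex, and
at least 3 interface residues per chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "InterfaceAnnotation",
    "FilterResult",
    "FormatError",
    "EmptyComplexError",
    "parse_complex",
    "annotate_interfaces",
    "filter_dataset",
    "greedy_identity_filter",
    "read_label_file",
    "write_label_file",
    "annotations_to_tsv",
]


class FormatError(ValueError):
    """Raised for unparseable structure or label text."""


class EmptyComplexError(ValueError):
    """Raised when a structure contains no protein chain."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # shape (3,), Å
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_index: int  # 1-based position within the chain
    code: str  # one-letter residue code ('X' for nonstandard amino acids)
    atoms: list[Atom]
    kind: str  # "protein" | "rna"

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")
        if self.kind not in ("protein", "rna"):
            raise ValueError(f"unknown residue kind {self.kind!r}")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    id: str
    protein_chains: list[list[Residue]]
    rna_chains: list[list[Residue]]
    resolution: float | None = None

    def __post_init__(self) -> None:
        ids = [c[0].chain_id for c in self.protein_chains + self.rna_chains if c]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")
        for chains, kind in ((self.protein_chains, "protein"), (self.rna_chains, "rna")):
            for chain in chains:
                for res in chain:
                    if res.kind != kind:
                        raise ValueError(
                            f"residue kind {res.kind!r} in {kind} chain {res.chain_id!r}"
                        )

    def protein_sequence(self, chain: list[Residue]) -> str:
        return "".join(r.code for r in chain)


@dataclass
class InterfaceAnnotation:
    chain_id: str
    sequence: str
    labels: np.ndarray  # binary, 1 = interface

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sequence):
            raise ValueError("labels and sequence must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_interface(self) -> int:
        return int(self.labels.sum())


# Residues that gemmi tabulates as amino acids but we map to 'X' are still
# retained positionally so sequence and label lengths track the structure.
_RNA_CODES = {"A", "C", "G", "U"}


def parse_complex(structure_text: str, structure_id: str = "") -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Protein residues are classified by the chemical-component tables bundled
    with gemmi; nonstandard amino acids become ``'X'`` but keep their position.
    Only standard ribonucleotides (A/C/G/U) populate RNA chains.  The first
    alternate location of each atom is kept; waters and other heteroatoms are
    ignored.
    """
    try:
        st = gemmi.read_pdb_string(structure_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB text: {exc}") from exc
    st.remove_alternative_conformations()  # hydrogens are kept: all atoms participate
    if len(st) == 0:
        raise FormatError("structure contains no model")

    protein_chains: list[list[Residue]] = []
    rna_chains: list[list[Residue]] = []
    for chain in st[0]:
        prot: list[Residue] = []
        rna: list[Residue] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            atoms = [
                Atom(element=a.element.name, coords=(a.pos.x, a.pos.y, a.pos.z), name=a.name)
                for a in res
            ]
            if not atoms:
                continue
            if info is not None and info.is_amino_acid():
                code = info.one_letter_code.upper() if info.is_standard() else "X"
                prot.append(
                    Residue(chain.name, len(prot) + 1, code, atoms, "protein")
                )
            elif info is not None and info.is_nucleic_acid() and res.name in _RNA_CODES:
                rna.append(Residue(chain.name, len(rna) + 1, res.name, atoms, "rna"))
            elif info is not None and info.is_water():
                continue
            # other heteroatoms (ions, ligands) are skipped
        if prot:
            protein_chains.append(prot)
        if rna:
            # disambiguate id if the same author chain held both polymer types
            if prot:
                for r in rna:
                    r.chain_id = chain.name + "_rna"
            rna_chains.append(rna)

    if not protein_chains:
        raise EmptyComplexError("structure has no protein chains")
    resolution = float(st.resolution) if st.resolution > 0 else None
    return ComplexStructure(
        id=structure_id or st.name or "complex",
        protein_chains=protein_chains,
        rna_chains=rna_chains,
        resolution=resolution,
    )


def annotate_interfaces(
    complex_: ComplexStructure, cutoff: float = 5.0
) -> list[InterfaceAnnotation]:
    """Label each protein residue 1 iff any of its atoms lies within ``cutoff``
    Å (inclusive) of any RNA atom in the complex.

    Returns one annotation per protein chain.  A complex with no RNA chains
    yields all-zero labels with a logged warning rather than an error.
    """
    if not complex_.protein_chains:
        raise EmptyComplexError("complex has no protein chains")
    rna_coords = [a.coords for ch in complex_.rna_chains for r in ch for a in r.atoms]
    annotations = []
    tree = cKDTree(np.asarray(rna_coords)) if rna_coords else None
    if tree is None:
        logger.warning("complex %s has no RNA chains; all labels 0", complex_.id)
    for chain in complex_.protein_chains:
        labels = np.zeros(len(chain), dtype=int)
        if tree is not None:
            for i, res in enumerate(chain):
                dmin, _ = tree.query(res.coords(), k=1)
                if np.min(dmin) <= cutoff:
                    labels[i] = 1
        annotations.append(
            InterfaceAnnotation(
                chain_id=chain[0].chain_id,
                sequence="".join(r.code for r in chain),
                labels=labels,
            )
        )
    return annotations


@dataclass
class FilterResult:
    kept: list[tuple[list[Residue], InterfaceAnnotation]]
    rejections: dict[str, int] = field(default_factory=dict)


def filter_dataset(
    complexes: list[ComplexStructure],
    min_resolution: float = 3.5,
    min_protein_len: int = 40,
    min_rna_len: int = 5,
    min_interfaces: int = 3,
    cutoff: float = 5.0,
) -> FilterResult:
    """Apply structure-derived admission criteria chain by chain.

    A chain is kept iff its parent complex resolves strictly below
    ``min_resolution`` Å, the chain has at least ``min_protein_len`` residues,
    the complex contains an RNA chain of at least ``min_rna_len`` nucleotides,
    and the chain has at least ``min_interfaces`` interface residues at the
    given cutoff.  Each rejected chain is counted under the first criterion it
    fails, in that order; missing resolution metadata counts as
    ``"unknown resolution"``.
    """
    kept: list[tuple[list[Residue], InterfaceAnnotation]] = []
    rejections: dict[str, int] = {
        "unknown resolution": 0,
        "resolution": 0,
        "length": 0,
        "rna_length": 0,
        "interfaces": 0,
    }
    for cx in complexes:
        annotations = annotate_interfaces(cx, cutoff=cutoff)
        has_long_rna = any(len(ch) >= min_rna_len for ch in cx.rna_chains)
        for chain, ann in zip(cx.protein_chains, annotations):
            if cx.resolution is None:
                rejections["unknown resolution"] += 1
            elif not cx.resolution < min_resolution:
                rejections["resolution"] += 1
            elif len(chain) < min_protein_len:
                rejections["length"] += 1
            elif not has_long_rna:
                rejections["rna_length"] += 1
            elif ann.n_interface < min_interfaces:
                rejections["interfaces"] += 1
            else:
                kept.append((chain, ann))
                continue
    return FilterResult(kept=kept, rejections=rejections)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment length (gaps included)."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


def greedy_identity_filter(sequences: list[str], max_identity: float = 0.30) -> list[str]:
    """Greedy longest-first redundancy reduction.

    Sequences are visited longest first (ties broken by input order); each is
    kept iff its pairwise global-alignment identity to every previously kept
    sequence is at most ``max_identity``.  This is a deliberately simple
    deterministic filter, not a reimplementation of clustering tools such as
    CD-HIT; it approximates the "at most 30% identity" admission criterion.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    aligner = _make_aligner()
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    kept: list[str] = []
    for i in order:
        seq = sequences[i]
        if all(pairwise_identity(seq, k, aligner) <= max_identity for k in kept):
            kept.append(seq)
    return kept


# ---------------------------------------------------------------------------
# Label-file I/O: per chain a '>' header, the sequence, and a same-length
# binary string (the layout of structure-derived benchmark label files).

def write_label_file(annotations: list[InterfaceAnnotation]) -> str:
    lines = []
    for ann in annotations:
        lines.append(f">{ann.chain_id}")
        lines.append(ann.sequence)
        lines.append("".join(str(x) for x in ann.labels))
    return "\n".join(lines) + "\n"


def read_label_file(text: str) -> list[InterfaceAnnotation]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError("label file must consist of header/sequence/labels triples")
    annotations = []
    for i in range(0, len(lines), 3):
        header, seq, lab = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise FormatError(f"expected '>' header at line {i + 1}")
        if len(seq) != len(lab) or not set(lab) <= {"0", "1"}:
            raise FormatError(f"bad label string for {header[1:]!r}")
        annotations.append(
            InterfaceAnnotation(header[1:], seq, np.array([int(c) for c in lab]))
        )
    return annotations


def annotations_to_tsv(annotations: list[InterfaceAnnotation]) -> str:
    """BED-like TSV: chain, 1-based position, residue, label."""
    rows = ["chain\tposition\tresidue\tlabel"]
    for ann in annotations:
        for pos, (res, lab) in enumerate(zip(ann.sequence, ann.labels), start=1):
            rows.append(f"{ann.chain_id}\t{pos}\t{res}\t{int(lab)}")
    return "\n".join(rows) + "\n"
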