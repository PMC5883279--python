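"""Codon-alignment I/O, validation, cleaning and concatenation.

In-frame protein-coding alignments are held as matrices of sense-codon
indices. Gap or ambiguous codons are allowed only before cleaning;
``clean_alignment`` applies complete deletion of any column containing one,
mirroring the removal of alignment gaps and uncertainties before dN/dS
estimation. Terminal stop codons are stripped on read; an internal stop is a
data error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .genetic_code import GAP_CODON, code_tables, translate_codon_indices


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


@dataclass
class CodonAlignment:
    """taxa x codon-site matrix over the sense codons of the genetic code."""

    gene_name: str
    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_sites) int16, GAP_CODON sentinel allowed pre-clean
    table_id: int = 1
    #: cleaned-column index -> original column index (identity if never cleaned)
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @property
    def is_clean(self) -> bool:
        return not (self.codons == GAP_CODON).any()

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def to_amino_acids(self) -> "AminoAcidAlignment":
        """Translate to an amino-acid alignment (cleaned alignments only)."""
        if not self.is_clean:
            raise AlignmentError(f"{self.gene_name}: translate requires a cleaned alignment")
        aa = translate_codon_indices(self.codons, self.table_id)
        return AminoAcidAlignment(self.gene_name, list(self.taxa), aa)


@dataclass
class AminoAcidAlignment:
    gene_name: str
    taxa: list[str]
    residues: np.ndarray  # (n_taxa, n_sites) int8 over PAML-order amino acids

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.residues.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.residues[self.taxa.index(taxon)]


def _encode_sequence(name: str, seq: str, table_id: int) -> np.ndarray:
    codons, codon_index, stops, _ = code_tables(table_id)
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise AlignmentError(f"{name}: length {len(seq)} not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(0, len(seq), 3):
        cod = seq[k : k + 3]
        if cod in codon_index:
            out[k // 3] = codon_index[cod]
        elif cod in stops:
            out[k // 3] = -2  # resolved by the caller (terminal strip vs error)
        else:
            out[k // 3] = GAP_CODON
    return out


def _rows_to_alignment(gene_name, names, seqs, table_id):
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"{gene_name}: sequences have unequal lengths {sorted(lengths)}")
    rows = [_encode_sequence(n, s, table_id) for n, s in zip(names, seqs)]
    mat = np.vstack(rows)
    # strip a trailing all-stop (or stop/gap) column: in-frame terminal stops
    if mat.shape[1] and (mat[:, -1] == -2).any() and np.isin(mat[:, -1], (-2, GAP_CODON)).all():
        mat = mat[:, :-1]
    stop_rows, stop_cols = np.nonzero(mat == -2)
    if stop_rows.size:
        r, c = stop_rows[0], stop_cols[0]
        raise AlignmentError(
            f"{gene_name}: internal stop codon in {names[r]} at codon site {c + 1}"
        )
    return CodonAlignment(gene_name, list(names), mat, table_id=table_id)


def read_gene_alignment(path, fmt: str = "fasta", gene_name: str | None = None,
                        table_id: int = 1) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA or relaxed PHYLIP.

    Terminal in-frame stop codons are stripped; internal stops raise
    :class:`AlignmentError` naming the taxon and codon site.
    """
    path = str(path)
    if gene_name is None:
        base = path.rsplit("/", 1)[-1]
        gene_name = base.split(".")[0]
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no sequences")
        names = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif fmt == "phylip":
        names, seqs = _read_relaxed_phylip(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    return _rows_to_alignment(gene_name, names, seqs, table_id)


def _read_relaxed_phylip(path):
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise AlignmentError(f"{path}: missing PHYLIP header")
        n, ln = int(header[0]), int(header[1])
        names, seqs = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise AlignmentError(f"{path}: malformed PHYLIP line {line!r}")
            names.append(parts[0])
            seqs.append(parts[1].replace(" ", "").strip())
        if len(names) != n:
            raise AlignmentError(f"{path}: expected {n} sequences, found {len(names)}")
        for nm, s in zip(names, seqs):
            if len(s) != ln:
                raise AlignmentError(f"{path}: {nm} has length {len(s)}, header says {ln}")
    return names, seqs


def decode_alignment(aln: CodonAlignment) -> list[str]:
    """Codon matrix back to nucleotide strings (gaps as '---')."""
    codons, _, _, _ = code_tables(aln.table_id)
    out = []
    for row in aln.codons:
        out.append("".join("---" if c == GAP_CODON else codons[c] for c in row))
    return out


def write_gene_alignment(aln: CodonAlignment, path, fmt: str = "fasta") -> None:
    seqs = decode_alignment(aln)
    with open(path, "w") as fh:
        if fmt == "fasta":
            for name, seq in zip(aln.taxa, seqs):
                fh.write(f">{name}\n{seq}\n")
        elif fmt == "phylip":
            fh.write(f" {aln.n_taxa} {aln.n_sites * 3}\n")
            for name, seq in zip(aln.taxa, seqs):
                fh.write(f"{name}  {seq}\n")
        else:
            raise ValueError(f"unknown alignment format {fmt!r}")


def clean_alignment(aln: CodonAlignment) -> CodonAlignment:
    """Complete deletion of codon columns containing any gap/ambiguous codon.

    The returned alignment carries a ``provenance`` array mapping cleaned
    column indices to columns of the input. Idempotent on clean alignments.
    """
    keep = ~(aln.codons == GAP_CODON).any(axis=0)
    if not keep.any():
        raise AlignmentError(f"{aln.gene_name}: all columns removed by cleaning")
    prov = np.nonzero(keep)[0]
    if aln.provenance is not None:
        prov = aln.provenance[prov]
    return replace(aln, codons=aln.codons[:, keep], provenance=prov)


def extract_codon_positions(aln: CodonAlignment, positions) -> list[str]:
    """Nucleotide alignment restricted to within-codon positions (1-based).

    Used to build 1st+2nd-position matrices for phylogenetic inference, where
    3rd positions are saturated. Returns one string per taxon, in order.
    """
    positions = sorted(set(positions))
    if not positions:
        raise ValueError("empty codon-position set")
    if not all(p in (1, 2, 3) for p in positions):
        raise ValueError("codon positions must be within {1, 2, 3}")
    rows = decode_alignment(aln)
    idx = [p - 1 for p in positions]
    return ["".join(row[3 * k + i] for k in range(aln.n_sites) for i in idx) for row in rows]


def read_class_map(path) -> dict[str, str]:
    """Gene -> functional class (photosynthesis / genetic_system) from TSV."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, cls = line.split("\t")[:2]
            mapping[gene] = cls
    return mapping


@dataclass
class ConcatenatedAlignment(CodonAlignment):
    """A class-level concatenation that remembers per-gene boundaries."""

    #: list of (gene_name, start, end) half-open codon-column spans
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def site_to_gene(self, site: int) -> tuple[str, int]:
        """Map a 0-based concatenated site to (gene, 0-based within-gene site)."""
        for gene, start, end in self.boundaries:
            if start <= site < end:
                return gene, site - start
        raise IndexError(f"site {site} outside concatenation of {self.n_sites} sites")


def concatenate_by_class(genes: list[CodonAlignment],
                         classes: dict[str, str]) -> dict[str, ConcatenatedAlignment]:
    """Concatenate gene alignments within each functional class.

    All genes must share one taxon set; rows are reordered to the first
    gene's taxon order. Boundary offsets allow mapping concatenated sites
    back to (gene, within-gene position).
    """
    if not genes:
        return {}
    ref_taxa = sorted(genes[0].taxa)
    out: dict[str, list] = {}
    for g in genes:
        if g.gene_name not in classes:
            raise AlignmentError(f"gene {g.gene_name} missing from the functional-class map")
        if sorted(g.taxa) != ref_taxa:
            missing = set(ref_taxa) ^ set(g.taxa)
            raise AlignmentError(f"gene {g.gene_name}: taxon-set mismatch ({sorted(missing)})")
        out.setdefault(classes[g.gene_name], []).append(g)
    result = {}
    for cls, members in out.items():
        order = members[0].taxa
        blocks, bounds, pos = [], [], 0
        for g in members:
            perm = [g.taxa.index(t) for t in order]
            blocks.append(g.codons[perm])
            bounds.append((g.gene_name, pos, pos + g.n_sites))
            pos += g.n_sites
        result[cls] = ConcatenatedAlignment(
            cls, list(order), np.hstack(blocks), table_id=members[0].table_id,
            boundaries=bounds)
    return result
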