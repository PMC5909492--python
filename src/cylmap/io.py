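"""Structures, population alignments and the mapping between them.

Structures are lightweight coordinate containers read from single-model PDB
files (gemmi does the parsing); population alignments are paired amino-acid /
nucleotide matrices with per-row clone counts, read from FASTA. The two are
linked by a residue-to-column map obtained by ungapped sliding of the
structure sequence along the alignment consensus.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq1

from .errors import InputError

GAP = "-"

#: codon -> amino acid (one letter, '*' for stop) under the standard code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

_COUNT_SUFFIX = re.compile(r"_n(\d+)$")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue: author index (string, insertion code preserved), 3-letter
    name, chain id and the ids of its member atoms."""

    index: str
    name: str
    chain: str
    atom_ids: tuple[int, ...]


@dataclass
class Structure:
    """A set of atoms with coordinates, grouped into residues and chains."""

    coords: np.ndarray              # (n_atoms, 3) in Angstrom
    atom_names: list[str]
    elements: list[str]
    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"non-finite coordinates in structure {self.label!r}")
        owned = [i for r in self.residues for i in r.atom_ids]
        if sorted(owned) != list(range(len(self.coords))):
            raise InputError("every atom must belong to exactly one residue")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def chain_residues(self, chain: str | None = None) -> list[Residue]:
        if chain is None:
            return list(self.residues)
        return [r for r in self.residues if r.chain == chain]

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of a chain ('X' for nonstandard residues)."""
        return "".join(
            seq1(r.name, undef_code="X") for r in self.chain_residues(chain)
        )

    def residue_coords(self, i: int) -> np.ndarray:
        return self.coords[list(self.residues[i].atom_ids)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=new, atom_names=list(self.atom_names),
                       elements=list(self.elements), residues=list(self.residues))

    def mean_size(self) -> float:
        """Mean atom-to-centroid distance (the subunit size scale s)."""
        return float(np.linalg.norm(self.coords - self.centroid(), axis=1).mean())


def read_structure(path: str) -> Structure:
    """Read a single-model PDB file.

    ATOM and HETATM records are retained in file order; for alternate
    locations only the highest-occupancy conformer of each atom is kept;
    insertion codes are preserved inside the string residue index.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise InputError(f"{path}: no model in file")
    model = st[0]
    coords: list[list[float]] = []
    atom_names: list[str] = []
    elements: list[str] = []
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            best: dict[str, tuple[float, int]] = {}
            ids: list[int] = []
            for atom in res:
                key = atom.name
                if key in best and atom.occ <= best[key][0]:
                    continue
                if key in best:  # replace lower-occupancy altloc in place
                    j = best[key][1]
                    coords[j] = [atom.pos.x, atom.pos.y, atom.pos.z]
                    elements[j] = atom.element.name
                    best[key] = (atom.occ, j)
                    continue
                j = len(coords)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                atom_names.append(atom.name)
                elements.append(atom.element.name)
                best[key] = (atom.occ, j)
                ids.append(j)
            index = f"{res.seqid.num}{res.seqid.icode.strip()}"
            residues.append(Residue(index, res.name, chain.name, tuple(ids)))
    if not coords:
        raise InputError(f"{path}: no ATOM/HETATM records")
    return Structure(np.array(coords), atom_names, elements, residues, label=str(path))


def write_structure(s: Structure, path: str) -> None:
    """Write a Structure back to PDB (coordinates kept to PDB precision)."""
    st = gemmi.Structure()
    st.name = s.label or "cylmap"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 1
    for r in s.residues:
        if r.chain not in chains:
            chains[r.chain] = gemmi.Chain(r.chain)
        res = gemmi.Residue()
        res.name = r.name
        m = re.match(r"(-?\d+)([A-Za-z]?)", r.index)
        num, icode = (int(m.group(1)), m.group(2) or " ") if m else (serial, " ")
        res.seqid = gemmi.SeqId(num, icode)
        for i in r.atom_ids:
            atom = gemmi.Atom()
            atom.name = s.atom_names[i]
            atom.element = gemmi.Element(s.elements[i])
            atom.pos = gemmi.Position(*s.coords[i])
            atom.occ = 1.0
            res.add_atom(atom)
            serial += 1
        chains[r.chain].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Population alignments
# ---------------------------------------------------------------------------

def translate_nt_row(nt: str) -> str:
    """Translate one aligned in-frame nucleotide row codon by codon.

    ``---`` becomes a gap; a codon with a partial gap or an ambiguous base
    becomes 'X'.
    """
    if len(nt) % 3:
        raise InputError("nucleotide row length not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i:i + 3].upper()
        if codon == GAP * 3:
            out.append(GAP)
        elif codon in CODON_TABLE:
            out.append(CODON_TABLE[codon])
        else:
            out.append("X")
    return "".join(out)


@dataclass
class PopulationAlignment:
    """Paired aa/nt multiple alignment with per-row clone copy counts.

    ``aa`` is (n_rows, L) of single characters; ``nt`` when present is
    (n_rows, 3L) and row-wise consistent with the translation of ``aa``.
    ``counts`` sum to the population (clone pool) size.
    """

    aa: np.ndarray
    counts: np.ndarray
    nt: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aa = np.asarray(self.aa, dtype="<U1")
        if self.aa.ndim != 2 or self.aa.size == 0:
            raise InputError("empty alignment")
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.aa.shape[0],) or np.any(self.counts < 1):
            raise InputError("counts must be positive, one per row")
        if not self.ids:
            self.ids = [f"row{i}" for i in range(self.aa.shape[0])]
        if self.nt is not None:
            self.nt = np.asarray(self.nt, dtype="<U1")
            if self.nt.shape != (self.aa.shape[0], 3 * self.aa.shape[1]):
                raise InputError("nt matrix must be rows x 3*L_aa")
            for j in range(self.nt.shape[0]):
                tr = translate_nt_row("".join(self.nt[j]))
                got = "".join(self.aa[j])
                if tr != got:
                    k = next(i for i, (a, b) in enumerate(zip(tr, got)) if a != b)
                    raise InputError(
                        f"row {self.ids[j]}: aa column {k} is {got[k]!r} but codon "
                        f"{''.join(self.nt[j, 3 * k:3 * k + 3])!r} translates to {tr[k]!r}"
                    )

    @property
    def n_rows(self) -> int:
        return self.aa.shape[0]

    @property
    def n_columns(self) -> int:
        return self.aa.shape[1]

    @property
    def population_size(self) -> int:
        return int(self.counts.sum())

    def aa_rows(self) -> list[str]:
        return ["".join(r) for r in self.aa]

    def nt_rows(self) -> list[str]:
        if self.nt is None:
            raise InputError("alignment has no nucleotide matrix")
        return ["".join(r) for r in self.nt]

    def consensus(self) -> str:
        """Count-weighted per-column majority character (ties: lexicographic)."""
        out = []
        for i in range(self.n_columns):
            tally: dict[str, int] = {}
            for j in range(self.n_rows):
                c = self.aa[j, i]
                tally[c] = tally.get(c, 0) + int(self.counts[j])
            out.append(min(tally, key=lambda c: (-tally[c], c)))
        return "".join(out)


def _default_count(record_id: str) -> int:
    m = _COUNT_SUFFIX.search(record_id)
    return int(m.group(1)) if m else 1


def read_population_fasta(
    nt_path: str | None = None,
    aa_path: str | None = None,
    counts: dict[str, int] | None = None,
) -> PopulationAlignment:
    """Read an aligned population FASTA (nt, aa or both).

    When only the nucleotide file is given, rows are translated internally
    with the standard code ('---' -> gap). Copy counts come from the
    ``counts`` mapping, else from a ``_n<int>`` id suffix, else 1. Duplicate
    records (identical at every supplied level) are merged with summed
    counts.
    """
    if nt_path is None and aa_path is None:
        raise InputError("need at least one of nt_path / aa_path")

    def load(path: str) -> tuple[list[str], list[str]]:
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise InputError(f"{path}: no FASTA records")
        seqs = [str(r.seq).upper() for r in recs]
        if len({len(s) for s in seqs}) != 1:
            raise InputError(f"{path}: ragged alignment (unequal sequence lengths)")
        return [r.id for r in recs], seqs

    if nt_path is not None:
        ids, nt_seqs = load(nt_path)
        if aa_path is not None:
            aa_ids, aa_seqs = load(aa_path)
            if len(aa_seqs) != len(nt_seqs):
                raise InputError("nt and aa files have different record counts")
        else:
            aa_seqs = [translate_nt_row(s) for s in nt_seqs]
    else:
        ids, aa_seqs = load(aa_path)
        nt_seqs = None

    n = len(ids)
    row_counts = [
        (counts or {}).get(ids[j], _default_count(ids[j])) for j in range(n)
    ]
    merged: dict[tuple, int] = {}
    merged_ids: dict[tuple, str] = {}
    order: list[tuple] = []
    for j in range(n):
        key = (aa_seqs[j], nt_seqs[j] if nt_seqs is not None else None)
        if key not in merged:
            merged[key] = 0
            merged_ids[key] = ids[j]
            order.append(key)
        merged[key] += row_counts[j]
    aa = np.array([list(k[0]) for k in order], dtype="<U1")
    nt = (
        np.array([list(k[1]) for k in order], dtype="<U1")
        if nt_seqs is not None
        else None
    )
    return PopulationAlignment(
        aa=aa,
        nt=nt,
        counts=np.array([merged[k] for k in order]),
        ids=[merged_ids[k] for k in order],
    )


def read_region_tsv(path: str) -> dict[str, np.ndarray]:
    """Region annotation sidecar: columns ``name`` and comma-separated
    1-based alignment column indices; returned 0-based."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "columns"} <= set(df.columns):
        raise InputError(f"{path}: expected columns 'name' and 'columns'")
    out: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        idx = np.array([int(x) - 1 for x in str(row["columns"]).split(",")])
        if np.any(idx < 0):
            raise InputError(f"{path}: region {row['name']}: indices are 1-based")
        out[str(row["name"])] = idx
    return out


def dedup_haplotypes(aln: PopulationAlignment, level: str = "aa") -> pd.DataFrame:
    """Unique haplotypes at the nt or aa level with counts and frequencies.

    Sorted by descending count; ties keep first-occurrence order.
    Frequencies sum to 1 over the clone pool.
    """
    if level not in ("nt", "aa"):
        raise InputError("level must be 'nt' or 'aa'")
    rows = aln.nt_rows() if level == "nt" else aln.aa_rows()
    tally: dict[str, int] = {}
    first: dict[str, int] = {}
    for j, s in enumerate(rows):
        if s not in tally:
            tally[s] = 0
            first[s] = j
        tally[s] += int(aln.counts[j])
    seqs = sorted(tally, key=lambda s: (-tally[s], first[s]))
    total = aln.population_size
    return pd.DataFrame(
        {
            "sequence": seqs,
            "count": [tally[s] for s in seqs],
            "frequency": [tally[s] / total for s in seqs],
        }
    )


# ---------------------------------------------------------------------------
# Structure <-> alignment mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueColumnMap:
    """Bijection between structure residue positions (of one chain) and
    alignment aa columns, found by ungapped sliding against the consensus."""

    chain: str
    offset: int
    identity: float
    pairs: tuple[tuple[int, int], ...]  # (residue position in chain, aa column)

    def column_of(self, residue_pos: int) -> int | None:
        for rp, col in self.pairs:
            if rp == residue_pos:
                return col
        return None

    def as_dict(self) -> dict[int, int]:
        return {rp: col for rp, col in self.pairs}


def map_structure_to_alignment(
    s: Structure,
    aln: PopulationAlignment,
    chain: str | None = None,
    min_identity: float = 0.9,
) -> ResidueColumnMap:
    """Slide the chain's residue sequence along the alignment consensus
    (no gaps) and keep the offset with maximal identity.

    Raises :class:`InputError` when the best identity falls below
    ``min_identity`` — usually a wrong chain or the wrong alignment.
    """
    chains = s.chains()
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise InputError(f"chain {chain!r} not in structure (has {chains})")
    seq = s.sequence(chain)
    cons = aln.consensus()
    if len(seq) > len(cons):
        raise InputError(
            f"chain {chain!r} has {len(seq)} residues, alignment only {len(cons)} columns"
        )
    best_offset, best_ident = 0, -1.0
    for off in range(len(cons) - len(seq) + 1):
        matches = sum(a == b for a, b in zip(seq, cons[off:off + len(seq)]))
        ident = matches / len(seq)
        if ident > best_ident:
            best_offset, best_ident = off, ident
    if best_ident < min_identity:
        raise InputError(
            f"best sliding identity {best_ident:.2f} < {min_identity}: "
            "wrong chain or wrong alignment?"
        )
    pairs = tuple((i, best_offset + i) for i in range(len(seq)))
    return ResidueColumnMap(chain=chain, offset=best_offset, identity=best_ident, pairs=pairs)
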