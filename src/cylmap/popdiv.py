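"""Population diversity statistics on pooled clone alignments.

Three measures drive everything downstream:

* per-column Shannon entropy (bits), count-weighted, gap as a 21st state;
* weighted amino-acid diversity pi over a column set — the average pairwise
  mismatch fraction across all clone pairs, with optional per-column weights:

      pi = 2 / (N (N-1) L) * sum_{j>k} sum_i (1 - I(A_ji, A_ki)) w_i

  where N is the clone pool size (copy counts honoured combinatorially,
  never by materializing rows) and L the number of selected columns;
* Nei–Gojobori-style dN/dS for a column set: per codon, expected
  synonymous / non-synonymous site counts come from enumerating the nine
  single-nucleotide neighbours; observed substitutions are the distinct
  single-nucleotide differences of each observed codon from the major
  (most frequent) codon, classified against the major-codon background.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CODON_TABLE, GAP, PopulationAlignment

#: sentinel returned when there is non-synonymous but no synonymous variation
UNDEFINED_HIGH = "undefined-high"
#: sentinel returned when a region carries no variation at all
NO_VARIATION = "no-variation"

_NT = "ACGT"


def shannon_profile(aln: PopulationAlignment) -> np.ndarray:
    """Count-weighted Shannon entropy (bits) per aa column; gap counts as a
    distinct 21st character state."""
    n_total = aln.population_size
    out = np.zeros(aln.n_columns)
    for i in range(aln.n_columns):
        tally: dict[str, int] = {}
        for j in range(aln.n_rows):
            c = aln.aa[j, i]
            tally[c] = tally.get(c, 0) + int(aln.counts[j])
        p = np.array(list(tally.values()), dtype=float) / n_total
        out[i] = float(-(p * np.log2(p)).sum()) if len(p) > 1 else 0.0
    return out


def pi_sites(
    aln: PopulationAlignment,
    columns: np.ndarray | list[int] | None = None,
    weights: np.ndarray | list[float] | None = None,
) -> float:
    """Weighted pairwise diversity over the selected columns.

    Pairs are enumerated over the expanded clone pool: a row with count c
    contributes c copies, so column mismatch mass is
    (N^2 - sum_a n_a^2) / 2 with n_a the per-state copy totals.
    """
    if columns is None:
        columns = np.arange(aln.n_columns)
    columns = np.asarray(columns, dtype=int)
    if columns.size == 0:
        raise InputError("empty column set")
    if np.any(columns < 0) or np.any(columns >= aln.n_columns):
        raise InputError("column index out of range")
    if weights is None:
        w = np.ones(columns.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (columns.size,) or np.any(w < 0):
            raise InputError("weights must be nonnegative, one per column")
    n = aln.population_size
    if n < 2:
        raise InputError("need a population of at least 2 sequences")
    counts = aln.counts.astype(float)
    acc = 0.0
    for wi, col in zip(w, columns):
        if wi == 0.0:
            continue
        tally: dict[str, float] = {}
        for j in range(aln.n_rows):
            c = aln.aa[j, col]
            tally[c] = tally.get(c, 0.0) + counts[j]
        na = np.array(list(tally.values()))
        mismatch_pairs = (n * n - float(na @ na)) / 2.0
        acc += wi * mismatch_pairs
    return 2.0 * acc / (n * (n - 1) * columns.size)


@lru_cache(maxsize=None)
def ng_codon_sites(codon: str) -> tuple[float, float]:
    """Expected (non-synonymous, synonymous) site counts of one codon.

    Each of the three positions contributes the fraction of its three
    single-nucleotide alternatives that are non-synonymous / synonymous;
    mutations to stop codons count as non-synonymous. The two counts sum
    to 3 exactly.
    """
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise InputError(f"not a codon: {codon!r}")
    aa = CODON_TABLE[codon]
    n_site = 0.0
    s_site = 0.0
    for pos in range(3):
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                s_site += 1.0 / 3.0
            else:
                n_site += 1.0 / 3.0
    return n_site, s_site


@dataclass(frozen=True)
class CodonColumnCounts:
    """Substitution and site counts for one aa column of the alignment."""

    k_n_sub: float
    k_s_sub: float
    k_n_site: float
    k_s_site: float

    def __add__(self, other: "CodonColumnCounts") -> "CodonColumnCounts":
        return CodonColumnCounts(
            self.k_n_sub + other.k_n_sub,
            self.k_s_sub + other.k_s_sub,
            self.k_n_site + other.k_n_site,
            self.k_s_site + other.k_s_site,
        )


def codon_column_counts(aln: PopulationAlignment, aa_column: int) -> CodonColumnCounts:
    """Count substitutions and expected sites at one codon column.

    The major codon is the count-weighted most frequent gap-free codon
    (ties broken lexicographically). Site counts are the Nei–Gojobori
    expectations averaged over gap-free rows, count-weighted. Substitutions
    are the distinct single-nucleotide differences of each observed codon
    from the major one, decomposed position-wise and classified
    synonymous / non-synonymous against the major codon background.
    """
    if aln.nt is None:
        raise InputError("alignment has no nucleotide matrix")
    if not 0 <= aa_column < aln.n_columns:
        raise InputError("aa column out of range")
    lo = 3 * aa_column
    codons = ["".join(aln.nt[j, lo:lo + 3]).upper() for j in range(aln.n_rows)]
    usable = [(c, int(aln.counts[j])) for j, c in enumerate(codons) if c in CODON_TABLE]
    if not usable:
        raise InputError(f"aa column {aa_column}: no gap-free codon in any row")
    tally: dict[str, int] = {}
    for c, cnt in usable:
        tally[c] = tally.get(c, 0) + cnt
    major = min(tally, key=lambda c: (-tally[c], c))
    total = sum(tally.values())
    n_site = sum(ng_codon_sites(c)[0] * cnt for c, cnt in tally.items()) / total
    s_site = sum(ng_codon_sites(c)[1] * cnt for c, cnt in tally.items()) / total
    k_n_sub = 0.0
    k_s_sub = 0.0
    major_aa = CODON_TABLE[major]
    for variant in tally:
        if variant == major:
            continue
        for pos in range(3):
            if variant[pos] == major[pos]:
                continue
            mutant = major[:pos] + variant[pos] + major[pos + 1:]
            if CODON_TABLE[mutant] == major_aa:
                k_s_sub += 1.0
            else:
                k_n_sub += 1.0
    return CodonColumnCounts(k_n_sub, k_s_sub, n_site, s_site)


def dnds_region(
    aln: PopulationAlignment,
    columns: np.ndarray | list[int] | None = None,
    weights: np.ndarray | list[float] | None = None,
) -> float | str:
    """Weighted dN/dS over a set of aa columns.

        (sum k_n_sub w / sum k_n_site w) / (sum k_s_sub w / sum k_s_site w)

    Returns :data:`NO_VARIATION` when neither substitution class is
    observed and :data:`UNDEFINED_HIGH` when only non-synonymous variation
    exists (the synonymous rate denominator vanishes).
    """
    if columns is None:
        columns = np.arange(aln.n_columns)
    columns = np.asarray(columns, dtype=int)
    if columns.size == 0:
        raise InputError("empty column set")
    if weights is None:
        w = np.ones(columns.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (columns.size,) or np.any(w < 0):
            raise InputError("weights must be nonnegative, one per column")
    per_col = [codon_column_counts(aln, int(col)) for col in columns]
    return dnds_from_counts(per_col, w)


def dnds_from_counts(
    counts: list[CodonColumnCounts],
    weights: np.ndarray | list[float],
) -> float | str:
    """The weighted dN/dS ratio from precomputed per-column counts."""
    w = np.asarray(weights, dtype=float)
    nsub = ssub = nsite = ssite = 0.0
    for wi, c in zip(w, counts):
        nsub += c.k_n_sub * wi
        ssub += c.k_s_sub * wi
        nsite += c.k_n_site * wi
        ssite += c.k_s_site * wi
    if nsub == 0.0 and ssub == 0.0:
        return NO_VARIATION
    if ssub == 0.0:
        return UNDEFINED_HIGH
    dn = nsub / nsite if nsite > 0 else 0.0
    ds = ssub / ssite
    return dn / ds


def region_pi_table(
    aln: PopulationAlignment,
    regions: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """pi (unit weights) per named region of alignment columns."""
    if regions is None:
        regions = aln.regions
    if not regions:
        raise InputError("no regions given")
    rows = []
    for name, cols in regions.items():
        cols = np.asarray(cols, dtype=int)
        if cols.size == 0:
            raise InputError(f"region {name!r} is empty")
        rows.append({"region": name, "n_columns": cols.size,
                     "pi": pi_sites(aln, cols)})
    return pd.DataFrame(rows)
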