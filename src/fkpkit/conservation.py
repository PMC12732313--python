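"""Reference-anchored residue-conservation census over an MSA.

Positions of interest are given on the ungapped coordinate system of a
reference row (e.g. G75 or R597 of the TxFKP enzyme) and mapped to
alignment columns.  Rows whose alignment only begins after a boundary
position (sequences lacking the N-terminal region entirely) are
excluded, per-position conservation is the fraction of retained rows
carrying the reference residue, and rows missing one or more positions
can be stratified by phylogenetic clade.

"Conserved" means strict residue identity (case-insensitive); a gap at a
scored column counts as non-conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO

log = logging.getLogger(__name__)

__all__ = [
    "read_alignment",
    "RefPositionMap",
    "parse_positions",
    "map_ref_positions",
    "apply_exclusion",
    "conservation_fraction",
    "stratify_missing",
]

GAP = "-"


def read_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> gapped-sequence mapping."""
    aln = AlignIO.read(path, "fasta")
    rows = {rec.id: str(rec.seq) for rec in aln}
    if len(rows) != len(aln):
        raise ValueError("duplicate sequence ids in alignment")
    return rows


def _check_alignment(aln: dict[str, str]) -> int:
    if not aln:
        raise ValueError("empty alignment")
    widths = {len(s) for s in aln.values()}
    if len(widths) != 1:
        raise ValueError(f"rows differ in length: {sorted(widths)}")
    return widths.pop()


@dataclass(frozen=True)
class RefPositionMap:
    """Reference-anchored positions resolved to 0-based alignment columns."""

    ref_id: str
    positions: tuple[tuple[int, str], ...]  # (1-based ungapped position, residue)
    columns: tuple[int, ...]  # 0-based alignment columns, parallel to positions


def parse_positions(tokens) -> list[tuple[int, str]]:
    """Parse ``["G75", "R597", ...]`` into (position, residue) pairs."""
    out = []
    for tok in tokens:
        out.append((int(tok[1:]), tok[0].upper()))
    if any(p <= 0 for p, _ in out):
        raise ValueError("positions are 1-based and must be positive")
    if out != sorted(out):
        raise ValueError("reference positions must be strictly increasing")
    return out


def _ref_columns(ref_row: str) -> list[int]:
    """For each ungapped reference position p (1-based), its alignment column."""
    return [c for c, ch in enumerate(ref_row) if ch != GAP]


def map_ref_positions(
    aln: dict[str, str], ref_id: str, positions
) -> RefPositionMap:
    """Resolve reference positions to alignment columns.

    Column c for position p satisfies: the number of non-gap reference
    characters in columns <= c equals p.  Errors if a stated residue does
    not match the reference row at the resolved column.
    """
    _check_alignment(aln)
    if ref_id not in aln:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    pairs = parse_positions(positions) if positions and isinstance(
        next(iter(positions)), str
    ) else sorted(positions)
    ref_row = aln[ref_id]
    cols_by_pos = _ref_columns(ref_row)
    resolved = []
    for pos, residue in pairs:
        if pos > len(cols_by_pos):
            raise IndexError(
                f"position {pos} beyond reference length {len(cols_by_pos)}"
            )
        col = cols_by_pos[pos - 1]
        found = ref_row[col].upper()
        if found != residue:
            raise ValueError(
                f"reference residue mismatch at position {pos}: "
                f"expected {residue}, found {found}"
            )
        resolved.append(col)
    return RefPositionMap(ref_id, tuple(pairs), tuple(resolved))


def apply_exclusion(
    aln: dict[str, str], ref_id: str, boundary: int
) -> list[str]:
    """Retain rows that align with the reference at or before ``boundary``.

    A row is excluded iff it is gapped in *every* column corresponding to
    reference positions 1..boundary — i.e. its alignment to the reference
    starts only after the boundary residue.  The reference row is always
    retained.
    """
    _check_alignment(aln)
    if ref_id not in aln:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    cols = _ref_columns(aln[ref_id])
    if not 1 <= boundary <= len(cols):
        raise ValueError(f"boundary {boundary} outside reference length")
    window = cols[:boundary]
    retained = []
    for rid, row in aln.items():
        if rid == ref_id or any(row[c] != GAP for c in window):
            retained.append(rid)
    return retained


def conservation_fraction(
    aln: dict[str, str], ref_map: RefPositionMap, retained
) -> pd.DataFrame:
    """Percent of retained rows matching the reference at each position.

    Returns a table with columns position, residue, column, n_retained,
    n_conserved, percent.  Gaps count as non-conserved.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained row set must be nonempty")
    rows = []
    for (pos, residue), col in zip(ref_map.positions, ref_map.columns):
        n_cons = sum(1 for rid in retained if aln[rid][col].upper() == residue)
        rows.append(
            {
                "position": pos,
                "residue": residue,
                "column": col,
                "n_retained": len(retained),
                "n_conserved": n_cons,
                "percent": 100.0 * n_cons / len(retained),
            }
        )
    return pd.DataFrame(rows)


def stratify_missing(
    aln: dict[str, str],
    ref_map: RefPositionMap,
    retained,
    clade_labels: dict[str, str],
    position_subset=None,
) -> pd.Series:
    """Clade distribution of rows non-conserved at >= 1 subset position.

    ``position_subset`` is a list of 1-based reference positions (default:
    all mapped positions).  Returns per-clade fractions summing to 1, or
    an empty Series with a warning when no row lacks any subset position.
    """
    retained = list(retained)
    unlabeled = [r for r in retained if r not in clade_labels]
    if unlabeled:
        raise KeyError(f"rows missing clade labels: {unlabeled[:10]}")
    wanted = set(position_subset) if position_subset else {
        p for p, _ in ref_map.positions
    }
    cols = [
        (col, residue)
        for (pos, residue), col in zip(ref_map.positions, ref_map.columns)
        if pos in wanted
    ]
    lacking = [
        rid
        for rid in retained
        if any(aln[rid][col].upper() != residue for col, residue in cols)
    ]
    if not lacking:
        log.warning("no retained row lacks any of the requested positions")
        return pd.Series(dtype=float)
    counts = pd.Series([clade_labels[r] for r in lacking]).value_counts()
    return counts / counts.sum()
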